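"""Term-structured fixed-effect designs.

Model selection here operates on *terms*, not columns: a sine/cosine
pair of one harmonic period enters and leaves the model as a unit, a
categorical factor contributes all its dummy columns jointly, and an
interaction cannot outlive its main effects (marginality).  Each
:class:`Term` therefore names a block of product columns over a base
frame, plus the terms it is marginal to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Term", "build_design", "interaction"]


@dataclass(frozen=True)
class Term:
    """A named block of design columns.

    ``columns`` maps output column name -> list of base-frame columns
    whose product forms it (empty list = constant 1).  ``parents`` are
    the names of terms that must stay in a model while this term is
    present is *their* responsibility; concretely a term may only be
    dropped when no retained term lists it among its ``parents``.
    """

    name: str
    columns: tuple[tuple[str, tuple[str, ...]], ...]
    protected: bool = False
    parents: tuple[str, ...] = ()

    @staticmethod
    def make(name: str, columns: dict[str, list[str]], protected: bool = False,
             parents: tuple[str, ...] = ()) -> "Term":
        return Term(
            name=name,
            columns=tuple((k, tuple(v)) for k, v in columns.items()),
            protected=protected,
            parents=parents,
        )

    @property
    def column_names(self) -> list[str]:
        return [c for c, _ in self.columns]


def interaction(a: Term, b: Term, name: str | None = None,
                parents: tuple[str, ...] | None = None) -> Term:
    """Product term of two terms (all pairwise column products)."""
    cols: dict[str, list[str]] = {}
    for ca, fa in a.columns:
        for cb, fb in b.columns:
            cols[f"{ca}:{cb}"] = list(fa) + list(fb)
    if parents is None:
        parents = (a.name, b.name)
    return Term.make(name or f"{a.name}:{b.name}", cols, parents=parents)


def build_design(frame: pd.DataFrame, terms: list[Term]) -> tuple[np.ndarray, list[str]]:
    """Materialise the stacked design matrix and its column names."""
    n = len(frame)
    blocks, names = [], []
    for term in terms:
        for col_name, factors in term.columns:
            if not factors:
                col = np.ones(n)
            else:
                col = np.ones(n)
                for f in factors:
                    col = col * frame[f].to_numpy(dtype=float)
            blocks.append(col)
            names.append(col_name)
    X = np.column_stack(blocks) if blocks else np.empty((n, 0))
    return X, names
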