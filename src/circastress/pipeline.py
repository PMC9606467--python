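"""End-to-end pipeline: simulate -> group -> fit, with a run manifest.

Artifacts are plain delimited text (UTF-8, header row, '.' decimal) and
JSON fit reports; the manifest records the config hash, seed, library
versions and per-stage row counts so identical configurations produce
identical directories.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, dump_config
from .cohort import generate_profiles
from .groups import assign_groups
from .models import (
    fit_circadian_overall,
    fit_circadian_split,
    fit_night_rmssd,
    fit_reactivity,
)
from .simulate import aggregate_mist, generate_hourly_cohort, generate_mist_cohort

__all__ = ["run_pipeline", "fit_report"]


def fit_report(results) -> dict:
    """JSON-serialisable report of one fitted mixed model."""
    fit = results.fit
    report = {
        "coefficients": {
            name: {
                "estimate": float(fit.params[name]),
                "se": float(fit.bse[name]),
                "t": float(fit.tvalues[name]),
                "p": float(fit.pvalues[name]),
            }
            for name in fit.params.index
        },
        "varcomp": {k: float(v) for k, v in fit.vc.items()},
        "residual_var": fit.scale,
        "loglik": fit.loglik,
        "aic": fit.aic,
        "n_obs": fit.n_obs,
        "n_subjects": fit.n_groups,
        "converged": fit.converged,
        "singular": fit.singular,
        "r2_conditional": fit.r2_conditional,
        "method": fit.method,
    }
    if results.stepwise_trace is not None:
        report["stepwise_trace"] = results.stepwise_trace.to_dict(orient="records")
    return report


def _require(path: Path, stage: str) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs {path.name}, which was not produced in this run "
            f"and does not exist in {path.parent}; enable the upstream stage or "
            f"place the file there"
        )
    return pd.read_csv(path)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run the configured stages and return the manifest.

    Stages: 'simulate' (cohort, hourly physiology, stress-task minutes),
    'group' (depression/chronic-stress labels), 'fit' (overall + split
    circadian models, night RMSSD, reactivity + contrasts, simulated
    curves).  Later stages read earlier artifacts from ``out_dir`` when
    a stage is toggled off.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_text = dump_config(config)
    manifest: dict = {
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": config.seed,
        "versions": {
            "circastress": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "rows": {},
    }
    (out / "config.yaml").write_text(config_text, encoding="utf-8")

    profiles = hourly = mist = groups = None
    if "simulate" in config.stages:
        profiles = generate_profiles(config.cohort, seed=config.seed)
        hourly = generate_hourly_cohort(
            profiles, config.effects, config.schedule, seed=config.seed
        )
        mist = generate_mist_cohort(profiles, config.effects, seed=config.seed)
        profiles.to_csv(out / "cohort.csv", index=False)
        hourly.to_csv(out / "hourly.csv", index=False)
        mist.to_csv(out / "mist.csv", index=False)
    elif {"group", "fit"} & set(config.stages):
        profiles = _require(out / "cohort.csv", "group")
        if "fit" in config.stages:
            hourly = _require(out / "hourly.csv", "fit")
            mist = _require(out / "mist.csv", "fit")
    for name, frame in (("cohort", profiles), ("hourly", hourly), ("mist", mist)):
        if frame is not None:
            manifest["rows"][name] = len(frame)

    if "group" in config.stages:
        assignment = assign_groups(profiles, mode=config.pss_mode)
        groups = assignment.table
        groups.to_csv(out / "groups.csv", index=False)
        manifest["pss_cuts"] = list(assignment.pss_cuts)
    elif "fit" in config.stages:
        groups = _require(out / "groups.csv", "fit")
    if groups is not None:
        manifest["rows"]["groups"] = len(groups)

    if "fit" in config.stages:
        overall = fit_circadian_overall(hourly, profiles, groups,
                                        stepwise=config.stepwise)
        (out / "fit_circadian_overall.json").write_text(
            json.dumps(fit_report(overall), indent=1), encoding="utf-8"
        )
        overall.simulate_curves().to_csv(out / "curves.csv", index=False)
        merged = hourly.merge(groups, on="pid")
        for stratum in ("low", "high"):
            if (merged.drop_duplicates("pid")["dep_group"] == stratum).sum() < 2:
                continue
            res = fit_circadian_split(hourly, profiles, groups, stratum=stratum)
            (out / f"fit_circadian_{stratum}_dep.json").write_text(
                json.dumps(fit_report(res), indent=1), encoding="utf-8"
            )
        night = fit_night_rmssd(hourly, profiles, groups)
        (out / "fit_night_rmssd.json").write_text(
            json.dumps(fit_report(night), indent=1), encoding="utf-8"
        )
        records = aggregate_mist(mist, qi_threshold=config.qi_threshold)
        react = fit_reactivity(records, groups=groups,
                               contrast_weights=config.contrast_weights)
        (out / "reactivity_fit.csv").write_text(
            react.coefficients().to_csv(), encoding="utf-8"
        )
        contrasts = pd.concat(
            [
                react.pairwise_contrasts("dep_group"),
                react.pairwise_contrasts("stress_group"),
            ],
            ignore_index=True,
        )
        contrasts.to_csv(out / "contrasts.csv", index=False)
        manifest["rows"]["contrasts"] = len(contrasts)

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8"
    )
    return manifest
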