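import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from circastress.config import CohortConfig, PlantedEffects
from circastress.cohort import generate_profiles
from circastress.simulate import generate_hourly_cohort

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def zero_effects(**overrides) -> PlantedEffects:
    """Planted effects with every coefficient and SD zeroed (then overridden)."""
    eff = PlantedEffects(
        beta0=np.log(65.0),
        target_mean_hr=None,
        harmonic_betas={k: 0.0 for k in PlantedEffects().harmonic_betas},
        covariate_betas={k: 0.0 for k in PlantedEffects().covariate_betas},
        dep_main=0.0,
        stress_main={"high": 0.0, "extreme": 0.0},
        dep_stress_main={"high": 0.0, "extreme": 0.0},
        dep_stress_circadian={},
    ).with_zero_noise()
    for key, value in overrides.items():
        setattr(eff, key, value)
    return eff


@pytest.fixture(scope="session")
def boosted_config() -> CohortConfig:
    """Cohort with enriched depression/extreme-stress arms for estimability."""
    return CohortConfig(
        n_participants=120, dep_high_prob=0.3, stress_group_probs=(0.4, 0.3, 0.3)
    )


@pytest.fixture(scope="session")
def boosted_cohort(boosted_config) -> pd.DataFrame:
    return generate_profiles(boosted_config, seed=7)


@pytest.fixture(scope="session")
def noiseless_hourly(boosted_cohort):
    """Deterministic hourly series with all planted defaults but zero SDs."""
    effects = PlantedEffects(target_mean_hr=None).with_zero_noise()
    return (
        generate_hourly_cohort(boosted_cohort, effects, seed=7),
        effects,
    )
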