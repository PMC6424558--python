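import numpy as np
import pandas as pd
import pytest

from gestage import SimulationConfig, simulate_cohort
from gestage.panel import default_panel


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_infants=300, seed=123)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def big_cohort():
    """n=5000 cohort used for distributional-recovery checks."""
    return simulate_cohort(SimulationConfig(n_infants=5000, seed=7))


def make_linear_cohort(n: int, seed: int, noise_sd: float = 0.0, active=None):
    """Cohort whose GA is an exact (or noisy) linear function of a few
    analytes -- the parameter-recovery oracle fixture.

    Returns (records, true_coefs) where true_coefs maps analyte -> slope
    on the raw scale.
    """
    rng = np.random.default_rng(seed)
    panel = default_panel()
    active = active or {"ALA": 0.008, "TSH": -0.15, "HBFA_RATIO": -0.8, "TYR": 0.01, "C5": 5.0}
    data = {}
    for name in panel.names:
        data[name] = rng.uniform(0.5, 10.0, n)
    ga = 39.0 + sum(c * (data[a] - np.mean(data[a])) for a, c in active.items())
    ga = ga + rng.normal(0, noise_sd, n) if noise_sd else ga
    records = pd.DataFrame(data)
    records.insert(0, "infant_id", [f"I{i}" for i in range(n)])
    records.insert(1, "sample_id", [f"S{i}" for i in range(n)])
    records.insert(2, "sample_type", "heel")
    records.insert(3, "sex", np.where(rng.random(n) < 0.5, "male", "female"))
    records.insert(4, "multiple_birth", np.arange(n) % 2)
    records.insert(5, "birthweight_g", rng.normal(2900, 400, n))
    records["ga_obs_weeks"] = ga
    records["age_at_collection_h"] = rng.uniform(1, 30, n)
    return records, active
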