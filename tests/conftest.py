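import numpy as np
import pandas as pd
import pytest

from crprog import Cohort, MIConfig, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def cohort_n2000() -> Cohort:
    return simulate_cohort(SimulationConfig(n_subjects=2000), seed=20260101)


@pytest.fixture(scope="session")
def cohort_n5000() -> Cohort:
    return simulate_cohort(SimulationConfig(n_subjects=5000), seed=20260102)


@pytest.fixture()
def desk_config() -> MIConfig:
    return MIConfig.desk(seed=7)


@pytest.fixture()
def toy_competing_df() -> pd.DataFrame:
    """Four subjects: cause-1 deaths at t=1 and 4, cause-2 death at t=2,
    censoring at t=3 (the worked example threaded through the estimation
    tests)."""
    return pd.DataFrame(
        {
            "time": [1.0, 2.0, 3.0, 4.0],
            "event": [1, 2, 0, 1],
        }
    )


def make_raw_cohort(n=50, seed=0, p_missing=0.3):
    """Small raw (uncoded) cohort table for I/O tests."""
    rng = np.random.default_rng(seed)
    c3s = rng.choice(["D3", "M3", ""], p=[0.4, 0.3, 0.3], size=n)
    outcome = rng.choice(["alive", 1, 2, 3, 4, 5, 6], size=n)
    return pd.DataFrame(
        {
            "id": [f"p{i}" for i in range(n)],
            "lbtd_mm": rng.uniform(2.5, 27.5, n).round(1),
            "age_years": rng.uniform(25, 95, n).round(0),
            "sex": rng.choice(["male", "female"], n),
            "c3s": c3s,
            "followup_years": rng.uniform(0.1, 20, n).round(2),
            "outcome": outcome,
        }
    )
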