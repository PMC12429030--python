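import numpy as np
import pandas as pd
import pytest

from axsurv.cohort import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort_10k():
    cfg = SimulationConfig.from_dict({"n": 10_000})
    return generate_cohort(cfg, seed=20240901)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_records():
    """20-record table with both exposure groups for oracle fixtures."""
    rng = np.random.default_rng(7)
    n = 20
    return pd.DataFrame({
        "id": np.arange(n),
        "age_group": rng.choice(["<50", "50-74", ">=75"], n),
        "year_dx": rng.integers(2000, 2021, n),
        "t_category": rng.integers(1, 3, n),
        "n_category": rng.integers(0, 2, n),
        "histology": rng.choice(["ductal", "lobular"], n),
        "grade": rng.integers(1, 4, n),
        "er": rng.integers(0, 2, n),
        "pr": rng.integers(0, 2, n),
        "her2": rng.integers(0, 2, n),
        "bcs": rng.integers(0, 2, n),
        "systemic": rng.integers(0, 2, n),
        "radiotherapy": rng.integers(0, 2, n),
        "months_dx_to_tx": rng.gamma(1.0, 1.0, n),
        "nodes_removed": rng.integers(1, 20, n),
        "nodes_positive": np.zeros(n, dtype=int),
        "surv_months": rng.exponential(80, n).round(1) + 0.5,
        "event": rng.integers(0, 2, n),
        "final_label": np.r_[["ALND"] * 8, ["SLNB"] * 12],
    })
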