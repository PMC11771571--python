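import warnings

import numpy as np
import pandas as pd
import pytest

import jmbiexp as jm
from jmbiexp.data import preprocess_covariates

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_truth():
    return jm.default_truth(n_patients=100)


@pytest.fixture(scope="session")
def small_block(small_truth):
    """One simulated competing-risks block with preprocessed covariates."""
    blk = jm.simulate_block(small_truth, seed=3)
    ds = blk.dataset
    cov, spec = preprocess_covariates(ds.covariates, log_columns=("albumin",))
    processed = jm.BlockDataset(ds.block_id, ds.series, ds.outcomes, cov,
                                ds.n_events)
    return blk, processed


@pytest.fixture(scope="session")
def joint_fit(small_block):
    """A gated joint fit of the small block, shared across test modules."""
    _, ds = small_block
    return jm.fit_joint(ds, chains=2, n_warmup=400, n_samples=1000, seed=42)


def make_tiny_block(n=8, seed=0, n_events=2):
    """Hand-size block for IO/contract tests."""
    rng = np.random.default_rng(seed)
    rows_l, rows_s, rows_c = [], [], []
    for i in range(n):
        pid = f"P{i}"
        T = float(rng.uniform(50, 300))
        ev = int(rng.integers(0, n_events + 1))
        rows_s.append((pid, T, ev))
        for k in (1, 2):
            times = np.sort(rng.uniform(0, T, size=rng.integers(0, 5)))
            for t in times:
                rows_l.append((pid, k, float(t), float(rng.uniform(1, 30))))
        rows_c.append((pid, float(rng.uniform(40, 80)),
                       "A" if rng.uniform() < 0.6 else "B"))
    longitudinal = pd.DataFrame(rows_l, columns=["patient_id", "biomarker_id",
                                                 "time", "value"])
    survival = pd.DataFrame(rows_s, columns=["patient_id", "time", "event"])
    covariates = pd.DataFrame(rows_c, columns=["patient_id", "age", "group"])
    return longitudinal, survival, covariates
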