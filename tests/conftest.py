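import numpy as np
import pandas as pd
import pytest

from cagnet.simulate import SimConfig, simulate_cohort, simulate_genus_table


@pytest.fixture(scope="session")
def small_config():
    """A small planted-block design used across modules."""
    return SimConfig(
        n_cases=60, n_controls=60, n_genera=18, n_blocks=3,
        block_sizes=(7, 6, 5), within_block_rho=0.8,
        effect_blocks={1: 0.8}, n_pathways=12, seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return small_cohort["genus"]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_table(array, prefix="g", index=None):
    """Wrap a 2-D array as a samples x features DataFrame."""
    arr = np.asarray(array, dtype=float)
    idx = index if index is not None else [f"s{i}" for i in range(arr.shape[0])]
    cols = [f"{prefix}{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=pd.Index(idx, name="sample_id"), columns=cols)
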