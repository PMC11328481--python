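import numpy as np
import pandas as pd
import pytest

from qimbalance import synth


def make_sample_table(p_low, groups, pair_ids=None):
    n = len(p_low)
    return pd.DataFrame({
        "sample_id": [f"s{i:03d}" for i in range(n)],
        "group": list(groups),
        "p_low": list(p_low),
        "pair_id": pair_ids if pair_ids is not None else [pd.NA] * n,
    })


@pytest.fixture(scope="session")
def small_dataset():
    """One 8+8 sample, 400-gene dataset with planted structure."""
    cfg = synth.SimConfig(
        n_control=8, n_disease=8, n_genes=400,
        n_low_markers=40, n_high_markers=40, n_disease_genes=30,
        qi_target=0.3, seed=11,
    )
    return synth.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260101)
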