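import pandas as pd
import pytest

from neutralstab.datamodel import CountTable, SampleFrame
from neutralstab.simulate import (
    NeutralSimConfig,
    simulate_metacommunity,
    simulate_neutral_counts,
)


@pytest.fixture
def small_counts() -> CountTable:
    """3 ZOTUs x 4 samples, fixed values."""
    df = pd.DataFrame(
        {"s1": [5, 1, 0], "s2": [0, 2, 7], "s3": [3, 3, 3], "s4": [10, 0, 2]},
        index=["z1", "z2", "z3"],
    )
    return CountTable(df)


@pytest.fixture
def small_frame() -> SampleFrame:
    df = pd.DataFrame(
        {
            "group": ["C", "C", "N", "N"],
            "time": [0, 5, 0, 5],
            "replicate": [1, 1, 1, 1],
            "lifestyle": ["PA", "PA", "FL", "FL"],
            "NO3N": [1.0, 4.0, 2.0, 1.0],
            "PO4P": [0.5, 0.9, 1.0, 1.4],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    return SampleFrame(df)


@pytest.fixture(scope="session")
def neutral_sim():
    """One medium neutral community with known truth, reused across tests."""
    cfg = NeutralSimConfig(S=1000, k=50, N=10_000, Nm=500.0, seed=7)
    p = simulate_metacommunity(cfg.S, cfg.abundance_sigma, cfg.seed)
    table, truth = simulate_neutral_counts(p, cfg)
    return cfg, p, table, truth
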