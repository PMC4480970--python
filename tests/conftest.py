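import numpy as np
import pandas as pd
import pytest

from foxdissect.io import CountMatrix
from foxdissect.simulate import SimulationConfig, simulate_counts


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """4 genes x 4 samples, two conditions, hand-set counts."""
    genes = ["g1", "g2", "g3", "g4"]
    counts = pd.DataFrame(
        {
            "a_r1": [100, 10, 50, 0],
            "a_r2": [110, 12, 55, 0],
            "b_r1": [200, 20, 10, 0],
            "b_r2": [190, 18, 12, 0],
        },
        index=genes,
    )
    lengths = pd.Series([1000.0, 2000.0, 500.0, 1500.0], index=genes)
    meta = pd.DataFrame(
        {"condition": ["a", "a", "b", "b"], "replicate": [1, 2, 1, 2]},
        index=counts.columns,
    )
    return CountMatrix(counts=counts, gene_lengths=lengths, metadata=meta)


@pytest.fixture(scope="session")
def null_study():
    """Global-null two-condition study, expressed mode only (session-cached)."""
    cfg = SimulationConfig(n_genes=2000, conditions=["control", "foxp3"],
                          n_regulated=0, pi_LE=0.0, frac_zero=0.0, seed=101)
    return simulate_counts(cfg)


@pytest.fixture(scope="session")
def bimodal_study():
    """Default bimodal study with planted regulated genes (session-cached)."""
    cfg = SimulationConfig(n_genes=4000,
                          conditions=["naive_th", "treg", "control", "foxp3"],
                          n_regulated=300, seed=202)
    return simulate_counts(cfg)
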