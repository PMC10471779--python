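import numpy as np
import pandas as pd
import pytest

import lfp


@pytest.fixture(scope="session")
def small_cohort():
    """Small but well-separated synthetic cohort used across modules."""
    cfg = lfp.CohortConfig(
        n_hv=30,
        n_per_cluster={"C1": 22, "C2": 30, "C3": 14},
        n_genes=1500,
        n_candidates=80,
        n_fingerprint_up=14,
        n_fingerprint_down=7,
        effect_sizes={"C1": 1.0, "C2": 0.0, "C3": 2.0},
        seed=42,
    )
    matrix, meta, truth = lfp.gen_cohort(cfg)
    return cfg, matrix, meta, truth


@pytest.fixture(scope="session")
def small_cohort_norm(small_cohort):
    _, matrix, meta, truth = small_cohort
    norm, _ = lfp.normalize(matrix)
    norm, _ = lfp.filter_genes(norm)
    return norm, meta, truth


@pytest.fixture()
def tiny_counts():
    """3 genes x 2 samples toy count matrix."""
    df = pd.DataFrame(
        [[10, 20], [0, 0], [5, 11]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2"],
    )
    return lfp.ExpressionMatrix(df, layer="counts")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
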