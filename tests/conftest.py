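import numpy as np
import pandas as pd
import pytest

from squidecon import (
    CellLabelTable,
    ExpressionMatrix,
    PlatformBiasModel,
    expected_value_mode,
    generate_concurrent,
    sample_design,
)


@pytest.fixture(scope="session")
def design():
    return sample_design(1)


@pytest.fixture(scope="session")
def expected_biased(design):
    """Expected-value concurrent dataset with per-gene capture bias."""
    return expected_value_mode(design, PlatformBiasModel(tau=0.5), n_genes=500)


@pytest.fixture(scope="session")
def expected_unbiased(design):
    """Noise- and bias-free expected-value dataset."""
    return expected_value_mode(design, PlatformBiasModel.unbiased(), n_genes=500)


@pytest.fixture(scope="session")
def sampled_small(design):
    """A small sampled concurrent dataset (shared across tests for speed)."""
    return generate_concurrent(
        design, PlatformBiasModel(tau=0.5), cells_per_sample=600, n_genes=800, seed=1
    )


@pytest.fixture()
def toy_sc():
    """Tiny single-cell matrix with hand-enumerable clusters.

    Two clusters: A (4 cells), B (200 cells expanded lazily in tests that
    need the 1% arm); here only 4 + 6 cells for mean/profile checks.
    """
    values = np.array([
        [2.0, 4.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
        [0.0, 0.0, 6.0, 2.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        [1.0, 1.0, 1.0, 1.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0],
    ])
    genes = ["g1", "g2", "g3"]
    cells = [f"c{i}" for i in range(10)]
    mat = ExpressionMatrix(values, genes, cells, "counts")
    labels = CellLabelTable(pd.DataFrame({
        "sample_id": ["s1"] * 5 + ["s2"] * 5,
        "cluster_id": ["A"] * 4 + ["B"] * 6,
        "mito_fraction": np.linspace(0.01, 0.10, 10),
        "ribo_fraction": np.linspace(0.02, 0.20, 10),
    }, index=pd.Index(cells, name="cell_id")))
    return mat, labels
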