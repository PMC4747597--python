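import numpy as np
import pytest

from splinesem import (
    BivariateDataset,
    KinshipMatrix,
    MarkerMatrix,
)
from splinesem.simulate import Fixture, simulate_fixture

import pandas as pd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_fixture():
    """A small structured panel reused across tests (deterministic)."""
    return simulate_fixture(n_lines=40, n_markers=200, n_genes_P=3, n_genes_A=2,
                            seed=7)


@pytest.fixture
def identity_fixture():
    """Panel with identity kinship and a single gene column, for closed-form
    checks that assume unrelated lines."""
    n = 30
    ids = [f"l{i:02d}" for i in range(n)]
    gene = pd.DataFrame({"gP01": [0] + [1, 0] * ((n - 1) // 2) + [0] * ((n - 1) % 2)},
                        index=ids)
    markers = MarkerMatrix(ids, np.tile([[1.0, -1.0]], (n, 1)) * 0 +
                           np.sign(np.arange(n)[:, None] % 2 - 0.5))
    return Fixture(
        markers=markers,
        gene_table=gene,
        manifest={"gP01": "P"},
        kinship=KinshipMatrix(ids, np.eye(n)),
        reference_line=ids[0],
        family=None,
    )


def make_dataset(n=20, seed=0, p_P=2, p_A=3):
    """Small synthetic dataset with arbitrary (valid) structure."""
    rng = np.random.default_rng(seed)
    ids = [f"l{i:02d}" for i in range(n)]
    X_P = np.column_stack([np.ones(n)] +
                          [rng.integers(0, 2, n) for _ in range(p_P - 1)])
    X_A = np.column_stack([X_P] + [rng.integers(0, 2, n) for _ in range(p_A - p_P)])
    A = rng.standard_normal((n, 2 * n))
    K = A @ A.T / (2 * n) + 0.05 * np.eye(n)
    y_P = rng.standard_normal(n) * 10
    y_A = rng.standard_normal(n) * 5
    return BivariateDataset(
        line_ids=ids,
        y_P=y_P - y_P.mean(),
        y_A=y_A - y_A.mean(),
        X_P=X_P,
        X_A=X_A,
        K=K,
        centering_means=(float(y_P.mean()), float(y_A.mean())),
    )


@pytest.fixture
def small_dataset():
    return make_dataset()
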