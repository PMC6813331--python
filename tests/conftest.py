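import warnings

import numpy as np
import pandas as pd
import pytest

from micronetfun import (
    FilterConfig,
    FunctionTable,
    OtuTable,
    SyntheticConfig,
    generate_dataset,
    preprocess,
)

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        n_bacteria=20, n_fungi=10, sequencing_depth=2000,
        supporters_per_function=4, seed=3,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """30-OTU, 50-sample synthetic study with ground truth."""
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_ready(small_dataset):
    """Standardized analysis-ready matrix plus functions and truth."""
    otu, functions, truth = small_dataset
    ready, _ = preprocess(otu, FilterConfig())
    return ready, functions, truth


@pytest.fixture(scope="session")
def small_props(small_dataset):
    """Filtered proportion-scale table (defines per-sample detection)."""
    otu, _, _ = small_dataset
    props, _ = preprocess(otu, FilterConfig(standardize=False))
    return props


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def exact_correlation_data(R, n, rng=None):
    """Columns whose sample correlation matrix equals ``R`` exactly.

    Build an n x p matrix with zero column means and Gram X'X/n = R by
    rotating an orthonormal, mean-zero basis through the Cholesky factor.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if rng is None:
        rng = np.random.default_rng(0)
    A = rng.standard_normal((n, p + 1))
    A -= A.mean(axis=0)
    Q, _ = np.linalg.qr(A)
    Q = Q[:, :p]
    # QR of a centered matrix keeps columns mean-zero; orthonormal columns
    L = np.linalg.cholesky(R + 1e-12 * np.eye(p))
    return np.sqrt(n) * Q @ L.T


@pytest.fixture()
def toy_table():
    ab = pd.DataFrame(
        [[2.0, 3.0, 5.0], [1.0, 1.0, 2.0], [4.0, 0.0, 4.0]],
        index=["s1", "s2", "s3"],
        columns=["b_1", "b_2", "f_1"],
    )
    return OtuTable(ab)
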