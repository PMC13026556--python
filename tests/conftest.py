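import numpy as np
import pandas as pd
import pytest

from lectnet.panel_io import (
    ExpressionMatrix,
    estimate_size_factors,
    normalize_log2,
)


def make_counts(values, genes=None, samples=None, condition="tumor"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i+1:03d}" for i in range(values.shape[0])]
    samples = samples or [f"S{j+1:03d}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples),
        condition=condition, units="raw_counts")


def make_log2(values, genes=None, samples=None, condition="tumor"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i+1:03d}" for i in range(values.shape[0])]
    samples = samples or [f"S{j+1:03d}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples),
        condition=condition, units="normalized_log2")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def random_counts(rng):
    """20 genes x 6 samples of NB-ish positive counts, no zeros."""
    return make_counts(rng.poisson(50, size=(20, 6)) + 1)


def normalize(mat):
    return normalize_log2(mat, estimate_size_factors(mat))
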