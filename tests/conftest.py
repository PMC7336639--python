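import numpy as np
import pytest
import scipy.sparse as sp

from myocomm.io import CountMatrix
from myocomm.preprocess import NormalizedMatrix, log_normalize


def make_counts(array, genes=None, cells=None) -> CountMatrix:
    """Dense array (genes x cells) -> CountMatrix with default names."""
    a = np.asarray(array)
    genes = genes or [f"G{i}" for i in range(a.shape[0])]
    cells = cells or [f"C{j}" for j in range(a.shape[1])]
    return CountMatrix(genes=genes, cells=cells, counts=sp.csr_matrix(a))


def make_normalized(array, genes=None, cells=None) -> NormalizedMatrix:
    """Dense array of log1p-normalized values -> NormalizedMatrix."""
    a = np.asarray(array, dtype=float)
    genes = genes or [f"G{i}" for i in range(a.shape[0])]
    cells = cells or [f"C{j}" for j in range(a.shape[1])]
    return NormalizedMatrix(genes=genes, cells=cells, values=sp.csr_matrix(a))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
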