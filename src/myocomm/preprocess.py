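"""Log-normalization and technical-covariate scaling.

``log_normalize`` rescales each cell to a common library size and takes
log1p, the standard depth correction for droplet UMI data.
``regress_covariates`` then removes per-gene linear effects of the 10x
library chemistry (categorical) and the number of genes detected per
cell (numeric) by ordinary least squares, and standardizes the
residuals gene-wise. The pipeline also accepts an externally
batch-integrated matrix in place of the log-normalized one, in which
case this regression is the only further correction applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizedMatrix",
    "ScaledMatrix",
    "log_normalize",
    "regress_covariates",
    "top_variable_genes",
]


@dataclass
class NormalizedMatrix:
    """log1p(count / cell_total * scale_factor), sparse gene-major."""

    genes: list[str]
    cells: list[str]
    values: sp.csr_matrix
    scale_factor: float = 10_000.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


@dataclass
class ScaledMatrix:
    """Residualized, per-gene standardized expression (dense gene-major)."""

    genes: list[str]
    cells: list[str]
    values: np.ndarray
    covariates_used: list[str] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, names) -> "ScaledMatrix":
        keep = set(names)
        idx = [i for i, g in enumerate(self.genes) if g in keep]
        return ScaledMatrix(
            genes=[self.genes[i] for i in idx],
            cells=list(self.cells),
            values=self.values[idx],
            covariates_used=list(self.covariates_used),
        )


def log_normalize(m: CountMatrix, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """Library-size normalize then log1p.

    value(g, c) = log1p(count(g, c) / total(c) * scale_factor); all-zero
    cells map to all-zero columns. Conservation: for any nonzero cell,
    sum_g expm1(value) equals ``scale_factor`` exactly.
    """
    counts = sp.csc_matrix(m.counts, dtype=np.float64)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    inv = np.where(totals > 0, scale_factor / np.maximum(totals, 1.0), 0.0)
    scaled = counts @ sp.diags(inv)
    scaled.data = np.log1p(scaled.data)
    return NormalizedMatrix(
        genes=list(m.genes), cells=list(m.cells), values=sp.csr_matrix(scaled),
        scale_factor=scale_factor,
    )


def top_variable_genes(nm: NormalizedMatrix, n: int) -> list[str]:
    """The ``n`` genes with highest variance of log-normalized expression,
    returned in genome order. Standardizing every gene before PCA gives
    background genes the same weight as markers, so restricting the
    embedding to variable genes is what lets the population structure
    dominate the principal components."""
    v = nm.values
    mean = np.asarray(v.mean(axis=1)).ravel()
    var = np.asarray(v.power(2).mean(axis=1)).ravel() - mean**2
    top = np.sort(np.argsort(var, kind="stable")[::-1][: min(n, len(nm.genes))])
    return [nm.genes[i] for i in top]


def _build_design(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept + chemistry one-hot (reference level dropped) + numeric
    columns; constant non-intercept columns are dropped with a warning."""
    n = len(covariates)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    for col in covariates.columns:
        series = covariates[col]
        if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(series.astype(str)))
            for lev in levels[1:]:  # drop reference level
                cols.append((series.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{col}[{lev}]")
        else:
            cols.append(series.to_numpy(dtype=float))
            names.append(col)
    X = np.column_stack(cols)
    keep = [0] + [
        j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0
    ]
    dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
    if dropped:
        logger.warning("dropping constant covariate column(s): %s", dropped)
    X = X[:, keep]
    names = [names[j] for j in keep]
    # guard against residual rank deficiency (e.g. collinear covariates)
    while np.linalg.matrix_rank(X) < X.shape[1] and X.shape[1] > 1:
        logger.warning("design rank-deficient; dropping covariate %r", names[-1])
        X = X[:, :-1]
        names = names[:-1]
    return X, names


def regress_covariates(
    nm: NormalizedMatrix,
    covariates: pd.DataFrame,
    clip: float = 10.0,
) -> ScaledMatrix:
    """OLS-residualize each gene on the covariates, then standardize.

    Per gene: fit expression ~ intercept + chemistry one-hot +
    n_genes_detected, keep residuals, divide by the residual sample
    standard deviation (ddof=1), and clip at +/- ``clip``. Constant
    genes come out all-zero.
    """
    if list(covariates.index) != list(nm.cells):
        raise ValueError("covariate table is not aligned to the matrix cells")
    if len(nm.cells) < 2:
        raise ValueError("need at least 2 cells to scale")
    X, names = _build_design(covariates)
    Y = nm.dense().T  # cells x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    sd = resid.std(axis=0, ddof=1)
    # genes constant up to numerical noise come out all-zero
    tol = 1e-10 * np.maximum(1.0, np.abs(Y).max(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(sd > tol, resid / np.maximum(sd, 1e-300), 0.0)
    np.clip(Z, -clip, clip, out=Z)
    return ScaledMatrix(
        genes=list(nm.genes), cells=list(nm.cells), values=Z.T, covariates_used=names
    )
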