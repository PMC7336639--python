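"""Per-cell quality control statistics and retention filters.

Cells are retained with strictly more than ``min_umi`` UMIs and strictly
less than ``max_mito_frac`` of UMIs mapped to mitochondrial genes
(symbols starting with ``mito_prefix``); genes are then retained when
expressed in at least ``min_cells_per_gene`` of the retained cells.
Cell filtering precedes gene filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix

__all__ = ["QCParams", "compute_cell_qc", "apply_qc_filters"]


@dataclass
class QCParams:
    min_umi: int = 1000          # strict: keep n_umi > min_umi
    max_mito_frac: float = 0.20  # strict: keep pct_mito < 100 * max_mito_frac
    min_cells_per_gene: int = 3  # non-strict: keep genes detected in >= this many cells
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_mito_frac <= 1.0:
            raise ValueError("max_mito_frac must be in [0, 1]")
        if self.min_umi < 0 or self.min_cells_per_gene < 0:
            raise ValueError("thresholds must be >= 0")


def compute_cell_qc(m: CountMatrix, params: QCParams | None = None) -> pd.DataFrame:
    """Per-cell QC table: n_umi, n_genes_detected, pct_mito (0-100).

    An all-zero cell has pct_mito 0 (0/0 is defined as 0) so it fails
    only the UMI rule.
    """
    params = params or QCParams()
    if not m.genes:
        raise ValueError("empty gene list")
    counts = m.counts.tocsc()
    n_umi = np.asarray(counts.sum(axis=0)).ravel()
    n_genes = np.asarray((counts > 0).sum(axis=0)).ravel()
    mito_mask = np.array([g.startswith(params.mito_prefix) for g in m.genes])
    mito_umi = (
        np.asarray(counts[mito_mask, :].sum(axis=0)).ravel()
        if mito_mask.any()
        else np.zeros_like(n_umi, dtype=float)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(n_umi > 0, 100.0 * mito_umi / np.maximum(n_umi, 1), 0.0)
    return pd.DataFrame(
        {
            "n_umi": n_umi.astype(int),
            "n_genes_detected": n_genes.astype(int),
            "pct_mito": pct,
        },
        index=pd.Index(m.cells, name="barcode"),
    )


def apply_qc_filters(
    m: CountMatrix, qc: pd.DataFrame, params: QCParams | None = None
) -> CountMatrix:
    """Apply the retention rules; original gene/cell order is preserved."""
    params = params or QCParams()
    if list(qc.index) != list(m.cells):
        raise ValueError("QC table is not aligned to the matrix cells")
    keep_cells = (qc["n_umi"].to_numpy() > params.min_umi) & (
        qc["pct_mito"].to_numpy() < 100.0 * params.max_mito_frac
    )
    sub = m.subset(cell_mask=keep_cells)
    n_cells_expr = np.asarray((sub.counts > 0).sum(axis=1)).ravel()
    keep_genes = n_cells_expr >= params.min_cells_per_gene
    return sub.subset(gene_mask=keep_genes)
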