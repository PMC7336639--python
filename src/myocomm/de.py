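"""Wilcoxon rank-sum differential expression with fraction/fold gates.

Marker detection follows the droplet-workflow convention: genes are
pre-gated on detection fraction and on the log2 fold-change of
pseudocounted, delogged mean normalized expression; a two-sided
Wilcoxon rank-sum (Mann-Whitney U) test is applied to the survivors and
p values are Benjamini-Hochberg corrected over the tested set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import NormalizedMatrix

__all__ = [
    "DEGParams",
    "wilcoxon_rank_sum",
    "log2_fold_change",
    "benjamini_hochberg",
    "find_markers",
    "find_all_markers",
    "dotplot_stats",
]

_EXACT_MAX_N = 12  # exact null enumeration below this combined sample size


@dataclass
class DEGParams:
    min_pct: float = 0.25        # detection-fraction gate
    lfc_threshold: float = 0.25  # |log2FC| must exceed this
    alpha: float = 0.05          # FDR level for the q-value calls
    pseudocount: float = 1.0
    pct_side: str = "either"     # "either": max of the two fractions; "focal": group only
    bh_scope: str = "gated"      # "gated": BH over surviving genes; "all": over every gene

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_pct <= 1.0:
            raise ValueError("min_pct must be in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.pct_side not in ("either", "focal"):
            raise ValueError("pct_side must be 'either' or 'focal'")
        if self.bh_scope not in ("gated", "all"):
            raise ValueError("bh_scope must be 'gated' or 'all'")


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (U statistic of x, p).

    U is computed from midranks. The p value comes from exact null
    enumeration when the combined sample size is at most 12 and there
    are no ties, and otherwise from the normal approximation with tie
    and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    tie_free = len(np.unique(np.concatenate([x, y]))) == x.size + y.size
    method = "exact" if (x.size + y.size <= _EXACT_MAX_N and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def log2_fold_change(group, reference, pseudocount: float = 1.0) -> float:
    """log2 of pseudocounted delogged mean normalized expression ratio.

    Inputs are log1p-normalized values; means are taken on the expm1
    (linear) scale before the ratio.
    """
    g = np.asarray(group, dtype=float)
    r = np.asarray(reference, dtype=float)
    if g.size == 0 or r.size == 0:
        raise ValueError("both groups must be nonempty")
    return float(
        np.log2((np.expm1(g).mean() + pseudocount) / (np.expm1(r).mean() + pseudocount))
    )


def benjamini_hochberg(pvals) -> np.ndarray:
    """Step-up BH q-values, clipped at 1, mapped back to input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_masks(labels, group, reference):
    labels = np.asarray(labels)
    in_mask = labels == group
    if not in_mask.any():
        raise ValueError(f"unknown or empty group label {group!r}")
    if reference == "rest":
        out_mask = ~in_mask
    else:
        out_mask = labels == reference
        if not out_mask.any():
            raise ValueError(f"unknown or empty reference label {reference!r}")
    if not out_mask.any():
        raise ValueError("reference group is empty")
    return in_mask, out_mask


def _matrix_stats(values, in_mask, out_mask, pseudocount):
    """Vectorized per-gene fractions, delogged means, and log2FC."""
    A = values[:, in_mask]
    B = values[:, out_mask]
    pct_in = np.asarray((A > 0).sum(axis=1)).ravel() / A.shape[1]
    pct_out = np.asarray((B > 0).sum(axis=1)).ravel() / B.shape[1]
    expm1_A = A.copy()
    expm1_B = B.copy()
    expm1_A.data = np.expm1(expm1_A.data)
    expm1_B.data = np.expm1(expm1_B.data)
    mean_in = np.asarray(expm1_A.sum(axis=1)).ravel() / A.shape[1]
    mean_out = np.asarray(expm1_B.sum(axis=1)).ravel() / B.shape[1]
    lfc = np.log2((mean_in + pseudocount) / (mean_out + pseudocount))
    return pct_in, pct_out, lfc


def _wilcoxon_matrix(dense_in: np.ndarray, dense_out: np.ndarray) -> np.ndarray:
    """Per-row two-sided rank-sum p values (rows are genes)."""
    n = dense_in.shape[1] + dense_out.shape[1]
    if n <= _EXACT_MAX_N:
        return np.array(
            [wilcoxon_rank_sum(a, b)[1] for a, b in zip(dense_in, dense_out)]
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-tied rows
        res = stats.mannwhitneyu(
            dense_in, dense_out, alternative="two-sided", method="asymptotic",
            use_continuity=True, axis=1,
        )
    return np.where(np.isnan(res.pvalue), 1.0, res.pvalue)


def find_markers(
    nm: NormalizedMatrix,
    labels,
    group,
    reference: str = "rest",
    params: DEGParams | None = None,
) -> pd.DataFrame:
    """Differential expression of ``group`` against ``reference``.

    Genes are gated on detection fraction (>= min_pct, on the max of the
    two groups by default) and |log2FC| > lfc_threshold; q values are BH
    over the gated set. Records are sorted by avg_log2fc descending.
    """
    params = params or DEGParams()
    in_mask, out_mask = _group_masks(labels, group, reference)
    values = nm.values.tocsc()
    pct_in, pct_out, lfc = _matrix_stats(values, in_mask, out_mask, params.pseudocount)

    if params.pct_side == "either":
        pct_gate = np.maximum(pct_in, pct_out) >= params.min_pct
    else:
        pct_gate = pct_in >= params.min_pct
    gate = pct_gate & (np.abs(lfc) > params.lfc_threshold)
    if params.bh_scope == "all":
        gate_for_test = np.ones_like(gate)
    else:
        gate_for_test = gate

    idx = np.flatnonzero(gate_for_test)
    if idx.size == 0:
        return _empty_deg_table()
    dense_in = np.asarray(values[idx][:, in_mask].todense())
    dense_out = np.asarray(values[idx][:, out_mask].todense())
    pvals = _wilcoxon_matrix(dense_in, dense_out)
    qvals = benjamini_hochberg(pvals)

    df = pd.DataFrame(
        {
            "gene": [nm.genes[i] for i in idx],
            "group": group,
            "reference": reference,
            "avg_log2fc": lfc[idx],
            "pct_in": pct_in[idx],
            "pct_out": pct_out[idx],
            "p_value": pvals,
            "q_value": qvals,
        }
    )
    if params.bh_scope == "all":
        df = df[gate[idx]]
    return df.sort_values("avg_log2fc", ascending=False, kind="mergesort").reset_index(drop=True)


def _empty_deg_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "gene", "group", "reference", "avg_log2fc", "pct_in", "pct_out",
            "p_value", "q_value",
        ]
    )


def find_all_markers(nm: NormalizedMatrix, labels, params: DEGParams | None = None) -> pd.DataFrame:
    """One-vs-rest marker detection for every cluster; table keyed by
    (cluster, gene). A single cluster has no rest and yields an empty table."""
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) < 2:
        return _empty_deg_table()
    tables = [find_markers(nm, labels, g, "rest", params) for g in sorted(groups, key=str)]
    return pd.concat(tables, ignore_index=True)


def dotplot_stats(nm: NormalizedMatrix, labels, genes) -> pd.DataFrame:
    """Per (cluster, gene): mean normalized expression and the fraction of
    cells with nonzero expression — the two dot-plot statistics."""
    labels = np.asarray(labels)
    gene_idx = nm.gene_index()
    known = []
    for g in genes:
        if g in gene_idx:
            known.append(g)
        else:
            warnings.warn(f"gene {g!r} not in matrix; omitted", stacklevel=2)
    values = nm.values.tocsr()
    rows = []
    for cluster in sorted(pd.unique(labels), key=str):
        mask = labels == cluster
        sub = values[:, np.flatnonzero(mask)]
        for g in known:
            v = np.asarray(sub[gene_idx[g]].todense()).ravel()
            rows.append(
                {
                    "cluster": cluster,
                    "gene": g,
                    "mean_expression": float(v.mean()) if v.size else 0.0,
                    "fraction_expressing": float((v > 0).mean()) if v.size else 0.0,
                }
            )
    return pd.DataFrame(rows, columns=["cluster", "gene", "mean_expression", "fraction_expressing"])
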