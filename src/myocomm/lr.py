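"""Ligand-receptor cell-communication scoring.

The model restricts a curated ligand-receptor pair database to
receptors differentially expressed by a focal population (one-vs-rest,
FDR q < alpha and positive fold-change). For each surviving pair and
every other ("sender") cell type, the raw interaction score is the
product of the mean receptor expression in the focal population and
the mean ligand expression in the sender. Scores are row-normalized
to Z-scores across senders, so a positive value marks a sender whose
ligand supply stands out for that pair, and each (pair, sender) entry
is flagged when the sender expresses the ligand differentially —
evidence the channel is cell-type specific.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import DEGParams, find_markers
from .io import LRPair
from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "de_receptors",
    "score_interactions",
    "zscore_rows",
    "flag_ligand_specificity",
    "rank_de_receptors",
    "export_chord_edges",
    "score_focal_population",
]

_SCORE_COLUMNS = [
    "pair_name", "ligand", "receptor", "focal", "sender",
    "raw_score", "z_score", "ligand_de", "receptor_de",
]


def de_receptors(
    nm: NormalizedMatrix,
    labels,
    focal: str,
    receptor_universe,
    params: DEGParams | None = None,
    pairwise_all: bool = False,
) -> set[str]:
    """Receptors differentially expressed by the focal population.

    One-vs-rest by default: keep universe genes with q < alpha and
    positive fold-change in focal vs all other cells. With
    ``pairwise_all`` a receptor must instead win (q < alpha, positive
    fold-change) against every other cell type individually.
    """
    params = params or DEGParams()
    universe = {g.upper() for g in receptor_universe}
    present = universe & set(nm.genes)
    if not present:
        logger.warning("receptor universe has no genes in the matrix")
        return set()

    def _hits(reference: str) -> set[str]:
        table = find_markers(nm, labels, focal, reference, params)
        hit = table[
            table["gene"].isin(present)
            & (table["q_value"] < params.alpha)
            & (table["avg_log2fc"] > 0)
        ]
        return set(hit["gene"])

    if not pairwise_all:
        return _hits("rest")
    others = [g for g in pd.unique(np.asarray(labels)) if g != focal]
    result = present.copy()
    for other in others:
        result &= _hits(other)
        if not result:
            break
    return result


def _mean_expression_by_type(nm: NormalizedMatrix, labels) -> pd.DataFrame:
    """Gene x cell-type arithmetic means of normalized (log1p) values."""
    labels = np.asarray(labels)
    values = nm.values.tocsc()
    cols = {}
    for ct in sorted(pd.unique(labels), key=str):
        mask = np.flatnonzero(labels == ct)
        cols[ct] = np.asarray(values[:, mask].mean(axis=1)).ravel()
    return pd.DataFrame(cols, index=nm.genes)


def score_interactions(
    nm: NormalizedMatrix,
    labels,
    focal: str,
    gated_receptors,
    pairs: list[LRPair],
    include_autocrine: bool = False,
    delog: bool = False,
) -> pd.DataFrame:
    """Raw interaction scores for every gated pair x sender cell type.

    raw_score = mean receptor expression in the focal population times
    mean ligand expression in the sender; senders exclude the focal
    population itself unless ``include_autocrine``. Pairs whose genes
    are absent from the matrix, or whose receptor is not gated, are
    skipped. With ``delog`` the means are taken on expm1 values.
    """
    labels = np.asarray(labels)
    if focal not in set(labels):
        raise ValueError(f"focal population {focal!r} not in labels")
    means = _mean_expression_by_type(nm, labels)
    if delog:
        means = np.expm1(means)
    gated = {g.upper() for g in gated_receptors}
    genes = set(nm.genes)
    senders = [ct for ct in means.columns if include_autocrine or ct != focal]

    rows = []
    for pair in pairs:
        lig, rec = pair.ligand.upper(), pair.receptor.upper()
        if rec not in gated or lig not in genes or rec not in genes:
            continue
        rec_mean = float(means.at[rec, focal])
        for sender in senders:
            rows.append(
                {
                    "pair_name": f"{lig}_{rec}",
                    "ligand": lig,
                    "receptor": rec,
                    "focal": focal,
                    "sender": sender,
                    "raw_score": rec_mean * float(means.at[lig, sender]),
                    "z_score": np.nan,
                    "ligand_de": False,
                    "receptor_de": True,
                }
            )
    return pd.DataFrame(rows, columns=_SCORE_COLUMNS)


def zscore_rows(table: pd.DataFrame) -> pd.DataFrame:
    """Fill ``z_score`` by standardizing raw scores across senders within
    each (pair, focal) row; constant or singleton rows get all zeros.
    Sample standard deviation (divisor n-1)."""
    out = table.copy()
    if out.empty:
        return out
    for (_, _), idx in out.groupby(["pair_name", "focal"]).groups.items():
        raw = out.loc[idx, "raw_score"].to_numpy(dtype=float)
        if raw.size < 2:
            z = np.zeros_like(raw)
        else:
            sd = raw.std(ddof=1)
            z = np.zeros_like(raw) if sd == 0 else (raw - raw.mean()) / sd
        out.loc[idx, "z_score"] = z
    return out


def flag_ligand_specificity(
    table: pd.DataFrame,
    nm: NormalizedMatrix,
    labels,
    params: DEGParams | None = None,
) -> pd.DataFrame:
    """Fill ``ligand_de``: True where the sender expresses the ligand
    differentially (one-vs-rest q < alpha, positive fold-change)."""
    params = params or DEGParams()
    out = table.copy()
    if out.empty:
        return out
    de_ligands_by_sender: dict[str, set[str]] = {}
    for sender in pd.unique(out["sender"]):
        t = find_markers(nm, labels, sender, "rest", params)
        hits = t[(t["q_value"] < params.alpha) & (t["avg_log2fc"] > 0)]
        de_ligands_by_sender[sender] = set(hits["gene"])
    out["ligand_de"] = [
        lig in de_ligands_by_sender[sender]
        for lig, sender in zip(out["ligand"], out["sender"])
    ]
    return out


def score_focal_population(
    nm: NormalizedMatrix,
    labels,
    focal: str,
    pairs: list[LRPair],
    params: DEGParams | None = None,
    gate_receptors: bool = True,
    **kwargs,
) -> pd.DataFrame:
    """Convenience pipeline for one focal population: receptor DE gate,
    raw scores, row Z-scores, ligand-specificity flags.

    With ``gate_receptors`` False every receptor present in the matrix
    is scored and ``receptor_de`` records which would have passed the
    gate (used for the full chord-edge export)."""
    params = params or DEGParams()
    universe = {p.receptor.upper() for p in pairs}
    gated = de_receptors(nm, labels, focal, universe, params)
    to_score = gated if gate_receptors else (universe & set(nm.genes))
    table = score_interactions(nm, labels, focal, to_score, pairs, **kwargs)
    if not gate_receptors and not table.empty:
        table["receptor_de"] = table["receptor"].isin(gated)
    table = zscore_rows(table)
    return flag_ligand_specificity(table, nm, labels, params)


def rank_de_receptors(deg_table: pd.DataFrame, receptor_universe) -> pd.DataFrame:
    """Receptor panel from a two-population DE table, ranked by
    fold-change (positive values up in the first population);
    ``significant`` flags q < 0.05."""
    universe = {g.upper() for g in receptor_universe}
    if deg_table.empty:
        return pd.DataFrame(columns=["gene", "avg_log2fc", "q_value", "significant"])
    panel = deg_table[deg_table["gene"].isin(universe)].copy()
    panel = panel.sort_values("avg_log2fc", ascending=False, kind="mergesort")
    panel["significant"] = panel["q_value"] < 0.05
    return panel[["gene", "avg_log2fc", "q_value", "significant"]].reset_index(drop=True)


def export_chord_edges(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Flatten per-focal score tables into one chord-diagram edge list:
    (sender, receiver, ligand, receptor, raw_score, z_score,
    significant), where ``significant`` marks edges whose receptor
    passed the focal population's DE gate."""
    frames = []
    for focal, t in tables.items():
        if t.empty:
            continue
        f = t.rename(columns={"focal": "receiver"}).copy()
        f["significant"] = f["receptor_de"].astype(bool)
        frames.append(
            f[["sender", "receiver", "ligand", "receptor", "raw_score", "z_score",
               "ligand_de", "significant"]]
        )
    if not frames:
        return pd.DataFrame(
            columns=["sender", "receiver", "ligand", "receptor", "raw_score", "z_score",
                     "ligand_de", "significant"]
        )
    return pd.concat(frames, ignore_index=True)
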