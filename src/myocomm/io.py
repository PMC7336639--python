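"""Readers and writers for the on-disk formats the pipeline touches.

Count matrices use the 10x triplet convention: a Matrix Market file of
gene x cell UMI counts plus one gene-symbol file and one barcode file.
Ligand-receptor pair tables are delimited text with a ligand and a
receptor symbol column (Ramilowski-style layouts are auto-detected).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "CountMatrix",
    "LRPair",
    "read_counts_mtx",
    "write_counts_mtx",
    "read_lr_table",
    "read_marker_table",
    "write_marker_table",
]


class FormatError(ValueError):
    """Raised when an on-disk file violates its declared format."""


@dataclass
class CountMatrix:
    """Sparse gene x cell raw UMI count matrix with gene symbols and barcodes.

    ``counts`` is gene-major (genes as rows) with nonnegative integer
    entries; ``genes`` and ``cells`` are the row/column name lists.
    """

    genes: list[str]
    cells: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.validate()

    def validate(self) -> None:
        n_g, n_c = self.counts.shape
        if n_g != len(self.genes) or n_c != len(self.cells):
            raise FormatError(
                f"count matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if len(set(self.genes)) != len(self.genes):
            raise FormatError("duplicate gene symbols")
        if len(set(self.cells)) != len(self.cells):
            raise FormatError("duplicate cell barcodes")
        data = self.counts.data
        if data.size:
            if data.min() < 0:
                raise FormatError("negative count entry")
            if not np.allclose(data, np.round(data)):
                raise FormatError("non-integer count entry")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def subset(self, gene_mask=None, cell_mask=None) -> "CountMatrix":
        """Row/column subset preserving order; masks are boolean or index arrays."""
        m = self.counts
        genes, cells = self.genes, self.cells
        if gene_mask is not None:
            idx = np.arange(len(genes))[np.asarray(gene_mask)]
            m = m[idx, :]
            genes = [genes[i] for i in idx]
        if cell_mask is not None:
            idx = np.arange(len(cells))[np.asarray(cell_mask)]
            m = m[:, idx]
            cells = [cells[i] for i in idx]
        return CountMatrix(genes=list(genes), cells=list(cells), counts=sp.csr_matrix(m))


class LRPair(NamedTuple):
    """A curated ligand-receptor gene pair, named ``LIGAND_RECEPTOR``."""

    ligand: str
    receptor: str

    @property
    def pair_name(self) -> str:
        return f"{self.ligand}_{self.receptor}"


def _find_one(dir_path: str, candidates: list[str], what: str) -> str:
    for name in candidates:
        p = os.path.join(dir_path, name)
        if os.path.exists(p):
            return p
    raise FileNotFoundError(f"no {what} file in {dir_path} (tried {candidates})")


def _collapse_duplicate_genes(genes: list[str], counts: sp.csr_matrix):
    """Sum rows sharing a gene symbol; keep first-occurrence order."""
    first: dict[str, int] = {}
    order: list[str] = []
    for g in genes:
        if g not in first:
            first[g] = len(order)
            order.append(g)
    if len(order) == len(genes):
        return genes, counts
    rows = np.array([first[g] for g in genes])
    agg = sp.csr_matrix(
        (np.ones(len(genes)), (rows, np.arange(len(genes)))),
        shape=(len(order), len(genes)),
    )
    return order, sp.csr_matrix(agg @ counts)


def read_counts_mtx(dir_path: str) -> CountMatrix:
    """Load a 10x-style directory (matrix.mtx + genes/features.tsv + barcodes.tsv).

    Gene symbols are uppercased; duplicate symbols are collapsed by
    summation. Both the CellRanger v2 (``genes.tsv``, 2 columns) and v3
    (``features.tsv``, 3 columns) gene-file dialects are accepted.
    """
    mtx_path = _find_one(dir_path, ["matrix.mtx", "counts.mtx"], "Matrix Market")
    gene_path = _find_one(dir_path, ["genes.tsv", "features.tsv"], "gene")
    bc_path = _find_one(dir_path, ["barcodes.tsv"], "barcode")

    try:
        mat = mmread(mtx_path)
    except Exception as e:  # malformed header or records
        raise FormatError(f"cannot parse {mtx_path}: {e}") from e
    counts = sp.csr_matrix(mat)

    gene_df = pd.read_csv(gene_path, sep="\t", header=None, dtype=str)
    # v2: [ensembl, symbol]; v3: [ensembl, symbol, feature_type]; 1 column: symbols
    symbol_col = 1 if gene_df.shape[1] >= 2 else 0
    genes = [str(g).upper() for g in gene_df.iloc[:, symbol_col]]
    barcodes = pd.read_csv(bc_path, sep="\t", header=None, dtype=str).iloc[:, 0].tolist()

    if counts.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"{mtx_path} header says {counts.shape}, but gene/barcode files give "
            f"({len(genes)}, {len(barcodes)})"
        )
    data = counts.data
    if data.size and (data.min() < 0 or not np.allclose(data, np.round(data))):
        raise FormatError(f"{mtx_path} contains negative or non-integer entries")
    counts = counts.astype(np.int64)

    genes, counts = _collapse_duplicate_genes(genes, counts)
    return CountMatrix(genes=genes, cells=barcodes, counts=counts)


def write_counts_mtx(m: CountMatrix, dir_path: str) -> None:
    """Write ``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv`` readable by
    :func:`read_counts_mtx` (round trip is the identity)."""
    os.makedirs(dir_path, exist_ok=True)
    mmwrite(os.path.join(dir_path, "matrix.mtx"), sp.coo_matrix(m.counts), field="integer")
    with open(os.path.join(dir_path, "genes.tsv"), "w") as fh:
        for g in m.genes:
            fh.write(f"{g}\t{g}\n")
    with open(os.path.join(dir_path, "barcodes.tsv"), "w") as fh:
        for b in m.cells:
            fh.write(f"{b}\n")


def _detect_lr_columns(cols: list[str]) -> tuple[str, str] | None:
    low = {c.lower(): c for c in cols}
    if "ligand" in low and "receptor" in low:
        return low["ligand"], low["receptor"]
    lig = [c for c in cols if "ligand" in c.lower()]
    rec = [c for c in cols if "receptor" in c.lower()]
    if lig and rec:
        return lig[0], rec[0]
    return None


def read_lr_table(file: str, alias_map: dict[str, str] | None = None) -> list[LRPair]:
    """Read a ligand-receptor pair table (tab- or comma-delimited).

    Column detection order: exact ``ligand``/``receptor`` headers, then any
    Ramilowski-style pair of columns containing those words (e.g.
    ``Ligand.ApprovedSymbol``), then a ``Pair.Name`` column of
    ``LIGAND_RECEPTOR`` strings. Symbols are uppercased, optionally mapped
    through ``alias_map``, and duplicate pairs dropped (first kept).
    """
    with open(file) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(file, sep=sep, dtype=str)
    cols = list(df.columns)
    found = _detect_lr_columns(cols)
    if found is not None:
        lig_col, rec_col = found
        lig = df[lig_col]
        rec = df[rec_col]
    else:
        pair_cols = [c for c in cols if c.lower().replace(".", "").replace("_", "") == "pairname"]
        if not pair_cols:
            raise FormatError(
                f"{file}: no ligand/receptor columns and no Pair.Name column (columns: {cols})"
            )
        parts = df[pair_cols[0]].str.split("_", n=1, expand=True)
        if parts.shape[1] < 2 or parts.isna().any().any():
            raise FormatError(f"{file}: Pair.Name entries are not LIGAND_RECEPTOR strings")
        lig, rec = parts[0], parts[1]

    alias = {k.upper(): v.upper() for k, v in (alias_map or {}).items()}
    pairs: list[LRPair] = []
    seen: set[tuple[str, str]] = set()
    for l, r in zip(lig, rec):
        if pd.isna(l) or pd.isna(r):
            continue
        l = alias.get(str(l).upper(), str(l).upper())
        r = alias.get(str(r).upper(), str(r).upper())
        if (l, r) not in seen:
            seen.add((l, r))
            pairs.append(LRPair(l, r))
    return pairs


def read_marker_table(file: str) -> dict[str, list[str]]:
    """Read a marker nomenclature file: TSV with cell_type and a
    comma-separated marker-gene column."""
    df = pd.read_csv(file, sep="\t", header=None, dtype=str, comment="#")
    out: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        out[str(row.iloc[0])] = [g.strip().upper() for g in str(row.iloc[1]).split(",") if g.strip()]
    return out


def write_marker_table(markers: dict[str, list[str]], file: str) -> None:
    with open(file, "w") as fh:
        for ct, genes in markers.items():
            fh.write(f"{ct}\t{','.join(genes)}\n")
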