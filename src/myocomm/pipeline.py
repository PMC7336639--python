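"""End-to-end pipeline: simulate/load -> QC -> normalize -> scale ->
cluster/annotate -> differential expression -> LR scoring.

Configuration is a plain YAML mapping validated against the stage
parameter dataclasses; every run writes a manifest recording inputs,
parameters, seeds, and SHA-256 checksums of each stage's outputs, and
a resumed run reloads any stage whose outputs are already on disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml
from scipy.io import mmread, mmwrite

from . import __version__
from .cluster import ClusterParams, annotate_clusters, build_snn_graph, cluster_graph, embed_pca
from .de import DEGParams, find_all_markers, find_markers
from .io import CountMatrix, read_counts_mtx, read_lr_table, read_marker_table, write_counts_mtx
from .lr import export_chord_edges, rank_de_receptors, score_focal_population
from .preprocess import NormalizedMatrix, log_normalize, regress_covariates, top_variable_genes
from .qc import QCParams, apply_qc_filters, compute_cell_qc
from .reference import DEFAULT_MARKERS
from .simulate import SynthSpec, demo_lr_pairs, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]

_FLOAT_FMT = "%.10g"

STAGES = ["simulate", "qc", "normalize", "scale", "cluster", "de", "lr"]


@dataclass
class PipelineConfig:
    seed: int = 0
    input_dir: str | None = None   # load instead of simulating when set
    lr_table: str | None = None    # falls back to the demo pair list
    markers_file: str | None = None
    out_dir: str = "myocomm_out"
    simulate: SynthSpec = field(default_factory=SynthSpec)
    qc: QCParams = field(default_factory=QCParams)
    scale_factor: float = 10_000.0
    clip: float = 10.0
    n_hvg: int | None = 300  # top-variance genes fed to PCA; None = all genes
    cluster: ClusterParams = field(default_factory=ClusterParams)
    de: DEGParams = field(default_factory=DEGParams)
    lr_focal: list[str] = field(default_factory=lambda: ["MuSC1", "MuSC2"])
    lr_include_autocrine: bool = False
    lr_pairwise_all: bool = False


class ConfigError(ValueError):
    pass


_SECTION_TYPES = {
    "simulate": SynthSpec,
    "qc": QCParams,
    "cluster": ClusterParams,
    "de": DEGParams,
}
_TOP_KEYS = {
    "seed", "input_dir", "lr_table", "markers_file", "out_dir", "scale_factor",
    "clip", "n_hvg", "lr_focal", "lr_include_autocrine", "lr_pairwise_all",
} | set(_SECTION_TYPES)


def validate_config(file: str | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Parse, default, and range-check a YAML config.

    An empty (or absent) file yields all documented defaults; unknown
    keys raise :class:`ConfigError` naming the key, as do out-of-range
    thresholds.
    """
    raw: dict = {}
    if file is not None:
        with open(file) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{file}: top level must be a mapping")
        raw = loaded
    raw = {**raw, **(overrides or {})}

    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")

    cfg = PipelineConfig()
    for key, value in raw.items():
        if key in _SECTION_TYPES:
            cls = _SECTION_TYPES[key]
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            valid_fields = {f.name for f in dataclasses.fields(cls)}
            bad = set(value) - valid_fields
            if bad:
                raise ConfigError(f"unknown key(s) in section {key!r}: {sorted(bad)}")
            try:
                setattr(cfg, key, cls(**value))
            except ValueError as e:
                raise ConfigError(f"section {key!r}: {e}") from e
        else:
            setattr(cfg, key, value)
    # propagate the master seed into stage params that consume one
    cfg.simulate.seed = cfg.seed
    cfg.cluster.seed = cfg.seed
    if cfg.scale_factor <= 0:
        raise ConfigError("scale_factor must be > 0")
    return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: str, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["simulate"]["lr_circuits"] = [list(dataclasses.astuple(c)) if dataclasses.is_dataclass(c)
                                    else list(c) for c in cfg.simulate.lr_circuits]
    return d


class _Run:
    """Stage executor with file-existence based resume."""

    def __init__(self, cfg: PipelineConfig, resume: bool = False):
        self.cfg = cfg
        self.resume = resume
        self.out = cfg.out_dir
        self.manifest: dict = {
            "version": __version__,
            "seed": cfg.seed,
            "config": _config_dict(cfg),
            "stages": {},
        }

    def stage_dir(self, name: str) -> str:
        d = os.path.join(self.out, name)
        os.makedirs(d, exist_ok=True)
        return d

    def cached(self, name: str, files: list[str]) -> bool:
        return self.resume and all(os.path.exists(f) for f in files)

    def record(self, name: str, files: list[str]) -> None:
        self.manifest["stages"][name] = {
            os.path.relpath(f, self.out): _sha256(f) for f in files
        }


def run_pipeline(cfg: PipelineConfig, resume: bool = False) -> dict:
    """Execute every stage; returns the manifest (also written to
    ``out_dir/manifest.json``)."""
    run = _Run(cfg, resume=resume)
    os.makedirs(cfg.out_dir, exist_ok=True)

    # --- simulate or load -------------------------------------------------
    d = run.stage_dir("simulate")
    meta_path = os.path.join(d, "cell_meta.tsv")
    sim_files = [os.path.join(d, f) for f in ("matrix.mtx", "genes.tsv", "barcodes.tsv")]
    if cfg.input_dir is not None:
        counts = read_counts_mtx(cfg.input_dir)
        mp = os.path.join(cfg.input_dir, "cell_meta.tsv")
        if os.path.exists(mp):
            meta = pd.read_csv(mp, sep="\t", index_col=0, dtype=str)
        else:
            meta = pd.DataFrame(
                {"donor": "donor00", "chemistry": "v2"}, index=pd.Index(counts.cells)
            )
        truth = None
        write_counts_mtx(counts, d)
        _write_tsv(meta, meta_path)
        files = sim_files + [meta_path]
    elif run.cached("simulate", sim_files + [meta_path]):
        logger.info("simulate: reusing cached outputs")
        counts = read_counts_mtx(d)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
        truth = None
        files = sim_files + [meta_path]
    else:
        counts, meta, truth = generate_dataset(cfg.simulate)
        write_counts_mtx(counts, d)
        _write_tsv(meta, meta_path)
        truth_path = os.path.join(d, "truth_markers.tsv")
        pd.DataFrame(
            [(p, ",".join(g)) for p, g in truth.markers.items()],
            columns=["population", "markers"],
        ).to_csv(truth_path, sep="\t", index=False)
        circ_path = os.path.join(d, "truth_circuits.tsv")
        pd.DataFrame(
            [dataclasses.asdict(c) for c in truth.circuits]
        ).to_csv(circ_path, sep="\t", index=False)
        files = sim_files + [meta_path, truth_path, circ_path]
    run.record("simulate", files)
    logger.info("simulate: %d genes x %d cells", *counts.shape)

    # --- qc ---------------------------------------------------------------
    d = run.stage_dir("qc")
    report_path = os.path.join(d, "qc_report.tsv")
    qc_files = [os.path.join(d, f) for f in ("matrix.mtx", "genes.tsv", "barcodes.tsv")]
    if run.cached("qc", qc_files + [report_path]):
        logger.info("qc: reusing cached outputs")
        filtered = read_counts_mtx(d)
    else:
        qc_table = compute_cell_qc(counts, cfg.qc)
        qc_table["pass_umi"] = qc_table["n_umi"] > cfg.qc.min_umi
        qc_table["pass_mito"] = qc_table["pct_mito"] < 100.0 * cfg.qc.max_mito_frac
        qc_table["pass"] = qc_table["pass_umi"] & qc_table["pass_mito"]
        _write_tsv(qc_table, report_path)
        filtered = apply_qc_filters(counts, qc_table.drop(columns=["pass_umi", "pass_mito", "pass"]), cfg.qc)
        write_counts_mtx(filtered, d)
    run.record("qc", qc_files + [report_path])
    logger.info("qc: retained %d genes x %d cells", *filtered.shape)
    meta = meta.loc[filtered.cells]

    # --- normalize --------------------------------------------------------
    d = run.stage_dir("normalize")
    norm_path = os.path.join(d, "normalized.mtx")
    if run.cached("normalize", [norm_path]):
        logger.info("normalize: reusing cached outputs")
        nm = NormalizedMatrix(
            genes=filtered.genes, cells=filtered.cells,
            values=sp.csr_matrix(mmread(norm_path)), scale_factor=cfg.scale_factor,
        )
    else:
        nm = log_normalize(filtered, cfg.scale_factor)
        mmwrite(norm_path, sp.coo_matrix(nm.values), precision=10)
    run.record("normalize", [norm_path])

    # --- scale ------------------------------------------------------------
    d = run.stage_dir("scale")
    scaled_path = os.path.join(d, "scaled.tsv")
    qc_stats = compute_cell_qc(filtered, cfg.qc)
    covariates = pd.DataFrame(
        {
            "chemistry": meta["chemistry"].to_numpy(),
            "n_genes_detected": qc_stats["n_genes_detected"].to_numpy(),
        },
        index=pd.Index(filtered.cells),
    )
    if run.cached("scale", [scaled_path]):
        logger.info("scale: reusing cached outputs")
        sdf = pd.read_csv(scaled_path, sep="\t", index_col=0)
        from .preprocess import ScaledMatrix

        sm = ScaledMatrix(genes=list(sdf.index), cells=list(sdf.columns), values=sdf.to_numpy())
    else:
        sm = regress_covariates(nm, covariates, clip=cfg.clip)
        _write_tsv(pd.DataFrame(sm.values, index=sm.genes, columns=sm.cells), scaled_path)
    run.record("scale", [scaled_path])

    # --- cluster + annotate ----------------------------------------------
    d = run.stage_dir("cluster")
    assign_path = os.path.join(d, "assignments.tsv")
    markers = (
        read_marker_table(cfg.markers_file) if cfg.markers_file else dict(DEFAULT_MARKERS)
    )
    if run.cached("cluster", [assign_path]):
        logger.info("cluster: reusing cached outputs")
        adf = pd.read_csv(assign_path, sep="\t", index_col=0)
        cluster_ids = adf["cluster"].to_numpy()
        cell_types = adf["cell_type"].to_numpy()
    else:
        sm_emb = sm.subset_genes(top_variable_genes(nm, cfg.n_hvg)) if cfg.n_hvg else sm
        emb = embed_pca(sm_emb, cfg.cluster.n_pcs, seed=cfg.cluster.seed)
        graph = build_snn_graph(emb, cfg.cluster)
        cluster_ids = cluster_graph(graph, cfg.cluster.resolution, seed=cfg.cluster.seed)
        markers_present = {
            ct: gs for ct, gs in markers.items() if any(g in set(nm.genes) for g in gs)
        }
        name_map = annotate_clusters(nm, cluster_ids, markers_present or markers)
        cell_types = np.array([name_map[int(c)] for c in cluster_ids])
        _write_tsv(
            pd.DataFrame(
                {"cluster": cluster_ids, "cell_type": cell_types},
                index=pd.Index(filtered.cells, name="barcode"),
            ),
            assign_path,
        )
    run.record("cluster", [assign_path])
    logger.info("cluster: %d clusters", len(np.unique(cluster_ids)))

    # --- differential expression -----------------------------------------
    d = run.stage_dir("de")
    all_path = os.path.join(d, "markers_all.tsv")
    de_files = [all_path]
    focal_pair_table = None
    focal_a, focal_b = (cfg.lr_focal + [None, None])[:2]
    pair_path = os.path.join(d, "focal_pair_de.tsv")
    have_pair = focal_a in set(cell_types) and focal_b in set(cell_types)
    if have_pair:
        de_files.append(pair_path)
    if run.cached("de", de_files):
        logger.info("de: reusing cached outputs")
        if have_pair:
            focal_pair_table = pd.read_csv(pair_path, sep="\t")
    else:
        all_markers = find_all_markers(nm, cell_types, cfg.de)
        all_markers.to_csv(all_path, sep="\t", index=False, float_format=_FLOAT_FMT)
        if have_pair:
            focal_pair_table = find_markers(nm, cell_types, focal_a, focal_b, cfg.de)
            focal_pair_table.to_csv(pair_path, sep="\t", index=False, float_format=_FLOAT_FMT)
    run.record("de", de_files)

    # --- ligand-receptor scoring ------------------------------------------
    d = run.stage_dir("lr")
    pairs = read_lr_table(cfg.lr_table) if cfg.lr_table else demo_lr_pairs(cfg.simulate)
    lr_files = []
    chord_path = os.path.join(d, "chord_edges.tsv")
    tables: dict[str, pd.DataFrame] = {}
    for focal in cfg.lr_focal:
        if focal not in set(cell_types):
            logger.warning("lr: focal population %r absent from annotations; skipped", focal)
            continue
        t = score_focal_population(
            nm, cell_types, focal, pairs, cfg.de,
            include_autocrine=cfg.lr_include_autocrine,
        )
        tables[focal] = t
        p = os.path.join(d, f"interactions_{focal}.tsv")
        t.to_csv(p, sep="\t", index=False, float_format=_FLOAT_FMT)
        lr_files.append(p)
        if not t.empty:
            zmat = t.pivot_table(index="pair_name", columns="sender", values="z_score")
            zp = os.path.join(d, f"zscores_{focal}.tsv")
            _write_tsv(zmat, zp)
            lr_files.append(zp)
    if focal_pair_table is not None:
        panel = rank_de_receptors(focal_pair_table, {p.receptor.upper() for p in pairs})
        pp = os.path.join(d, "receptor_panel.tsv")
        panel.to_csv(pp, sep="\t", index=False, float_format=_FLOAT_FMT)
        lr_files.append(pp)
    edges = export_chord_edges(tables)
    edges.to_csv(chord_path, sep="\t", index=False, float_format=_FLOAT_FMT)
    lr_files.append(chord_path)
    run.record("lr", lr_files)

    manifest_path = os.path.join(cfg.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(run.manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete; manifest at %s", manifest_path)
    return run.manifest
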