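"""Multi-donor synthetic UMI count generator with planted ground truth.

The generator emulates the statistical structure of a droplet scRNA-seq
muscle atlas: ~10 donors with widely varying cell yields, two 10x
library chemistries with different depth, ~16 cell populations each
carrying a disjoint marker-gene program, mitochondrial genes holding a
fixed share of baseline expression, and planted ligand-receptor
circuits (a ligand elevated in a sender population paired with a
receptor elevated in a receiver population).

Counts are negative-binomial draws parameterized by (mean, size); the
size (dispersion) parameter is shared across genes. Donor-to-donor
depth variation is a log-normal multiplicative factor, and each donor
has its own RNG stream derived from the master seed so outputs are
stable under donor-count changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, LRPair
from .reference import DEFAULT_CIRCUITS, DEFAULT_MARKERS, DEFAULT_POPULATIONS, MITO_GENE_NAMES

__all__ = [
    "LRCircuit",
    "SynthSpec",
    "SynthTruth",
    "plant_marker",
    "plant_lr_circuit",
    "generate_dataset",
    "demo_lr_pairs",
]


class SpecError(ValueError):
    """Raised when a SynthSpec is internally infeasible."""


@dataclass(frozen=True)
class LRCircuit:
    """A planted communication channel: ligand up ``fold``-fold in the
    sender population, receptor up ``fold``-fold in the receiver."""

    ligand: str
    receptor: str
    sender: str
    receiver: str
    fold: float = 8.0


@dataclass
class SynthSpec:
    """Parameters of the synthetic atlas.

    Defaults mirror the profiled study design: 10 donors averaging
    2206 +/- 1961 cells each, two chemistries (v2/v3), 16 populations in
    equal proportion, and three planted ligand-receptor circuits.
    ``baseline_mean`` is the mean UMI per gene per cell on the linear
    scale before population/batch adjustments.
    """

    n_donors: int = 10
    cells_per_donor_mean: float = 2206.0
    cells_per_donor_sd: float = 1961.0
    n_populations: int = 16
    population_names: list[str] | None = None
    population_proportions: list[float] | None = None
    n_genes: int = 2000
    n_mito_genes: int = 13
    baseline_mean: float = 1.0
    nb_dispersion: float = 10.0
    mito_share: float = 0.10
    marker_genes_per_population: int = 10
    marker_log2fc: float = 2.0
    chemistry_effect: dict[str, float] = field(default_factory=lambda: {"v2": 1.0, "v3": 1.6})
    donor_depth_sigma: float = 0.3
    lr_circuits: list[LRCircuit] = field(
        default_factory=lambda: [LRCircuit(*c) for c in DEFAULT_CIRCUITS]
    )
    seed: int = 0

    def __post_init__(self) -> None:
        coerced = []
        for c in self.lr_circuits:
            if isinstance(c, LRCircuit):
                coerced.append(c)
            elif isinstance(c, dict):
                coerced.append(LRCircuit(**c))
            else:
                coerced.append(LRCircuit(*c))
        self.lr_circuits = coerced

    def resolved_populations(self) -> list[str]:
        if self.population_names is not None:
            if len(self.population_names) != self.n_populations:
                raise SpecError("population_names length differs from n_populations")
            return list(self.population_names)
        if self.n_populations == len(DEFAULT_POPULATIONS):
            return list(DEFAULT_POPULATIONS)
        return [f"Pop{i:02d}" for i in range(self.n_populations)]

    def resolved_proportions(self) -> np.ndarray:
        if self.population_proportions is None:
            return np.full(self.n_populations, 1.0 / self.n_populations)
        p = np.asarray(self.population_proportions, dtype=float)
        if len(p) != self.n_populations:
            raise SpecError("population_proportions length differs from n_populations")
        if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
            raise SpecError("population_proportions must be a simplex vector")
        return p

    def validate(self) -> None:
        if self.baseline_mean <= 0 or self.nb_dispersion <= 0:
            raise SpecError("baseline_mean and nb_dispersion must be > 0")
        if not 0 <= self.mito_share < 1:
            raise SpecError("mito_share must be in [0, 1)")
        if self.n_mito_genes > len(MITO_GENE_NAMES) + 10_000:
            raise SpecError("n_mito_genes unreasonably large")
        self.resolved_proportions()
        n_marker = self.marker_genes_per_population * self.n_populations
        if n_marker + self.n_mito_genes > self.n_genes:
            raise SpecError(
                f"{n_marker} marker + {self.n_mito_genes} mito genes exceed n_genes={self.n_genes}"
            )


@dataclass
class SynthTruth:
    """Planted ground truth emitted alongside a generated dataset."""

    cell_table: pd.DataFrame  # index barcode; columns donor, chemistry, population
    markers: dict[str, list[str]]  # population -> marker gene symbols
    circuits: list[LRCircuit]
    expected_means: pd.DataFrame  # genes x populations, pre-batch linear means


def _gene_names(spec: SynthSpec, populations: list[str]) -> tuple[list[str], dict[str, list[str]]]:
    """Build the gene list: per-population markers (canonical names where the
    default nomenclature applies), circuit genes, generic filler, mito genes."""
    markers: dict[str, list[str]] = {}
    used: set[str] = set()
    for pop in populations:
        canon = DEFAULT_MARKERS.get(pop, [])
        names: list[str] = []
        for j in range(spec.marker_genes_per_population):
            name = canon[j] if j < len(canon) else f"{pop.upper()}-M{j + 1}"
            name = name.upper()
            if name in used:
                raise SpecError(f"marker gene {name} assigned to two populations")
            used.add(name)
            names.append(name)
        markers[pop] = names

    circuit_genes: list[str] = []
    for c in spec.lr_circuits:
        for g in (c.ligand.upper(), c.receptor.upper()):
            if g not in used and g not in circuit_genes:
                circuit_genes.append(g)

    mito = [MITO_GENE_NAMES[i] if i < len(MITO_GENE_NAMES) else f"MT-G{i + 1}"
            for i in range(spec.n_mito_genes)]
    n_named = sum(len(v) for v in markers.values()) + len(circuit_genes) + len(mito)
    n_filler = spec.n_genes - n_named
    if n_filler < 0:
        raise SpecError("marker + circuit + mito genes exceed n_genes")
    filler = [f"G{i + 1:05d}" for i in range(n_filler)]
    genes = [g for pop in populations for g in markers[pop]] + circuit_genes + filler + mito
    return genes, markers


def _baseline_means(spec: SynthSpec, genes: list[str]) -> np.ndarray:
    """Per-gene baseline linear means; MT- genes share ``mito_share`` of the
    total expression budget ``n_genes * baseline_mean``."""
    total = spec.n_genes * spec.baseline_mean
    is_mito = np.array([g.startswith("MT-") for g in genes])
    base = np.empty(len(genes))
    n_mito = int(is_mito.sum())
    if n_mito == 0:
        base[:] = spec.baseline_mean
    else:
        base[is_mito] = spec.mito_share * total / n_mito
        base[~is_mito] = (1 - spec.mito_share) * total / (len(genes) - n_mito)
    return base


def plant_marker(
    means: pd.DataFrame, marker_assignments: dict[str, list[str]], log2fc: float
) -> pd.DataFrame:
    """Multiply each marker gene's mean by ``2**log2fc`` in its own population.

    ``means`` is a genes x populations table of linear-scale means; marker
    sets must be disjoint across populations.
    """
    seen: set[str] = set()
    out = means.copy()
    for pop, genes in marker_assignments.items():
        if pop not in out.columns:
            raise SpecError(f"unknown population {pop!r}")
        for g in genes:
            if g in seen:
                raise SpecError(f"marker gene {g} assigned to multiple populations")
            seen.add(g)
            if g not in out.index:
                raise SpecError(f"marker gene {g} not in gene list")
            out.loc[g, pop] *= 2.0 ** log2fc
    return out


def plant_lr_circuit(means: pd.DataFrame, circuits: list[LRCircuit]) -> pd.DataFrame:
    """Elevate each circuit's ligand mean in its sender population and its
    receptor mean in its receiver population by the circuit fold."""
    out = means.copy()
    for c in circuits:
        for gene, pop in ((c.ligand.upper(), c.sender), (c.receptor.upper(), c.receiver)):
            if gene not in out.index:
                raise SpecError(f"circuit gene {gene} not in gene list")
            if pop not in out.columns:
                raise SpecError(f"circuit population {pop!r} unknown")
            out.loc[gene, pop] *= c.fold
    return out


def _draw_n_cells(rng: np.random.Generator, mean: float, sd: float) -> int:
    """Log-normal cell-yield draw matching the requested mean and sd."""
    if mean <= 0:
        return 0
    if sd <= 0:
        return int(round(mean))
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return int(round(float(rng.lognormal(mu, np.sqrt(sigma2)))))


def generate_dataset(spec: SynthSpec) -> tuple[CountMatrix, pd.DataFrame, SynthTruth]:
    """Draw a full synthetic atlas: counts, per-cell metadata, ground truth.

    Bitwise reproducible given ``spec.seed``; each donor consumes an
    independent child RNG stream.
    """
    spec.validate()
    populations = spec.resolved_populations()
    proportions = spec.resolved_proportions()
    genes, markers = _gene_names(spec, populations)

    base = _baseline_means(spec, genes)
    means = pd.DataFrame(
        np.tile(base[:, None], (1, len(populations))), index=genes, columns=populations
    )
    means = plant_marker(means, markers, spec.marker_log2fc)
    means = plant_lr_circuit(means, spec.lr_circuits)
    mean_mat = means.to_numpy()  # genes x populations

    chem_labels = sorted(spec.chemistry_effect)
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_donors)

    blocks: list[sp.csr_matrix] = []
    meta_rows: list[pd.DataFrame] = []
    r = spec.nb_dispersion
    for d in range(spec.n_donors):
        rng = np.random.default_rng(streams[d])
        n_cells = _draw_n_cells(rng, spec.cells_per_donor_mean, spec.cells_per_donor_sd)
        chemistry = chem_labels[d % len(chem_labels)] if chem_labels else "v2"
        depth = float(rng.lognormal(-spec.donor_depth_sigma**2 / 2, spec.donor_depth_sigma))
        if n_cells == 0:
            continue
        pops = rng.choice(len(populations), size=n_cells, p=proportions)
        mu = mean_mat[:, pops] * (spec.chemistry_effect.get(chemistry, 1.0) * depth)
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)
        blocks.append(sp.csr_matrix(counts))
        barcodes = [f"D{d:02d}-{i:05d}" for i in range(n_cells)]
        meta_rows.append(
            pd.DataFrame(
                {
                    "donor": f"donor{d:02d}",
                    "chemistry": chemistry,
                    "population": [populations[k] for k in pops],
                },
                index=barcodes,
            )
        )

    if blocks:
        counts_all = sp.csr_matrix(sp.hstack(blocks))
        meta = pd.concat(meta_rows)
    else:
        counts_all = sp.csr_matrix((len(genes), 0), dtype=np.int64)
        meta = pd.DataFrame(columns=["donor", "chemistry", "population"])
    meta.index.name = "barcode"

    cm = CountMatrix(genes=genes, cells=list(meta.index), counts=counts_all.astype(np.int64))
    truth = SynthTruth(
        cell_table=meta.copy(),
        markers=markers,
        circuits=list(spec.lr_circuits),
        expected_means=means,
    )
    return cm, meta, truth


def demo_lr_pairs(spec: SynthSpec, n_decoys: int = 12) -> list[LRPair]:
    """A small pair table for end-to-end runs: the planted circuits plus
    decoy pairs drawn from generic background genes."""
    genes, _ = _gene_names(spec, spec.resolved_populations())
    filler = [g for g in genes if g.startswith("G0") or g.startswith("G1")]
    pairs = [LRPair(c.ligand.upper(), c.receptor.upper()) for c in spec.lr_circuits]
    for i in range(min(n_decoys, len(filler) // 2)):
        pairs.append(LRPair(filler[2 * i], filler[2 * i + 1]))
    return pairs
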