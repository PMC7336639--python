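"""Default cell-type nomenclature for adult human skeletal muscle.

Sixteen populations spanning the four tissue compartments (muscle,
endothelial/vascular, stromal, immune), each with canonical marker genes
used both to label synthetic populations and to annotate clusters:
PAX7 marks muscle stem cells (MuSCs), RGS5 pericytes, MYH11 smooth
muscle, and so on. The MuSC pool is split into a quiescent (MuSC1,
PAX7/DLK1-high) and an early-activated (MuSC2, inflammatory
CCL2/IL32 signature) subpopulation.
"""

from __future__ import annotations

# population -> canonical marker symbols (order fixes gene naming in the simulator)
DEFAULT_MARKERS: dict[str, list[str]] = {
    "MuSC1": ["PAX7", "DLK1", "CDKN1C"],
    "MuSC2": ["CCL2", "IL32", "CXCL1"],
    "Myonuclei": ["ACTA1", "MYH1"],
    "SmoothMuscle": ["MYH11", "ACTA2"],
    "Pericyte": ["RGS5", "NOTCH3"],
    "Endothelial1": ["PECAM1", "CDH5"],
    "Endothelial2": ["VWF", "CLDN5"],
    "Lymphatic": ["PROX1", "LYVE1"],
    "Fibroblast1": ["COL1A1", "DCN"],
    "Fibroblast2": ["PDGFRA", "FBN1"],
    "Fibroblast3": ["SMOC2", "GSN"],
    "Adipocyte": ["ADIPOQ", "PLIN1"],
    "Macrophage": ["CD68", "LYZ"],
    "Tcell": ["CD3E", "CD2"],
    "Bcell": ["MS4A1", "CD79A"],
    "Erythroblast": ["HBB", "HBA1"],
}

DEFAULT_POPULATIONS: list[str] = list(DEFAULT_MARKERS)

# planted cell-communication circuits: (ligand, receptor, sender, receiver, fold)
DEFAULT_CIRCUITS: list[tuple[str, str, str, str, float]] = [
    ("TNFSF12", "TNFRSF12A", "Fibroblast2", "MuSC2", 8.0),
    ("EGF", "EGFR", "Myonuclei", "MuSC1", 8.0),
    ("JAG1", "NOTCH3", "Endothelial1", "Pericyte", 8.0),
]

# the 13 protein-coding genes of the human mitochondrial genome
MITO_GENE_NAMES: list[str] = [
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
]
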