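"""Default marker-panel definitions and the compartment taxonomy.

The panels collect the classic and newly reported peripheral-glia markers:
a pan-glial panel expressed across all Schwann-cell subtypes, per-subtype
panels for myelinating (MG), non-myelinating (NMG), and terminal (TG) glia,
a shared NMG+TG program, and contaminant panels of classic lineage markers
used to screen out epithelial / immune / endothelial / stromal cells that
co-cluster with rare glia.
"""

from __future__ import annotations

from .atlas_io import GenePanel, PanelSet

PAN_GLIAL_GENES = ("SOX10", "PLP1", "S100B", "CRYAB", "GPM6B", "CDH19")
#: Classic panel used for cluster scoring (adds Ncam1/Gfap-style breadth).
CLASSIC_GLIAL_GENES = ("SOX10", "NCAM1", "PLP1", "S100B", "GFAP")

MG_GENES = ("PRX", "CLDN19", "PLLP", "DRP2", "BCAS1")
NMG_GENES = ("SCN7A", "GFRA3", "IGFBP7", "RARRES2", "CHL1")
TG_GENES = ("BCHE", "CPM", "TINAGL1", "GPC3")
#: Expressed by NMG and TG alike, distinguishing both from MG.
NMG_TG_SHARED_GENES = ("APOE", "MARCKS", "MATN3")

CONTAMINANT_GENES = {
    "epithelial": ("EPCAM", "CDH1", "KRT5"),
    "immune": ("PTPRC", "CD3E", "CD19"),
    "endothelial": ("PECAM1", "CDH5", "VWF"),
    "stromal": ("COL1A1", "PDGFRA", "DCN"),
}

#: Panel of immediate-early genes marking dissociation-activated cells;
#: used by the optional single-donor activation exclusion rule.
ACTIVATION_GENES = ("FOS", "JUN", "IER2")

#: Tissues treated as central nervous system and excluded before screening.
CNS_TISSUE_BLACKLIST = ("Brain_Non-Myeloid", "Brain_Myeloid")

#: Maps prior annotations / truth labels to broad compartments. Used when
#: building the pan-glial marker background (non-glia minus immune and germ).
DEFAULT_COMPARTMENTS = {
    "glia": "glia",
    "glia_MG": "glia",
    "glia_NMG": "glia",
    "glia_TG": "glia",
    "glia_MGxNMG": "glia",
    "glia_MGxTG": "glia",
    "glia_NMGxTG": "glia",
    "epithelial": "epithelial",
    "immune": "immune",
    "endothelial": "endothelial",
    "stromal": "stromal",
    "germ": "germ",
    "neural": "neural",
}


def default_panels() -> PanelSet:
    """The panel configuration every stage defaults to."""
    return PanelSet(
        pan_glial=GenePanel("pan_glial", "pan_glial", PAN_GLIAL_GENES),
        subtypes={
            "MG": GenePanel("MG", "subtype_MG", MG_GENES),
            "NMG": GenePanel("NMG", "subtype_NMG", NMG_GENES),
            "TG": GenePanel("TG", "subtype_TG", TG_GENES),
        },
        contaminants={
            lineage: GenePanel(lineage, f"contaminant_{lineage}", genes)
            for lineage, genes in CONTAMINANT_GENES.items()
        },
    )
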