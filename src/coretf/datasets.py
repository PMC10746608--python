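"""Small bundled reference lists from the mammal-domestication TF survey.

These transcribe the published candidate lists so the downstream stages of
the pipeline (core-TF calling, partner counting, hub ranking) can be
exercised and checked without the original web-service libraries:

* ``SELECTED_TFS`` — 53 TFs found within a curated list of 764 genes under
  positive selection in domesticated mammals (the selected-gene list crossed
  with the human TF census).
* ``TARGET_ENRICHED_TFS`` — 66 TFs whose experimentally demonstrated
  (ChIP-seq) target sets are over-represented in the same 764-gene list at
  adjusted p < 0.01.
* ``CORE_TFS`` — their five-member intersection.
* ``SHARED_PATHWAYS`` — pathway names reported enriched across the target
  lists of the four core TFs with available ChIP-seq data (NR3C2 had none).
* ``CORE_TF_PARTNERS`` — per core TF, its protein-interaction partners among
  each of the two candidate lists.  The published table is typographically
  garbled in places; the SOX2 row and the entries among the five core TFs
  are unambiguous and are the ones relied on in tests.

Symbols are verbatim from the source tables (some are non-HGNC dialects,
e.g. "OCT4", "P300", "GF1"); no alias resolution is applied, so overlaps
are exactly the published ones.
"""

from __future__ import annotations

from .io import GeneList

__all__ = [
    "SELECTED_TFS",
    "TARGET_ENRICHED_TFS",
    "CORE_TFS",
    "SHARED_PATHWAYS",
    "CORE_TF_PARTNERS",
    "selected_tfs_list",
    "target_enriched_tfs_list",
]

#: TFs under positive selection in domesticated mammals (53)
SELECTED_TFS: tuple[str, ...] = (
    "ARID3B", "CBX2", "CUX2", "DMRT3", "EEA1", "ELF2", "ETV4", "FOXD3",
    "FOXI1", "FOXJ3", "GRHL3", "HMGA2", "IKZF1", "JRKL", "KLF4", "LIN28B",
    "LTF", "MAFK", "MBD2", "MITF", "NPAS3", "NR2F2", "NR3C1", "NR3C2",
    "NRF1", "OLIG1", "PAX2", "PAX3", "PHF20", "PLAG1", "PPARD", "PRMT3",
    "SETBP1", "SKI", "SOX10", "SOX2", "SOX6", "SOX9", "SREBF1", "TFCP2L1",
    "THYN1", "TLX3", "ZFAT", "ZNF236", "ZNF286A", "ZNF286B", "ZNF436",
    "ZNF492", "ZNF516", "ZNF521", "ZNF555", "ZNF679", "ZNF780B",
)

#: TFs whose ChIP-seq target sets are enriched in the selected-gene list (66)
TARGET_ENRICHED_TFS: tuple[str, ...] = (
    "AF4", "AR", "ARNT", "BRD4", "CDX2", "CEBPA", "CEBPD", "CTBP1",
    "CTBP2", "CTCF", "CTNNB1", "DROSHA", "FLI1", "FOXA1", "FOXA2", "FOXM1",
    "GATA1", "GATA2", "GF1", "GF1B", "JARID2", "KDM2B", "KLF1", "KLF4",
    "KLF5", "LEF1", "LMO2", "LUZP1", "MBD3", "MEIS1", "MITF", "MTF2",
    "NFKB1", "NR3C1", "NR3C2", "OCT4", "OLIG2", "P300", "POU3F2", "POU5F1",
    "PPAR", "REST", "RING1B", "RUNX2", "SMAD3", "SMAD4", "SMARCA4",
    "SMARCD1", "SOX11", "SOX2", "STAT1", "STAT3", "SUZ12", "TAL1", "TBX3",
    "TCF3", "TCF4", "TEAD4", "TOP2B", "TP53", "TP63", "UBTF", "WT1",
    "YAP1", "ZFP57", "ZNF217",
)

#: the dual-evidence intersection
CORE_TFS: tuple[str, ...] = ("KLF4", "MITF", "NR3C1", "NR3C2", "SOX2")

#: pathway names enriched across the target lists of SOX2, KLF4, MITF, NR3C1.
#: The source table prints seven rows but its text counts "only 6 pathways";
#: "Signal transduction" may be a super-heading — both counts are accepted
#: where this fixture is used.
SHARED_PATHWAYS: tuple[str, ...] = (
    "Signal transduction",
    "Axon guidance",
    "BDNF signaling pathway",
    "Interleukin-2 signaling pathway",
    "TGF-beta regulation of extracellular matrix",
    "VEGFA-VEGFR2 signaling pathway",
    "Adipogenesis",
)

#: per core TF: (partners among SELECTED_TFS, partners among TARGET_ENRICHED_TFS)
CORE_TF_PARTNERS: dict[str, dict[str, tuple[str, ...]]] = {
    "SOX2": {
        "selected": ("ARID3B", "CBX2", "ELF2", "MBD2", "MITF", "SOX2", "SOX6"),
        "target_enriched": (
            "ARNT", "CEBPD", "CTBP1", "CTBP2", "CTCF", "CTNNB1", "FLI1",
            "KDM2B", "LUZP1", "MBD3", "MITF", "POU5F1", "RUNX2", "SMARCA4",
            "SMARCD1", "SOX2", "TBX3", "TCF3", "TP63", "UBTF", "YAP1",
        ),
    },
    "MITF": {
        "selected": ("SOX2",),
        "target_enriched": ("SOX2", "LEF1"),
    },
    "KLF4": {
        "selected": ("ZNF516",),
        "target_enriched": ("AR", "KDM2B"),
    },
    "NR3C1": {
        "selected": ("ARID3B", "FOXJ3", "NR2F2", "NR3C1", "NR3C2", "ZNF516"),
        "target_enriched": (
            "CEBPA", "KDM2B", "NFKB1", "NR3C1", "NR3C2", "SMAD3", "STAT3", "TP53",
        ),
    },
    "NR3C2": {
        "selected": ("NR3C1",),
        "target_enriched": ("NR3C1", "TP53"),
    },
}


def selected_tfs_list() -> GeneList:
    """The selected-TF column as a GeneList."""
    return GeneList.from_iterable(SELECTED_TFS, label="selected_tfs")


def target_enriched_tfs_list() -> GeneList:
    """The target-enriched-TF column as a GeneList."""
    return GeneList.from_iterable(TARGET_ENRICHED_TFS, label="target_enriched_tfs")
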