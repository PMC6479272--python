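"""The sphingolipid/lysophosphatidate/immune multigene signature.

The default signature measured by the qPCR panel comprises 38 genes of the
sphingolipid and lysophosphatidate (LPA) signaling machinery -- the
sphingomyelin/salvage-pathway enzymes, the S1P and LPA receptor families and
the CD1 lipid-antigen-presentation molecules -- plus 8 immune lineage markers
covering B cells, T cells and the monocyte/macrophage compartment.  Four
housekeeping genes serve as the normalization reference for relative
quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GeneSignature",
    "default_signature",
    "SPHINGO_LPA_GENES",
    "IMMUNE_GENES",
    "HOUSEKEEPING_GENES",
    "IMMUNE_CORE_GENES",
]

#: Sphingolipid / lysophosphatidate signaling genes (38).
SPHINGO_LPA_GENES: tuple[str, ...] = (
    # S1P phosphatases and lipid phosphate phosphatases
    "SGPP1", "SGPP2", "PPAP2A", "PPAP2B", "PPAP2C",
    # S1P lyase and sphingosine kinases
    "SGPL1", "SPHK1", "SPHK2",
    # autotaxin (LPA-producing lysophospholipase D)
    "ENPP2",
    # sphingomyelinases
    "SMPD1", "SMPD2", "SMPD3",
    # ceramide synthases
    "CERS1", "CERS2", "CERS3", "CERS4", "CERS5", "CERS6",
    # ceramidases
    "ASAH1", "NAAA",
    # ceramide kinase
    "CERK",
    # sphingomyelin synthases
    "SGMS1", "SGMS2",
    # transferases utilizing ceramide
    "UGT8", "UGCG",
    # S1P receptors
    "S1PR1", "S1PR2", "S1PR3", "S1PR4", "S1PR5",
    # LPA receptors
    "LPAR1", "LPAR2", "LPAR3", "LPAR4", "LPAR5", "LPAR6",
    # CD1 lipid antigen presentation
    "CD1B", "CD1D",
)

#: Immune lineage markers (8): B cells (MS4A1/CD20, IgG and IgM mature
#: transcripts), monocyte/macrophage (CD14, CD68, CD163), T cells (CD3E)
#: and the pan-leukocyte marker PTPRC/CD45.
IMMUNE_GENES: tuple[str, ...] = (
    "MS4A1", "IGHG1", "IGHM", "CD14", "CD68", "CD163", "CD3E", "PTPRC",
)

#: Housekeeping genes used as the qPCR normalization reference.
HOUSEKEEPING_GENES: tuple[str, ...] = ("ACTB", "TOP1", "UBC", "YWHAZ")

#: Ten genes defining the immune sub-cluster used to rank patient clusters
#: as immune-low vs immune-high: the 8 immune markers plus the two
#: sphingolipid-associated genes that co-cluster with them.
IMMUNE_CORE_GENES: tuple[str, ...] = IMMUNE_GENES + ("S1PR4", "CD1B")


@dataclass(frozen=True)
class GeneSignature:
    """A gene signature split into sphingolipid/LPA and immune categories.

    Parameters
    ----------
    sphingo_lpa
        Sphingolipid/lysophosphatidate-associated gene symbols.
    immune
        Immune lineage marker symbols.
    hkg
        Housekeeping gene symbols (normalization reference only, never part
        of the analysis matrix).
    immune_core
        Genes used to rank patient clusters by immune content when
        assigning immune-low/high/mixed subtypes.
    """

    sphingo_lpa: tuple[str, ...] = SPHINGO_LPA_GENES
    immune: tuple[str, ...] = IMMUNE_GENES
    hkg: tuple[str, ...] = HOUSEKEEPING_GENES
    immune_core: tuple[str, ...] = IMMUNE_CORE_GENES

    def __post_init__(self) -> None:
        genes = self.genes
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene symbols in signature")
        if set(self.hkg) & set(genes):
            raise ValueError("housekeeping genes overlap signature genes")
        missing = set(self.immune_core) - set(genes)
        if missing:
            raise ValueError(f"immune_core genes not in signature: {sorted(missing)}")

    @property
    def genes(self) -> tuple[str, ...]:
        """All analysis genes (sphingolipid/LPA first, then immune)."""
        return self.sphingo_lpa + self.immune

    def category(self, gene: str) -> str:
        if gene in self.sphingo_lpa:
            return "sphingo_lpa"
        if gene in self.immune:
            return "immune"
        raise KeyError(gene)


def default_signature() -> GeneSignature:
    """The default 38/8-gene sphingolipid/LPA/immune signature."""
    return GeneSignature()
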