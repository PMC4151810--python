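"""Definition of the six-locus UGT1A genotyping panel.

The pipeline works on a fixed, ordered panel of biallelic UGT1A sites.
Genotypes are coded 0/1/2 as the count of the panel's *variant* allele
(``var_label``) — the nomenclature variant, not the cohort's minor allele.
The distinction matters: the UGT1A9*1b "variant" (the T10 promoter repeat)
is the *major* allele in East Asian cohorts, so frequency-based minor-allele
coding would silently flip that locus between cohorts.

``risk_allele`` records which allele is associated with reduced SN-38
glucuronidation (and hence toxicity risk); for UGT1A9*1b this is the
reference T9 allele.
"""

from __future__ import annotations

from dataclasses import dataclass

MISSING: int = -1  # sentinel for an untyped genotype / unknown field


@dataclass(frozen=True)
class LocusDef:
    """A biallelic site of the panel.

    ``ref_label``/``var_label`` are allele names as written in star-allele
    nomenclature (sequence strings for the two repeat polymorphisms).
    """

    locus_id: str
    gene: str
    star_or_change: str
    rs_id: str
    ref_label: str
    var_label: str
    risk_allele: str  # "ref" or "var"

    def __post_init__(self) -> None:
        if self.ref_label == self.var_label:
            raise ValueError(f"{self.locus_id}: ref and var alleles must differ")
        if self.risk_allele not in ("ref", "var"):
            raise ValueError(f"{self.locus_id}: risk_allele must be 'ref' or 'var'")

    def risk_allele_count(self, genotype: int) -> int:
        """Count of risk alleles implied by a 0/1/2 variant-allele count."""
        if genotype == MISSING:
            return MISSING
        return genotype if self.risk_allele == "var" else 2 - genotype


#: Panel order is fixed; every genotype vector and haplotype string in the
#: package is indexed against this order.
DEFAULT_PANEL: tuple[LocusDef, ...] = (
    LocusDef("UGT1A1_6", "UGT1A1", "*6", "rs4148323", "G", "A", "var"),
    LocusDef("UGT1A1_28", "UGT1A1", "*28", "rs8175347", "TA6", "TA7", "var"),
    LocusDef("UGT1A1_60", "UGT1A1", "*60", "rs4124874", "T", "G", "var"),
    LocusDef("UGT1A7_387", "UGT1A7", "387T>G", "rs17868323", "T", "G", "var"),
    LocusDef("UGT1A7_622", "UGT1A7", "622T>C", "rs11692021", "T", "C", "var"),
    LocusDef("UGT1A9_1b", "UGT1A9", "*1b", "rs35426722", "T9", "T10", "ref"),
)

PANEL_LOCUS_IDS: tuple[str, ...] = tuple(l.locus_id for l in DEFAULT_PANEL)


def validate_panel(panel: tuple[LocusDef, ...]) -> None:
    ids = [l.locus_id for l in panel]
    if len(set(ids)) != len(ids):
        raise ValueError("panel locus_id values must be unique")
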