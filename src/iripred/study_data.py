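"""Published summary statistics of the motivating irinotecan cohort.

The pipeline was developed against a 123-patient metastatic colorectal
cancer cohort (73 training / 50 validation) genotyped at six UGT1A loci.
Patient-level data were never released, but the publication prints the
marginal summaries reproduced here: per-locus genotype-by-toxicity counts,
the twelve estimated six-locus haplotypes with their frequencies, the
confusion-matrix accounting of the published rule system, and the 2x2
count pairs behind its odds ratios.  These constants are *inputs*: the
statistical engines recompute every derived quantity from them at run
time.

Haplotype allele strings are over ``{R, V}`` in panel order
(UGT1A1*6, *28, *60, UGT1A7 387, 622, UGT1A9*1b), ``V`` meaning the
panel's variant allele (A, TA7, G, G, C, T10 respectively).
"""

from __future__ import annotations

from .cohort import Cohort, PatientRecord
from .panel import DEFAULT_PANEL

# --- per-locus genotype x toxicity counts (full 123-patient cohort) -----
# {locus_id: (yes_counts, no_counts)} with genotype classes ordered by
# variant-allele count 0, 1, 2.  A None entry means the class was not
# observed (UGT1A1*28 homozygotes were dose-excluded from enrolment).
GENOTYPE_TOXICITY_COUNTS: dict[str, tuple[tuple[int, ...], tuple[int, ...]]] = {
    "UGT1A1_6": ((27, 21, 3), (57, 15, 0)),
    "UGT1A1_28": ((40, 11), (63, 9)),  # 2x2: no *28/*28 patients enrolled
    "UGT1A1_60": ((27, 20, 4), (44, 26, 2)),
    "UGT1A7_387": ((9, 34, 8), (32, 35, 5)),
    "UGT1A7_622": ((18, 31, 2), (52, 17, 3)),
    "UGT1A9_1b": ((8, 34, 9), (5, 33, 34)),  # var = T10; T9/T9 is class 0
}

# haplotype dose (0/1/2 copies) x toxicity for the three common haplotypes
HAPLOTYPE_TOXICITY_COUNTS: dict[str, tuple[tuple[int, ...], tuple[int, ...]]] = {
    "Hp-I": ((12, 32, 7), (6, 37, 29)),
    "Hp-II": ((27, 22, 2), (59, 13, 0)),
    "Hp-III": ((38, 12, 1), (53, 19, 0)),
}

# clinical dichotomies x toxicity (yes, no)
GENDER_TOXICITY_COUNTS = {"M": (31, 47), "F": (20, 25)}
AGE_TOXICITY_COUNTS = {"le60": (15, 35), "gt60": (36, 37)}

# overall outcome margin
N_TOTAL, N_TOXIC = 123, 51
N_TRAINING, N_VALIDATION = 73, 50

# --- six-locus haplotypes (complete-case population, n=103; and n=123) ---
# (name, allele_string, freq_n103, freq_n123); frequencies are printed to
# 3 dp and do not sum exactly to 1 — normalize before simulating.
HAPLOTYPES: tuple[tuple[str, str, float, float], ...] = (
    ("Hp-I", "RRRRRV", 0.524, 0.573),
    ("Hp-II", "VRRVVR", 0.170, 0.159),
    ("Hp-III", "RRVVRR", 0.131, 0.134),
    ("Hp-IV", "RVVVVR", 0.063, 0.041),
    ("Hp-V", "RVVRRV", 0.044, 0.028),
    ("Hp-VI", "RRRVVR", 0.015, 0.016),
    ("Hp-VII", "RRVVVR", 0.015, 0.012),
    ("Hp-VIII", "RVVVRR", 0.010, 0.012),
    ("Hp-IX", "RRVRRV", 0.010, 0.008),
    ("Hp-X", "VRRVVV", 0.010, 0.008),
    ("Hp-XI", "RRRVRR", 0.005, 0.004),
    ("Hp-XII", "VRRRRV", 0.005, 0.004),
)


def haplotype_frequencies(population: str = "n103") -> dict[str, float]:
    """Normalized haplotype frequency map keyed by allele string."""
    col = {"n103": 2, "n123": 3}[population]
    total = sum(h[col] for h in HAPLOTYPES)
    return {h[1]: h[col] / total for h in HAPLOTYPES}


# --- published rule-system accounting (training / validation columns) ----
# tp/fp/tn/fn are within rule-matched patients; unmatched patients are
# counted separately by outcome.
TRAINING_CONFUSION = dict(tp=19, fp=3, tn=33, fn=7, unmatched_toxic=8, unmatched_nontoxic=3)
VALIDATION_CONFUSION = dict(tp=7, fp=3, tn=24, fn=9, unmatched_toxic=1, unmatched_nontoxic=6)

# --- (toxic, non-toxic) count pairs behind the published odds ratios -----
# Reference group in both splits: patients homozygous for the most common
# haplotype (Hp-I +/+).
OR_REFERENCE = {"training": (5, 15), "validation": (2, 14)}
OR_GROUPS: dict[str, dict[str, tuple[int, int]]] = {
    "training": {
        "hpI_noncarrier_or_het": (29, 24),
        "hpII_carrier": (16, 8),
        "system_negative": (7, 33),
        "system_positive": (19, 3),
        "ugt1a1_6_carrier": (16, 9),
        "ugt1a1_28_het": (7, 7),
        "ugt1a1_60_carrier": (18, 15),
        "ugt1a7_387_carrier": (27, 21),
        "ugt1a7_622_carrier": (20, 13),
        "ugt1a9_1b_t9_carrier": (27, 20),
    },
    "validation": {
        "hpI_noncarrier_or_het": (15, 19),
        "hpII_carrier": (8, 5),
        "system_negative": (9, 24),
        "system_positive": (7, 3),
        "ugt1a1_6_carrier": (8, 6),
        "ugt1a1_28_het": (4, 2),
        "ugt1a1_60_carrier": (6, 13),
        "ugt1a7_387_carrier": (15, 19),
        "ugt1a7_622_carrier": (13, 7),
        "ugt1a9_1b_t9_carrier": (15, 18),
    },
}

# training-population age cutoff selected by ROC/Youden in the publication
PUBLISHED_AGE_CUTOFF = 60


def reconstructed_marginal_cohort() -> Cohort:
    """Synthetic 123-patient cohort reproducing the published margins.

    Within each outcome class, every locus column (and gender/age) is
    filled deterministically to match the published genotype-by-toxicity
    counts.  Columns are filled independently, so all *marginal* and
    per-locus cross-tabulations are exact while the joint structure
    (haplotype phase, LD between columns) is NOT representative — use
    :mod:`iripred.simulate` when joint structure matters.
    """
    def expand(counts_by_class):
        out = []
        for value, count in counts_by_class:
            out.extend([value] * count)
        return out

    columns: dict[str, list[int]] = {}
    for locus_id, (yes, no) in GENOTYPE_TOXICITY_COUNTS.items():
        col = expand(list(enumerate(yes))) + expand(list(enumerate(no)))
        columns[locus_id] = col
    gender = (
        expand([("M", GENDER_TOXICITY_COUNTS["M"][0]), ("F", GENDER_TOXICITY_COUNTS["F"][0])])
        + expand([("M", GENDER_TOXICITY_COUNTS["M"][1]), ("F", GENDER_TOXICITY_COUNTS["F"][1])])
    )
    age = (
        expand([(55, AGE_TOXICITY_COUNTS["le60"][0]), (65, AGE_TOXICITY_COUNTS["gt60"][0])])
        + expand([(55, AGE_TOXICITY_COUNTS["le60"][1]), (65, AGE_TOXICITY_COUNTS["gt60"][1])])
    )
    toxicity = [1] * N_TOXIC + [0] * (N_TOTAL - N_TOXIC)

    records = []
    for i in range(N_TOTAL):
        genotypes = tuple(columns[l.locus_id][i] for l in DEFAULT_PANEL)
        records.append(
            PatientRecord(f"P{i + 1:03d}", genotypes, gender[i], age[i], toxicity[i], "unassigned")
        )
    return Cohort(DEFAULT_PANEL, records)
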