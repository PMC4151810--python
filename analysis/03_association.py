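#!/usr/bin/env python
"""Per-locus toxicity associations, twice over: (a) recomputed from the
published genotype-by-toxicity counts of the 123-patient cohort, and
(b) on the simulated training cohort — exact 2xK p plus trend p each."""

import argparse
from pathlib import Path

import numpy as np

from iripred import study_data
from iripred.assoc import (
    association_report_tsv,
    cochran_armitage_trend,
    fisher_exact_2x2,
    fisher_exact_2xk,
    genotype_association_scan,
    odds_ratio_vs_reference,
)
from iripred.cohort import read_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=RESULTS / "cohort_training.tsv")
    args = ap.parse_args()
    RESULTS.mkdir(exist_ok=True)

    pub_path = RESULTS / "association_published_counts.tsv"
    with open(pub_path, "w") as fh:
        fh.write("group\tcounts_yes\tcounts_no\texact_p\ttrend_p\n")
        for locus, (yes, no) in study_data.GENOTYPE_TOXICITY_COUNTS.items():
            t = np.array([yes, no])
            p = fisher_exact_2xk(t) if len(yes) > 2 else fisher_exact_2x2(t)
            trend = (f"{cochran_armitage_trend(t)[1]:.3f}" if len(yes) > 2 else "-")
            fh.write(f"{locus}\t{yes}\t{no}\t{p:.3f}\t{trend}\n")
            print(f"{locus}: exact p = {p:.3f}, trend p = {trend}")
        for label, pair in (("gender", study_data.GENDER_TOXICITY_COUNTS),
                            ("age", study_data.AGE_TOXICITY_COUNTS)):
            t = np.array(list(pair.values())).T
            p = fisher_exact_2x2(t)
            fh.write(f"{label}\t{tuple(t[0])}\t{tuple(t[1])}\t{p:.3f}\t-\n")
            print(f"{label}: exact p = {p:.3f}")
    print(f"published-count associations -> {pub_path}")

    # odds ratios against the common-haplotype homozygote reference
    or_path = RESULTS / "odds_ratios_published_counts.tsv"
    with open(or_path, "w") as fh:
        fh.write("split\tgroup\tOR\tci_low\tci_high\tfisher_p\n")
        for split in ("training", "validation"):
            ref = study_data.OR_REFERENCE[split]
            for group, counts in study_data.OR_GROUPS[split].items():
                r = odds_ratio_vs_reference(counts, ref)
                fh.write(f"{split}\t{group}\t{r.odds_ratio:.2f}\t{r.ci95[0]:.2f}\t"
                         f"{r.ci95[1]:.2f}\t{r.p_fisher:.3f}\n")
    print(f"odds ratios -> {or_path}")

    sim_path = RESULTS / "association_simulated.tsv"
    cohort = read_cohort(args.cohort)
    association_report_tsv(genotype_association_scan(cohort), sim_path)
    print(f"simulated-cohort associations -> {sim_path}")


if __name__ == "__main__":
    main()
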