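#!/usr/bin/env python
"""Score the learned rule system on the simulated training and validation
cohorts: matched fraction, accuracy among matched patients, PPV/NPV, and
the overall accuracy/sensitivity/specificity that count unmatched patients
as errors.  Also reports the odds ratio of toxicity for positively
predicted patients against the rule-negative group."""

import argparse
from pathlib import Path

from iripred.assoc import odds_ratio_vs_reference
from iripred.cohort import read_cohort
from iripred.patterns import RuleSystem
from iripred.predict import evaluate_rule_system

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--rules", type=Path, default=RESULTS / "rules.json")
    args = ap.parse_args()
    system = RuleSystem.from_json(args.rules)

    out_path = RESULTS / "evaluation.tsv"
    with open(out_path, "w") as fh:
        fh.write("split\tmetric\tpercent\n")
        for split in ("training", "validation"):
            cohort = read_cohort(RESULTS / f"cohort_{split}.tsv")
            report = evaluate_rule_system(system, cohort)
            print(report.format_block(f"{split} (n={report.n})"))
            for metric, value in report.as_percent_dict().items():
                fh.write(f"{split}\t{metric}\t{value}\n")
            if report.tp + report.fp > 0 and report.fn + report.tn > 0:
                r = odds_ratio_vs_reference((report.tp, report.fp),
                                            (report.fn, report.tn))
                print(f"  OR, predicted-positive vs predicted-negative: "
                      f"{r.odds_ratio:.2f} ({r.ci95[0]:.2f}-{r.ci95[1]:.2f}), "
                      f"p = {r.p_fisher:.3g}")
            print()
    print(f"evaluation table -> {out_path}")


if __name__ == "__main__":
    main()
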