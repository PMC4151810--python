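#!/usr/bin/env python
"""Learn the combination rule system from the simulated training cohort:
Youden age cutoff, exhaustive evaluation of all 36,863 patterns, support
and predictive-value filtering at >= 2 matches / >= 80%, redundancy
pruning.  Writes the system as JSON and a readable TSV."""

import argparse
from pathlib import Path

from iripred.cohort import read_cohort
from iripred.patterns import RuleConfig, build_rule_system

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=RESULTS / "cohort_training.tsv")
    ap.add_argument("--min-pred", type=float, default=0.80)
    ap.add_argument("--min-support", type=int, default=2)
    ap.add_argument("--sffs", action="store_true",
                    help="pre-select the slot universe with SFFS")
    args = ap.parse_args()

    cohort = read_cohort(args.cohort)
    config = RuleConfig(min_support=args.min_support, min_pred_value=args.min_pred,
                        use_sffs=args.sffs)
    system = build_rule_system(cohort, config)

    cand = system.provenance["n_candidates"]
    print(f"age cutoff (Youden): {system.age_cutoff} years")
    print(f"candidates passing filters: {cand['positive']} positive, "
          f"{cand['negative']} negative")
    print(f"after redundancy pruning:   {len(system.positive_rules)} positive, "
          f"{len(system.negative_rules)} negative rules")
    if args.sffs:
        print(f"SFFS-selected features: {system.provenance['sffs']['selected']}")

    system.to_json(RESULTS / "rules.json")
    system.to_tsv(RESULTS / "rules.tsv")
    print(f"rule system -> {RESULTS / 'rules.json'} and rules.tsv")


if __name__ == "__main__":
    main()
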