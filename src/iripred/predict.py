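"""Apply a rule system to patients and score its predictive performance.

Unmatched patients (no rule fires) count against overall accuracy,
sensitivity and specificity but are excluded from the within-matched
metrics (accuracy-in-matched, PPV, NPV) — the accounting used for a
screening system whose rules deliberately abstain on unseen profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .assoc import AssocResult, odds_ratio_vs_reference
from .cohort import Cohort, PatientRecord
from .patterns import PatternStats, RuleSystem, pattern_matches

log = logging.getLogger(__name__)

POSITIVE, NEGATIVE, UNMATCHED = "POSITIVE", "NEGATIVE", "UNMATCHED"


@dataclass(frozen=True)
class PredictionOutcome:
    patient_id: str
    label: str
    fired_positive: tuple[int, ...] = ()
    fired_negative: tuple[int, ...] = ()
    conflict: bool = False


@dataclass(frozen=True)
class EvaluationReport:
    n: int
    tp: int
    fp: int
    tn: int
    fn: int
    unmatched_toxic: int
    unmatched_nontoxic: int

    @property
    def n_matched(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_unmatched(self) -> int:
        return self.unmatched_toxic + self.unmatched_nontoxic

    @property
    def matched_fraction(self) -> float:
        return self.n_matched / self.n if self.n else float("nan")

    @property
    def accuracy_in_matched(self) -> float:
        return (self.tp + self.tn) / self.n_matched if self.n_matched else float("nan")

    @property
    def ppv(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def npv(self) -> float:
        d = self.tn + self.fn
        return self.tn / d if d else float("nan")

    @property
    def overall_accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else float("nan")

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn + self.unmatched_toxic
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp + self.unmatched_nontoxic
        return self.tn / d if d else float("nan")

    def as_percent_dict(self) -> dict[str, float]:
        """The report in the units of the published table (percent, 1 dp)."""
        return {
            "matched": round(100 * self.matched_fraction, 1),
            "accuracy_in_matched": round(100 * self.accuracy_in_matched, 1),
            "ppv": round(100 * self.ppv, 1),
            "npv": round(100 * self.npv, 1),
            "overall_accuracy": round(100 * self.overall_accuracy, 1),
            "sensitivity": round(100 * self.sensitivity, 1),
            "specificity": round(100 * self.specificity, 1),
        }

    def format_block(self, title: str = "Predictive performance") -> str:
        lines = [
            title,
            f"  Matched with a combination   {self.n_matched}/{self.n} ({100 * self.matched_fraction:.1f}%)",
            f"  Accuracy in applied patients {self.tp + self.tn}/{self.n_matched} ({100 * self.accuracy_in_matched:.1f}%)",
            f"  Positive predictive value    {self.tp}/{self.tp + self.fp} ({100 * self.ppv:.1f}%)",
            f"  Negative predictive value    {self.tn}/{self.tn + self.fn} ({100 * self.npv:.1f}%)",
            f"  Accuracy                     {self.tp + self.tn}/{self.n} ({100 * self.overall_accuracy:.1f}%)",
            f"  Sensitivity                  {self.tp}/{self.tp + self.fn + self.unmatched_toxic} ({100 * self.sensitivity:.1f}%)",
            f"  Specificity                  {self.tn}/{self.tn + self.fp + self.unmatched_nontoxic} ({100 * self.specificity:.1f}%)",
        ]
        return "\n".join(lines)


def predict_patient(system: RuleSystem, patient: PatientRecord) -> PredictionOutcome:
    """Label a patient POSITIVE/NEGATIVE/UNMATCHED under a rule system.

    If rules of both categories fire, the conflict is resolved toward the
    category holding the highest training predictive value, ties toward
    POSITIVE (safety first); the conflict is flagged and logged.
    """
    if system.n_rules == 0:
        raise ValueError("empty rule system")
    fired_pos = tuple(
        i for i, s in enumerate(system.positive_rules)
        if pattern_matches(s.pattern, patient, system.age_cutoff)
    )
    fired_neg = tuple(
        i for i, s in enumerate(system.negative_rules)
        if pattern_matches(s.pattern, patient, system.age_cutoff)
    )
    if fired_pos and fired_neg:
        best_pos = max(system.positive_rules[i].pred_value("positive") for i in fired_pos)
        best_neg = max(system.negative_rules[i].pred_value("negative") for i in fired_neg)
        label = NEGATIVE if best_neg > best_pos else POSITIVE
        log.info("patient %s matches both categories (pos %.3f vs neg %.3f) -> %s",
                 patient.patient_id, best_pos, best_neg, label)
        return PredictionOutcome(patient.patient_id, label, fired_pos, fired_neg, conflict=True)
    if fired_pos:
        return PredictionOutcome(patient.patient_id, POSITIVE, fired_pos, ())
    if fired_neg:
        return PredictionOutcome(patient.patient_id, NEGATIVE, (), fired_neg)
    return PredictionOutcome(patient.patient_id, UNMATCHED)


def evaluate_rule_system(system: RuleSystem, cohort: Cohort) -> EvaluationReport:
    """Score a rule system on a cohort with known outcomes."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    records = [r for r in cohort if r.toxicity is not None]
    if len(records) < len(cohort):
        log.warning("%d patients with unknown toxicity excluded from evaluation",
                    len(cohort) - len(records))
    if not records:
        raise ValueError("no patient has a known outcome")
    tp = fp = tn = fn = um_tox = um_non = 0
    for rec in records:
        outcome = predict_patient(system, rec)
        if outcome.label == POSITIVE:
            if rec.toxicity:
                tp += 1
            else:
                fp += 1
        elif outcome.label == NEGATIVE:
            if rec.toxicity:
                fn += 1
            else:
                tn += 1
        else:
            if rec.toxicity:
                um_tox += 1
            else:
                um_non += 1
    return EvaluationReport(len(records), tp, fp, tn, fn, um_tox, um_non)


def prediction_association(report: EvaluationReport, reference: tuple[int, int]) -> AssocResult:
    """Odds ratio of toxicity for positively predicted patients vs a
    reference group of (toxic, non-toxic) counts."""
    return odds_ratio_vs_reference(
        (report.tp, report.fp), reference,
        label="prediction_positive", ref_label="configured reference group",
    )


def predictions_tsv(system: RuleSystem, cohort: Cohort, path) -> None:
    with open(path, "w") as fh:
        fh.write("patient_id\tlabel\tfired_positive\tfired_negative\tconflict\n")
        for rec in cohort:
            o = predict_patient(system, rec)
            fh.write(
                f"{o.patient_id}\t{o.label}\t"
                + ",".join(f"P{i + 1}" for i in o.fired_positive) + "\t"
                + ",".join(f"N{i + 1}" for i in o.fired_negative) + "\t"
                + ("yes" if o.conflict else "no") + "\n"
            )
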