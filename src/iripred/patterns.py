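"""Combination-pattern rule discovery over genotypes, gender and age.

A *pattern* assigns each of the six genotype slots one of
{HOM_REF, HET, HOM_VAR, ANY}, the gender slot one of {M, F, ANY} and the
age slot one of {LE (<= cutoff), GT (> cutoff), ANY}; the all-ANY pattern
is excluded, giving 4^6 x 3^2 - 1 = 36,863 candidate combinations for the
default panel.  The engine exhaustively evaluates every pattern on a
training cohort, keeps those with at least ``min_support`` matches and a
positive (or negative) predictive value of at least ``min_pred_value``,
and prunes patterns dominated by a retained generalization.  Sequential
forward floating selection (SFFS) over the eight features is available as
an optional pre-selection of the slots the patterns may constrain.

Exhaustive evaluation is O(n * 2^8): a patient with no missing fields is
matched by exactly 2^8 patterns (each slot either equals the patient's
value or is ANY), so match/toxic counts for the whole pattern space are
accumulated by enumerating those per-patient index sets.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .cohort import Cohort, PatientRecord
from .panel import MISSING

ANY_GENO = 3  # genotype slot wildcard (slots 0/1/2 are literal counts)
ANY_CLIN = 2  # gender/age slot wildcard
GENO_TOKENS = {0: "HOM_REF", 1: "HET", 2: "HOM_VAR", 3: "ANY"}
GENDER_TOKENS = {0: "M", 1: "F", 2: "ANY"}
AGE_TOKENS = {0: "LE", 1: "GT", 2: "ANY"}
_TOKEN_TO_GENO = {v: k for k, v in GENO_TOKENS.items()}
_TOKEN_TO_GENDER = {v: k for k, v in GENDER_TOKENS.items()}
_TOKEN_TO_AGE = {v: k for k, v in AGE_TOKENS.items()}

#: age cutoff used when no training cohort is available to select one
DEFAULT_AGE_CUTOFF = 60

_PRED_TOL = 1e-9  # guards inclusive >= threshold comparisons in float


@dataclass(frozen=True)
class Pattern:
    genotype_slots: tuple[int, ...]
    gender_slot: int = ANY_CLIN
    age_slot: int = ANY_CLIN

    def __post_init__(self) -> None:
        if all(s == ANY_GENO for s in self.genotype_slots) and \
                self.gender_slot == ANY_CLIN and self.age_slot == ANY_CLIN:
            raise ValueError("the all-ANY pattern is excluded")

    @property
    def specificity(self) -> int:
        return (
            sum(1 for s in self.genotype_slots if s != ANY_GENO)
            + (self.gender_slot != ANY_CLIN)
            + (self.age_slot != ANY_CLIN)
        )

    def key(self) -> tuple[int, ...]:
        return (*self.genotype_slots, self.gender_slot, self.age_slot)

    def tokens(self) -> tuple[str, ...]:
        return (
            *(GENO_TOKENS[s] for s in self.genotype_slots),
            GENDER_TOKENS[self.gender_slot],
            AGE_TOKENS[self.age_slot],
        )

    @classmethod
    def from_tokens(cls, tokens) -> "Pattern":
        *geno, gender, age = tokens
        return cls(
            tuple(_TOKEN_TO_GENO[t] for t in geno),
            _TOKEN_TO_GENDER[gender],
            _TOKEN_TO_AGE[age],
        )

    def generalizations(self):
        """Every pattern obtained by relaxing a non-empty slot subset to ANY."""
        options = [
            ((s,) if s == ANY_GENO else (s, ANY_GENO)) for s in self.genotype_slots
        ]
        options.append((self.gender_slot,) if self.gender_slot == ANY_CLIN else (self.gender_slot, ANY_CLIN))
        options.append((self.age_slot,) if self.age_slot == ANY_CLIN else (self.age_slot, ANY_CLIN))
        for combo in product(*options):
            if combo == self.key():
                continue
            try:
                yield Pattern(tuple(combo[:-2]), combo[-2], combo[-1])
            except ValueError:
                continue  # the all-ANY relaxation

    def constrained_features(self, locus_ids) -> frozenset[str]:
        feats = {l for l, s in zip(locus_ids, self.genotype_slots) if s != ANY_GENO}
        if self.gender_slot != ANY_CLIN:
            feats.add("gender")
        if self.age_slot != ANY_CLIN:
            feats.add("age")
        return frozenset(feats)


@dataclass(frozen=True)
class PatternStats:
    pattern: Pattern
    n_match: int
    n_toxic: int

    @property
    def toxic_rate(self) -> float:
        return self.n_toxic / self.n_match if self.n_match else float("nan")

    def pred_value(self, category: str) -> float:
        if not self.n_match:
            return float("nan")
        return self.toxic_rate if category == "positive" else 1.0 - self.toxic_rate


# ---------------------------------------------------------------------------
# enumeration and matching
# ---------------------------------------------------------------------------

def count_patterns(n_genotype_slots: int, include_gender: bool = True,
                   include_age: bool = True) -> int:
    return 4 ** n_genotype_slots * 3 ** (int(include_gender) + int(include_age)) - 1


def enumerate_patterns(n_genotype_slots: int, include_gender: bool = True,
                       include_age: bool = True):
    """Lazily yield every pattern exactly once (all-ANY excluded)."""
    if n_genotype_slots < 1:
        raise ValueError("need at least one genotype slot")
    gender_opts = (0, 1, ANY_CLIN) if include_gender else (ANY_CLIN,)
    age_opts = (0, 1, ANY_CLIN) if include_age else (ANY_CLIN,)
    for slots in product((0, 1, 2, ANY_GENO), repeat=n_genotype_slots):
        for g in gender_opts:
            for a in age_opts:
                try:
                    yield Pattern(slots, g, a)
                except ValueError:
                    continue


def pattern_matches(pattern: Pattern, patient: PatientRecord, age_cutoff: int) -> bool:
    """True iff every non-ANY slot equals the patient's value.

    A field that is MISSING can never satisfy a non-ANY slot.  Age is
    dichotomized as (<= cutoff) / (> cutoff).
    """
    for slot, g in zip(pattern.genotype_slots, patient.genotypes):
        if slot != ANY_GENO and g != slot:
            return False
    if pattern.gender_slot != ANY_CLIN:
        if patient.gender is None or {"M": 0, "F": 1}[patient.gender] != pattern.gender_slot:
            return False
    if pattern.age_slot != ANY_CLIN:
        side = 0 if patient.age_years <= age_cutoff else 1
        if side != pattern.age_slot:
            return False
    return True


def evaluate_pattern(pattern: Pattern, cohort: Cohort, age_cutoff: int) -> PatternStats:
    """Match/toxic counts over patients with known toxicity."""
    n_match = n_toxic = 0
    for rec in cohort:
        if rec.toxicity is None:
            continue
        if pattern_matches(pattern, rec, age_cutoff):
            n_match += 1
            n_toxic += rec.toxicity
    return PatternStats(pattern, n_match, n_toxic)


# ---------------------------------------------------------------------------
# vectorized exhaustive evaluation
# ---------------------------------------------------------------------------

def _pattern_index(key: tuple[int, ...], g: int) -> int:
    idx = 0
    for s in key[:g]:
        idx = idx * 4 + s
    idx = idx * 3 + key[g]
    idx = idx * 3 + key[g + 1]
    return idx


def _index_to_pattern(idx: int, g: int) -> Pattern:
    age = idx % 3
    idx //= 3
    gender = idx % 3
    idx //= 3
    slots = []
    for _ in range(g):
        slots.append(idx % 4)
        idx //= 4
    return Pattern(tuple(reversed(slots)), gender, age)


def evaluate_all_patterns(cohort: Cohort, age_cutoff: int) -> tuple[np.ndarray, np.ndarray]:
    """(n_match, n_toxic) over the full pattern space, indexed canonically.

    Patients with missing toxicity are excluded entirely; a missing
    genotype or gender only blocks patterns that constrain that slot.
    """
    g = len(cohort.panel)
    size = 4 ** g * 9
    n_match = np.zeros(size, dtype=np.int64)
    n_toxic = np.zeros(size, dtype=np.int64)
    tox = cohort.toxicity_array()
    keep = tox != MISSING
    if not keep.any():
        return n_match, n_toxic
    G = cohort.genotype_matrix()[keep]
    sex = cohort.gender_array()[keep]
    side = (cohort.age_array()[keep] > age_cutoff).astype(np.int64)
    toxic = tox[keep] == 1
    n = G.shape[0]
    n_slots = g + 2

    for mask in range(1 << n_slots):
        idx = np.zeros(n, dtype=np.int64)
        valid = np.ones(n, dtype=bool)
        for i in range(g):
            if mask & (1 << i):
                digit = G[:, i]
                valid &= digit != MISSING
                digit = np.where(digit == MISSING, 0, digit)
            else:
                digit = np.full(n, ANY_GENO, dtype=np.int64)
            idx = idx * 4 + digit
        if mask & (1 << g):
            digit = sex
            valid &= digit != MISSING
            digit = np.where(digit == MISSING, 0, digit)
        else:
            digit = np.full(n, ANY_CLIN, dtype=np.int64)
        idx = idx * 3 + digit
        if mask & (1 << (g + 1)):
            idx = idx * 3 + side
        else:
            idx = idx * 3 + ANY_CLIN
        np.add.at(n_match, idx[valid], 1)
        np.add.at(n_toxic, idx[valid & toxic], 1)
    return n_match, n_toxic


# ---------------------------------------------------------------------------
# age cutoff by Youden index
# ---------------------------------------------------------------------------

def determine_age_cutoff(cohort: Cohort, candidate_ages=None) -> int:
    """Age threshold maximizing Youden's J for "age > t predicts toxicity".

    Candidate thresholds default to the distinct observed ages; ties are
    broken toward the smallest threshold.
    """
    ages, labels = [], []
    for rec in cohort:
        if rec.toxicity is None:
            continue
        ages.append(rec.age_years)
        labels.append(rec.toxicity)
    ages = np.asarray(ages)
    labels = np.asarray(labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both toxic and non-toxic patients to pick a cutoff")
    cands = sorted(set(candidate_ages) if candidate_ages is not None else set(ages.tolist()))
    best_t, best_j = None, -np.inf
    for t in cands:
        sens = np.sum((ages > t) & (labels == 1)) / n_pos
        spec = np.sum((ages <= t) & (labels == 0)) / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return int(best_t)


# ---------------------------------------------------------------------------
# candidate generation, filtering, pruning
# ---------------------------------------------------------------------------

def build_candidate_rules(
    cohort: Cohort,
    age_cutoff: int,
    min_support: int = 2,
    min_pred_value: float = 0.80,
    allowed_features: frozenset[str] | None = None,
) -> tuple[list[PatternStats], list[PatternStats]]:
    """All patterns meeting the support and predictive-value thresholds.

    Support excludes unobserved and single-case patterns (min_support = 2
    by default); thresholds are inclusive at ``min_pred_value``.  If
    ``allowed_features`` is given, patterns constraining any other slot
    are discarded (the SFFS-restricted search space).
    """
    g = len(cohort.panel)
    locus_ids = tuple(l.locus_id for l in cohort.panel)
    n_match, n_toxic = evaluate_all_patterns(cohort, age_cutoff)
    support_ok = np.flatnonzero(n_match >= min_support)
    positive: list[PatternStats] = []
    negative: list[PatternStats] = []
    for idx in support_ok:
        m = int(n_match[idx])
        t = int(n_toxic[idx])
        is_pos = t + _PRED_TOL >= min_pred_value * m
        is_neg = (m - t) + _PRED_TOL >= min_pred_value * m
        if not (is_pos or is_neg):
            continue
        try:
            pat = _index_to_pattern(int(idx), g)
        except ValueError:
            continue  # all-ANY index
        if allowed_features is not None and \
                not pat.constrained_features(locus_ids) <= allowed_features:
            continue
        stats = PatternStats(pat, m, t)
        if is_pos:
            positive.append(stats)
        if is_neg:
            negative.append(stats)
    positive.sort(key=lambda s: s.pattern.key())
    negative.sort(key=lambda s: s.pattern.key())
    return positive, negative


def prune_redundant(candidates: list[PatternStats], category: str) -> list[PatternStats]:
    """Drop patterns dominated by a retained generalization.

    A candidate A is redundant when some retained B constrains a subset of
    A's slots with the same values (so matches(A) is a subset of
    matches(B)) and B's predictive value is at least A's.  Candidates are
    processed by increasing specificity, then lexicographic slot order, so
    among equivalent patterns the most general, lexicographically smallest
    survives.  Pruning never changes the rule set's predictions: every
    removed pattern's matches are covered by a retained same-category rule.
    """
    if category not in ("positive", "negative"):
        raise ValueError("category must be 'positive' or 'negative'")
    retained: dict[tuple[int, ...], float] = {}
    out: list[PatternStats] = []
    for stats in sorted(candidates, key=lambda s: (s.pattern.specificity, s.pattern.key())):
        pv = stats.pred_value(category)
        dominated = any(
            retained.get(gen.key(), -np.inf) + _PRED_TOL >= pv
            for gen in stats.pattern.generalizations()
        )
        if not dominated:
            retained[stats.pattern.key()] = pv
            out.append(stats)
    out.sort(key=lambda s: s.pattern.key())
    return out


# ---------------------------------------------------------------------------
# SFFS feature selection
# ---------------------------------------------------------------------------

@dataclass
class SFFSState:
    best_subsets: dict[int, frozenset[str]]
    criterion_values: dict[int, object]
    selected: frozenset[str]


def sffs_select(criterion, feature_universe, d_target: int | None = None) -> SFFSState:
    """Sequential forward floating selection over a feature universe.

    ``criterion`` maps a frozenset of features to a comparable score
    (float or tuple).  Starting from the empty set, each round adds the
    feature improving the criterion most (step 1), then conditionally
    removes the least useful feature and keeps floating backward while
    doing so improves the recorded best value at the smaller size
    (steps 2-3, applied only while the current size exceeds 2).  The best
    subset of every visited size is recorded.

    The per-size records are seeded with a plain sequential-forward ascent
    before floating begins, so the returned subsets are never worse than
    forward selection's at any size (floating can only improve them).
    """
    features = sorted(feature_universe)
    target = d_target if d_target is not None else len(features)
    if not 0 < target <= len(features):
        raise ValueError("d_target out of range")

    def J(subset: frozenset[str]):
        val = criterion(subset)
        try:
            finite = np.all(np.isfinite(np.asarray(val, dtype=float)))
        except (TypeError, ValueError):
            finite = True
        if not finite:
            raise ValueError(f"criterion non-finite on subset {sorted(subset)}")
        return val

    X = frozenset()
    k = 0
    best_sub: dict[int, frozenset[str]] = {0: X}
    best_val: dict[int, object] = {0: J(X)}

    # seed: plain forward ascent (the algorithm with no exclusions taken)
    F = frozenset()
    for size in range(1, len(features) + 1):
        scored = sorted(((J(F | {f}), f) for f in features if f not in F),
                        key=lambda t: t[1])
        val_f, x_f = max(scored, key=lambda t: t[0])
        F = F | {x_f}
        best_val[size], best_sub[size] = val_f, F

    while k < len(features):
        # step 1: conditional inclusion
        remaining = [f for f in features if f not in X]
        scored = [(J(X | {f}), f) for f in remaining]
        scored.sort(key=lambda t: t[1])
        val_j, x_j = max(scored, key=lambda t: t[0])
        X = X | {x_j}
        k += 1
        if k not in best_val or val_j > best_val[k]:
            best_val[k], best_sub[k] = val_j, X

        # steps 2-3: conditional exclusion with backward floating
        while k > 2:
            scored_r = [(J(X - {f}), f) for f in sorted(X)]
            val_r, x_r = max(scored_r, key=lambda t: t[0])
            if x_r == x_j or not val_r > best_val.get(k - 1, -np.inf):
                break
            X = X - {x_r}
            k -= 1
            best_val[k], best_sub[k] = val_r, X
            x_j = None  # further removals are unconditional floating
        if k >= target and target in best_sub:
            break

    sizes = [s for s in best_sub if s > 0]
    if d_target is not None:
        chosen = best_sub[min(best_sub, key=lambda s: abs(s - target))] if target not in best_sub else best_sub[target]
    else:
        chosen = best_sub[max(sizes, key=lambda s: (best_val[s], -s))] if sizes else frozenset()
    return SFFSState(best_sub, best_val, chosen)


# ---------------------------------------------------------------------------
# rule system
# ---------------------------------------------------------------------------

@dataclass
class RuleConfig:
    min_support: int = 2
    min_pred_value: float = 0.80
    age_cutoff: int | str = "auto"
    use_sffs: bool = False
    sffs_target_k: int | None = None

    def to_dict(self) -> dict:
        return {
            "min_support": self.min_support,
            "min_pred_value": self.min_pred_value,
            "age_cutoff": self.age_cutoff,
            "use_sffs": self.use_sffs,
            "sffs_target_k": self.sffs_target_k,
        }


@dataclass
class RuleSystem:
    positive_rules: list[PatternStats]
    negative_rules: list[PatternStats]
    age_cutoff: int
    locus_ids: tuple[str, ...]
    min_support: int = 2
    min_pred_value: float = 0.80
    provenance: dict = field(default_factory=dict)

    @property
    def n_rules(self) -> int:
        return len(self.positive_rules) + len(self.negative_rules)

    def to_json(self, path=None) -> str:
        def rule_dict(stats: PatternStats, category: str) -> dict:
            return {
                "slots": list(stats.pattern.tokens()),
                "n_match": stats.n_match,
                "n_toxic": stats.n_toxic,
                "pred_value": stats.pred_value(category),
                "category": category,
            }

        doc = {
            "age_cutoff": self.age_cutoff,
            "locus_ids": list(self.locus_ids),
            "min_support": self.min_support,
            "min_pred_value": self.min_pred_value,
            "provenance": self.provenance,
            "positive_rules": [rule_dict(s, "positive") for s in self.positive_rules],
            "negative_rules": [rule_dict(s, "negative") for s in self.negative_rules],
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "RuleSystem":
        if hasattr(source, "read"):
            doc = json.load(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)

        def parse(rules):
            return [
                PatternStats(Pattern.from_tokens(r["slots"]), r["n_match"], r["n_toxic"])
                for r in rules
            ]

        return cls(
            parse(doc["positive_rules"]),
            parse(doc["negative_rules"]),
            doc["age_cutoff"],
            tuple(doc["locus_ids"]),
            doc["min_support"],
            doc["min_pred_value"],
            doc.get("provenance", {}),
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("category\t" + "\t".join(self.locus_ids) + "\tgender\tage\tn_match\tn_toxic\tpred_value\n")
            for category, rules in (("positive", self.positive_rules), ("negative", self.negative_rules)):
                for s in rules:
                    fh.write(
                        category + "\t" + "\t".join(s.pattern.tokens())
                        + f"\t{s.n_match}\t{s.n_toxic}\t{s.pred_value(category):.3f}\n"
                    )


def rule_system_criterion(cohort: Cohort, age_cutoff: int, min_support: int = 2,
                          min_pred_value: float = 0.80):
    """SFFS criterion J: overall training accuracy of the rule system built
    from patterns restricted to a feature subset, tie-broken by the number
    of rule-matched patients."""
    from .predict import evaluate_rule_system  # local import avoids a cycle

    locus_ids = tuple(l.locus_id for l in cohort.panel)
    cache: dict[frozenset[str], tuple[float, int]] = {}

    def J(subset: frozenset[str]) -> tuple[float, int]:
        subset = frozenset(subset)
        if subset in cache:
            return cache[subset]
        pos, neg = build_candidate_rules(
            cohort, age_cutoff, min_support, min_pred_value, allowed_features=subset
        )
        system = RuleSystem(
            prune_redundant(pos, "positive"), prune_redundant(neg, "negative"),
            age_cutoff, locus_ids, min_support, min_pred_value,
        )
        if system.n_rules == 0:
            cache[subset] = (0.0, 0)
            return cache[subset]
        report = evaluate_rule_system(system, cohort)
        cache[subset] = (report.overall_accuracy, report.n_matched)
        return cache[subset]

    return J


def build_rule_system(cohort: Cohort, config: RuleConfig | None = None) -> RuleSystem:
    """Full training pipeline: age cutoff -> (optional SFFS) -> exhaustive
    enumeration -> support/predictive-value filtering -> redundancy pruning.
    """
    config = config or RuleConfig()
    if config.age_cutoff == "auto":
        age_cutoff = determine_age_cutoff(cohort)
    else:
        age_cutoff = int(config.age_cutoff)

    locus_ids = tuple(l.locus_id for l in cohort.panel)
    allowed = None
    sffs_info = None
    if config.use_sffs:
        criterion = rule_system_criterion(
            cohort, age_cutoff, config.min_support, config.min_pred_value
        )
        state = sffs_select(criterion, (*locus_ids, "gender", "age"), config.sffs_target_k)
        allowed = state.selected
        sffs_info = {
            "selected": sorted(state.selected),
            "criterion_values": {str(k): list(map(float, np.atleast_1d(np.asarray(v, dtype=float))))
                                 for k, v in state.criterion_values.items()},
        }

    pos, neg = build_candidate_rules(
        cohort, age_cutoff, config.min_support, config.min_pred_value, allowed_features=allowed
    )
    positive = prune_redundant(pos, "positive")
    negative = prune_redundant(neg, "negative")
    if not positive and not negative:
        warnings.warn("no patterns survived filtering; rule system is empty", stacklevel=2)

    cohort_hash = hashlib.sha256(
        "\n".join(f"{r.patient_id},{r.genotypes},{r.gender},{r.age_years},{r.toxicity}"
                  for r in cohort).encode()
    ).hexdigest()[:16]
    provenance = {
        "n_training": len(cohort),
        "training_hash": cohort_hash,
        "config": config.to_dict(),
        "n_candidates": {"positive": len(pos), "negative": len(neg)},
        "sffs": sffs_info,
    }
    return RuleSystem(positive, negative, age_cutoff, locus_ids,
                      config.min_support, config.min_pred_value, provenance)
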