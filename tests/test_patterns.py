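import time
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iripred.cohort import Cohort, PatientRecord
from iripred.panel import DEFAULT_PANEL, PANEL_LOCUS_IDS
from iripred.patterns import (
    ANY_CLIN,
    ANY_GENO,
    DEFAULT_AGE_CUTOFF,
    Pattern,
    PatternStats,
    RuleConfig,
    build_candidate_rules,
    build_rule_system,
    count_patterns,
    determine_age_cutoff,
    enumerate_patterns,
    evaluate_all_patterns,
    evaluate_pattern,
    pattern_matches,
    prune_redundant,
    sffs_select,
)
from iripred.predict import evaluate_rule_system, predict_patient
from iripred.simulate import default_paper_like_config, simulate_cohort

ALL_ANY_BUT = lambda **kw: Pattern(
    tuple(kw.get(f"g{i}", ANY_GENO) for i in range(6)),
    kw.get("gender", ANY_CLIN),
    kw.get("age", ANY_CLIN),
)


# ---------------------------------------------------------------- enumeration

@pytest.mark.parametrize(
    "g, gender, age, expected",
    [(6, True, True, 36863), (1, False, False, 3), (2, False, False, 15)],
)
def test_pattern_count_closed_form(g, gender, age, expected):
    assert count_patterns(g, gender, age) == expected
    patterns = list(enumerate_patterns(g, gender, age))
    assert len(patterns) == expected
    assert len(set(p.key() for p in patterns)) == expected


def test_enumeration_matches_count_for_small_slot_numbers():
    for g in (1, 2, 3):
        for gender, age in product((False, True), repeat=2):
            pats = set(p.key() for p in enumerate_patterns(g, gender, age))
            assert len(pats) == count_patterns(g, gender, age)


def test_all_any_pattern_is_excluded():
    with pytest.raises(ValueError):
        Pattern((ANY_GENO,) * 6, ANY_CLIN, ANY_CLIN)


# ------------------------------------------------------------------- matching

def test_matching_semantics():
    patient = PatientRecord("x", (2, 1, 0, -1, 0, 0), "M", 60, 1)
    assert pattern_matches(ALL_ANY_BUT(g0=2), patient, 60)
    assert not pattern_matches(ALL_ANY_BUT(g0=1), patient, 60)
    # a MISSING genotype never satisfies a non-ANY slot
    assert not pattern_matches(ALL_ANY_BUT(g3=0), patient, 60)
    # age 60 with cutoff 60 is on the LE side
    assert pattern_matches(ALL_ANY_BUT(age=0), patient, 60)
    assert not pattern_matches(ALL_ANY_BUT(age=1), patient, 60)
    assert pattern_matches(ALL_ANY_BUT(gender=0), patient, 60)
    missing_gender = PatientRecord("y", (0,) * 6, None, 50, 0)
    assert not pattern_matches(ALL_ANY_BUT(gender=0), missing_gender, 60)


@given(st.data())
@settings(max_examples=80, derandomize=True)
def test_matching_monotone_under_slot_relaxation(data):
    slots = tuple(data.draw(st.integers(0, 3)) for _ in range(6))
    gender = data.draw(st.integers(0, 2))
    age = data.draw(st.integers(0, 2))
    if all(s == ANY_GENO for s in slots) and gender == ANY_CLIN and age == ANY_CLIN:
        return
    pattern = Pattern(slots, gender, age)
    patient = PatientRecord(
        "p",
        tuple(data.draw(st.sampled_from([0, 1, 2, -1])) for _ in range(6)),
        data.draw(st.sampled_from(["M", "F", None])),
        data.draw(st.integers(20, 90)),
        1,
    )
    matched = pattern_matches(pattern, patient, 60)
    for gen in pattern.generalizations():
        if matched:
            assert pattern_matches(gen, patient, 60)


def test_evaluate_pattern_on_marginal_cohort(marginal_cohort):
    male_only = ALL_ANY_BUT(gender=0)
    stats = evaluate_pattern(male_only, marginal_cohort, 60)
    assert (stats.n_match, stats.n_toxic) == (78, 31)


def test_evaluate_pattern_excludes_unknown_toxicity(tiny_cohort):
    # patient "f" matches but has unknown outcome
    stats = evaluate_pattern(ALL_ANY_BUT(g5=2), tiny_cohort, 60)
    assert (stats.n_match, stats.n_toxic) == (2, 0)


def test_vectorized_evaluation_agrees_with_scalar(marginal_cohort):
    n_match, n_toxic = evaluate_all_patterns(marginal_cohort, 60)
    rng = np.random.default_rng(5)
    from iripred.patterns import _index_to_pattern, _pattern_index

    for _ in range(60):
        idx = int(rng.integers(0, len(n_match)))
        try:
            pat = _index_to_pattern(idx, 6)
        except ValueError:
            continue
        stats = evaluate_pattern(pat, marginal_cohort, 60)
        assert (stats.n_match, stats.n_toxic) == (n_match[idx], n_toxic[idx])
        assert _pattern_index(pat.key(), 6) == idx


# ----------------------------------------------------------------- age cutoff

def test_age_cutoff_smallest_perfect_threshold():
    recs = [
        PatientRecord("t1", (0,) * 6, "M", 70, 1),
        PatientRecord("t2", (0,) * 6, "M", 71, 1),
        PatientRecord("n1", (0,) * 6, "M", 50, 0),
        PatientRecord("n2", (0,) * 6, "M", 51, 0),
    ]
    assert determine_age_cutoff(Cohort(DEFAULT_PANEL, recs)) == 51


def test_age_cutoff_near_zero_youden_when_independent():
    rng = np.random.default_rng(13)
    recs = [
        PatientRecord(f"p{i}", (0,) * 6, "M", int(rng.integers(30, 90)),
                      int(rng.random() < 0.4))
        for i in range(4000)
    ]
    cohort = Cohort(DEFAULT_PANEL, recs)
    t = determine_age_cutoff(cohort)
    ages = np.array([r.age_years for r in recs])
    tox = np.array([r.toxicity for r in recs])
    sens = np.sum((ages > t) & (tox == 1)) / tox.sum()
    spec = np.sum((ages <= t) & (tox == 0)) / (len(tox) - tox.sum())
    assert sens + spec - 1 < 0.08


def test_age_cutoff_requires_both_classes():
    recs = [PatientRecord("a", (0,) * 6, "M", 50, 1)]
    with pytest.raises(ValueError):
        determine_age_cutoff(Cohort(DEFAULT_PANEL, recs))


def test_default_cutoff_without_cohort():
    assert DEFAULT_AGE_CUTOFF == 60


# ----------------------------------------------------------------- candidates

def _mini_cohort(rows):
    return Cohort(
        DEFAULT_PANEL,
        [PatientRecord(f"p{i}", g, s, a, t, "training")
         for i, (g, s, a, t) in enumerate(rows)],
    )


def test_candidate_thresholds_inclusive():
    # 5 matching patients, 4 toxic -> PPV exactly 0.80 qualifies
    rows = [((2, 0, 0, 0, 0, 0), "M", 50, 1)] * 4 + [((2, 0, 0, 0, 0, 0), "M", 50, 0)]
    rows += [((0, 0, 0, 0, 0, 0), "M", 50, 0)] * 5
    pos, neg = build_candidate_rules(_mini_cohort(rows), 60)
    hom_var_first = ALL_ANY_BUT(g0=2)
    assert any(s.pattern == hom_var_first for s in pos)
    stats = next(s for s in pos if s.pattern == hom_var_first)
    assert (stats.n_match, stats.n_toxic) == (5, 4)


def test_min_support_excludes_single_cases():
    rows = [((2, 0, 0, 0, 0, 0), "M", 50, 1)] + [((0, 0, 0, 0, 0, 0), "M", 50, 0)] * 4
    pos, _ = build_candidate_rules(_mini_cohort(rows), 60)
    assert not any(s.pattern == ALL_ANY_BUT(g0=2) for s in pos)


# -------------------------------------------------------------------- pruning

def test_generalization_dominates_specialization():
    a = PatternStats(ALL_ANY_BUT(g0=2, gender=0), 4, 4)
    b = PatternStats(ALL_ANY_BUT(g0=2), 6, 6)
    kept = prune_redundant([a, b], "positive")
    assert kept == [b]
    # but a strictly better specialization survives
    a2 = PatternStats(ALL_ANY_BUT(g0=2, gender=0), 4, 4)
    b2 = PatternStats(ALL_ANY_BUT(g0=2), 6, 5)
    kept = prune_redundant([a2, b2], "positive")
    assert set(s.pattern for s in kept) == {a2.pattern, b2.pattern}


def test_disjoint_slot_patterns_both_retained():
    a = PatternStats(ALL_ANY_BUT(g0=2), 4, 4)
    b = PatternStats(ALL_ANY_BUT(g1=1), 5, 4)
    assert len(prune_redundant([a, b], "positive")) == 2


def _random_candidates(rng, cohort, category, n_patterns=15):
    cands = []
    for _ in range(n_patterns):
        slots = tuple(
            int(rng.integers(0, 3)) if rng.random() < 0.3 else ANY_GENO for _ in range(6)
        )
        gender = int(rng.integers(0, 2)) if rng.random() < 0.3 else ANY_CLIN
        age = int(rng.integers(0, 2)) if rng.random() < 0.3 else ANY_CLIN
        try:
            pat = Pattern(slots, gender, age)
        except ValueError:
            continue
        stats = evaluate_pattern(pat, cohort, 60)
        if stats.n_match:
            cands.append(stats)
    return cands


def test_pruning_preserves_matched_union_and_predictions():
    rng = np.random.default_rng(23)
    cohort = simulate_cohort(default_paper_like_config(60, seed=31))
    for trial in range(50):
        for category in ("positive", "negative"):
            cands = _random_candidates(rng, cohort, category)
            kept = prune_redundant(cands, category)
            assert set(s.pattern.key() for s in kept) <= set(s.pattern.key() for s in cands)
            before = set()
            after = set()
            for rec in cohort:
                if any(pattern_matches(s.pattern, rec, 60) for s in cands):
                    before.add(rec.patient_id)
                if any(pattern_matches(s.pattern, rec, 60) for s in kept):
                    after.add(rec.patient_id)
            assert before == after


# ----------------------------------------------------------------------- SFFS

def test_sffs_with_monotone_criterion_is_plain_forward_selection():
    features = [f"f{i}" for i in range(6)]
    state = sffs_select(lambda X: len(X), features)
    subsets = [state.best_subsets[k] for k in sorted(state.best_subsets)]
    for small, big in zip(subsets, subsets[1:]):
        assert small < big  # nested chain, no floating exclusions


def _xor_style_criterion():
    """Pair {x1, x2} is jointly perfect; a decoy is the best singleton."""
    def J(X):
        X = frozenset(X)
        has_pair = {"x1", "x2"} <= X
        score = 0.5
        if "decoy" in X:
            score = max(score, 0.6 if len(X) == 1 else 0.8)
        if has_pair:
            score = 1.0
        return score - 0.001 * len(X)  # mild penalty breaks ties toward small sets
    return J


def test_sffs_recovers_pair_greedy_forward_misses():
    features = ["decoy", "x1", "x2", "n1", "n2", "n3", "n4", "n5"]
    J = _xor_style_criterion()
    # plain greedy forward selection at k=2
    best1 = max(features, key=lambda f: J(frozenset({f})))
    assert best1 == "decoy"
    forward2 = max(
        (frozenset({best1, f}) for f in features if f != best1), key=J
    )
    assert J(forward2) < 1.0 - 0.01
    state = sffs_select(J, features)
    assert state.best_subsets[2] == frozenset({"x1", "x2"})
    assert state.criterion_values[2] == pytest.approx(1.0 - 0.002)


def test_sffs_bounded_by_exhaustive_and_at_least_forward():
    rng = np.random.default_rng(41)
    features = [f"f{i}" for i in range(8)]
    for trial in range(10):
        values = {
            frozenset(S): float(rng.random())
            for r in range(0, 9)
            for S in __import__("itertools").combinations(features, r)
        }
        J = lambda X: values[frozenset(X)]
        state = sffs_select(J, features)
        # exhaustive upper bound per size
        for k, sub in state.best_subsets.items():
            if k == 0:
                continue
            best_k = max(v for S, v in values.items() if len(S) == k)
            assert state.criterion_values[k] <= best_k + 1e-12
        # never below plain forward selection
        X = frozenset()
        for k in range(1, 9):
            X = max((X | {f} for f in features if f not in X), key=J)
            if k in state.criterion_values:
                assert state.criterion_values[k] >= J(X) - 1e-12


def test_sffs_rejects_non_finite_criterion():
    with pytest.raises(ValueError, match="non-finite"):
        sffs_select(lambda X: float("nan") if len(X) == 2 else len(X), ["a", "b", "c"])


# ---------------------------------------------------------------- rule system

def test_build_rule_system_plant_and_recover():
    planted_pos = ALL_ANY_BUT(g4=1, gender=0)   # 622 het males -> toxic
    planted_neg = ALL_ANY_BUT(g0=0, g5=2)       # *6 wild-type, 1b hom -> safe
    config = default_paper_like_config(400, seed=19)
    config.planted_patterns = [(planted_pos, 0.97), (planted_neg, 0.02)]
    cohort = simulate_cohort(config, split="training")
    system = build_rule_system(cohort, RuleConfig(age_cutoff=60))

    def covered(planted, rules):
        keys = {s.pattern.key() for s in rules}
        if planted.key() in keys:
            return True
        return any(g.key() in keys for g in planted.generalizations())

    assert covered(planted_pos, system.positive_rules)
    assert covered(planted_neg, system.negative_rules)


def test_build_rule_system_all_negative_outcomes():
    rows = [((i % 3, 0, 0, 0, 0, 0), "M", 50 + i, 0) for i in range(12)]
    system = build_rule_system(_mini_cohort(rows), RuleConfig(age_cutoff=60))
    assert system.positive_rules == []
    assert len(system.negative_rules) > 0


def test_rule_system_self_consistency_and_runtime():
    cohort = simulate_cohort(default_paper_like_config(200, seed=3), split="training")
    t0 = time.time()
    system = build_rule_system(cohort, RuleConfig())
    elapsed = time.time() - t0
    assert elapsed < 60
    for category, rules in (("positive", system.positive_rules),
                            ("negative", system.negative_rules)):
        for s in rules:
            fresh = evaluate_pattern(s.pattern, cohort, system.age_cutoff)
            assert (fresh.n_match, fresh.n_toxic) == (s.n_match, s.n_toxic)
            assert fresh.n_match >= system.min_support
            assert fresh.pred_value(category) >= system.min_pred_value - 1e-9


def test_rule_system_json_round_trip(tmp_path):
    cohort = simulate_cohort(default_paper_like_config(120, seed=9), split="training")
    system = build_rule_system(cohort, RuleConfig(age_cutoff=60))
    path = tmp_path / "rules.json"
    system.to_json(path)
    from iripred.patterns import RuleSystem

    back = RuleSystem.from_json(path)
    assert [s.pattern for s in back.positive_rules] == [s.pattern for s in system.positive_rules]
    assert [s.pattern for s in back.negative_rules] == [s.pattern for s in system.negative_rules]
    assert back.age_cutoff == system.age_cutoff


def test_sffs_restricted_system_runs():
    cohort = simulate_cohort(default_paper_like_config(150, seed=17), split="training")
    system = build_rule_system(cohort, RuleConfig(age_cutoff=60, use_sffs=True, sffs_target_k=3))
    selected = set(system.provenance["sffs"]["selected"])
    assert selected <= set(PANEL_LOCUS_IDS) | {"gender", "age"}
    locus_ids = tuple(PANEL_LOCUS_IDS)
    for s in system.positive_rules + system.negative_rules:
        assert s.pattern.constrained_features(locus_ids) <= selected
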