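"""Synthetic cohorts with the structure the analysis pipeline assumes.

Each patient receives two six-locus haplotypes drawn i.i.d. from a
configured frequency table (random mating, so every locus is in
Hardy-Weinberg equilibrium in expectation and the between-locus LD is
exactly the table's), a gender, an integer age, and a Bernoulli severe-
toxicity outcome from a logistic model:

    logit P(toxicity) = intercept + sum_l beta_l * (risk alleles at l)
                        + beta_female * [female] + beta_age * [age > cutoff]

Risk-allele orientation follows the panel (for UGT1A9*1b the reference T9
allele carries the risk).  Optional *planted patterns* override the
toxicity probability for every matching patient — the handle used by
plant-and-recover tests of the rule-discovery engine.

Randomness is split into one named stream per sampling stage (haplotypes,
gender, age, toxicity, missingness), all derived from a single seed, so
adding a stage never perturbs the others.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .cohort import Cohort, PatientRecord
from .panel import DEFAULT_PANEL, MISSING, LocusDef
from .patterns import Pattern, pattern_matches
from . import study_data

#: default marginal severe-toxicity rate (51 of 123 patients)
DEFAULT_TOXICITY_RATE = study_data.N_TOXIC / study_data.N_TOTAL

#: default per-risk-allele log-odds; chosen so carrier toxicity rates rise
#: with risk-allele dose at the associated loci (strongest at UGT1A1*6 and
#: UGT1A7 622) while the haplotype table induces the published LD structure
DEFAULT_BETAS = {
    "UGT1A1_6": 0.85,
    "UGT1A1_28": 0.35,
    "UGT1A1_60": 0.25,
    "UGT1A7_387": 0.25,
    "UGT1A7_622": 0.55,
    "UGT1A9_1b": 0.35,
}
DEFAULT_BETA_FEMALE = 0.10
DEFAULT_BETA_AGE = 0.75


@dataclass
class SimulationConfig:
    n_patients: int
    haplotype_freqs: dict[str, float]
    intercept: float
    betas: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETAS))
    beta_female: float = DEFAULT_BETA_FEMALE
    beta_age_gt: float = DEFAULT_BETA_AGE
    male_prob: float = 78 / 123
    age_mean: float = 62.0
    age_sd: float = 10.0
    age_cutoff: int = 60
    missing_rate: float = 0.0
    planted_patterns: list[tuple[Pattern, float]] = field(default_factory=list)
    seed: int = 0
    panel: tuple[LocusDef, ...] = DEFAULT_PANEL

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        total = sum(self.haplotype_freqs.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")
        if any(f < 0 for f in self.haplotype_freqs.values()):
            raise ValueError("negative haplotype frequency")
        if not 0.0 <= self.male_prob <= 1.0:
            raise ValueError("male_prob must be a probability")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be a probability")
        for pat, p in self.planted_patterns:
            if not 0.0 <= p <= 1.0:
                raise ValueError("planted toxicity probability must be in [0, 1]")
        ids = {l.locus_id for l in self.panel}
        unknown = set(self.betas) - ids
        if unknown:
            raise ValueError(f"betas for unknown loci: {sorted(unknown)}")


def _hap_var_bits(hap: str) -> tuple[int, ...]:
    return tuple(1 if c == "V" else 0 for c in hap)


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _genotype_distribution(config: SimulationConfig):
    """Distribution of (genotype vector, probability) under random mating."""
    haps = sorted(config.haplotype_freqs.items())
    dist: dict[tuple[int, ...], float] = {}
    for ha, fa in haps:
        for hb, fb in haps:
            g = tuple(a + b for a, b in zip(_hap_var_bits(ha), _hap_var_bits(hb)))
            dist[g] = dist.get(g, 0.0) + fa * fb
    return dist


def _prob_age_gt(config: SimulationConfig) -> float:
    # ages are rounded to integers, so age > cutoff means raw age >= cutoff + 0.5
    return float(norm.sf(config.age_cutoff + 0.5, config.age_mean, config.age_sd))


def _linear_risk(config: SimulationConfig, genotype: tuple[int, ...]) -> float:
    s = 0.0
    for locus, g in zip(config.panel, genotype):
        beta = config.betas.get(locus.locus_id, 0.0)
        s += beta * locus.risk_allele_count(g)
    return s


def expected_toxicity_rate(config: SimulationConfig) -> float:
    """Exact marginal toxicity probability under the logistic model."""
    p_age = _prob_age_gt(config)
    p_female = 1.0 - config.male_prob
    total = 0.0
    for genotype, pg in _genotype_distribution(config).items():
        base = config.intercept + _linear_risk(config, genotype)
        for female, pf in ((0, 1 - p_female), (1, p_female)):
            for age_gt, pa in ((0, 1 - p_age), (1, p_age)):
                total += pg * pf * pa * _sigmoid(
                    base + config.beta_female * female + config.beta_age_gt * age_gt
                )
    return total


def calibrate_intercept(config: SimulationConfig, target_rate: float) -> float:
    """Intercept making the exact marginal toxicity rate equal target_rate."""
    def f(b0: float) -> float:
        return expected_toxicity_rate(replace(config, intercept=b0)) - target_rate

    return float(brentq(f, -20.0, 20.0, xtol=1e-10))


def default_paper_like_config(n_patients: int = 1000, seed: int = 0) -> SimulationConfig:
    """The calibrated default: published complete-case haplotype frequencies,
    78/123 male, age ~ N(62, 10), and effect sizes yielding a ~41% marginal
    toxicity rate with risk rising across risk-allele dose."""
    config = SimulationConfig(
        n_patients=n_patients,
        haplotype_freqs=study_data.haplotype_frequencies("n103"),
        intercept=0.0,
        seed=seed,
    )
    config.intercept = calibrate_intercept(config, DEFAULT_TOXICITY_RATE)
    return config


def simulate_cohort(config: SimulationConfig, split: str = "unassigned") -> Cohort:
    """Draw a cohort; fully reproducible from ``config.seed``."""
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rng_hap, rng_sex, rng_age, rng_tox, rng_miss = (
        np.random.default_rng(s) for s in streams
    )
    haps = sorted(config.haplotype_freqs.items())
    hap_strings = [h for h, _ in haps]
    hap_bits = np.array([_hap_var_bits(h) for h in hap_strings], dtype=np.int64)
    probs = np.array([f for _, f in haps], dtype=float)
    probs = probs / probs.sum()

    n = config.n_patients
    draws = rng_hap.choice(len(hap_strings), size=(n, 2), p=probs)
    genotypes = hap_bits[draws[:, 0]] + hap_bits[draws[:, 1]]
    female = rng_sex.random(n) >= config.male_prob
    ages = np.clip(
        np.rint(rng_age.normal(config.age_mean, config.age_sd, size=n)), 20, 90
    ).astype(int)

    records: list[PatientRecord] = []
    tox_u = rng_tox.random(n)
    miss_u = rng_miss.random((n, len(config.panel))) if config.missing_rate > 0 else None
    for i in range(n):
        g = tuple(int(x) for x in genotypes[i])
        gender = "F" if female[i] else "M"
        age = int(ages[i])
        rec = PatientRecord(f"S{i + 1:05d}", g, gender, age, 0, split)
        p = _sigmoid(
            config.intercept
            + _linear_risk(config, g)
            + config.beta_female * female[i]
            + config.beta_age_gt * (age > config.age_cutoff)
        )
        for pat, forced in config.planted_patterns:
            if pattern_matches(pat, rec, config.age_cutoff):
                p = forced
                break
        toxicity = int(tox_u[i] < p)
        if miss_u is not None:
            g = tuple(
                MISSING if miss_u[i, j] < config.missing_rate else v
                for j, v in enumerate(g)
            )
        records.append(PatientRecord(rec.patient_id, g, gender, age, toxicity, split))
    return Cohort(config.panel, records)


def load_sim_config(path, seed: int | None = None) -> SimulationConfig:
    """Read a ``[simulate]`` section from a TOML file.

    Recognized keys: n_patients, haplotype_population ("n103"/"n123") or an
    inline ``haplotype_freqs`` table, male_prob, age_mean, age_sd,
    age_cutoff, missing_rate, intercept (or target_toxicity_rate to
    calibrate it), betas table, beta_female, beta_age_gt, seed.
    """
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    sim = doc.get("simulate", {})
    freqs = sim.get("haplotype_freqs")
    if freqs is None:
        freqs = study_data.haplotype_frequencies(sim.get("haplotype_population", "n103"))
    config = SimulationConfig(
        n_patients=int(sim.get("n_patients", 1000)),
        haplotype_freqs=freqs,
        intercept=float(sim.get("intercept", 0.0)),
        betas={**DEFAULT_BETAS, **sim.get("betas", {})},
        beta_female=float(sim.get("beta_female", DEFAULT_BETA_FEMALE)),
        beta_age_gt=float(sim.get("beta_age_gt", DEFAULT_BETA_AGE)),
        male_prob=float(sim.get("male_prob", 78 / 123)),
        age_mean=float(sim.get("age_mean", 62.0)),
        age_sd=float(sim.get("age_sd", 10.0)),
        age_cutoff=int(sim.get("age_cutoff", 60)),
        missing_rate=float(sim.get("missing_rate", 0.0)),
        seed=int(seed if seed is not None else sim.get("seed", 0)),
    )
    if "intercept" not in sim:
        target = float(sim.get("target_toxicity_rate", DEFAULT_TOXICITY_RATE))
        config.intercept = calibrate_intercept(config, target)
    return config
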