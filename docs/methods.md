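# Methods

## Data model and allele orientation

The panel is a fixed, ordered list of six biallelic UGT1A sites:
UGT1A1\*6 (211G>A, rs4148323), UGT1A1\*28 (TA6>TA7, rs8175347),
UGT1A1\*60 (−3279T>G, rs4124874), UGT1A7 387T>G (rs17868323),
UGT1A7 622T>C (rs11692021) and UGT1A9\*1b (−118 T9>T10, rs35426722).
Genotypes are coded 0/1/2 as counts of the panel's **variant allele** (the
nomenclature variant), never the cohort minor allele: the UGT1A9\*1b
variant T10 is the *major* allele in East Asian cohorts, and minor-allele
coding would silently flip that locus between cohorts. A separate
`risk_allele` attribute records the toxicity-associated allele (the
reference T9 for \*1b, the variant for the other five loci); the synthetic
risk model and reporting use it, the genotype codes never change.

Severe toxicity is a precomputed binary meaning grade ≥3 hematologic
toxicity at any point during therapy. Missing genotype, gender or outcome
values are accepted as "", "NA" or "." and written back as "NA". Haplotypes
are strings over {R, V} in panel order.

## Per-locus statistics

The Hardy–Weinberg test is the exact conditional test: holding the
observed allele counts fixed, the probability of each heterozygote count
is `n! / (n_RR! n_RV! n_VV!) · 2^n_RV · n_R! n_V! / (2n)!`, and the p-value
sums all counts no more probable than the observed one (plain p, no
mid-correction, matching the common exact-test convention). It is verified
against an exact-rational enumeration oracle rather than against any
published rounded value, because published tables rarely state which HWE
test flavor produced them.

## EM haplotype phasing

Frequencies maximize the standard multilocus unphased-genotype likelihood:
a patient with genotype g contributes `sum over compatible unordered pairs
{a,b} of (2−[a=b]) f_a f_b`. The E-step distributes each patient's two
chromosomes over compatible pairs proportionally to those terms; the
M-step renormalizes. Choices:

* **Complete cases only.** Patients missing any requested locus are
  excluded from EM (mirroring common practice for small panels); the
  number used is recorded on the result.
* **Deterministic initialization** uniform over the haplotypes compatible
  with at least one patient; the seed argument is reserved for optional
  random restarts and unused by default.
* **Convergence** at relative log-likelihood change < 1e-10 or 1,000
  iterations; the full log-likelihood path is exported and is asserted
  non-decreasing (an EM guarantee, so a violation indicates a bug).
* Haplotypes below 1e-6 are hidden from reports but kept on the simplex.
* Genotype rows are deduplicated before EM; cost scales with distinct
  genotypes (at most 3⁶ = 729), not patients.

Diplotype assignment picks the compatible pair maximizing class
probability (2 f_a f_b off-diagonal, f_a² on it); the posterior is that
mass over all compatible pairs. Ties are broken toward the
lexicographically smallest sorted pair and flagged. A genotype compatible
with no positive-frequency pair yields an unresolved call with posterior 0.

LD marginalizes the haplotype table to two loci: D = p_VV − p_V p_V′,
D′ = |D| / D_max, r² = D² / (p_V(1−p_V)p_V′(1−p_V′)); LOD is the base-10
log likelihood ratio against independence scaled by the number of
chromosomes when provided.

## Association statistics

* Fisher 2×2 is the two-sided probability-mass convention (the SPSS/R
  behavior), delegated to scipy.
* The 2×K Freeman–Halton test enumerates all tables with the observed
  margins over the K free first-row cells (K ≤ 6) and sums conditional
  probabilities ≤ the observed one, with a 1e-7 relative guard so
  floating-point noise cannot exclude exact ties.
* The Cochran–Armitage trend test is the asymptotic statistic without
  continuity correction, default scores (0, 1, 2); its p-value is
  invariant to affine score rescaling (tested).
* Odds ratios use Woolf (log) 95% intervals,
  `exp(ln OR ± 1.96 √(Σ 1/cell))`; this interval reproduces the published
  CIs checked by hand. Haldane–Anscombe +0.5 is applied to all four cells
  only when some cell is zero, with a warning. The reference group is
  explicit configuration; the convention that reproduces the published
  odds ratios is "patients homozygous for the most frequent haplotype".
* No multiple-testing correction is applied, matching the source analyses.

## The combination-pattern engine

A pattern constrains any subset of 8 slots: six genotype slots
(HOM_REF/HET/HOM_VAR/ANY), gender (M/F/ANY) and age (≤cutoff / >cutoff /
ANY); the all-ANY pattern is excluded, so the default space has
4⁶·3² − 1 = 36,863 patterns. A missing patient field never satisfies a
non-ANY slot (conservative), and patients with unknown outcome are
excluded from pattern statistics.

**Exhaustive evaluation is O(n·2⁸)**, not O(n·36,863): a patient with no
missing fields is matched by exactly the 2⁸ patterns obtained by keeping
or wildcarding each of their 8 values, so match and toxic counts for the
entire space are accumulated per patient over those 256 pattern indices.

The age cutoff maximizes Youden's J (sensitivity + specificity − 1) for
the classifier "age > t predicts toxicity" over the distinct observed
training ages, smallest t on ties; 60 years is the fallback when no
training cohort is supplied.

Filtering keeps patterns with at least `min_support = 2` matched patients
(excluding unobserved and single-case patterns) and predictive value —
toxic fraction for positive candidates, non-toxic fraction for negative —
of at least `min_pred_value = 0.80`. Both thresholds are inclusive
(a value of exactly 80% survives, since only values *below* 80% are
excluded); comparisons carry a 1e-9 absolute guard so 4/5 is never lost to
rounding.

**Redundancy pruning** removes pattern A when a retained pattern B
constrains a subset of A's slots with the same values — hence
matches(A) ⊆ matches(B) — and B's predictive value is at least A's. This
is deliberately the weakest pruning that provably leaves the rule system's
training predictions unchanged (tested on random candidate sets).
Candidates are processed by increasing specificity then lexicographic slot
order, making builds bit-for-bit reproducible.

**SFFS** implements floating selection over the 8 features: conditional
inclusion of the feature improving the criterion most, conditional
exclusion of the least useful feature, and continued backward floating
while it improves the recorded best at the smaller size (floating only
while more than two features are held). One deliberate addition: the
per-size records are seeded with a single plain sequential-forward ascent
before floating begins. The literal floating procedure can end with a
size-k record worse than plain forward selection's, because a backward
float diverts the ascent path and sizes above the float point may never be
revisited from the original chain; seeding makes "SFFS is never worse than
forward selection at any size" true by construction, and floating can only
improve on it. The default criterion J for rule learning is the overall
training accuracy of the rule system built from patterns restricted to the
candidate feature subset, tie-broken by the number of matched patients.
Exhaustive enumeration is the default rule generator; SFFS is an optional
pre-selection stage (`use_sffs`), since with 8 features the exhaustive
space is trivially feasible and the two stages are complementary.

## Prediction and evaluation accounting

A patient is POSITIVE if only positive rules fire, NEGATIVE if only
negative rules fire, UNMATCHED if none fires. If both categories fire the
label follows the higher training predictive value, ties resolve to
POSITIVE (safety first); conflicts are flagged and logged. Evaluation
reports tp/fp/tn/fn within matched patients plus unmatched counts by
outcome; sensitivity is tp/(tp+fn+unmatched_toxic), specificity
tn/(tn+fp+unmatched_nontoxic), overall accuracy (tp+tn)/n — i.e. abstaining
counts as an error for the cohort-level metrics but not for the
within-matched metrics. This accounting simultaneously reproduces all
seven published training-column fractions from the published confusion
counts, which is why it is the one implemented.

## Synthetic cohorts

The generator emulates the cohort structure the analysis assumes: two
haplotypes per patient drawn i.i.d. from a frequency table (random mating —
HWE holds in expectation and between-locus LD is exactly the table's),
gender Bernoulli (male 78/123 by default), age normal(62, 10) rounded and
clipped to [20, 90] (the default implies P(age>60) ≈ 0.56, close to the
published 73/123 split), and toxicity Bernoulli with

    logit p = intercept + Σ_l β_l · (risk alleles at l)
              + β_female·[female] + β_age·[age > 60]

Default β (per risk allele): \*6 0.85, \*28 0.35, \*60 0.25, 387 0.25,
622 0.55, \*1b(T9) 0.35; β_female 0.10, β_age 0.75. These are calibration
choices, not estimates — no published per-allele effect sizes conditional
on haplotype background exist — chosen so toxicity rises with risk-allele
dose at the loci reported as associated, strongest at UGT1A1\*6 and UGT1A7
622. The intercept is solved by root finding so the *exact* marginal
toxicity rate (expectation over the discrete genotype × gender × age
distribution) equals 51/123 ≈ 0.415. Planted patterns may override the
toxicity probability of matching patients (first match wins), the handle
used by plant-and-recover tests. One seed spawns a named RNG stream per
sampling stage, so adding a stage never perturbs the others.

What the generator does **not** emulate: dosing and regimen effects,
population stratification or HWE violations (the published validation
cohort shows one at UGT1A9\*1b), genotyping error, and any non-UGT1A
toxicity factor beyond the gender/age terms. Passing tests therefore
demonstrate correctness of the machinery under the assumed generating
model, not clinical performance on real cohorts.

## Reconstructed marginal cohort

`study_data.reconstructed_marginal_cohort()` is a synthetic 123-patient
table whose per-locus genotype×toxicity, gender and age-split counts equal
the published tables exactly; columns are filled independently within each
outcome class, so joint structure (LD, haplotype phase) is *not*
representative. It exists to verify marginal statistics end-to-end through
the cohort container and must not be used for haplotype or multi-locus
work — the simulator is the tool for that.

## Problem sizes and numerical choices

Tests and the acceptance script run the simulator at n = 2,000 for EM
recovery (3-standard-error tolerance), n = 50,000 for law-of-large-numbers
frequency checks, and n = 300/200 for rule-system training/validation
demos; these sizes give stable statistics for the quantities checked.
Exact-test implementations are compared against integer-exact enumeration
oracles on every 2×2 and 2×3 table with n ≤ 12. All orderings (pattern
enumeration, rule serialization, tie-breaks) are deterministic, so every
artifact is bit-for-bit reproducible from its seed and configuration.

## Known limitations

* The EM phaser is designed for small panels (≤ ~10 loci); no
  partition-ligation is implemented.
* The Freeman–Halton test enumerates exhaustively and is capped at K = 6
  columns.
* Rule conflicts (both categories firing) cannot arise among rules learned
  from the same training data at thresholds ≥ 0.8 unless a patient
  satisfies rules whose matched sets were disjoint in training; the
  resolution policy is therefore rarely exercised in practice and is
  always logged when it is.
* The predictor is categorical by design; it produces no calibrated risk
  scores.
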