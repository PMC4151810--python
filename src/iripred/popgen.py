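"""Allele/genotype statistics, EM haplotype phasing and pairwise LD.

This stage replaces an interactive haplotype-analysis GUI with library
code: per-locus allele frequencies and an exact Hardy-Weinberg test,
maximum-likelihood multilocus haplotype frequencies from unphased
genotypes via EM, most-probable diplotype assignment, and the standard
pairwise LD measures (D, Lewontin's D', r-squared, LOD).

Haplotypes are strings over ``{R, V}`` in panel order, ``V`` marking the
panel's variant allele at that locus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .cohort import Cohort
from .panel import MISSING

PRUNE_THRESHOLD = 1e-6  # haplotypes below this are hidden from reports


# ---------------------------------------------------------------------------
# per-locus statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeCounts:
    locus_id: str
    n0: int
    n1: int
    n2: int
    n_missing: int = 0

    @property
    def n_typed(self) -> int:
        return self.n0 + self.n1 + self.n2


def genotype_counts(cohort: Cohort, locus_id: str) -> GenotypeCounts:
    j = cohort.locus_index(locus_id)
    g = cohort.genotype_matrix()[:, j] if len(cohort) else np.empty(0, dtype=int)
    return GenotypeCounts(
        locus_id,
        int(np.sum(g == 0)),
        int(np.sum(g == 1)),
        int(np.sum(g == 2)),
        int(np.sum(g == MISSING)),
    )


def variant_allele_frequency(counts: GenotypeCounts) -> float:
    """Frequency of the panel's variant allele: (n1 + 2 n2) / 2n."""
    if counts.n_typed == 0:
        raise ValueError(f"{counts.locus_id}: no typed genotypes, frequency undefined")
    return (counts.n1 + 2 * counts.n2) / (2 * counts.n_typed)


def minor_allele_frequency(counts: GenotypeCounts) -> float:
    f = variant_allele_frequency(counts)
    return min(f, 1.0 - f)


def hwe_exact_test(counts: GenotypeCounts) -> float:
    """Exact conditional Hardy-Weinberg test (plain p, no mid-correction).

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one.
    """
    n = counts.n_typed
    if n == 0:
        raise ValueError("no typed genotypes")
    n_var = counts.n1 + 2 * counts.n2
    rare = min(n_var, 2 * n - n_var)
    if rare == 0:
        return 1.0

    def log_prob(het: int) -> float:
        hom_rare = (rare - het) // 2
        hom_common = n - het - hom_rare
        return (
            math.lgamma(n + 1)
            - math.lgamma(hom_rare + 1)
            - math.lgamma(het + 1)
            - math.lgamma(hom_common + 1)
            + het * math.log(2.0)
            + math.lgamma(rare + 1)
            + math.lgamma(2 * n - rare + 1)
            - math.lgamma(2 * n + 1)
        )

    hets = range(rare % 2, rare + 1, 2)
    probs = {h: math.exp(log_prob(h)) for h in hets}
    p_obs = probs[counts.n1]
    p = sum(q for q in probs.values() if q <= p_obs * (1.0 + 1e-12))
    return min(1.0, p)


# ---------------------------------------------------------------------------
# haplotype frequency table
# ---------------------------------------------------------------------------

def _hap_to_int(s: str) -> int:
    code = 0
    for c in s:
        code = (code << 1) | (1 if c == "V" else 0)
    return code


def _int_to_hap(code: int, n_loci: int) -> str:
    return "".join("V" if (code >> (n_loci - 1 - i)) & 1 else "R" for i in range(n_loci))


@dataclass
class HaplotypeFreqTable:
    """Haplotype frequencies over an ordered subset of panel loci.

    ``freqs`` holds the full probability simplex (all haplotypes with any
    mass); the :attr:`haplotypes` view prunes entries below
    ``PRUNE_THRESHOLD`` for reporting.
    """

    loci: tuple[str, ...]
    freqs: dict[str, float]
    loglik: float = float("nan")
    n_iterations: int = 0
    converged: bool = True
    n_complete: int = 0
    loglik_path: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        total = sum(self.freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")
        if any(len(h) != len(self.loci) for h in self.freqs):
            raise ValueError("haplotype string length must equal number of loci")

    @classmethod
    def from_frequencies(cls, loci, mapping: dict[str, float], normalize: bool = False):
        if normalize:
            total = sum(mapping.values())
            mapping = {h: f / total for h, f in mapping.items()}
        return cls(tuple(loci), dict(mapping))

    @property
    def haplotypes(self) -> list[tuple[str, float]]:
        out = [(h, f) for h, f in self.freqs.items() if f >= PRUNE_THRESHOLD]
        return sorted(out, key=lambda hf: (-hf[1], hf[0]))

    def frequency(self, hap: str) -> float:
        return self.freqs.get(hap, 0.0)

    def variant_freq(self, locus_id: str) -> float:
        j = self.loci.index(locus_id)
        return sum(f for h, f in self.freqs.items() if h[j] == "V")

    def two_locus_freqs(self, locus_a: str, locus_b: str) -> dict[tuple[str, str], float]:
        ia, ib = self.loci.index(locus_a), self.loci.index(locus_b)
        out: dict[tuple[str, str], float] = {}
        for h, f in self.freqs.items():
            key = (h[ia], h[ib])
            out[key] = out.get(key, 0.0) + f
        return out

    def to_tsv(self, path, allele_labels: dict[str, tuple[str, str]] | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("haplotype\t" + "\t".join(self.loci) + "\tfrequency\n")
            for h, f in self.haplotypes:
                if allele_labels:
                    labels = [
                        allele_labels[l][1] if c == "V" else allele_labels[l][0]
                        for l, c in zip(self.loci, h)
                    ]
                else:
                    labels = list(h)
                fh.write(f"{h}\t" + "\t".join(labels) + f"\t{f:.3f}\n")


# ---------------------------------------------------------------------------
# EM estimation
# ---------------------------------------------------------------------------

def _compatible_pairs(genotype: tuple[int, ...]) -> list[tuple[int, int]]:
    """All unordered haplotype-int pairs consistent with a complete genotype."""
    n = len(genotype)
    base = 0
    het_positions = []
    for i, g in enumerate(genotype):
        bit = 1 << (n - 1 - i)
        if g == 2:
            base |= bit
        elif g == 1:
            het_positions.append(bit)
    if not het_positions:
        return [(base, base)]
    pairs = set()
    k = len(het_positions)
    for mask in range(1 << k):
        a = base
        b = base
        for idx, bit in enumerate(het_positions):
            if (mask >> idx) & 1:
                a |= bit
            else:
                b |= bit
        pairs.add((min(a, b), max(a, b)))
    return sorted(pairs)


def em_haplotype_frequencies(
    cohort: Cohort,
    loci: tuple[str, ...] | None = None,
    tol: float = 1e-10,
    max_iter: int = 1000,
    seed: int = 0,
) -> HaplotypeFreqTable:
    """EM estimate of multilocus haplotype frequencies from unphased genotypes.

    Patients with a missing genotype at any requested locus are excluded
    (complete-case analysis).  Initialization is deterministic: uniform
    over the haplotypes compatible with at least one patient.  ``seed`` is
    reserved for optional random restarts and unused by the default
    deterministic run.

    The log-likelihood is guaranteed non-decreasing per iteration (checked
    and exported as ``loglik_path``); convergence is a relative change
    below ``tol``.
    """
    loci = tuple(loci) if loci is not None else tuple(l.locus_id for l in cohort.panel)
    idx = [cohort.locus_index(l) for l in loci]
    G = cohort.genotype_matrix()[:, idx] if len(cohort) else np.empty((0, len(idx)), int)
    complete = G[(G != MISSING).all(axis=1)]
    n = complete.shape[0]
    if n == 0:
        raise ValueError("no patient has complete genotypes at the requested loci")

    # deduplicate genotype rows; EM cost scales with distinct genotypes
    rows, counts = np.unique(complete, axis=0, return_counts=True)
    pair_lists = [_compatible_pairs(tuple(row)) for row in rows]

    support = sorted({h for pairs in pair_lists for ab in pairs for h in ab})
    if not support:
        raise ValueError("no compatible haplotypes")
    f = {h: 1.0 / len(support) for h in support}

    loglik_path: list[float] = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        expected = {h: 0.0 for h in support}
        loglik = 0.0
        for pairs, w in zip(pair_lists, counts):
            weights = [
                (2.0 if a != b else 1.0) * f[a] * f[b] for a, b in pairs
            ]
            total = sum(weights)
            if total <= 0.0:
                # mass vanished from every compatible pair; re-seed uniformly
                weights = [1.0] * len(pairs)
                total = float(len(pairs))
            loglik += w * math.log(total) if total > 0 else -np.inf
            for (a, b), wt in zip(pairs, weights):
                share = w * wt / total
                expected[a] += share
                expected[b] += share
        loglik_path.append(loglik)
        f = {h: c / (2.0 * n) for h, c in expected.items()}
        if prev != -np.inf and loglik - prev < tol * max(1.0, abs(prev)):
            converged = True
            break
        prev = loglik

    n_loci = len(loci)
    freqs = {_int_to_hap(h, n_loci): v for h, v in f.items() if v > 0.0}
    # guard the simplex against accumulated rounding
    total = sum(freqs.values())
    freqs = {h: v / total for h, v in freqs.items()}
    return HaplotypeFreqTable(
        loci, freqs, loglik=loglik_path[-1], n_iterations=it,
        converged=converged, n_complete=n, loglik_path=loglik_path,
    )


# ---------------------------------------------------------------------------
# diplotype assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiplotypeCall:
    patient_id: str
    hap_a: str | None
    hap_b: str | None
    posterior: float
    tied: bool = False

    @property
    def resolved(self) -> bool:
        return self.hap_a is not None


def assign_diplotypes(cohort: Cohort, table: HaplotypeFreqTable) -> list[DiplotypeCall]:
    """Most-probable diplotype per patient under the frequency table.

    The probability of an unordered pair {a, b} is 2 f_a f_b (f_a^2 when
    a == b); the posterior is that mass over all pairs compatible with the
    patient's genotype at every non-missing locus.  Ties are broken by the
    lexicographically smallest sorted pair and flagged.
    """
    idx = [cohort.locus_index(l) for l in table.loci]
    haps = [(h, f) for h, f in table.freqs.items() if f > 0.0]
    calls: list[DiplotypeCall] = []
    for rec in cohort:
        g = [rec.genotypes[j] for j in idx]
        cands: list[tuple[float, str, str]] = []
        for (ha, fa), (hb, fb) in combinations(haps, 2):
            if _pair_consistent(ha, hb, g):
                a, b = sorted((ha, hb))
                cands.append((2.0 * fa * fb, a, b))
        for ha, fa in haps:
            if _pair_consistent(ha, ha, g):
                cands.append((fa * fa, ha, ha))
        if not cands:
            calls.append(DiplotypeCall(rec.patient_id, None, None, 0.0))
            continue
        total = sum(w for w, _, _ in cands)
        best_w = max(w for w, _, _ in cands)
        best = sorted([(a, b) for w, a, b in cands if w >= best_w * (1 - 1e-12)])
        a, b = best[0]
        calls.append(
            DiplotypeCall(rec.patient_id, a, b, best_w / total, tied=len(best) > 1)
        )
    return calls


def _pair_consistent(ha: str, hb: str, genotype: list[int]) -> bool:
    for ca, cb, g in zip(ha, hb, genotype):
        if g == MISSING:
            continue
        if (ca == "V") + (cb == "V") != g:
            return False
    return True


# ---------------------------------------------------------------------------
# pairwise LD
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LDResult:
    locus_a: str
    locus_b: str
    D: float
    D_prime: float
    r_squared: float
    LOD: float


def pairwise_ld(
    table: HaplotypeFreqTable,
    locus_a: str,
    locus_b: str,
    n_haplotypes: int | None = None,
) -> LDResult:
    """D, D', r-squared and LOD between two loci of a haplotype table.

    D is computed on the variant-variant cell: D = p_VV - p_V(a) p_V(b).
    LOD is the base-10 log likelihood ratio of the observed two-locus
    frequencies against independence, scaled by ``n_haplotypes`` (2N);
    NaN when ``n_haplotypes`` is not given.
    """
    pa = table.variant_freq(locus_a)
    pb = table.variant_freq(locus_b)
    if not (0.0 < pa < 1.0) or not (0.0 < pb < 1.0):
        raise ValueError(f"LD undefined: monomorphic locus among ({locus_a}, {locus_b})")
    two = table.two_locus_freqs(locus_a, locus_b)
    p_vv = two.get(("V", "V"), 0.0)
    D = p_vv - pa * pb
    if D >= 0:
        d_max = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        d_max = min(pa * pb, (1 - pa) * (1 - pb))
    d_prime = abs(D) / d_max if d_max > 0 else 0.0
    r2 = D * D / (pa * (1 - pa) * pb * (1 - pb))

    lod = float("nan")
    if n_haplotypes is not None:
        marg = {"V": {"a": pa, "b": pb}, "R": {"a": 1 - pa, "b": 1 - pb}}
        lod = 0.0
        for (ca, cb) in (("R", "R"), ("R", "V"), ("V", "R"), ("V", "V")):
            p_obs = two.get((ca, cb), 0.0)
            if p_obs <= 0.0:
                continue
            p_ind = marg[ca]["a"] * marg[cb]["b"]
            lod += n_haplotypes * p_obs * math.log10(p_obs / p_ind)
    return LDResult(locus_a, locus_b, D, min(1.0, d_prime), min(1.0, r2), lod)


def ld_matrix(table: HaplotypeFreqTable, n_haplotypes: int | None = None) -> list[LDResult]:
    out = []
    for a, b in combinations(table.loci, 2):
        try:
            out.append(pairwise_ld(table, a, b, n_haplotypes))
        except ValueError:
            continue
    return out
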