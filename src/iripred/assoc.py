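"""Exact and asymptotic association statistics for 2xK outcome tables.

Conventions follow what SPSS and R produce: the two-sided Fisher p-value
is the probability-mass method (sum of all margin-consistent tables whose
conditional probability does not exceed the observed one, with a 1e-7
relative guard against floating-point ties), the 2xK generalization is
the Freeman-Halton test by exhaustive enumeration, the trend test is the
asymptotic Cochran-Armitage statistic without continuity correction, and
odds-ratio confidence intervals are Woolf (log) intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .cohort import Cohort
from .panel import MISSING

_TIE_REL_TOL = 1e-7


@dataclass(frozen=True)
class AssocResult:
    label: str
    p_fisher: float | None = None
    p_trend: float | None = None
    odds_ratio: float | None = None
    ci95: tuple[float, float] | None = None
    reference: str | None = None
    counts: tuple | None = None


def _check_2xk(table) -> np.ndarray:
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise ValueError(f"expected a 2xK table with K >= 2, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("cell counts must be non-negative")
    return t


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (probability-mass method)."""
    t = _check_2xk(table)
    if t.shape[1] != 2:
        raise ValueError("fisher_exact_2x2 requires exactly 2 columns")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("degenerate margin (empty row or column); p = 1", stacklevel=2)
        return 1.0
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def fisher_exact_2xk(table) -> float:
    """Freeman-Halton exact p for a 2xK table by exhaustive enumeration.

    Sums the conditional (multivariate hypergeometric) probabilities of
    every table with the observed margins whose probability is at most the
    observed table's.  Enumeration is over the K free cells of the first
    row; K is capped at 6.
    """
    t = _check_2xk(table)
    k = t.shape[1]
    if k > 6:
        raise ValueError(f"K = {k} unsupported (enumeration bound is 6)")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = int(t.sum())
    if (row == 0).any() or (col == 0).any():
        warnings.warn("degenerate margin (empty row or column); p = 1", stacklevel=2)
        return 1.0

    lg = [math.lgamma(i + 1) for i in range(n + 1)]
    log_k = sum(lg[r] for r in row) + sum(lg[c] for c in col) - lg[n]

    def log_prob(cells_row0) -> float:
        s = log_k
        for a, c in zip(cells_row0, col):
            s -= lg[a] + lg[c - a]
        return s

    obs = log_prob(t[0])
    log_tie = math.log1p(_TIE_REL_TOL)
    r0 = int(row[0])
    p_total = 0.0

    def rec(j: int, remaining: int, cells: list[int]) -> None:
        nonlocal p_total
        if j == k - 1:
            if remaining <= col[j]:
                lp = log_prob(cells + [remaining])
                if lp <= obs + log_tie:
                    p_total += math.exp(lp)
            return
        lo = max(0, remaining - int(col[j + 1:].sum()))
        hi = min(int(col[j]), remaining)
        for a in range(lo, hi + 1):
            rec(j + 1, remaining - a, cells + [a])

    rec(0, r0, [])
    return min(1.0, p_total)


def cochran_armitage_trend(table, scores=(0, 1, 2)) -> tuple[float, float]:
    """Cochran-Armitage trend test on a 2xK dose table.

    Rows are (cases, controls), columns are ordered dose categories.
    Returns (Z, two-sided p from the normal distribution); no continuity
    correction.  The p-value is invariant to affine rescaling of scores.
    """
    t = _check_2xk(table)
    s = np.asarray(scores, dtype=float)
    if len(s) != t.shape[1]:
        raise ValueError("scores length must equal number of columns")
    if not (np.diff(s) > 0).all():
        raise ValueError("scores must be strictly increasing")
    cases = t[0].astype(float)
    n_col = t.sum(axis=0).astype(float)
    N = n_col.sum()
    R = cases.sum()
    p_bar = R / N
    T = float(np.sum(s * (cases - n_col * p_bar)))
    var = p_bar * (1 - p_bar) * (np.sum(s**2 * n_col) - np.sum(s * n_col) ** 2 / N)
    if var <= 0:
        raise ValueError("zero variance: no spread in dose categories")
    z = T / math.sqrt(var)
    return z, float(2.0 * sps.norm.sf(abs(z)))


def odds_ratio_vs_reference(exposed: tuple[int, int], reference: tuple[int, int],
                            label: str = "", ref_label: str = "reference") -> AssocResult:
    """Odds ratio of outcome in an exposed group vs a reference group.

    Both groups are (n_yes, n_no).  The 95% CI is the Woolf interval
    exp(ln OR +/- 1.96 sqrt(sum 1/cell)); when any cell is zero, the
    Haldane-Anscombe +0.5 correction is applied to all four cells and a
    warning is emitted.  The two-sided Fisher p of the implied 2x2 is
    attached.
    """
    e_yes, e_no = exposed
    r_yes, r_no = reference
    if min(exposed) < 0 or min(reference) < 0:
        raise ValueError("counts must be non-negative")
    if e_yes + e_no == 0 or r_yes + r_no == 0:
        raise ValueError("a group with zero total has no defined odds")
    cells = [e_yes, e_no, r_yes, r_no]
    if 0 in cells:
        warnings.warn("zero cell: Haldane-Anscombe +0.5 applied", stacklevel=2)
        cells = [c + 0.5 for c in cells]
    a, b, c, d = cells
    or_ = (a * d) / (b * c)
    se = math.sqrt(sum(1.0 / x for x in cells))
    lo, hi = math.exp(math.log(or_) - 1.96 * se), math.exp(math.log(or_) + 1.96 * se)
    p = fisher_exact_2x2([[e_yes, e_no], [r_yes, r_no]])
    return AssocResult(
        label=label, p_fisher=p, odds_ratio=or_, ci95=(lo, hi),
        reference=ref_label, counts=(exposed, reference),
    )


def genotype_association_scan(cohort: Cohort) -> list[AssocResult]:
    """Per-locus toxicity association: exact 2x3 (or 2x2) p and trend p.

    Patients with missing toxicity or a missing genotype at the scanned
    locus are excluded from that locus's table.  Loci with a single
    observed genotype class are skipped with a warning.
    """
    G = cohort.genotype_matrix()
    tox = cohort.toxicity_array()
    results: list[AssocResult] = []
    for j, locus in enumerate(cohort.panel):
        ok = (G[:, j] != MISSING) & (tox != MISSING)
        g, t = G[ok, j], tox[ok]
        classes = [c for c in (0, 1, 2) if np.sum(g == c) > 0]
        if len(classes) < 2:
            warnings.warn(f"{locus.locus_id}: single genotype class, skipped", stacklevel=2)
            continue
        table = np.array(
            [[int(np.sum((g == c) & (t == 1))) for c in classes],
             [int(np.sum((g == c) & (t == 0))) for c in classes]]
        )
        p_fisher = fisher_exact_2xk(table)
        p_trend = None
        if len(classes) >= 3:
            try:
                _, p_trend = cochran_armitage_trend(table, scores=classes)
            except ValueError:
                p_trend = None
        results.append(
            AssocResult(label=locus.locus_id, p_fisher=p_fisher, p_trend=p_trend,
                        counts=tuple(tuple(int(x) for x in row) for row in table))
        )
    return results


def association_report_tsv(results: list[AssocResult], path, bh_column: bool = False) -> None:
    """Tabular association report; ``bh_column=True`` appends
    Benjamini-Hochberg adjusted exact p-values (off by default, matching
    the uncorrected source analyses)."""
    bh = {}
    if bh_column:
        with_p = [r for r in results if r.p_fisher is not None]
        adjusted = sps.false_discovery_control([r.p_fisher for r in with_p])
        bh = {id(r): q for r, q in zip(with_p, adjusted)}
    with open(path, "w") as fh:
        header = "group\tcounts\tfisher_p\ttrend_p\tOR\tci95_low\tci95_high\treference"
        fh.write(header + ("\tfisher_p_bh\n" if bh_column else "\n"))
        for r in results:
            fh.write(
                "\t".join([
                    r.label,
                    repr(r.counts) if r.counts else "",
                    f"{r.p_fisher:.3f}" if r.p_fisher is not None else "",
                    f"{r.p_trend:.3f}" if r.p_trend is not None else "",
                    f"{r.odds_ratio:.2f}" if r.odds_ratio is not None else "",
                    f"{r.ci95[0]:.2f}" if r.ci95 else "",
                    f"{r.ci95[1]:.2f}" if r.ci95 else "",
                    r.reference or "",
                ] + ([f"{bh[id(r)]:.3f}" if id(r) in bh else ""] if bh_column else []))
                + "\n"
            )
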