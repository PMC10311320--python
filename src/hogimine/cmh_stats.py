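"""Cochran-Mantel-Haenszel test, minimum attainable p-values, and the
descendant envelope used for search-space pruning.

The CMH statistic for a 2x2xC table with per-stratum margins
(n_j, n1_j) and pattern counts (x_j carriers, a_j carrier-cases) is

    T = [ sum_j (a_j - x_j n1_j / n_j) ]^2
        / sum_j x_j (n_j - x_j) n1_j (n_j - n1_j) / (n_j^2 (n_j - 1))

with p = Pr[chi2_1 >= T].  Strata with zero variance (x_j in {0, n_j},
n1_j in {0, n_j}, or n_j <= 1) contribute nothing to either sum; a wholly
degenerate table gives T = 0, p = 1.  No continuity correction is applied,
matching the convention of the significant-pattern-mining literature.

Because T depends on the a_j only through their sum, the minimum attainable
p-value given the margins is reached at one of the two extreme totals
(every a_j at its upper, or every a_j at its lower, bound) -- this is what
makes Tarone-style testability pruning cheap.

The *envelope* extends this to all descendants of a pattern: descendants
have supersets of the support, hence componentwise-larger x.  The envelope
is a lower bound on the minimum attainable p-value over the whole box
{x' : x_j <= x'_j <= n_j}.  The default "tight" method maximises the two
corner statistics over a per-stratum candidate grid; each corner statistic
is, coordinate-wise on every linear piece of its clamped numerator, a ratio
of a convex quadratic over a positive concave quadratic, hence quasiconvex,
so the box maximum lies on the grid of piece endpoints -- the candidate set
{x_j, n1_j, n_j - n1_j, n_j} (clamped).  A separable Cauchy-Schwarz bound
is available as a certified fallback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Sequence

from .bitsupport import StratifiedCounts, StratumMasks

__all__ = [
    "TestResult",
    "chi2_sf",
    "cmh_pvalue",
    "min_attainable_pvalue",
    "envelope_pvalue",
    "cmh_statistic_margins",
    "corner_statistic_margins",
    "envelope_pvalue_margins",
    "test_pattern_counts",
]


def chi2_sf(t: float) -> float:
    """Survival function of chi-square with 1 df: Pr[X >= t] = erfc(sqrt(t/2))."""
    if t <= 0.0:
        return 1.0
    return math.erfc(math.sqrt(0.5 * t))


@dataclass(frozen=True)
class TestResult:
    """CMH outcome for one pattern: statistic, p, and the two pruning bounds."""

    T: float
    p: float
    p_min: float
    p_env: float


def cmh_statistic_margins(x: Sequence[int], a: Sequence[int], masks: StratumMasks) -> float:
    num = 0.0
    den = 0.0
    for j in range(masks.C):
        xj = x[j]
        nj = masks.n_per[j]
        num += a[j] - xj * masks.ratio[j]
        den += xj * (nj - xj) * masks.var_coef[j]
    if den <= 0.0:
        return 0.0
    return num * num / den


def cmh_pvalue(counts: StratifiedCounts) -> tuple[float, float]:
    """CMH chi-square statistic (1 df) and its p-value, no continuity correction."""
    t = cmh_statistic_margins(counts.x, counts.a, counts.masks)
    return t, chi2_sf(t)


def corner_statistic_margins(x: Sequence[int], masks: StratumMasks) -> float:
    """max over the two extreme a-totals of T(a | x); depends on margins only."""
    expect = 0.0
    den = 0.0
    s_hi = 0.0
    s_lo = 0.0
    for j in range(masks.C):
        xj = x[j]
        nj = masks.n_per[j]
        n1j = masks.n1_per[j]
        expect += xj * masks.ratio[j]
        den += xj * (nj - xj) * masks.var_coef[j]
        s_hi += xj if xj < n1j else n1j
        lo = xj - (nj - n1j)
        if lo > 0:
            s_lo += lo
    if den <= 0.0:
        return 0.0
    d_hi = s_hi - expect
    d_lo = s_lo - expect
    return max(d_hi * d_hi, d_lo * d_lo) / den


def min_attainable_pvalue(counts: StratifiedCounts) -> float:
    """Smallest p-value achievable given the margins (support), over all
    feasible case splits a.  Uses only x, n, n1; equals 1 on degenerate tables."""
    return chi2_sf(corner_statistic_margins(counts.x, counts.masks))


def _candidate_values(xj: int, nj: int, n1j: int) -> tuple[int, ...]:
    cands = {xj, nj}
    for v in (n1j, nj - n1j):
        if v > xj:
            cands.add(v if v < nj else nj)
    return tuple(sorted(cands))


def envelope_pvalue(counts: StratifiedCounts, method: str = "tight") -> float:
    """Certified lower bound on min_attainable_pvalue over every descendant
    support box {x' : x_j <= x'_j <= n_j}.

    "tight" maximises the corner statistic over the per-stratum candidate
    grid (exact, <= 4^C evaluations); "separable" uses the Cauchy-Schwarz
    per-stratum bound (valid but looser).
    """
    return envelope_pvalue_margins(counts.x, counts.masks, method)


def envelope_pvalue_margins(
    x: Sequence[int], masks: StratumMasks, method: str = "tight"
) -> float:
    """Margin-level form of :func:`envelope_pvalue` (used in the hot loop)."""
    if method == "tight":
        cand_sets = [
            _candidate_values(x[j], masks.n_per[j], masks.n1_per[j])
            for j in range(masks.C)
        ]
        if masks.C == 1:
            best = max(corner_statistic_margins((v,), masks) for v in cand_sets[0])
        else:
            best = 0.0
            for combo in product(*cand_sets):
                t = corner_statistic_margins(combo, masks)
                if t > best:
                    best = t
        return chi2_sf(best)
    if method == "separable":
        # (sum u)^2 / (sum v) <= sum u^2/v for v > 0, so the box maximum of T
        # is bounded by the sum over strata of the per-stratum maxima.
        bound = 0.0
        for j in range(masks.C):
            nj = masks.n_per[j]
            n1j = masks.n1_per[j]
            best_j = 0.0
            for v in _candidate_values(x[j], nj, n1j):
                dj = v * (nj - v) * masks.var_coef[j]
                if dj <= 0.0:
                    continue
                e = v * masks.ratio[j]
                hi = (v if v < n1j else n1j) - e
                lo = max(0, v - (nj - n1j)) - e
                t = max(hi * hi, lo * lo) / dj
                if t > best_j:
                    best_j = t
            bound += best_j
        return chi2_sf(bound)
    raise ValueError(f"unknown envelope method {method!r}")


def test_pattern_counts(counts: StratifiedCounts, envelope_method: str = "tight") -> TestResult:
    """Convenience bundle: statistic, p, minimum attainable p, and envelope."""
    t, p = cmh_pvalue(counts)
    p_min = min_attainable_pvalue(counts)
    p_env = envelope_pvalue(counts, method=envelope_method)
    return TestResult(T=t, p=p, p_min=p_min, p_env=p_env)
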