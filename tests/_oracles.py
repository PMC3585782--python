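"""Independent brute-force oracles used to cross-check the implementation.

Everything here is derived from first principles (exhaustive enumeration,
closed forms, dense grids) and never calls the code paths it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import numpy as np


def brute_force_scan(hom, het, missing, positions, params):
    """All maximal qualifying homozygous runs by exhaustive window enumeration.

    For every start, walk right accumulating het/missing counts and gap
    checks, recording the furthest homozygous end; keep runs not strictly
    contained in another valid run; then apply the size criterion.
    Returns a list of (start, end) index pairs.
    """
    n = len(hom)
    max_end: dict[int, int] = {}
    for s in range(n):
        if not hom[s]:
            continue
        nh = nm = 0
        best = None
        for e in range(s, n):
            if (
                e > s
                and params.max_gap_kb is not None
                and positions[e] - positions[e - 1] > params.max_gap_kb * 1000.0
            ):
                break
            nh += bool(het[e])
            nm += bool(missing[e])
            if nh > params.max_het or nm > params.max_missing:
                break
            if hom[e]:
                best = e
        if best is not None:
            max_end[s] = best
    maximal = []
    reach = -1
    for s in sorted(max_end):
        if max_end[s] > reach:
            maximal.append((s, max_end[s]))
            reach = max_end[s]
    out = []
    for s, e in maximal:
        if params.min_kb is not None:
            span_kb = (positions[e] - positions[s] + 1) / 1000.0
            ok = span_kb >= params.min_kb and e - s + 1 >= params.min_snps_if_kb
        else:
            ok = e - s + 1 >= params.min_snps
        if ok:
            out.append((s, e))
    return out


def hypergeom_pmf_exact(k, r1, r2, m) -> Fraction:
    """Exact fixed-margin table probability as a rational number."""
    return Fraction(
        math.comb(r1, k) * math.comb(r2, m - k), math.comb(r1 + r2, m)
    )


def fisher_p_enum(a, b, c, d) -> float:
    """Two-sided point-probability Fisher p by exact rational enumeration."""
    r1, r2, m = a + b, c + d, a + c
    p_obs = hypergeom_pmf_exact(a, r1, r2, m)
    lo, hi = max(0, m - r2), min(r1, m)
    total = Fraction(0)
    for k in range(lo, hi + 1):
        pk = hypergeom_pmf_exact(k, r1, r2, m)
        if pk <= p_obs:
            total += pk
    return float(total)


def _cond_loglik(psi_log, a, r1, r2, m) -> float:
    lo, hi = max(0, m - r2), min(r1, m)
    terms = [
        math.log(math.comb(r1, k)) + math.log(math.comb(r2, m - k)) + k * psi_log
        for k in range(lo, hi + 1)
    ]
    mx = max(terms)
    log_denom = mx + math.log(sum(math.exp(t - mx) for t in terms))
    return (
        math.log(math.comb(r1, a)) + math.log(math.comb(r2, m - a)) + a * psi_log
        - log_denom
    )


def cmle_odds_ratio_grid(a, b, c, d) -> float:
    """Conditional-MLE odds ratio by dense log-grid search plus refinement."""
    r1, r2, m = a + b, c + d, a + c
    lo, hi = max(0, m - r2), min(r1, m)
    if a == hi:
        return math.inf
    if a == lo:
        return 0.0
    grid = np.linspace(math.log(1e-8), math.log(1e8), 2001)
    vals = [_cond_loglik(x, a, r1, r2, m) for x in grid]
    i = int(np.argmax(vals))
    left, right = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    for _ in range(200):  # golden-section refinement on the log scale
        m1 = left + 0.381966 * (right - left)
        m2 = right - 0.381966 * (right - left)
        if _cond_loglik(m1, a, r1, r2, m) < _cond_loglik(m2, a, r1, r2, m):
            left = m1
        else:
            right = m2
    return math.exp((left + right) / 2.0)


def normalized_cut(S: np.ndarray, side_a) -> float:
    """Normalized-cut value of a bipartition (degrees include the diagonal)."""
    n = S.shape[0]
    a = sorted(side_a)
    b = sorted(set(range(n)) - set(a))
    cut = S[np.ix_(a, b)].sum()
    vol_a = S[a, :].sum()
    vol_b = S[b, :].sum()
    if vol_a == 0 or vol_b == 0:
        return math.inf
    return float(cut * (1.0 / vol_a + 1.0 / vol_b))


def all_bipartitions(n):
    """Every bipartition of range(n) into two non-empty sides (each once)."""
    items = list(range(n))
    for r in range(1, n // 2 + 1):
        for side in combinations(items, r):
            # equal halves would appear twice; keep the one holding item 0
            if 2 * r == n and 0 not in side:
                continue
            yield set(side)


def min_ncut_bipartitions(S: np.ndarray):
    """All bipartition ncut values sorted ascending: [(value, side), ...]."""
    scored = [
        (normalized_cut(S, side), side) for side in all_bipartitions(S.shape[0])
    ]
    scored.sort(key=lambda t: t[0])
    return scored
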