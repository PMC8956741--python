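"""Independent brute-force oracles used by the test suite.

Everything here is computed by direct summation/enumeration in exact rational
arithmetic (or full enumeration of small sample spaces), independent of the
scipy/statsmodels code paths the implementation uses.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


def exact_binomial_tail(k: int, n: int, p_num: int, p_den: int) -> Fraction:
    """P(X >= k), X ~ Binomial(n, p_num/p_den), exact rational."""
    p = Fraction(p_num, p_den)
    q = 1 - p
    total = Fraction(0)
    for i in range(k, n + 1):
        total += math.comb(n, i) * p**i * q**(n - i)
    return total


def exact_binomial_two_sided(k: int, n: int, p: Fraction) -> Fraction:
    """Two-sided exact binomial p: sum of all outcome probabilities not
    exceeding the observed one (the small-p-value definition scipy uses)."""
    q = 1 - p
    pmf = [math.comb(n, i) * p**i * q**(n - i) for i in range(n + 1)]
    obs = pmf[k]
    return sum((x for x in pmf if x <= obs), Fraction(0))


def exact_fisher_two_sided(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    Conditional on the margins, sums the probabilities of every table at
    least as extreme (pmf <= observed pmf) — exact rational arithmetic, so
    ties are handled without floating-point tolerance.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    k_lo, k_hi = max(0, c1 - r2), min(r1, c1)
    weights = {
        k: math.comb(r1, k) * math.comb(r2, c1 - k)
        for k in range(k_lo, k_hi + 1)
    }
    obs = weights[a]
    tail = sum(w for w in weights.values() if w <= obs)
    return Fraction(tail, denom)


def bh_stepup(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values by the direct step-up recursion."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p_values[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def exact_cluster_pvalue(
    n_residues: int, cluster_members: set[int], n_mutations: int, observed: int
) -> Fraction:
    """P(cluster sum >= observed) under uniform multinomial placement of
    ``n_mutations`` labeled mutations over ``n_residues`` residues, by full
    enumeration of all n_residues**n_mutations placements."""
    hits = 0
    total = 0
    for placement in itertools.product(range(n_residues), repeat=n_mutations):
        total += 1
        if sum(1 for r in placement if r in cluster_members) >= observed:
            hits += 1
    return Fraction(hits, total)


def two_prop_ccorr_pvalue(x1: int, n1: int, x2: int, n2: int) -> float:
    """Continuity-corrected two-proportion z-test p, textbook z formulation."""
    from scipy.stats import chi2

    p1, p2 = x1 / n1, x2 / n2
    pbar = (x1 + x2) / (n1 + n2)
    if pbar in (0.0, 1.0):
        return 1.0
    corr = min(abs(p1 - p2), 0.5 * (1 / n1 + 1 / n2))
    stat = (abs(p1 - p2) - corr) ** 2 / (pbar * (1 - pbar) * (1 / n1 + 1 / n2))
    return float(chi2.sf(stat, df=1))


def plackett_p11(p1: float, p2: float, psi: float) -> float:
    """Joint cell probability from marginals and odds ratio (quadratic root),
    derived independently by solving psi = p11 p00 / (p10 p01)."""
    if abs(psi - 1) < 1e-12:
        return p1 * p2
    s = 1 + (p1 + p2) * (psi - 1)
    return (s - math.sqrt(s * s - 4 * psi * (psi - 1) * p1 * p2)) / (2 * (psi - 1))
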