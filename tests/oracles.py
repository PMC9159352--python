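"""Independent brute-force reference implementations used only by tests.

Every function here recomputes a statistic by direct enumeration or an
algebraically different route from the package code it checks.
"""

from fractions import Fraction
from itertools import combinations
from math import comb, factorial

import numpy as np


def pairwise_site_pi(column: np.ndarray) -> float:
    """Mean pairwise difference at one site by enumerating haplotype pairs."""
    n = len(column)
    diff = sum(1 for i, j in combinations(range(n), 2) if column[i] != column[j])
    return diff / comb(n, 2)


def pairwise_window_pi(hap: np.ndarray, span: int) -> float:
    """All-pairs Hamming distance over a window, per bp."""
    n = hap.shape[0]
    total = sum(
        int(np.sum(hap[i] != hap[j])) for i, j in combinations(range(n), 2)
    )
    return total / comb(n, 2) / span


def wc_fst_anova(pops: list[np.ndarray]) -> tuple[float, float, float]:
    """Weir-Cockerham components via the nested ANOVA route.

    ``pops`` holds, per population, an (n_i, 2) array of allele indicators
    per individual.  Returns (a, b, c) = (sigma2_a, sigma2_b, sigma2_w).
    """
    r = len(pops)
    n = np.array([p.shape[0] for p in pops], dtype=float)
    n_tot = n.sum()
    ind_means = [p.mean(axis=1) for p in pops]
    pop_means = np.array([m.mean() for m in ind_means])
    grand = float(np.sum(n * pop_means) / n_tot)

    ssw = sum(float(np.sum((p - m[:, None]) ** 2))
              for p, m in zip(pops, ind_means))
    ssb = 2.0 * sum(float(np.sum((m - pm) ** 2))
                    for m, pm in zip(ind_means, pop_means))
    ssa = 2.0 * float(np.sum(n * (pop_means - grand) ** 2))

    msw = ssw / n_tot
    msb = ssb / (n_tot - r)
    msa = ssa / (r - 1)
    nc = (n_tot - np.sum(n ** 2) / n_tot) / (r - 1)
    sigma_w = msw
    sigma_b = (msb - msw) / 2.0
    sigma_a = (msa - msb) / (2.0 * nc)
    return sigma_a, sigma_b, sigma_w


def ehhs_bruteforce(hap: np.ndarray, core: int, t: int) -> float:
    """EHHS at marker t by enumerating haplotype pairs over the span."""
    n = hap.shape[0]
    lo, hi = min(core, t), max(core, t)
    span = hap[:, lo:hi + 1]
    same_span = sum(
        1 for i, j in combinations(range(n), 2)
        if np.array_equal(span[i], span[j])
    )
    same_core = sum(
        1 for i, j in combinations(range(n), 2) if hap[i, core] == hap[j, core]
    )
    return same_span / same_core


def hwe_enumeration(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact HWE p by full enumeration with exact rational arithmetic."""
    n = n_hom1 + n_het + n_hom2
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    n_common = 2 * n - n_rare
    if n_rare == 0:
        return 1.0

    def prob(h: int) -> Fraction:
        hom_rare = (n_rare - h) // 2
        hom_common = n - h - hom_rare
        num = (
            Fraction(factorial(n))
            / (factorial(hom_rare) * factorial(h)
               * factorial(hom_common))
            * Fraction(2) ** h
        )
        den = Fraction(factorial(2 * n),
                       factorial(n_rare) * factorial(n_common))
        return num / den

    hets = range(n_rare % 2, min(n_rare, n_common) + 1, 2)
    probs = {h: prob(h) for h in hets}
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs))


def bh_bruteforce(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the step-up definition."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, pvals[i] * m / rank_from_top)
        adj[i] = running_min
    return adj
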