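"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and, where possible, the library
routines) they validate.
"""

import numpy as np
from scipy.stats import hypergeom, rankdata


def bh_stepup(pvalues):
    """Benjamini-Hochberg adjusted p-values by the literal step-up rule:
    q_(i) = min_{j >= i} p_(j) * m / j, clipped at 1."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fisher_exact_enumeration(n11, n10, n01, n00):
    """Two-sided Fisher exact p by exhaustive enumeration of all 2x2
    tables with the observed margins, summing hypergeometric
    probabilities no greater than the observed table's."""
    r1 = n11 + n10
    c1 = n11 + n01
    n = n11 + n10 + n01 + n00
    if n == 0:
        return 1.0
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(ks, n, c1, r1)
    p_obs = hypergeom.pmf(n11, n, c1, r1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def conditional_odds_ratio_plain(n11, n10, n01, n00):
    """Plain cross-product odds ratio (no continuity correction);
    inf/0 for zero cells."""
    with np.errstate(divide="ignore", invalid="ignore"):
        return (n11 * n00) / (n10 * n01) if n10 * n01 else np.inf


def spearman_rho_via_pearson(x, y):
    """Spearman rho as the Pearson correlation of tie-averaged ranks."""
    rx, ry = rankdata(x), rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])
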