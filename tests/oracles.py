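"""Independent reference implementations used only by the tests.

Everything here is written directly from textbook formulas or brute-force
enumeration, deliberately along different algebraic paths than the
package, so agreement is evidence of correctness rather than repetition.
"""

from __future__ import annotations

import itertools
from math import comb, sqrt

import numpy as np


# -- diversity ---------------------------------------------------------------

def pi_pairwise(calls_at_site) -> float:
    """Mean pairwise difference by explicit enumeration of sample pairs."""
    vals = [c for c in calls_at_site if c in (0, 1)]
    n = len(vals)
    if n < 2:
        return float("nan")
    diff = sum(1 for x, y in itertools.combinations(vals, 2) if x != y)
    return diff / comb(n, 2)


def watterson(S: int, n: int) -> float:
    return S / sum(1.0 / i for i in range(1, n))


def tajimas_d(pi_sum: float, S: int, n: int) -> float:
    """Tajima (1989) D from the published constants, coded independently."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_sum - S / a1) / sqrt(e1 * S + e2 * S * (S - 1))


def wc_fst_haploid(k1: int, n1: int, k2: int, n2: int) -> float:
    """W&C 1984 via the spec's n-bar/n_c parameterization (with the
    within-component prefactor), not the ANOVA arrangement the package uses."""
    r = 2
    p1, p2 = k1 / n1, k2 / n2
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    if pbar <= 0 or pbar >= 1:
        return float("nan")
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    inner = pbar * (1 - pbar) - s2 * (r - 1) / r
    a = (nbar / nc) * (s2 - inner / (nbar - 1))
    b = (nbar / (nbar - 1)) * inner
    return a / (a + b)


# -- Fay & Wu ----------------------------------------------------------------

def fay_wu_h_norm(counts: np.ndarray, n: int) -> float:
    """Normalized H from the unfolded spectrum, direct sums."""
    S = float(sum(counts[1:n]))
    tp = sum(2 * j * (n - j) / (n * (n - 1)) * counts[j] for j in range(1, n))
    tl = sum(j * counts[j] for j in range(1, n)) / (n - 1)
    an = sum(1.0 / i for i in range(1, n))
    bn = sum(1.0 / i**2 for i in range(1, n))
    bn1 = sum(1.0 / i**2 for i in range(1, n + 1))
    tw = S / an
    t2 = S * (S - 1) / (an**2 + bn)
    var = tw * (n - 2) / (6 * (n - 1)) + t2 * (
        18 * n**2 * (3 * n + 2) * bn1 - (88 * n**3 + 9 * n**2 - 13 * n + 6)
    ) / (9 * n * (n - 1) ** 2)
    return (tp - tl) / sqrt(var)


# -- sweep model enumeration -------------------------------------------------

def sweep_dist_enum(n: int, p_e: float, q: np.ndarray) -> np.ndarray:
    """Exhaustive enumeration of the post-sweep count distribution.

    q is the background probability over derived counts 1..n-1 (length
    n+1 with zeros at 0 and n).  Enumerates the number of escapees e, the
    background count j, every subset-draw of e+1 of the n pre-sweep
    lineages (hypergeometric by combinatorics), and the choice of the
    swept ancestor among them.
    """
    out = np.zeros(n + 1)
    for e in range(n + 1):
        w_e = comb(n, e) * p_e**e * (1 - p_e) ** (n - e)
        if w_e == 0:
            continue
        if e == n:
            out += w_e * q
            continue
        m = e + 1
        for j in range(1, n):
            if q[j] == 0:
                continue
            for k in range(0, m + 1):
                if k > j or m - k > n - j:
                    continue
                hyp = comb(j, k) * comb(n - j, m - k) / comb(n, m)
                w = w_e * q[j] * hyp
                # the swept ancestor is each of the m drawn lineages equally
                if k >= 1:
                    out[k - 1 + (n - e)] += w * k / m
                out[k] += w * (m - k) / m
    return out


# -- rank-sum and enrichment -------------------------------------------------

def wilcoxon_exact_two_sided(a, b) -> float:
    """Exact two-sided rank-sum p by full enumeration of group assignments."""
    pooled = sorted(a) + sorted(b)
    n = len(pooled)
    na = len(a)
    ranks = {v: r for r, v in enumerate(sorted(pooled), 1)}
    obs = sum(ranks[v] for v in a)
    mu = na * (n + 1) / 2
    count = total = 0
    for combo in itertools.combinations(range(1, n + 1), na):
        w = sum(combo)
        total += 1
        if abs(w - mu) >= abs(obs - mu) - 1e-12:
            count += 1
    return count / total


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by direct combinatorial summation."""
    return sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)) / comb(N, n)


def by_adjust(pvals) -> list[float]:
    """Benjamini-Yekutieli step-up, coded from the definition."""
    p = list(pvals)
    m = len(p)
    c = sum(1.0 / i for i in range(1, m + 1))
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m * c / rank)
        adj[i] = val
        prev = val
    return adj


def quantile_type7(values, q: float) -> float:
    """Linear-interpolation quantile from the (n-1)q + 1 position formula."""
    v = sorted(values)
    h = (len(v) - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])
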