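"""SweepFinder-style composite likelihood ratio scan.

The model: at physical distance d from a putative sweep center, a sampled
lineage escapes the sweep with probability p_e = 1 - exp(-alpha * d).
Non-escaped lineages coalesce star-like into a single swept ancestor, so
a site's post-sweep allele count is obtained by drawing the escapees plus
that ancestor from the genome-wide background site-frequency spectrum and
copying the ancestor's allele onto all non-escapees.  The composite
likelihood of the sites near a grid point is maximized over the sweep
intensity alpha and compared with the likelihood under the background
spectrum alone: CLR = 2 (max_alpha log CL - log CL_null).

Two code paths share one model: an exact path (``sweep_site_distribution``
and ``composite_log_likelihood``, used directly by small-sample tests)
and a bucketed prefix-sum path used by ``clr_scan`` that discretizes
alpha * d so genome-size scans run in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom, hypergeom

from ._core import logger
from .io import AncestralAlleles, GenotypeMatrix
from .sfs import SFS, alt_counts, build_sfs

__all__ = [
    "BackgroundSFS",
    "escape_probability",
    "sweep_site_distribution",
    "composite_log_likelihood",
    "clr_scan",
    "grid_points",
]

#: alpha*d beyond which a site is treated as unaffected (p_e > 0.999)
X_MAX = -np.log(1e-3)
#: alpha*d below which the fully-swept limit distribution is used
X_MIN = 1e-4
#: pseudo-count floor for empty background classes
PSEUDO_COUNT = 0.5


class BackgroundSFS:
    """Genome-wide spectrum used as the CLR null, at the modal sample size.

    Internally always an unfolded probability vector over classes 1..n-1
    (a folded input spectrum is symmetrized); ``folded_mode`` records
    whether observations are compared on the folded scale.  Empty classes
    are floored at a pseudo-count so every q_j > 0.
    """

    def __init__(self, n: int, q: np.ndarray, folded_mode: bool):
        if len(q) != n + 1:
            raise ValueError("q must have length n + 1")
        self.n = n
        self.q = q / q[1:n].sum()
        self.q[0] = self.q[n] = 0.0
        if (self.q[1:n] <= 0).any():
            raise ValueError("background classes must be positive")
        self.folded_mode = folded_mode
        self._projections: dict[int, BackgroundSFS] = {n: self}

    @classmethod
    def from_sfs(cls, sfs: SFS, pseudo: float = PSEUDO_COUNT) -> "BackgroundSFS":
        n = sfs.n
        if sfs.folded:
            cf = sfs.counts.copy()
            valid = np.arange(1, n // 2 + 1)
            cf[valid] = np.maximum(cf[valid], pseudo)
            q = np.zeros(n + 1)
            for j in range(1, n):
                m = min(j, n - j)
                q[j] = cf[m] if 2 * m == n else cf[m] / 2.0
            return cls(n, q, folded_mode=True)
        c = sfs.counts.copy()
        c[1:n] = np.maximum(c[1:n], pseudo)
        c[0] = c[n] = 0.0
        return cls(n, c, folded_mode=False)

    def at_n(self, m: int) -> "BackgroundSFS":
        """Background projected to a smaller sample size by hypergeometric
        downsampling, renormalized over segregating classes."""
        if m not in self._projections:
            if m > self.n:
                raise ValueError("cannot project background upward")
            j = np.arange(1, self.n)
            k = np.arange(m + 1)
            # pmf matrix: rows j, cols k
            pm = hypergeom.pmf(k[None, :], self.n, j[:, None], m)
            qm = self.q[1:self.n] @ pm
            qm[0] = qm[m] = 0.0
            self._projections[m] = BackgroundSFS(m, qm, self.folded_mode)
        return self._projections[m]

    def null_logprob(self, m: int) -> np.ndarray:
        """log P(observed class) under the background at sample size m,
        on the folded scale when in folded mode."""
        q = self.at_n(m).q
        with np.errstate(divide="ignore"):
            if self.folded_mode:
                return np.log(_fold_probs(q, m))
            return np.log(q)


def _fold_probs(p: np.ndarray, n: int) -> np.ndarray:
    """Collapse an unfolded probability vector to folded (minor) classes."""
    out = np.zeros(n + 1)
    for c in range(0, n // 2 + 1):
        out[c] = p[c] + (p[n - c] if c != n - c else 0.0)
    return out


def escape_probability(alpha: float, d_bp: float) -> float:
    """Probability a lineage escapes a sweep of intensity alpha at distance d."""
    if alpha < 0 or d_bp < 0:
        raise ValueError("alpha and distance must be non-negative")
    return -float(np.expm1(-alpha * d_bp))


def _dist_given_escapes(n: int, background: BackgroundSFS) -> np.ndarray:
    """M[e, b] = P(post-sweep derived count b | e escapees), e = 0..n.

    Given e escapees, e+1 pre-sweep lineages (escapees + the swept
    ancestor) are drawn from the background; the ancestor's allele is
    copied onto the n-e non-escapees.  e = n means no sweep: background.
    """
    bg = background.at_n(n)
    q = bg.q[1:n]  # classes 1..n-1
    j = np.arange(1, n)
    M = np.zeros((n + 1, n + 1))
    M[n] = bg.q
    for e in range(n):
        m = e + 1
        k = np.arange(m + 1)
        pm = hypergeom.pmf(k[None, :], n, j[:, None], m)  # (n-1, m+1)
        proj = q @ pm  # P(k derived among the m pre-sweep lineages)
        for kk in range(m + 1):
            p_anc_derived = kk / m
            if kk >= 1:
                M[e, kk - 1 + (n - e)] += proj[kk] * p_anc_derived
            M[e, kk] += proj[kk] * (1.0 - p_anc_derived)
    return M


def sweep_site_distribution(
    n: int,
    p_e: float,
    background: BackgroundSFS,
    condition_segregating: bool = False,
) -> np.ndarray:
    """Post-sweep distribution of the derived count at one site.

    Marginalizes the per-escapee-count distribution over
    e ~ Binomial(n, p_e).  With ``condition_segregating`` the classes
    1..n-1 are renormalized (the scan works on segregating sites only).
    Returns a vector over counts 0..n; p_e = 1 returns the background.
    """
    if not 0.0 <= p_e <= 1.0:
        raise ValueError("p_e must lie in [0, 1]")
    M = _dist_given_escapes(n, background)
    w = binom.pmf(np.arange(n + 1), n, p_e)
    dist = w @ M
    if condition_segregating:
        dist = dist.copy()
        dist[0] = dist[n] = 0.0
        tot = dist.sum()
        if tot > 0:
            dist /= tot
    return dist


def composite_log_likelihood(
    sites: tuple[np.ndarray, np.ndarray, np.ndarray],
    test_pos: float,
    alpha: float,
    background: BackgroundSFS,
) -> float:
    """Sum over sites of log P(observed class | p_e(alpha, distance)).

    ``sites`` is (pos, observed class, sample size); classes are derived
    counts (folded minor counts in folded mode).  Sites with p_e > 0.999
    contribute the null (background) term.  Exact path: used by tests and
    as the reference for the bucketed scan.
    """
    pos, jobs, ns = (np.asarray(a) for a in sites)
    if len(pos) == 0:
        raise ValueError("empty site set")
    total = 0.0
    cache: dict[tuple[int, float], np.ndarray] = {}
    for p, j, n in zip(pos, jobs, ns):
        n = int(n)
        pe = escape_probability(alpha, abs(float(p) - float(test_pos)))
        if pe > 0.999:
            total += background.null_logprob(n)[int(j)]
            continue
        key = (n, pe)
        if key not in cache:
            dist = sweep_site_distribution(n, pe, background, condition_segregating=True)
            if background.folded_mode:
                dist = _fold_probs(dist, n)
            with np.errstate(divide="ignore"):
                cache[key] = np.log(dist)
        total += cache[key][int(j)]
    return float(total)


# ---------------------------------------------------------------------------
# genome scan (bucketed fast path)
# ---------------------------------------------------------------------------

@dataclass
class CLRResult:
    chrom: str
    grid_pos: float
    clr: float
    alpha_hat: float
    n_sites_used: int


def grid_points(max_pos: int, grid_bp: int) -> np.ndarray:
    """Centers of non-overlapping grid cells tiling [0, max_pos).

    A trailing partial cell is kept when it spans at least half a cell.
    """
    points = []
    start = 0
    while start < max_pos:
        end = min(start + grid_bp, max_pos)
        if end - start >= grid_bp / 2:
            points.append(start + (end - start) / 2.0)
        start += grid_bp
    return np.asarray(points)


def _alpha_grid(grid_bp: int, n_points: int = 40) -> np.ndarray:
    """Log-spaced sweep intensities spanning p_e(alpha, grid_bp) in
    [1e-4, 1 - 1e-4]."""
    a_min = -np.log1p(-1e-4) / grid_bp
    a_max = -np.log(1e-4) / grid_bp
    return np.exp(np.linspace(np.log(a_min), np.log(a_max), n_points))


class _BucketTables:
    """Per-chromosome prefix sums of bucketed log site probabilities.

    alpha * d is discretized into log-spaced buckets; for each bucket the
    conditional sweep distribution is tabulated per distinct sample size,
    and cumulative sums over (position-sorted) sites turn any
    (grid point, alpha) evaluation into O(n_buckets) range sums.
    """

    def __init__(self, pos, jobs, ns, background: BackgroundSFS, n_buckets: int = 128):
        self.pos = pos
        self.n_sites = len(pos)
        self.x_edges = np.concatenate(
            [[0.0], np.exp(np.linspace(np.log(X_MIN), np.log(X_MAX), n_buckets))]
        )
        mids = np.sqrt(self.x_edges[1:] * np.maximum(self.x_edges[:-1], X_MIN / 4))
        pe_reps = -np.expm1(-mids)
        distinct_n = np.unique(ns)
        logp = {}
        lognull = {}
        for n in distinct_n:
            n = int(n)
            M = _dist_given_escapes(n, background)
            e = np.arange(n + 1)
            W = binom.pmf(e[None, :], n, pe_reps[:, None])  # (nb, n+1)
            dists = W @ M  # (nb, n+1)
            dists[:, 0] = dists[:, n] = 0.0
            tot = dists.sum(axis=1, keepdims=True)
            dists = np.where(tot > 0, dists / np.where(tot == 0, 1.0, tot), 0.0)
            if background.folded_mode:
                folded = np.zeros_like(dists)
                for c in range(0, n // 2 + 1):
                    folded[:, c] = dists[:, c] + (dists[:, n - c] if c != n - c else 0.0)
                dists = folded
            with np.errstate(divide="ignore"):
                logp[n] = np.log(dists)
            lognull[n] = background.null_logprob(n)
        nb = len(pe_reps)
        site_logp = np.empty((nb, self.n_sites))
        site_null = np.empty(self.n_sites)
        for n in distinct_n:
            n = int(n)
            sel = ns == n
            site_logp[:, sel] = logp[n][:, jobs[sel]]
            site_null[sel] = lognull[n][jobs[sel]]
        self.cs = np.concatenate(
            [np.zeros((nb, 1)), np.cumsum(site_logp, axis=1)], axis=1
        )
        self.cs0 = np.concatenate([[0.0], np.cumsum(site_null)])
        self.total_null = float(self.cs0[-1])
        self._bucket_idx = np.arange(nb)

    def loglik(self, test_pos: float, alphas: np.ndarray) -> np.ndarray:
        """Composite log likelihood at one grid point for many alphas."""
        alphas = np.atleast_1d(np.asarray(alphas, dtype=float))
        E = self.x_edges[None, :] / alphas[:, None]  # (na, nb+1) distances
        R = np.searchsorted(self.pos, test_pos + E, side="left")
        L = np.searchsorted(self.pos, test_pos - E, side="right")
        b = self._bucket_idx
        sweep = (
            self.cs[b, R[:, 1:]] - self.cs[b, R[:, :-1]]
            + self.cs[b, L[:, :-1]] - self.cs[b, L[:, 1:]]
        )
        null = (
            self.cs0[R[:, 1:]] - self.cs0[R[:, :-1]]
            + self.cs0[L[:, :-1]] - self.cs0[L[:, 1:]]
        )
        return self.total_null + (sweep - null).sum(axis=1)


def _golden_refine(tables: _BucketTables, t: float, lo: float, hi: float, iters: int = 16):
    """Golden-section maximization of log CL over log alpha in [lo, hi]."""
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = np.log(lo), np.log(hi)
    c, d = b - phi * (b - a), a + phi * (b - a)
    fc = tables.loglik(t, np.exp(c))[0]
    fd = tables.loglik(t, np.exp(d))[0]
    for _ in range(iters):
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = tables.loglik(t, np.exp(c))[0]
        else:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = tables.loglik(t, np.exp(d))[0]
    if fc >= fd:
        return np.exp(c), fc
    return np.exp(d), fd


def clr_scan(
    gm: GenotypeMatrix,
    panel: str,
    grid_bp: int = 150_000,
    ancestral: AncestralAlleles | None = None,
    background: BackgroundSFS | None = None,
    min_sites: int = 50,
    n_alpha: int = 40,
) -> pd.DataFrame:
    """CLR scan for one panel on a fixed physical grid.

    One grid point per non-overlapping ``grid_bp`` cell per chromosome;
    at each, the CLR is maximized over a log-spaced alpha grid refined by
    golden section.  Works on the folded spectrum unless an ancestral
    table is supplied.  Chromosomes with fewer than ``min_sites``
    segregating sites are skipped with a warning.  Returns a DataFrame
    with columns chrom, grid_pos, clr, alpha_hat, n_sites.
    """
    if background is None:
        background = BackgroundSFS.from_sfs(build_sfs(gm, panel, ancestral=ancestral))
    folded = background.folded_mode
    k, n = alt_counts(gm.panel_calls(panel))
    seg = (k > 0) & (k < n) & (n >= 2) & (n <= background.n)
    pol = ancestral.polarize(gm) if (ancestral is not None and not folded) else None
    if pol is not None:
        seg &= pol >= 0

    alphas = _alpha_grid(grid_bp, n_alpha)
    rows: list[CLRResult] = []
    for chrom in gm.chromosomes():
        sl = gm.chrom_slice(chrom)
        csel = np.zeros(gm.n_sites, dtype=bool)
        csel[sl] = True
        csel &= seg
        idx = np.flatnonzero(csel)
        if idx.size < min_sites:
            logger.warning("clr_scan: %s has %d segregating sites < %d, skipped",
                           chrom, idx.size, min_sites)
            continue
        pos = gm.pos[idx].astype(float)
        ks, nss = k[idx], n[idx]
        if folded:
            jobs = np.minimum(ks, nss - ks)
        else:
            jobs = np.where(pol[idx] == 1, ks, nss - ks)
        tables = _BucketTables(pos, jobs.astype(np.int64), nss.astype(np.int64), background)
        for t in grid_points(int(gm.pos[sl][-1]), grid_bp):
            ll = tables.loglik(t, alphas)
            i_best = int(np.argmax(ll))
            lo = alphas[max(0, i_best - 1)]
            hi = alphas[min(len(alphas) - 1, i_best + 1)]
            a_hat, ll_best = _golden_refine(tables, t, lo, hi)
            ll_best = max(ll_best, float(ll[i_best]))
            if ll[i_best] >= ll_best:
                a_hat = float(alphas[i_best])
            clr = 2.0 * max(0.0, ll_best - tables.total_null)
            cutoff = X_MAX / a_hat
            n_used = int(
                np.searchsorted(pos, t + cutoff) - np.searchsorted(pos, t - cutoff)
            )
            rows.append(CLRResult(chrom, float(t), float(clr), float(a_hat), n_used))
    return pd.DataFrame(
        [(r.chrom, r.grid_pos, r.clr, r.alpha_hat, r.n_sites_used) for r in rows],
        columns=["chrom", "grid_pos", "clr", "alpha_hat", "n_sites"],
    )
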