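"""Site-frequency-spectrum statistics.

Per-site nucleotide diversity and Weir & Cockerham's FST, per-window
Tajima's D, genome-wide SFS construction (with outgroup polarization and
hypergeometric projection to a common sample size), Fay & Wu's normalized
H, and haplotype spectra.  All estimators are on the per-SNP scale: the
window machinery averages per-SNP values rather than dividing by
accessible bases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from ._core import MISSING, NOT_DEFINED, harmonic, harmonic2, logger
from .io import AncestralAlleles, GenotypeMatrix

__all__ = [
    "SFS",
    "alt_counts",
    "site_pi",
    "pi_per_site",
    "watterson_theta",
    "tajima_constants",
    "tajimas_d",
    "site_fst_wc",
    "fst_per_site",
    "site_stats",
    "build_sfs",
    "fold_sfs",
    "project_count",
    "fay_wu_h_normalized",
    "haplotype_spectrum",
]


# ---------------------------------------------------------------------------
# per-site building blocks
# ---------------------------------------------------------------------------

def alt_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(alt-allele count, non-missing count) per site for a calls block."""
    calls = np.atleast_2d(calls)
    n = (calls != MISSING).sum(axis=1)
    k = (calls == 1).sum(axis=1)
    return k.astype(np.int64), n.astype(np.int64)


def pi_per_site(calls: np.ndarray) -> np.ndarray:
    """Unbiased per-site diversity 2*p*(1-p)*n/(n-1); NaN where n < 2.

    Equals the mean pairwise difference among the non-missing haploid
    calls at the site.
    """
    k, n = alt_counts(calls)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * k * (n - k) / (n * (n - 1.0))
    pi[n < 2] = NOT_DEFINED
    return pi


def site_pi(calls_at_site: np.ndarray) -> float:
    """Scalar per-site diversity for one panel's calls at one site."""
    return float(pi_per_site(np.asarray(calls_at_site, dtype=np.int8)[None, :])[0])


def watterson_theta(S: int, n: int) -> float:
    """Watterson's estimator theta_W = S / a1 (per window, per-SNP scale)."""
    if S < 0:
        raise ValueError("S must be non-negative")
    return S / harmonic(n)


def tajima_constants(n: int) -> tuple[float, float]:
    """(e1, e2) of Tajima's variance normalization for sample size n."""
    a1 = harmonic(n)
    a2 = harmonic2(n)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return c1 / a1, c2 / (a1**2 + a2)


def tajimas_d(window_calls: np.ndarray) -> float:
    """Tajima's D for one panel over one window of sites.

    The effective sample size is the rounded mean non-missing count over
    the window's segregating sites; pi is the exact per-site mean pairwise
    difference summed over sites.  Returns NOT_DEFINED when the window has
    no segregating site; returns exactly 0 when the numerator vanishes
    (which covers n = 2, where pi_sum = S and a1 = 1).
    """
    k, n = alt_counts(window_calls)
    seg = (k > 0) & (k < n) & (n >= 2)
    S = int(seg.sum())
    if S == 0:
        return NOT_DEFINED
    n_eff = int(round(n[seg].mean()))
    if n_eff < 2:
        return NOT_DEFINED
    if n_eff < 4:
        logger.warning("tajimas_d: effective n=%d < 4, variance unstable", n_eff)
    ks, ns = k[seg], n[seg]
    pi_sum = float(np.sum(2.0 * ks * (ns - ks) / (ns * (ns - 1.0))))
    num = pi_sum - S / harmonic(n_eff)
    e1, e2 = tajima_constants(n_eff)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return 0.0 if abs(num) < 1e-12 else NOT_DEFINED
    return num / np.sqrt(var)


def fst_per_site(calls: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Weir & Cockerham (1984) FST per site for haploid samples, 2 panels.

    ANOVA form: a = (MSP - MSG)/nc (between-panel component), b = MSG
    (within component; the heterozygosity term is zero for haploids),
    FST = a/(a+b).  Negative estimates are retained.  NaN where either
    panel has fewer than 2 non-missing calls or the site is monomorphic
    across both panels.
    """
    calls = np.atleast_2d(calls)
    k1, n1 = alt_counts(calls[:, mask_a])
    k2, n2 = alt_counts(calls[:, mask_b])
    N = n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = k1 / n1
        p2 = k2 / n2
        pbar = (k1 + k2) / N
        nc = N - (n1**2 + n2**2) / N
        ssp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
        ssg = n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)
        msp = ssp  # / (r - 1) with r = 2
        msg = ssg / (N - 2)
        a = (msp - msg) / nc
        fst = a / (a + msg)
    bad = (n1 < 2) | (n2 < 2) | (pbar <= 0) | (pbar >= 1)
    fst = np.where(bad, NOT_DEFINED, fst)
    return fst


def genome_fst(calls: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Multi-locus Weir & Cockerham FST: ratio of summed variance components.

    The standard genome-wide differentiation estimate (PLINK's "weighted"
    FST): sum_i a_i / sum_i (a_i + b_i) over polymorphic sites.  Unlike
    the unweighted mean of per-site ratios it is not depressed by
    low-frequency sites.
    """
    calls = np.atleast_2d(calls)
    k1, n1 = alt_counts(calls[:, mask_a])
    k2, n2 = alt_counts(calls[:, mask_b])
    ok = (n1 >= 2) & (n2 >= 2)
    k1, n1, k2, n2 = k1[ok], n1[ok], k2[ok], n2[ok]
    p1, p2 = k1 / n1, k2 / n2
    N = n1 + n2
    pbar = (k1 + k2) / N
    nc = N - (n1**2 + n2**2) / N
    ssp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (N - 2)
    a = (ssp - msg) / nc
    poly = (pbar > 0) & (pbar < 1)
    denom = float(np.sum((a + msg)[poly]))
    if denom == 0:
        return NOT_DEFINED
    return float(np.sum(a[poly]) / denom)


def site_fst_wc(calls_at_site: np.ndarray, panel: np.ndarray) -> float:
    """Scalar W&C FST at one site given per-sample panel labels."""
    panel = np.asarray(panel, dtype=object)
    labels = sorted(set(panel.tolist()))
    if len(labels) != 2:
        raise ValueError("exactly two panels required")
    calls = np.asarray(calls_at_site, dtype=np.int8)[None, :]
    return float(fst_per_site(calls, panel == labels[0], panel == labels[1])[0])


def site_stats(gm: GenotypeMatrix):
    """Per-site pi for each panel and cross-panel FST as a DataFrame."""
    import pandas as pd

    a, b = gm.panels
    mask_a, mask_b = gm.panel_mask(a), gm.panel_mask(b)
    return pd.DataFrame(
        {
            "chrom": gm.chrom,
            "pos": gm.pos,
            f"pi_{a}": pi_per_site(gm.calls[:, mask_a]),
            f"pi_{b}": pi_per_site(gm.calls[:, mask_b]),
            "fst": fst_per_site(gm.calls, mask_a, mask_b),
        }
    )


# ---------------------------------------------------------------------------
# SFS construction
# ---------------------------------------------------------------------------

@dataclass
class SFS:
    """Allele-count spectrum at haploid sample size n.

    ``counts[j]`` is the (possibly fractional, after projection) number of
    sites with j copies of the derived (unfolded) or minor (folded)
    allele.  Valid classes are 1..n-1 unfolded, 1..floor(n/2) folded.
    """

    n: int
    counts: np.ndarray  # float, length n + 1, classes 0 and n unused
    polarized: bool
    folded: bool

    @property
    def S(self) -> float:
        return float(self.counts[1:self.n].sum())

    def normalized(self) -> np.ndarray:
        tot = self.S
        if tot == 0:
            raise ValueError("empty SFS")
        return self.counts / tot


def project_count(j: int, n: int, m: int) -> np.ndarray:
    """Hypergeometric spread of a derived count j at size n down to size m.

    Returns the probability vector over counts 0..m of the number of
    derived alleles among m haploids drawn without replacement from the n.
    """
    if m > n:
        raise ValueError("cannot project up")
    return hypergeom.pmf(np.arange(m + 1), n, j, m)


def fold_sfs(sfs: SFS) -> SFS:
    """Fold derived-allele classes j and n-j together into minor classes."""
    n = sfs.n
    c = np.zeros(n + 1)
    for j in range(1, n):
        c[min(j, n - j)] += sfs.counts[j]
    return SFS(n=n, counts=c, polarized=False, folded=True)


def build_sfs(
    gm: GenotypeMatrix,
    panel: str,
    ancestral: AncestralAlleles | None = None,
    folded: bool | None = None,
) -> SFS:
    """Genome-wide SFS for one panel.

    Sites with a non-modal number of non-missing calls are spread over
    count classes by hypergeometric projection to the panel's modal n
    (sites with fewer calls than the modal n are skipped).  With an
    ancestral table the spectrum is unfolded (derived counts); sites that
    cannot be polarized are skipped and logged.  Without one, the minor
    allele spectrum is built and marked folded.
    """
    if folded is None:
        folded = ancestral is None
    if not folded and ancestral is None:
        raise ValueError("unfolded SFS requires an ancestral table")
    k, n = alt_counts(gm.panel_calls(panel))
    seg = (k > 0) & (k < n) & (n >= 2)
    if not seg.any():
        raise ValueError(f"no segregating sites in panel {panel}")
    n_modal = int(np.bincount(n[seg]).argmax())

    if ancestral is not None:
        pol = ancestral.polarize(gm)
    else:
        pol = np.ones(gm.n_sites, dtype=np.int8)  # treat alt as focal, fold later

    counts = np.zeros(n_modal + 1)
    n_unpol = n_small = 0
    idx = np.flatnonzero(seg)
    for i in idx:
        if pol[i] < 0:
            n_unpol += 1
            continue
        d = int(k[i]) if pol[i] == 1 else int(n[i] - k[i])
        if n[i] == n_modal:
            counts[d] += 1.0
        elif n[i] > n_modal:
            counts += project_count(d, int(n[i]), n_modal)
        else:
            n_small += 1
    counts[0] = counts[n_modal] = 0.0  # spectrum over segregating classes
    if n_unpol and ancestral is not None:
        logger.info("build_sfs: %d segregating sites unpolarized, skipped", n_unpol)
    if n_small:
        logger.info("build_sfs: %d sites below modal n skipped", n_small)
    out = SFS(n=n_modal, counts=counts, polarized=ancestral is not None, folded=False)
    return fold_sfs(out) if folded else out


# ---------------------------------------------------------------------------
# Fay & Wu's normalized H
# ---------------------------------------------------------------------------

def fay_wu_h_normalized(sfs: SFS) -> float:
    """Normalized H = (theta_pi - theta_L) / sqrt(Var).

    theta_L weights high-frequency derived classes; an excess of those
    (the sweep signature) drives H negative.  The variance normalization
    follows the standard derivation with theta estimated by theta_W and
    theta^2 by S(S-1)/(a1^2 + b_n).
    """
    if not sfs.polarized or sfs.folded:
        raise ValueError("normalized H requires outgroup polarization")
    n = sfs.n
    j = np.arange(1, n)
    Sj = sfs.counts[1:n]
    S = float(Sj.sum())
    if S < 2:
        return NOT_DEFINED
    theta_pi = float(np.sum(2.0 * j * (n - j) / (n * (n - 1.0)) * Sj))
    theta_l = float(np.sum(j * Sj)) / (n - 1.0)
    a1 = harmonic(n)
    bn = harmonic2(n)
    bn1 = harmonic2(n + 1)
    theta_w = S / a1
    theta_sq = S * (S - 1.0) / (a1**2 + bn)
    var = (
        theta_w * (n - 2.0) / (6.0 * (n - 1.0))
        + theta_sq
        * (18.0 * n**2 * (3.0 * n + 2.0) * bn1 - (88.0 * n**3 + 9.0 * n**2 - 13.0 * n + 6.0))
        / (9.0 * n * (n - 1.0) ** 2)
    )
    if var <= 0:
        return NOT_DEFINED
    return (theta_pi - theta_l) / float(np.sqrt(var))


# ---------------------------------------------------------------------------
# haplotype spectra
# ---------------------------------------------------------------------------

def haplotype_spectrum(
    gm: GenotypeMatrix, chrom: str, start: int, end: int
) -> list[tuple[str, dict[str, int]]]:
    """Distinct complete haplotypes in a region with per-panel counts.

    Samples with any missing call in the region are excluded.  Sorted by
    total count descending, ties by haplotype string.
    """
    idx = gm.region_index(chrom, start, end)
    if idx.size == 0:
        raise ValueError(f"empty region {chrom}:{start}-{end}")
    block = gm.calls[idx]
    complete = ~(block == MISSING).any(axis=0)
    spectra: dict[str, dict[str, int]] = {}
    for s in np.flatnonzero(complete):
        hap = "".join(str(int(x)) for x in block[:, s])
        per = spectra.setdefault(hap, {})
        label = gm.panel[s]
        per[label] = per.get(label, 0) + 1
    order = sorted(spectra.items(), key=lambda kv: (-sum(kv[1].values()), kv[0]))
    return order
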