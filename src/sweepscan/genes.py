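"""Candidate-gene mapping, gene-wise statistics, set tests and enrichment.

Candidate regions map to genes by gene-body overlap.  Gene-wise
statistics (pi, Tajima's D, FST, Fay & Wu's normalized H) use the longest
protein-coding transcript plus 5 kb upstream (strand-aware) and require
at least 5 SNPs.  Candidate versus remaining gene sets are compared with
two-sided Wilcoxon rank-sum tests; GO-term enrichment uses the
hypergeometric upper tail with Benjamini-Yekutieli FDR control, which is
valid under the arbitrary dependence among overlapping gene sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._core import NOT_DEFINED, logger
from .io import AncestralAlleles, GeneAnnotation, GenotypeMatrix
from .sfs import SFS, alt_counts, fold_sfs, fst_per_site, pi_per_site, tajimas_d, fay_wu_h_normalized

__all__ = [
    "regions_to_genes",
    "gene_region",
    "genewise_stats",
    "partition_fst",
    "wilcoxon_rank_sum",
    "hypergeom_enrichment",
    "by_adjust",
    "estimate_segment_length",
]


# ---------------------------------------------------------------------------
# region -> gene mapping
# ---------------------------------------------------------------------------

def regions_to_genes(regions: pd.DataFrame, annotation: GeneAnnotation) -> dict[str, set[str]]:
    """Candidate gene ids per pool: gene body overlaps a region by >= 1 bp."""
    out: dict[str, set[str]] = {}
    g = annotation.genes
    for pool, sub in regions.groupby("pool"):
        hits: set[str] = set()
        for _, r in sub.iterrows():
            sel = (g["chrom"] == r["chrom"]) & (g["start"] <= r["end"]) & (g["end"] >= r["start"])
            hits.update(g.index[sel])
        out[pool] = hits
    for pool, hits in out.items():
        logger.info("regions_to_genes: %d candidate genes for pool %s", len(hits), pool)
    return out


def gene_region(row: pd.Series, upstream_bp: int = 5000) -> tuple[int, int]:
    """Longest-transcript span extended ``upstream_bp`` from the 5' end.

    For a plus-strand gene the upstream extension is on the lower
    coordinate side; for minus strand, on the higher side.  Truncated at
    position 1.
    """
    s, e = int(row["tx_start"]), int(row["tx_end"])
    if row["strand"] == "-":
        return s, e + upstream_bp
    return max(1, s - upstream_bp), e


def _region_stats(
    gm: GenotypeMatrix,
    idx: np.ndarray,
    panels: tuple[str, str],
    pol: np.ndarray | None,
    min_snps: int,
) -> dict[str, float]:
    a, b = panels
    out = {f"pi_{a}": NOT_DEFINED, f"pi_{b}": NOT_DEFINED,
           f"td_{a}": NOT_DEFINED, f"td_{b}": NOT_DEFINED,
           "fst": NOT_DEFINED, f"h_{a}": NOT_DEFINED, f"h_{b}": NOT_DEFINED,
           "n_snps": int(idx.size)}
    if idx.size < min_snps:
        return out
    calls = gm.calls[idx]
    mask = {p: gm.panel_mask(p) for p in panels}
    for p in panels:
        sub = calls[:, mask[p]]
        pi = pi_per_site(sub)
        out[f"pi_{p}"] = float(np.nanmean(pi)) if np.any(~np.isnan(pi)) else NOT_DEFINED
        out[f"td_{p}"] = tajimas_d(sub)
    fst = fst_per_site(calls, mask[a], mask[b])
    out["fst"] = float(np.nanmean(fst)) if np.any(~np.isnan(fst)) else NOT_DEFINED
    if pol is not None:
        for p in panels:
            out[f"h_{p}"] = _region_h(calls[:, mask[p]], pol[idx])
    return out


def _region_h(calls: np.ndarray, pol: np.ndarray) -> float:
    """Fay & Wu's normalized H over a region from polarized counts."""
    k, n = alt_counts(calls)
    seg = (k > 0) & (k < n) & (n >= 2) & (pol >= 0)
    if seg.sum() < 2:
        return NOT_DEFINED
    n_eff = int(np.bincount(n[seg]).argmax())
    counts = np.zeros(n_eff + 1)
    from .sfs import project_count

    for i in np.flatnonzero(seg):
        d = int(k[i]) if pol[i] == 1 else int(n[i] - k[i])
        if n[i] == n_eff:
            counts[d] += 1.0
        elif n[i] > n_eff:
            counts += project_count(d, int(n[i]), n_eff)
    counts[0] = counts[n_eff] = 0.0
    sfs = SFS(n=n_eff, counts=counts, polarized=True, folded=False)
    return fay_wu_h_normalized(sfs)


def genewise_stats(
    gm: GenotypeMatrix,
    annotation: GeneAnnotation,
    ancestral: AncestralAlleles | None = None,
    upstream_bp: int = 5000,
    min_snps: int = 5,
) -> pd.DataFrame:
    """Per-gene pi, Tajima's D, FST and normalized H on the gene region.

    The region is the longest transcript plus ``upstream_bp`` upstream of
    the 5' end; all statistics are NOT_DEFINED below ``min_snps`` SNPs.
    """
    a, b = gm.panels
    pol = ancestral.polarize(gm) if ancestral is not None else None
    rows = []
    for gid, row in annotation.genes.iterrows():
        s, e = gene_region(row, upstream_bp)
        idx = gm.region_index(row["chrom"], s, e)
        st = _region_stats(gm, idx, (a, b), pol, min_snps)
        st.update(gene=gid, chrom=row["chrom"], region_start=s, region_end=e)
        rows.append(st)
    cols = ["gene", "chrom", "region_start", "region_end", "n_snps",
            f"pi_{a}", f"pi_{b}", f"td_{a}", f"td_{b}", "fst", f"h_{a}", f"h_{b}"]
    return pd.DataFrame(rows, columns=cols).set_index("gene")


def partition_fst(
    gm: GenotypeMatrix,
    annotation: GeneAnnotation,
    min_snps: int = 5,
) -> pd.DataFrame:
    """Mean per-site FST for exonic / genic / 500 bp / 5 kb upstream regions.

    "Genic" is the longest-transcript span; each partition requires at
    least ``min_snps`` SNPs, otherwise NOT_DEFINED.
    """
    a, b = gm.panels
    mask_a, mask_b = gm.panel_mask(a), gm.panel_mask(b)
    fst_site = fst_per_site(gm.calls, mask_a, mask_b)

    def mean_fst(idx: np.ndarray) -> float:
        if idx.size < min_snps:
            return NOT_DEFINED
        vals = fst_site[idx]
        return float(np.nanmean(vals)) if np.any(~np.isnan(vals)) else NOT_DEFINED

    rows = []
    for gid, row in annotation.genes.iterrows():
        chrom = row["chrom"]
        ts, te = int(row["tx_start"]), int(row["tx_end"])
        genic = gm.region_index(chrom, ts, te)
        exonic = np.concatenate(
            [gm.region_index(chrom, s, e) for s, e in annotation.exons.get(gid, [])]
        ) if annotation.exons.get(gid) else np.empty(0, dtype=np.int64)
        if row["strand"] == "-":
            up5k = gm.region_index(chrom, te + 1, te + 5000)
            up500 = gm.region_index(chrom, te + 1, te + 500)
        else:
            up5k = gm.region_index(chrom, max(1, ts - 5000), ts - 1)
            up500 = gm.region_index(chrom, max(1, ts - 500), ts - 1)
        rows.append(
            dict(gene=gid,
                 fst_exonic=mean_fst(np.unique(exonic)),
                 fst_genic=mean_fst(genic),
                 fst_up500=mean_fst(up500),
                 fst_up5k=mean_fst(up5k))
        )
    return pd.DataFrame(rows).set_index("gene")


# ---------------------------------------------------------------------------
# rank-sum tests and enrichment
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact enumeration when min(n_a, n_b) <= 10 and there are no ties,
    otherwise the normal approximation with tie and continuity
    correction.  Returns (U statistic, two-sided p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 defined values per group")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(len(a) * len(b) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 10 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def by_adjust(pvals) -> np.ndarray:
    """Benjamini-Yekutieli adjusted p-values (arbitrary dependence)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_by")[1]


def hypergeom_enrichment(
    candidates: set[str],
    term_map: dict[str, set[str]],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Term over-representation among candidates vs the annotated universe.

    Universe N = genes with >= 1 term; for each term, K = annotated genes
    with the term, n = candidates in the universe, k = candidates with
    the term; p = P(X >= k) hypergeometric upper tail; BY-adjusted p
    thresholded at ``fdr``.
    """
    universe = set(term_map)
    cand = candidates & universe
    dropped = len(candidates) - len(cand)
    if dropped:
        logger.info("hypergeom_enrichment: %d candidates without annotation dropped", dropped)
    N, n = len(universe), len(cand)
    terms: dict[str, set[str]] = {}
    for gene, ts in term_map.items():
        for t in ts:
            terms.setdefault(t, set()).add(gene)
    rows = []
    for term, members in sorted(terms.items()):
        K = len(members)
        k = len(members & cand)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append(dict(term=term, k=k, K=K, n=n, N=N, p=p))
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if len(df):
        df["p_adj"] = by_adjust(df["p"].to_numpy())
        df["significant"] = df["p_adj"] <= fdr
        df = df.sort_values("p").reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# introgression segment length
# ---------------------------------------------------------------------------

def estimate_segment_length(
    donor_marker_positions, left_flank_pos: float, right_flank_pos: float
) -> float:
    """Donor-segment length: marker span plus half of each flanking gap."""
    d = np.sort(np.asarray(donor_marker_positions, dtype=float))
    if d.size < 1:
        raise ValueError("need at least one donor marker")
    first, last = d[0], d[-1]
    if not (left_flank_pos < first and right_flank_pos > last):
        raise ValueError("flanking markers must lie outside the donor span")
    return float((last - first) + (first - left_flank_pos) / 2.0 + (right_flank_pos - last) / 2.0)
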