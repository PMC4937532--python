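"""Sliding windows, empirical thresholds and candidate-region merging.

Windows are index-based: 40 SNPs sliding by 10 % (4 SNPs), the trailing
partial window dropped.  Per-SNP pi and FST are averaged over the
window's defined sites, Tajima's D is computed per window per panel, and
each window inherits the CLR of the physical grid cell containing its
midpoint.  A window is a candidate for a pool when it sits in the low
tail of pi and D for that pool and the high tail of FST and that pool's
CLR; adjacent passing windows merge into candidate regions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._core import NOT_DEFINED, logger
from .io import GenotypeMatrix, RunConfig
from .sfs import alt_counts, fst_per_site, pi_per_site, tajima_constants

__all__ = [
    "make_snp_windows",
    "tajimas_d_windows",
    "window_stats",
    "quantile_thresholds",
    "pool_thresholds",
    "flag_and_merge",
    "region_summary",
]


def make_snp_windows(n_sites: int, size: int = 40, step_fraction: float = 0.10) -> np.ndarray:
    """Start indices of index-based sliding windows.

    step = max(1, round(step_fraction * size)); the last partial window is
    dropped.  Returns an empty array (with a warning) when n_sites < size.
    """
    if n_sites < size:
        logger.warning("make_snp_windows: %d sites < window size %d", n_sites, size)
        return np.empty(0, dtype=np.int64)
    step = max(1, int(round(step_fraction * size)))
    count = (n_sites - size) // step + 1
    return np.arange(count, dtype=np.int64) * step


def _window_sums(values: np.ndarray, starts: np.ndarray, size: int):
    """(sum over defined, count defined) per window via cumulative sums."""
    defined = ~np.isnan(values)
    v = np.where(defined, values, 0.0)
    cs = np.concatenate([[0.0], np.cumsum(v)])
    cn = np.concatenate([[0], np.cumsum(defined)])
    return cs[starts + size] - cs[starts], cn[starts + size] - cn[starts]


def _window_mean(values: np.ndarray, starts: np.ndarray, size: int) -> np.ndarray:
    """Window mean over defined sites; NOT_DEFINED when > 50 % undefined."""
    s, c = _window_sums(values, starts, size)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s / c
    return np.where(c >= size / 2.0, mean, NOT_DEFINED)


def tajimas_d_windows(calls: np.ndarray, starts: np.ndarray, size: int) -> np.ndarray:
    """Vectorized per-window Tajima's D for one panel.

    Same definition as :func:`sweepscan.sfs.tajimas_d`: effective n is the
    rounded mean non-missing count over the window's segregating sites.
    """
    k, n = alt_counts(calls)
    seg = (k > 0) & (k < n) & (n >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where(seg, 2.0 * k * (n - k) / (n * (n - 1.0)), 0.0)
    cs_S = np.concatenate([[0], np.cumsum(seg)])
    cs_pi = np.concatenate([[0.0], np.cumsum(pi)])
    cs_n = np.concatenate([[0.0], np.cumsum(np.where(seg, n, 0))])
    S = (cs_S[starts + size] - cs_S[starts]).astype(float)
    pi_sum = cs_pi[starts + size] - cs_pi[starts]
    n_sum = cs_n[starts + size] - cs_n[starts]

    out = np.full(len(starts), NOT_DEFINED)
    has = S > 0
    if not has.any():
        return out
    n_eff = np.zeros(len(starts), dtype=np.int64)
    n_eff[has] = np.round(n_sum[has] / S[has]).astype(np.int64)
    n_max = int(n_eff.max())
    h1 = np.concatenate([[0.0], np.cumsum(1.0 / np.arange(1, max(n_max, 2)))])
    e1 = np.zeros(n_max + 1)
    e2 = np.zeros(n_max + 1)
    for nn in range(2, n_max + 1):
        e1[nn], e2[nn] = tajima_constants(nn)
    ok = has & (n_eff >= 2)
    a1 = h1[np.clip(n_eff - 1, 0, None)]
    with np.errstate(divide="ignore", invalid="ignore"):
        num = pi_sum - S / a1
        var = e1[np.clip(n_eff, 0, n_max)] * S + e2[np.clip(n_eff, 0, n_max)] * S * (S - 1)
        d = num / np.sqrt(var)
    zero_var = ok & (var <= 0)
    out[ok] = d[ok]
    out[zero_var & (np.abs(num) < 1e-12)] = 0.0
    out[zero_var & (np.abs(num) >= 1e-12)] = NOT_DEFINED
    return out


def window_stats(
    gm: GenotypeMatrix,
    clr: dict[str, pd.DataFrame],
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Per-window statistics table for both panels.

    ``clr`` maps each panel label to the output of
    :func:`sweepscan.clr.clr_scan`.  Columns: chrom, first/last global SNP
    index, pos_first/pos_last, plus pi_<panel>, td_<panel>, clr_<panel>
    and the shared fst.
    """
    config = config or RunConfig()
    size = config.window_size_snps
    a, b = gm.panels
    mask = {p: gm.panel_mask(p) for p in (a, b)}
    pi_site = {p: pi_per_site(gm.calls[:, mask[p]]) for p in (a, b)}
    fst_site = fst_per_site(gm.calls, mask[a], mask[b])

    cell_clr: dict[str, dict[tuple[str, int], float]] = {}
    for p, table in clr.items():
        d: dict[tuple[str, int], float] = {}
        for _, row in table.iterrows():
            d[(row["chrom"], int(row["grid_pos"] // config.clr_grid_bp))] = row["clr"]
        cell_clr[p] = d

    frames = []
    for chrom in gm.chromosomes():
        sl = gm.chrom_slice(chrom)
        starts = make_snp_windows(sl.stop - sl.start, size, config.window_step_fraction)
        if starts.size == 0:
            continue
        pos = gm.pos[sl]
        mid = (pos[starts] + pos[starts + size - 1]) / 2.0
        cells = (mid // config.clr_grid_bp).astype(int)
        df = pd.DataFrame(
            {
                "chrom": chrom,
                "first": starts + sl.start,
                "last": starts + sl.start + size - 1,
                "pos_first": pos[starts],
                "pos_last": pos[starts + size - 1],
                "n_snps": size,
            }
        )
        for p in (a, b):
            df[f"pi_{p}"] = _window_mean(pi_site[p][sl], starts, size)
            df[f"td_{p}"] = tajimas_d_windows(gm.calls[sl][:, mask[p]], starts, size)
            lut = cell_clr.get(p, {})
            df[f"clr_{p}"] = [lut.get((chrom, c), NOT_DEFINED) for c in cells]
        df["fst"] = _window_mean(fst_site[sl], starts, size)
        frames.append(df)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def quantile_thresholds(values: np.ndarray, q: float) -> float:
    """Linear-interpolation (type-7) quantile over defined values."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 10:
        raise ValueError(f"need >= 10 defined values for a quantile, got {len(v)}")
    return float(np.quantile(v, q))


def pool_thresholds(
    ws: pd.DataFrame, pool: str, low_q: float = 0.10, high_q: float = 0.90
) -> dict[str, float]:
    """Genome-wide thresholds for one pool's four-statistic pass rule."""
    return {
        "pi": quantile_thresholds(ws[f"pi_{pool}"], low_q),
        "td": quantile_thresholds(ws[f"td_{pool}"], low_q),
        "clr": quantile_thresholds(ws[f"clr_{pool}"], high_q),
        "fst": quantile_thresholds(ws["fst"], high_q),
    }


def flag_and_merge(
    ws: pd.DataFrame, thresholds: dict[str, float], pool: str
) -> pd.DataFrame:
    """Merge adjacent windows passing all four thresholds into regions.

    Pass rule: pi_pool <= q10, TD_pool <= q10, CLR_pool >= q90,
    FST >= q90 (undefined values fail).  Windows whose SNP-index ranges
    overlap or abut merge; the region spans min pos_first .. max pos_last.
    """
    passing = (
        (ws[f"pi_{pool}"] <= thresholds["pi"])
        & (ws[f"td_{pool}"] <= thresholds["td"])
        & (ws[f"clr_{pool}"] >= thresholds["clr"])
        & (ws["fst"] >= thresholds["fst"])
    )
    sub = ws[passing.fillna(False)].sort_values(["chrom", "first"])
    regions = []
    cur = None
    for _, w in sub.iterrows():
        if (
            cur is not None
            and w["chrom"] == cur["chrom"]
            and w["first"] <= cur["last_idx"] + 1
        ):
            cur["last_idx"] = max(cur["last_idx"], w["last"])
            cur["end"] = max(cur["end"], w["pos_last"])
            cur["n_windows"] += 1
        else:
            if cur is not None:
                regions.append(cur)
            cur = dict(
                chrom=w["chrom"], start=int(w["pos_first"]), end=int(w["pos_last"]),
                pool=pool, first_idx=int(w["first"]), last_idx=int(w["last"]),
                n_windows=1,
            )
    if cur is not None:
        regions.append(cur)
    return pd.DataFrame(
        regions,
        columns=["chrom", "start", "end", "pool", "first_idx", "last_idx", "n_windows"],
    )


def region_summary(regions: pd.DataFrame, genome_bp: int) -> dict[str, float]:
    """Count, mean length (kb) and genome fraction covered by regions."""
    if len(regions) == 0:
        return {"n_regions": 0, "mean_length_kb": 0.0, "genome_fraction": 0.0}
    lengths = regions["end"] - regions["start"] + 1
    return {
        "n_regions": int(len(regions)),
        "mean_length_kb": float(lengths.mean() / 1e3),
        "genome_fraction": float(lengths.sum() / genome_bp),
    }
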