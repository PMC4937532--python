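"""Four-gamete minimum-recombination screen.

The four-gamete test on a pair of sites detects at least one historical
recombination event when all four two-locus gametes (00, 01, 10, 11) are
observed.  Adjacent-SNP tests are binned (1000 tests per bin) and
expressed as events per Mb; bins in the per-chromosome low tail mark
low-recombination regions, where sweep-like signals are harder to tell
from background selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._core import MISSING, NOT_DEFINED, logger
from .io import GenotypeMatrix
from .windows import quantile_thresholds

__all__ = [
    "four_gamete_pair",
    "fgt_scan",
    "low_recombination_regions",
    "candidate_low_rec_overlap",
]

#: a trailing partial bin is kept when it has at least this many tests
MIN_PARTIAL_BIN = 100


def four_gamete_pair(calls_i: np.ndarray, calls_j: np.ndarray) -> float:
    """1 if all four gametes occur, 0 if not, NOT_DEFINED when untestable.

    Uses pairwise-complete samples; the test is undefined with fewer than
    4 complete pairs or when either site is monomorphic in that subset.
    """
    ci = np.asarray(calls_i, dtype=np.int8)
    cj = np.asarray(calls_j, dtype=np.int8)
    ok = (ci != MISSING) & (cj != MISSING)
    if ok.sum() < 4:
        return NOT_DEFINED
    ci, cj = ci[ok], cj[ok]
    if len(set(ci.tolist())) < 2 or len(set(cj.tolist())) < 2:
        return NOT_DEFINED
    gametes = set(zip(ci.tolist(), cj.tolist()))
    return 1.0 if len(gametes) == 4 else 0.0


def _adjacent_events(calls: np.ndarray) -> np.ndarray:
    """Vectorized four-gamete result per adjacent site pair (NaN undefined)."""
    a, b = calls[:-1], calls[1:]
    ok = (a != MISSING) & (b != MISSING)
    n_ok = ok.sum(axis=1)
    g = np.zeros((len(a), 4), dtype=bool)
    for idx, (x, y) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)]):
        g[:, idx] = ((a == x) & (b == y) & ok).any(axis=1)
    poly_a = ((a == 0) & ok).any(axis=1) & ((a == 1) & ok).any(axis=1)
    poly_b = ((b == 0) & ok).any(axis=1) & ((b == 1) & ok).any(axis=1)
    defined = (n_ok >= 4) & poly_a & poly_b
    events = np.where(g.all(axis=1), 1.0, 0.0)
    events[~defined] = NOT_DEFINED
    return events


def fgt_scan(gm: GenotypeMatrix, panel: str, bin_sites: int = 1000) -> pd.DataFrame:
    """Bin adjacent-pair four-gamete tests and report events per Mb.

    Consecutive blocks of ``bin_sites`` adjacent-pair tests form bins; a
    trailing partial bin is kept when it holds >= 100 tests.  The rate is
    detected events divided by the bin's physical span in Mb.
    """
    calls = gm.panel_calls(panel)
    rows = []
    for chrom in gm.chromosomes():
        sl = gm.chrom_slice(chrom)
        n_pairs = sl.stop - sl.start - 1
        if n_pairs < 1:
            continue
        events = _adjacent_events(calls[sl])
        pos = gm.pos[sl]
        start = 0
        while start < n_pairs:
            stop = min(start + bin_sites, n_pairs)
            if stop - start < bin_sites and stop - start < MIN_PARTIAL_BIN:
                break
            ev = events[start:stop]
            n_events = float(np.nansum(ev))
            span_mb = (pos[stop] - pos[start]) / 1e6
            rows.append(
                dict(
                    chrom=chrom,
                    first=start + sl.start,
                    last=stop + sl.start,  # index of last site of the final pair
                    pos_first=int(pos[start]),
                    pos_last=int(pos[stop]),
                    n_tests=stop - start,
                    n_defined=int(np.sum(~np.isnan(ev))),
                    events=n_events,
                    rate=n_events / span_mb if span_mb > 0 else NOT_DEFINED,
                )
            )
            start = stop
    return pd.DataFrame(
        rows,
        columns=["chrom", "first", "last", "pos_first", "pos_last",
                 "n_tests", "n_defined", "events", "rate"],
    )


def low_recombination_regions(bins: pd.DataFrame, q: float = 0.10) -> pd.DataFrame:
    """Flag bins with rate <= the per-chromosome ``q`` quantile."""
    bins = bins.copy()
    bins["low_rec"] = False
    for chrom, sub in bins.groupby("chrom"):
        thr = quantile_thresholds(sub["rate"].to_numpy(), q)
        bins.loc[sub.index, "low_rec"] = sub["rate"] <= thr
    return bins


def candidate_low_rec_overlap(genes: pd.DataFrame, bins: pd.DataFrame) -> float:
    """Fraction of candidate genes NOT overlapping a low-recombination bin.

    ``genes`` needs columns chrom, start, end; overlap is any shared bp
    with a flagged bin's physical span.
    """
    flagged = bins[bins["low_rec"]]
    if len(genes) == 0:
        logger.warning("candidate_low_rec_overlap: no candidate genes")
        return NOT_DEFINED
    in_low = np.zeros(len(genes), dtype=bool)
    for chrom, sub in flagged.groupby("chrom"):
        sel = genes["chrom"] == chrom
        if not sel.any():
            continue
        gs = genes.loc[sel, "start"].to_numpy()
        ge = genes.loc[sel, "end"].to_numpy()
        hit = np.zeros(sel.sum(), dtype=bool)
        for _, b in sub.iterrows():
            hit |= (gs <= b["pos_last"]) & (ge >= b["pos_first"])
        in_low[np.flatnonzero(sel.to_numpy())] |= hit
    return float(1.0 - in_low.mean())
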