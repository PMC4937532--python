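"""Shared sentinels and small numeric helpers."""

from __future__ import annotations

import logging

import numpy as np

#: Code for a missing haploid call in a genotype matrix.
MISSING: int = -1

#: Sentinel for a statistic that is undefined on its input (e.g. FST at a
#: site monomorphic across both panels).  NaN so that numpy masking works.
NOT_DEFINED: float = float("nan")

logger = logging.getLogger("sweepscan")


def is_defined(x) -> np.ndarray:
    """Boolean mask of entries that are not the NOT_DEFINED sentinel."""
    return ~np.isnan(np.asarray(x, dtype=float))


def harmonic(n: int) -> float:
    """a1 = sum_{i=1}^{n-1} 1/i (Watterson's denominator)."""
    if n < 2:
        raise ValueError("harmonic number requires n >= 2")
    return float(np.sum(1.0 / np.arange(1, n)))


def harmonic2(n: int) -> float:
    """b_n = sum_{i=1}^{n-1} 1/i^2."""
    if n < 2:
        raise ValueError("requires n >= 2")
    return float(np.sum(1.0 / np.arange(1, n) ** 2))
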