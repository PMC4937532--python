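"""Marker and sequence-variant filters, and LD pruning.

Array-marker filtering removes sites with >= 10 % missing calls and sites
monomorphic across the combined panels.  Sequence-variant filtering
applies mapping-quality, genotype-quality, coverage, spacing and
missingness rules appropriate for whole-genome resequencing of inbred
lines.  LD pruning walks sites left to right dropping sites in strong LD
with the nearest retained site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._core import MISSING, NOT_DEFINED, logger
from .io import GenotypeMatrix, _panels_for, _load_panel_map

__all__ = [
    "FilterReport",
    "filter_array_sites",
    "filter_sequence_variants",
    "ld_r2",
    "ld_prune",
]

#: coverage bounds (min DP, max DP) per sequencing depth class
COVERAGE_BOUNDS = {"medium": (3, 60), "deep": (10, 300)}


@dataclass
class FilterReport:
    """Per-rule removal counts; removed + retained = input sites."""

    input_sites: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    retained: int = 0
    masked_calls: dict[str, int] = field(default_factory=dict)

    def add(self, rule: str, n: int) -> None:
        self.removed[rule] = self.removed.get(rule, 0) + int(n)

    @property
    def total_removed(self) -> int:
        return sum(self.removed.values())

    def check(self) -> "FilterReport":
        if self.total_removed + self.retained != self.input_sites:
            raise AssertionError("filter report does not reconcile")
        if any(v < 0 for v in self.removed.values()):
            raise AssertionError("negative removal count")
        return self

    def to_frame(self):
        import pandas as pd

        rows = [("input", self.input_sites)]
        rows += [(f"removed_{k}", v) for k, v in sorted(self.removed.items())]
        rows += [(f"masked_{k}", v) for k, v in sorted(self.masked_calls.items())]
        rows.append(("retained", self.retained))
        return pd.DataFrame(rows, columns=["rule", "count"])


# ---------------------------------------------------------------------------
# array markers
# ---------------------------------------------------------------------------

def filter_array_sites(
    gm: GenotypeMatrix, max_missing: float = 0.10
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop sites with missing fraction >= ``max_missing`` or monomorphic.

    Monomorphism is judged on the combined panels after masking: a site
    with at most one allele observed among non-missing calls is removed.
    """
    report = FilterReport(input_sites=gm.n_sites)
    miss_frac = (gm.calls == MISSING).mean(axis=1)
    high_missing = miss_frac >= max_missing
    n_alt = (gm.calls == 1).sum(axis=1)
    n_ref = (gm.calls == 0).sum(axis=1)
    mono = (n_alt == 0) | (n_ref == 0)
    keep = ~high_missing & ~mono
    report.add("missingness", high_missing.sum())
    report.add("monomorphic", (mono & ~high_missing).sum())
    report.retained = int(keep.sum())
    report.check()
    if report.retained == 0:
        raise ValueError("empty matrix after filtering")
    logger.info(
        "filter_array_sites: %d -> %d sites (%s)",
        gm.n_sites, report.retained, dict(report.removed),
    )
    return gm.take_sites(np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# whole-genome sequence variants
# ---------------------------------------------------------------------------

def filter_sequence_variants(
    vcf_path: str,
    panel_map,
    line_class="medium",
    min_mq: float = 30.0,
    min_gq: float = 5.0,
    max_missing: float = 0.50,
    min_spacing_bp: int = 3,
    major_af_filter: bool = False,
    major_af: float = 0.90,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Read and filter sequence variants from a VCF.

    Keeps bi-allelic SNPs with site MQ >= ``min_mq``; masks genotype calls
    failing GQ > ``min_gq`` (strict) or the per-line coverage bounds
    (medium: 3 <= DP <= 60, deep: 10 <= DP <= 300); removes both members
    of retained SNP pairs closer than ``min_spacing_bp``; removes sites
    with more than ``max_missing`` missing calls.  ``line_class`` is a
    single class or a per-sample mapping.  The optional within-set major
    allele frequency filter (off by default) removes sites whose major
    allele among confident calls is below ``major_af`` -- it suppresses
    sequencing artifacts but also deletes strongly differentiated sites,
    so a two-panel scan should leave it off.
    """
    from cyvcf2 import VCF

    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    mapping = _load_panel_map(panel_map)
    if isinstance(line_class, str):
        classes = {s: line_class for s in samples}
    else:
        classes = dict(line_class)
    bounds = np.array(
        [COVERAGE_BOUNDS[classes.get(s, "medium")] for s in samples], dtype=float
    )

    report = FilterReport(input_sites=0)
    chrom, pos, ref, alt, rows = [], [], [], [], []
    n_gq_mask = n_dp_mask = n_het = 0
    for v in vcf:
        report.input_sites += 1
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            report.add("indel_or_multiallelic", 1)
            continue
        mq = v.INFO.get("MQ")
        if mq is None or mq < min_mq:
            report.add("mapping_quality", 1)
            continue
        missing_fields = []
        gq = dp = None
        for name in ("GQ", "DP"):
            try:
                val = v.format(name)
            except KeyError:
                val = None
            if val is None:
                missing_fields.append(name)
            elif name == "GQ":
                gq = val
            else:
                dp = val
        if missing_fields:
            raise ValueError(f"missing FORMAT fields: {missing_fields}")
        gq = np.asarray(gq, dtype=float).reshape(len(samples))
        dp = np.asarray(dp, dtype=float).reshape(len(samples))
        row = np.full(len(samples), MISSING, dtype=np.int8)
        for j, g in enumerate(v.genotypes):
            alleles = [a for a in g[:-1] if a >= 0]
            if not alleles:
                continue
            if len(set(alleles)) > 1:
                n_het += 1
                continue
            row[j] = alleles[0]
        called = row != MISSING
        bad_gq = called & ~(gq > min_gq)
        bad_dp = called & ((dp < bounds[:, 0]) | (dp > bounds[:, 1]))
        n_gq_mask += int(bad_gq.sum())
        n_dp_mask += int((bad_dp & ~bad_gq).sum())
        row[bad_gq | bad_dp] = MISSING
        if major_af_filter:
            k = (row == 1).sum()
            n = (row != MISSING).sum()
            if n > 0 and max(k, n - k) / n < major_af:
                report.add("major_allele_frequency", 1)
                continue
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        rows.append(row)

    chrom = np.array(chrom, dtype=object)
    pos = np.array(pos, dtype=np.int64)
    calls = np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)

    # spacing: both members of a too-close adjacent pair go
    close = np.zeros(len(pos), dtype=bool)
    if len(pos) > 1:
        same = chrom[1:] == chrom[:-1]
        near = (pos[1:] - pos[:-1]) < min_spacing_bp
        hit = same & near
        close[:-1] |= hit
        close[1:] |= hit
    report.add("spacing", close.sum())

    miss = (calls == MISSING).mean(axis=1) > max_missing if len(pos) else np.array([], bool)
    high_missing = miss & ~close
    report.add("missingness", high_missing.sum())

    keep = ~close & ~high_missing
    report.retained = int(keep.sum())
    report.masked_calls = {"genotype_quality": n_gq_mask, "coverage": n_dp_mask,
                           "heterozygous": n_het}
    report.check()
    gm = GenotypeMatrix(
        chrom=chrom[keep],
        pos=pos[keep],
        ref=np.array(ref, dtype=object)[keep],
        alt=np.array(alt, dtype=object)[keep],
        calls=calls[keep],
        samples=samples,
        panel=_panels_for(samples, mapping),
    )
    logger.info("filter_sequence_variants: %d -> %d sites", report.input_sites, report.retained)
    return gm, report


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def ld_r2(calls_i: np.ndarray, calls_j: np.ndarray) -> float:
    """Squared haplotype correlation r^2 on pairwise-complete haploid calls.

    r^2 = (p_AB - p_A p_B)^2 / (p_A (1-p_A) p_B (1-p_B)).  Returns
    NOT_DEFINED when either site is monomorphic in the complete subset.
    """
    ci = np.asarray(calls_i, dtype=np.int8)
    cj = np.asarray(calls_j, dtype=np.int8)
    ok = (ci != MISSING) & (cj != MISSING)
    ci, cj = ci[ok].astype(float), cj[ok].astype(float)
    if len(ci) < 2:
        return NOT_DEFINED
    pa, pb = ci.mean(), cj.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return NOT_DEFINED
    pab = (ci * cj).mean()
    return float((pab - pa * pb) ** 2 / (pa * (1 - pa) * pb * (1 - pb)))


def ld_prune(
    gm: GenotypeMatrix, r2_threshold: float = 0.8, lookback: int = 100
) -> np.ndarray:
    """Indices of sites kept after LD pruning.

    Walks sites left to right within each chromosome; a site is dropped
    when its r^2 with the nearest previously retained site within a
    ``lookback``-SNP window exceeds the threshold.
    """
    kept: list[int] = []
    for chrom in gm.chromosomes():
        sl = gm.chrom_slice(chrom)
        last_kept: int | None = None
        for i in range(sl.start, sl.stop):
            if last_kept is not None and i - last_kept <= lookback:
                r2 = ld_r2(gm.calls[i], gm.calls[last_kept])
                if not np.isnan(r2) and r2 > r2_threshold:
                    continue
            kept.append(i)
            last_kept = i
    return np.array(kept, dtype=np.int64)
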