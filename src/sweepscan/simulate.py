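"""Synthetic two-panel genotype data with planted pool-specific sweeps.

The generator states a small, analytically controllable world rather than
a full coalescent: per-SNP ancestral frequencies follow a truncated
Beta(0.5, 0.5); the two panels' frequencies diverge around them under the
Balding-Nichols model with F = 0.14 (the genome-wide differentiation
level of temperate Dent/Flint elite material); linkage comes from Markov
copying of sample haplotypes out of a finite founder pool with
geometric block lengths; a centromere-like stretch with longer copying
blocks depresses detectable recombination.  Sweeps are planted with the
same star-like escape model the CLR scan assumes: per sample, an
exponential escape distance on each side of the sweep center, inside
which the sample carries the sweeper haplotype.  Everything is
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from ._core import MISSING, logger
from .io import GeneAnnotation, GenotypeMatrix, AncestralAlleles

__all__ = [
    "SimParams",
    "simulate_neutral_panels",
    "inject_sweep",
    "default_sweep_centers",
    "simulate_annotation",
    "simulate_outgroup",
    "make_truth_table",
    "simulate_dataset",
    "write_vcf",
    "write_gff3",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimParams:
    """Stated world of the generator (defaults mirror the study panels)."""

    n_samples: tuple[int, int] = (70, 66)
    panel_labels: tuple[str, str] = ("DENT", "FLINT")
    n_chrom: int = 2
    chrom_len_bp: int = 25_000_000
    n_snps_per_chrom: int = 50_000
    beta_shape: tuple[float, float] = (0.5, 0.5)
    p_bounds: tuple[float, float] = (0.02, 0.98)  # 1/(2N)-style polymorphism floor
    divergence_f: float = 0.14
    # fraction of sites that arose after the panel split (panel-private
    # derived alleles) and the founder-count ceiling of their frequency
    # law (young alleles have not reached high frequency).  Jointly these
    # balance post-split mutation input against divergence drift so each
    # panel's derived spectrum is neutral in expectation
    # (E[theta_pi] = E[theta_L], i.e. E[H] = 0); see the methods note.
    post_split_fraction: float = 0.5
    private_max_founders: int = 7
    n_founders: int = 30
    copy_block_snps: float = 50.0
    n_sweeps_per_pool: int = 10
    # default sweep intensity: affected span (p_e < 0.99) ~ +-0.46 Mb,
    # core (p_e < 0.5) ~ +-70 kb -- localized sweeps at the physical scale
    # of the candidate regions the scan is built to find
    sweep_alpha: float = 1e-5
    missing_rate: float = 0.02
    polarization_error: float = 0.01
    # centromere-like low-recombination stretch (copying blocks lengthened)
    low_rec_half_width_frac: float = 0.08
    low_rec_block_factor: float = 15.0
    plant_low_rec: bool = True
    # annotation
    n_genes_per_chrom: int = 1000
    gene_mean_bp: int = 4000
    n_go_terms: int = 50
    enriched_term: str = "GO:9999999"
    rng_seed: int = 1

    def __post_init__(self) -> None:
        for r in (self.divergence_f, self.missing_rate, self.polarization_error):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    @property
    def genome_bp(self) -> int:
        return self.n_chrom * self.chrom_len_bp

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]


# ---------------------------------------------------------------------------
# neutral background
# ---------------------------------------------------------------------------

def _positions(rng: np.random.Generator, params: SimParams) -> np.ndarray:
    need = params.n_snps_per_chrom
    draw = rng.integers(1, params.chrom_len_bp + 1, size=int(need * 1.2))
    pos = np.unique(draw)
    while pos.size < need:
        extra = rng.integers(1, params.chrom_len_bp + 1, size=need)
        pos = np.unique(np.concatenate([pos, extra]))
    return pos[np.sort(rng.choice(pos.size, need, replace=False))]


def _truncated_beta(rng, a: float, b: float, lo: float, hi: float, size: int) -> np.ndarray:
    u = rng.uniform(beta_dist.cdf(lo, a, b), beta_dist.cdf(hi, a, b), size)
    return beta_dist.ppf(u, a, b)


def _founder_alleles(rng, p_panel: np.ndarray, n_founders: int) -> np.ndarray:
    """(n_sites, n_founders) 0/1 with exactly round(n_founders * p) carriers.

    Systematic rounding keeps the founder-pool frequency within 1/(2K) of
    the Balding-Nichols draw, so the realized panel differentiation tracks
    the model F instead of picking up founder-sampling noise.
    """
    n_sites = len(p_panel)
    n_alt = np.round(n_founders * p_panel).astype(np.int64)
    r = rng.random((n_sites, n_founders))
    ranks = np.argsort(np.argsort(r, axis=1), axis=1)
    return (ranks < n_alt[:, None]).astype(np.int8)


def _copy_haplotypes(
    rng, founders: np.ndarray, n_samples: int, switch_prob: np.ndarray
) -> np.ndarray:
    """Markov founder-copying haplotypes: (n_sites, n_samples) calls."""
    n_sites, n_founders = founders.shape
    switch = rng.random((n_sites, n_samples)) < switch_prob[:, None]
    switch[0, :] = True
    idx = np.arange(n_sites)[:, None] * switch
    seg_start = np.maximum.accumulate(idx, axis=0)
    draws = rng.integers(0, n_founders, size=(n_sites, n_samples))
    founder_of = draws[seg_start, np.arange(n_samples)[None, :]]
    return founders[np.arange(n_sites)[:, None], founder_of]


def _switch_probs(pos: np.ndarray, params: SimParams) -> np.ndarray:
    """Per-site copying switch probability; reduced in the planted
    low-recombination stretch around the chromosome middle."""
    base = 1.0 / params.copy_block_snps
    probs = np.full(len(pos), base)
    if params.plant_low_rec:
        c = params.chrom_len_bp / 2.0
        hw = params.low_rec_half_width_frac * params.chrom_len_bp
        probs[(pos > c - hw) & (pos < c + hw)] = base / params.low_rec_block_factor
    return probs


def low_rec_truth(params: SimParams) -> pd.DataFrame:
    """Physical span of the planted low-recombination stretch per chromosome."""
    c = params.chrom_len_bp / 2.0
    hw = params.low_rec_half_width_frac * params.chrom_len_bp
    return pd.DataFrame(
        [
            dict(chrom=ch, start=int(c - hw), end=int(c + hw))
            for ch in params.chrom_names()
        ]
    )


def _site_frequencies(rng, params: SimParams, n_sites: int):
    """Panel allele frequencies and derived-state assignment per site.

    Sites are a mixture of shared ancestral polymorphisms and post-split
    panel-private variants.  Shared sites: ancestral-population frequency
    p0 ~ truncated Beta, panel frequencies Balding-Nichols around p0, and
    the alt allele is the derived one with the neutral stationary
    probability 1 - p0 (an allele at frequency x is derived with
    probability 1 - x under the 1/x spectrum).  Private sites: one panel
    carries a derived alt allele at founder frequency c/K, c weighted
    proportional to 1/c up to a ceiling (young alleles are rare); the
    other panel is ancestral-fixed.  The private fraction and ceiling
    balance drift's high-frequency-derived excess so the per-panel
    derived spectrum is neutral in expectation.
    """
    a, b = params.beta_shape
    lo, hi = params.p_bounds
    f = params.divergence_f
    K = params.n_founders

    p_a = np.empty(n_sites)
    p_b = np.empty(n_sites)
    alt_is_derived = np.ones(n_sites, dtype=bool)

    private = rng.random(n_sites) < params.post_split_fraction
    shared = ~private
    n_sh = int(shared.sum())
    p0 = _truncated_beta(rng, a, b, lo, hi, n_sh)
    if f < 1e-9:
        pa_sh = pb_sh = p0
    else:
        pa_sh = rng.beta(p0 * (1 - f) / f, (1 - p0) * (1 - f) / f)
        pb_sh = rng.beta(p0 * (1 - f) / f, (1 - p0) * (1 - f) / f)
    p_a[shared], p_b[shared] = pa_sh, pb_sh
    alt_is_derived[shared] = rng.random(n_sh) < (1.0 - p0)

    n_pr = n_sites - n_sh
    c = np.arange(1, params.private_max_founders + 1)
    freq_w = (1.0 / c) / np.sum(1.0 / c)
    x = c[rng.choice(len(c), size=n_pr, p=freq_w)] / K
    carrier_a = rng.random(n_pr) < 0.5
    p_a[private] = np.where(carrier_a, x, 0.0)
    p_b[private] = np.where(carrier_a, 0.0, x)
    return p_a, p_b, alt_is_derived


def simulate_neutral_panels(
    params: SimParams, rng=None, return_polarity: bool = False
):
    """Two-panel neutral genotypes (no sweeps, no missingness sprinkled).

    Missing calls are added by :func:`simulate_dataset` after sweep
    injection so that planted haplotype tracts stay intact.  With
    ``return_polarity`` also returns the per-site truth of whether the
    alt allele is the derived one.
    """
    rng = np.random.default_rng(params.rng_seed) if rng is None else rng
    chroms, poss, refs, alts, blocks, pols = [], [], [], [], [], []
    for chrom in params.chrom_names():
        pos = _positions(rng, params)
        n_sites = len(pos)
        p_a, p_b, alt_is_derived = _site_frequencies(rng, params, n_sites)
        panel_calls = []
        for p_pool, n_pool in zip((p_a, p_b), params.n_samples):
            founders = _founder_alleles(rng, p_pool, params.n_founders)
            panel_calls.append(
                _copy_haplotypes(rng, founders, n_pool, _switch_probs(pos, params))
            )
        ref_idx = rng.integers(0, 4, n_sites)
        alt_idx = (ref_idx + rng.integers(1, 4, n_sites)) % 4
        chroms.append(np.full(n_sites, chrom, dtype=object))
        poss.append(pos)
        refs.append(_BASES[ref_idx])
        alts.append(_BASES[alt_idx])
        blocks.append(np.concatenate(panel_calls, axis=1))
        pols.append(alt_is_derived)
    samples = [f"{lab}_{i:03d}" for lab, n in zip(params.panel_labels, params.n_samples)
               for i in range(n)]
    panel = np.concatenate(
        [np.full(n, lab, dtype=object) for lab, n in zip(params.panel_labels, params.n_samples)]
    )
    gm = GenotypeMatrix(
        chrom=np.concatenate(chroms),
        pos=np.concatenate(poss),
        ref=np.concatenate(refs).astype(object),
        alt=np.concatenate(alts).astype(object),
        calls=np.concatenate(blocks, axis=0),
        samples=samples,
        panel=panel,
    ).validate()
    if return_polarity:
        return gm, np.concatenate(pols)
    return gm


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

def inject_sweep(
    gm: GenotypeMatrix,
    pool: str,
    chrom: str,
    center: int,
    alpha: float,
    rng,
    in_place: bool = False,
) -> tuple[GenotypeMatrix, dict]:
    """Plant one pool-specific sweep with the star-like escape model.

    One sample of the pool is the sweeper; every pool sample draws an
    exponential escape distance (mean 1/alpha) on each side of the
    center and carries the sweeper's haplotype inside it, so the per-site
    replacement probability is 1 - p_e(alpha, d) and swept material forms
    contiguous tracts.  Returns the matrix and a truth record whose span
    covers p_e < 0.99.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if not in_place:
        gm = GenotypeMatrix(
            chrom=gm.chrom, pos=gm.pos, ref=gm.ref, alt=gm.alt,
            calls=gm.calls.copy(), samples=list(gm.samples), panel=gm.panel,
        )
    members = np.flatnonzero(gm.panel_mask(pool))
    sweeper = int(rng.choice(members))
    sl = gm.chrom_slice(chrom)
    pos = gm.pos[sl]
    sweep_hap = gm.calls[sl, sweeper].copy()
    d_left = rng.exponential(1.0 / alpha, size=len(members))
    d_right = rng.exponential(1.0 / alpha, size=len(members))
    for m, dl, dr in zip(members, d_left, d_right):
        inside = (pos > center - dl) & (pos < center + dr)
        gm.calls[sl.start:sl.stop, m][inside] = sweep_hap[inside]
    half = np.log(100.0) / alpha  # p_e < 0.99
    truth = dict(
        pool=pool, chrom=chrom, center=int(center), alpha=alpha,
        span_start=int(max(1, center - half)), span_end=int(center + half),
        sweeper=gm.samples[sweeper],
    )
    return gm, truth


def default_sweep_centers(params: SimParams, rng) -> list[tuple[str, str, int]]:
    """(pool, chrom, center) for the default sweep layout.

    Sweeps are spread evenly along each chromosome with a small jitter,
    pools alternating, so neighbouring sweep cores do not collide.
    """
    total = 2 * params.n_sweeps_per_pool
    per_chrom = total // params.n_chrom
    out = []
    i_global = 0
    for chrom in params.chrom_names():
        spacing = params.chrom_len_bp / (per_chrom + 1)
        for i in range(per_chrom):
            center = (i + 1) * spacing + rng.uniform(-0.15, 0.15) * spacing
            pool = params.panel_labels[i_global % 2]
            out.append((pool, chrom, int(center)))
            i_global += 1
    n_a = sum(1 for p, _, _ in out if p == params.panel_labels[0])
    if n_a != params.n_sweeps_per_pool:
        raise ValueError("sweep layout does not balance pools")
    return out


def make_truth_table(sweeps: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(
        sweeps,
        columns=["pool", "chrom", "center", "alpha", "span_start", "span_end", "sweeper"],
    )


# ---------------------------------------------------------------------------
# annotation, GO terms, outgroup
# ---------------------------------------------------------------------------

def simulate_annotation(
    params: SimParams, truth: pd.DataFrame, rng
) -> tuple[GeneAnnotation, dict[str, set[str]]]:
    """Random non-overlapping gene models plus a gene -> GO-term map.

    Genes average ``gene_mean_bp`` with 1-6 exons.  To make enrichment
    testable, 20 % of the genes inside a sweep core (p_e < 0.5 around a
    planted center) carry a designated term versus 2 % elsewhere;
    background terms are assigned uniformly.
    """
    rows, exons = [], {}
    gid = 0
    for chrom in params.chrom_names():
        mean_gap = params.chrom_len_bp / params.n_genes_per_chrom - params.gene_mean_bp
        if mean_gap <= 0:
            raise ValueError("gene request exceeds chromosome capacity")
        cursor = 1
        for _ in range(params.n_genes_per_chrom):
            gap = int(rng.exponential(mean_gap)) + 1
            length = max(300, int(rng.normal(params.gene_mean_bp, params.gene_mean_bp / 3)))
            start = cursor + gap
            end = start + length - 1
            if end > params.chrom_len_bp:
                break
            gid += 1
            name = f"gene{gid:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(1, 7))
            bounds = np.sort(rng.choice(np.arange(1, length), size=2 * n_ex - 2, replace=False)) \
                if length > 2 * n_ex else np.array([], dtype=int)
            edges = np.concatenate([[0], bounds, [length]])
            ivs = []
            for k in range(0, len(edges) - 1, 2):
                ivs.append((start + int(edges[k]), start + int(edges[k + 1]) - 1))
            exons[name] = ivs if ivs else [(start, end)]
            rows.append(dict(gene=name, chrom=chrom, start=start, end=end, strand=strand,
                             longest_tx=f"{name}_t1", tx_start=start, tx_end=end))
            cursor = end
    genes = pd.DataFrame(rows).set_index("gene")
    ann = GeneAnnotation(genes=genes, exons=exons).validate()

    mids = (genes["start"] + genes["end"]) / 2.0
    in_core = np.zeros(len(genes), dtype=bool)
    for _, s in truth.iterrows():
        half = np.log(2.0) / s["alpha"]  # p_e < 0.5
        in_core |= (
            (genes["chrom"] == s["chrom"]).to_numpy()
            & (mids > s["center"] - half).to_numpy()
            & (mids < s["center"] + half).to_numpy()
        )
    go_map: dict[str, set[str]] = {}
    terms = [f"GO:{i:07d}" for i in range(1, params.n_go_terms + 1)]
    for i, name in enumerate(genes.index):
        picks = rng.choice(params.n_go_terms, size=int(rng.integers(1, 4)), replace=False)
        go_map[name] = {terms[j] for j in picks}
        p_hit = 0.20 if in_core[i] else 0.02
        if rng.random() < p_hit:
            go_map[name].add(params.enriched_term)
    return ann, go_map


def simulate_outgroup(
    gm: GenotypeMatrix, error_rate: float, rng, alt_is_derived=None
) -> AncestralAlleles:
    """Outgroup-derived ancestral bases with a polarization flip rate.

    ``alt_is_derived`` is the generator's per-site polarity truth
    (default: alt derived everywhere); at ``error_rate`` the reported
    base is flipped to the derived allele, emulating outgroup
    misalignment or lineage sorting."""
    if alt_is_derived is None:
        alt_is_derived = np.ones(gm.n_sites, dtype=bool)
    flip = rng.random(gm.n_sites) < error_rate
    table = {}
    for i in range(gm.n_sites):
        anc, der = (gm.ref[i], gm.alt[i]) if alt_is_derived[i] else (gm.alt[i], gm.ref[i])
        table[(gm.chrom[i], int(gm.pos[i]))] = der if flip[i] else anc
    return AncestralAlleles(table)


# ---------------------------------------------------------------------------
# one-stop dataset
# ---------------------------------------------------------------------------

def simulate_dataset(params: SimParams, with_sweeps: bool = True) -> dict:
    """Full synthetic dataset: genotypes, truth table, annotation, GO map,
    ancestral table.  Missingness is sprinkled after sweep injection."""
    rng = np.random.default_rng(params.rng_seed)
    gm, alt_is_derived = simulate_neutral_panels(params, rng, return_polarity=True)
    sweeps: list[dict] = []
    if with_sweeps and params.n_sweeps_per_pool > 0:
        for pool, chrom, center in default_sweep_centers(params, rng):
            gm, truth = inject_sweep(
                gm, pool, chrom, center, params.sweep_alpha, rng, in_place=True
            )
            sweeps.append(truth)
    if params.missing_rate > 0:
        miss = rng.random(gm.calls.shape) < params.missing_rate
        gm.calls[miss] = MISSING
    truth_table = make_truth_table(sweeps)
    ann, go_map = simulate_annotation(params, truth_table, rng)
    anc = simulate_outgroup(gm, params.polarization_error, rng, alt_is_derived)
    logger.info("simulate_dataset: %d sites, %d samples, %d sweeps",
                gm.n_sites, gm.n_samples, len(sweeps))
    return dict(
        genotypes=gm, truth=truth_table, annotation=ann, go_map=go_map,
        ancestral=anc, low_rec=low_rec_truth(params), params=params,
    )


# ---------------------------------------------------------------------------
# writers for the simulated formats
# ---------------------------------------------------------------------------

def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Plain-text VCF with haploid-coded homozygous diploid GT calls."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in gm.chromosomes():
            sl = gm.chrom_slice(chrom)
            fh.write(f"##contig=<ID={chrom},length={int(gm.pos[sl][-1]) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        code = {0: "0/0", 1: "1/1", MISSING: "./."}
        for i in range(gm.n_sites):
            gts = "\t".join(code[int(c)] for c in gm.calls[i])
            fh.write(f"{gm.chrom[i]}\t{gm.pos[i]}\t.\t{gm.ref[i]}\t{gm.alt[i]}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


def write_gff3(ann: GeneAnnotation, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, row in ann.genes.iterrows():
            c, s, e, st = row["chrom"], row["start"], row["end"], row["strand"]
            tx = row["longest_tx"]
            fh.write(f"{c}\tsim\tgene\t{s}\t{e}\t.\t{st}\t.\tID={gid}\n")
            fh.write(f"{c}\tsim\tmRNA\t{row['tx_start']}\t{row['tx_end']}\t.\t{st}\t.\t"
                     f"ID={tx};Parent={gid}\n")
            for k, (xs, xe) in enumerate(ann.exons.get(gid, []), 1):
                fh.write(f"{c}\tsim\texon\t{xs}\t{xe}\t.\t{st}\t.\t"
                         f"ID={tx}.exon{k};Parent={tx}\n")
                fh.write(f"{c}\tsim\tCDS\t{xs}\t{xe}\t.\t{st}\t0\t"
                         f"ID={tx}.cds{k};Parent={tx}\n")


def write_ancestral_tsv(anc: AncestralAlleles, path: str) -> None:
    rows = sorted(anc._table.items())
    with open(path, "w") as fh:
        for (chrom, pos), base in rows:
            fh.write(f"{chrom}\t{pos}\t{base}\n")


def write_go_tsv(go_map: dict[str, set[str]], path: str) -> None:
    with open(path, "w") as fh:
        for gene in sorted(go_map):
            for term in sorted(go_map[gene]):
                fh.write(f"{gene}\t{term}\n")
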