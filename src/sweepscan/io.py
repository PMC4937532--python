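"""Readers, writers and run configuration.

External formats handled here: VCF (read, via cyvcf2), a simple TSV
site x sample genotype dialect (read/write), GFF3 annotation (read, via
gffutils), TSV ancestral-allele and gene->GO mappings (read), BED and TSV
region/statistics tables (write).

Internal coordinates are 1-based inclusive throughout (GFF3 convention);
BED output is converted to 0-based half-open on write.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd
import yaml

from ._core import MISSING, logger

__all__ = [
    "GenotypeMatrix",
    "GeneAnnotation",
    "AncestralAlleles",
    "RunConfig",
    "read_genotypes",
    "write_genotypes_tsv",
    "read_annotation",
    "read_ancestral_table",
    "read_go_map",
    "write_regions",
    "write_stats",
    "read_stats",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Haploid 0/1/MISSING calls at ordered sites for two labelled panels.

    Each inbred line contributes a single allele per site: homozygous
    diploid calls collapse to one haploid allele and heterozygous calls
    are masked as missing at read time.
    """

    chrom: np.ndarray          # str per site
    pos: np.ndarray            # int64, 1-based, strictly increasing per chrom
    ref: np.ndarray            # str per site
    alt: np.ndarray            # str per site
    calls: np.ndarray          # int8 (n_sites, n_samples), values {0, 1, MISSING}
    samples: list[str]
    panel: np.ndarray          # str label per sample

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.panel = np.asarray(self.panel, dtype=object)

    # -- basic geometry -----------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def panels(self) -> list[str]:
        return sorted(set(self.panel.tolist()))

    def panel_mask(self, label: str) -> np.ndarray:
        return self.panel == label

    def panel_calls(self, label: str) -> np.ndarray:
        return self.calls[:, self.panel_mask(label)]

    def chromosomes(self) -> list[str]:
        seen: list[str] = []
        for c in self.chrom:
            if not seen or seen[-1] != c:
                seen.append(c)
        return seen

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero(self.chrom == chrom)
        if idx.size == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            calls=self.calls[index],
            samples=list(self.samples),
            panel=self.panel.copy(),
        )

    def region_index(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Site indices with ``chrom`` and start <= pos <= end (1-based)."""
        sl = self.chrom_slice(chrom)
        pos = self.pos[sl]
        lo = int(np.searchsorted(pos, start, side="left"))
        hi = int(np.searchsorted(pos, end, side="right"))
        return np.arange(sl.start + lo, sl.start + hi)

    # -- validation ---------------------------------------------------------
    def validate(self) -> "GenotypeMatrix":
        ok = np.isin(self.calls, (0, 1, MISSING))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValueError(
                f"invalid call value {self.calls[bad[0], bad[1]]} at site "
                f"{self.chrom[bad[0]]}:{self.pos[bad[0]]}"
            )
        for chrom in set(self.chrom.tolist()):
            p = self.pos[self.chrom == chrom]
            d = np.diff(p)
            if (d <= 0).any():
                i = int(np.flatnonzero(d <= 0)[0])
                raise ValueError(
                    f"positions not strictly increasing on {chrom} at {chrom}:{p[i + 1]}"
                )
        if self.calls.shape != (self.n_sites, self.n_samples):
            raise ValueError("calls shape does not match sites x samples")
        counts = pd.Series(self.panel).value_counts()
        if len(counts) != 2:
            raise ValueError(f"expected exactly 2 panels, got {list(counts.index)}")
        if (counts < 2).any():
            raise ValueError("each panel needs at least 2 samples")
        return self


@dataclass
class GeneAnnotation:
    """Gene models with the longest protein-coding transcript per gene.

    ``genes`` is indexed by gene id with columns chrom, start, end, strand,
    longest_tx, tx_start, tx_end (1-based inclusive).  ``exons`` maps the
    gene id to the exon intervals of its longest transcript.
    """

    genes: pd.DataFrame
    exons: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def validate(self) -> "GeneAnnotation":
        g = self.genes
        if not g.index.is_unique:
            raise ValueError("gene ids are not unique")
        if (g["start"] > g["end"]).any():
            raise ValueError("gene with start > end")
        for gid, ivs in self.exons.items():
            ts, te = g.loc[gid, "tx_start"], g.loc[gid, "tx_end"]
            for s, e in ivs:
                if s > e or s < ts or e > te:
                    raise ValueError(f"exon [{s},{e}] outside transcript of {gid}")
        return self


class AncestralAlleles:
    """Map (chrom, pos) -> ancestral base; absent sites are unpolarized."""

    def __init__(self, table: dict[tuple[str, int], str]):
        self._table = table

    def __len__(self) -> int:
        return len(self._table)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self._table

    def get(self, chrom: str, pos: int) -> str | None:
        return self._table.get((chrom, int(pos)))

    def polarize(self, gm: GenotypeMatrix) -> np.ndarray:
        """Per-site polarization code for a genotype matrix.

        Returns int8 per site: 1 if the alt allele is derived (ancestral
        base equals ref), 0 if the ref allele is derived (ancestral equals
        alt), -1 if the site cannot be polarized (no outgroup information
        or the ancestral base matches neither allele).
        """
        out = np.full(gm.n_sites, -1, dtype=np.int8)
        n_mismatch = 0
        for i in range(gm.n_sites):
            anc = self._table.get((gm.chrom[i], int(gm.pos[i])))
            if anc is None:
                continue
            if anc == gm.ref[i]:
                out[i] = 1
            elif anc == gm.alt[i]:
                out[i] = 0
            else:
                n_mismatch += 1
        if n_mismatch:
            logger.info("polarize: %d sites with ancestral base matching neither allele", n_mismatch)
        return out


@dataclass
class RunConfig:
    """All tunable thresholds of the scan, with the study defaults."""

    window_size_snps: int = 40
    window_step_fraction: float = 0.10
    clr_grid_bp: int = 150_000
    low_quantile: float = 0.10
    high_quantile: float = 0.90
    min_snps_per_gene: int = 5
    upstream_bp: int = 5_000
    fgt_bin_sites: int = 1_000
    ld_prune_r2: float = 0.8
    fdr: float = 0.05
    rng_seed: int = 1

    def __post_init__(self) -> None:
        for q in (self.low_quantile, self.high_quantile):
            if not 0.0 < q < 1.0:
                raise ValueError("quantiles must lie in (0, 1)")
        if self.window_size_snps < 2:
            raise ValueError("window size must be >= 2")
        for name in ("clr_grid_bp", "upstream_bp", "fgt_bin_sites"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({f.name: getattr(self, f.name) for f in dc_fields(self)}, fh)


# ---------------------------------------------------------------------------
# genotype readers/writers
# ---------------------------------------------------------------------------

def _load_panel_map(panel_map) -> dict[str, str]:
    if isinstance(panel_map, dict):
        return dict(panel_map)
    df = pd.read_csv(panel_map, sep="\t", header=None, names=["sample", "panel"], dtype=str)
    return dict(zip(df["sample"], df["panel"]))


def read_genotypes(path: str, panel_map, fmt: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or the TSV dialect.

    ``panel_map`` is a sample -> panel-label dict or the path of a
    two-column TSV (sample, panel).  Diploid homozygous calls collapse to
    a single haploid allele; heterozygous calls become MISSING (their
    count is logged).  Indels and multi-allelic sites are skipped.
    """
    if fmt is None:
        fmt = "tsv" if os.path.basename(path).endswith((".tsv", ".txt")) else "vcf"
    mapping = _load_panel_map(panel_map)
    if fmt == "vcf":
        gm = _read_vcf(path, mapping)
    elif fmt == "tsv":
        gm = _read_tsv(path, mapping)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")
    return gm.validate()


def _panels_for(samples: list[str], mapping: dict[str, str]) -> np.ndarray:
    missing = [s for s in samples if s not in mapping]
    if missing:
        raise ValueError(f"samples without panel label: {missing[:5]}")
    return np.array([mapping[s] for s in samples], dtype=object)


def _read_vcf(path: str, mapping: dict[str, str]) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    chrom, pos, ref, alt, rows = [], [], [], [], []
    n_het = n_skipped = 0
    last: dict[str, int] = {}
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        if v.CHROM in last and v.POS <= last[v.CHROM]:
            raise ValueError(f"positions not sorted: {v.CHROM}:{v.POS}")
        last[v.CHROM] = v.POS
        row = np.full(len(samples), MISSING, dtype=np.int8)
        for j, g in enumerate(v.genotypes):
            alleles = [a for a in g[:-1] if a >= 0]
            if not alleles:
                continue
            if len(set(alleles)) > 1:
                n_het += 1
                continue
            row[j] = alleles[0]
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        rows.append(row)
    if n_het:
        logger.info("read_genotypes: %d heterozygous calls masked as missing", n_het)
    if n_skipped:
        logger.info("read_genotypes: %d non-biallelic-SNP records skipped", n_skipped)
    return GenotypeMatrix(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        calls=np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8),
        samples=samples,
        panel=_panels_for(samples, mapping),
    )


def _read_tsv(path: str, mapping: dict[str, str]) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    fixed = ["chrom", "pos", "ref", "alt"]
    samples = [c for c in df.columns if c not in fixed]
    calls = df[samples].to_numpy(dtype=object)
    out = np.full(calls.shape, MISSING, dtype=np.int8)
    out[calls == 0] = 0
    out[calls == "0"] = 0
    out[calls == 1] = 1
    out[calls == "1"] = 1
    for chrom in df["chrom"].unique():
        p = df.loc[df["chrom"] == chrom, "pos"].to_numpy()
        bad = np.flatnonzero(np.diff(p) <= 0)
        if bad.size:
            raise ValueError(f"positions not sorted: {chrom}:{p[bad[0] + 1]}")
    return GenotypeMatrix(
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(dtype=np.int64),
        ref=df["ref"].to_numpy(dtype=object),
        alt=df["alt"].to_numpy(dtype=object),
        calls=out,
        samples=samples,
        panel=_panels_for(samples, mapping),
    )


def write_genotypes_tsv(gm: GenotypeMatrix, path: str) -> None:
    """Write the TSV dialect: chrom, pos, ref, alt, one column per sample."""
    cells = gm.calls.astype(object)
    cells[gm.calls == MISSING] = "NA"
    cols = {"chrom": gm.chrom, "pos": gm.pos, "ref": gm.ref, "alt": gm.alt}
    cols.update({s: cells[:, j] for j, s in enumerate(gm.samples)})
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def write_panel_map(gm: GenotypeMatrix, path: str) -> None:
    pd.DataFrame({"sample": gm.samples, "panel": gm.panel}).to_csv(
        path, sep="\t", index=False, header=False
    )


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def read_annotation(gff3_path: str) -> GeneAnnotation:
    """Load gene models from GFF3 and pick the longest transcript per gene.

    The longest protein-coding transcript is chosen by summed CDS length
    (summed exon length when a transcript has no CDS features); ties break
    by lexicographic transcript id.
    """
    import gffutils

    if os.path.getsize(gff3_path) == 0 or not _has_features(gff3_path):
        logger.warning("read_annotation: no features in %s", gff3_path)
        return GeneAnnotation(
            genes=pd.DataFrame(
                columns=["chrom", "start", "end", "strand", "longest_tx", "tx_start", "tx_end"]
            ),
            exons={},
        )
    db = gffutils.create_db(
        gff3_path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows, exons = [], {}
    for gene in db.features_of_type("gene"):
        gid = gene.id
        best = None  # (key, tx_id, tx_feature)
        for tx in db.children(gene, featuretype=("mRNA", "transcript"), level=1):
            cds = list(db.children(tx, featuretype="CDS"))
            parts = cds if cds else list(db.children(tx, featuretype="exon"))
            length = sum(f.end - f.start + 1 for f in parts)
            key = (-length, tx.id)
            if best is None or key < best[0]:
                best = (key, tx.id, tx)
        if best is None:
            logger.warning("gene %s has no transcript; using gene span", gid)
            tx_id, tx_start, tx_end = gid, gene.start, gene.end
            exons[gid] = [(gene.start, gene.end)]
        else:
            _, tx_id, tx = best
            tx_start, tx_end = tx.start, tx.end
            ivs = sorted(
                (f.start, f.end) for f in db.children(tx, featuretype="exon")
            ) or [(tx.start, tx.end)]
            exons[gid] = ivs
        rows.append(
            dict(gene=gid, chrom=gene.seqid, start=gene.start, end=gene.end,
                 strand=gene.strand, longest_tx=tx_id, tx_start=tx_start, tx_end=tx_end)
        )
    orphans = [
        f.id for f in db.features_of_type(("mRNA", "transcript"))
        if not list(db.parents(f, featuretype="gene"))
    ]
    if orphans:
        raise ValueError(f"mRNA without parent gene: {orphans[:5]}")
    genes = pd.DataFrame(rows).set_index("gene")
    return GeneAnnotation(genes=genes, exons=exons).validate()


def _has_features(path: str) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return True
    return False


# ---------------------------------------------------------------------------
# small tables
# ---------------------------------------------------------------------------

def read_ancestral_table(path: str) -> AncestralAlleles:
    """TSV (chrom, pos, ancestral); rows with non-ACGT bases are skipped."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos", "anc"],
                     dtype={"chrom": str, "anc": str}, comment="#")
    good = df["anc"].isin(list("ACGT"))
    n_bad = int((~good).sum())
    if n_bad:
        logger.warning("read_ancestral_table: %d rows with invalid base skipped", n_bad)
    df = df[good]
    return AncestralAlleles(
        {(c, int(p)): a for c, p, a in zip(df["chrom"], df["pos"], df["anc"])}
    )


def read_go_map(path: str) -> dict[str, set[str]]:
    """Two-column TSV (gene, term) -> gene -> set of terms."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"], dtype=str)
    out: dict[str, set[str]] = {}
    for g, t in zip(df["gene"], df["term"]):
        out.setdefault(g, set()).add(t)
    return out


def write_regions(regions: pd.DataFrame, path: str, fmt: str = "TSV") -> None:
    """Write candidate regions; BED converts 1-based inclusive to 0-based half-open."""
    fmt = fmt.upper()
    if fmt == "BED":
        bed = regions.copy()
        bed["start"] = bed["start"] - 1
        cols = ["chrom", "start", "end"] + [c for c in bed.columns if c not in ("chrom", "start", "end")]
        bed[cols].to_csv(path, sep="\t", index=False, header=False)
    elif fmt == "TSV":
        regions.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown region format {fmt!r}")


def write_stats(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_stats(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
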