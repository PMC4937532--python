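"""End-to-end screen: filter -> stats -> windows -> CLR -> thresholds ->
regions -> genes -> polarization test -> enrichment -> recombination."""

from __future__ import annotations

import hashlib
import json
import os

import numpy as np
import pandas as pd

from ._core import logger
from .io import (
    AncestralAlleles,
    GeneAnnotation,
    GenotypeMatrix,
    RunConfig,
    write_regions,
    write_stats,
)
from .qc import filter_array_sites
from .clr import clr_scan
from .windows import flag_and_merge, pool_thresholds, region_summary, window_stats
from .genes import genewise_stats, hypergeom_enrichment, regions_to_genes, wilcoxon_rank_sum
from .recomb import candidate_low_rec_overlap, fgt_scan, low_recombination_regions

__all__ = ["run_full_scan"]


def _digest(gm: GenotypeMatrix) -> str:
    h = hashlib.sha256()
    h.update(gm.calls.tobytes())
    h.update(gm.pos.tobytes())
    return h.hexdigest()[:16]


def run_full_scan(
    gm: GenotypeMatrix,
    annotation: GeneAnnotation,
    ancestral: AncestralAlleles | None = None,
    go_map: dict[str, set[str]] | None = None,
    config: RunConfig | None = None,
    out_dir: str | None = None,
    genome_bp: int | None = None,
) -> dict:
    """Run the whole pool-specific sweep screen.

    Returns a dict with the filtered matrix, per-window statistics,
    per-pool thresholds/regions/candidate genes, gene-wise statistics
    (with the candidate-vs-rest normalized-H rank-sum test when an
    ancestral table is given), GO enrichment (when a term map is given),
    the recombination bins and the per-pool fraction of candidates
    outside low-recombination regions, plus a reproducibility manifest.
    """
    config = config or RunConfig()
    a, b = gm.panels
    if genome_bp is None:
        genome_bp = int(sum(gm.pos[gm.chrom_slice(c)][-1] for c in gm.chromosomes()))

    gm_f, report = filter_array_sites(gm)
    clr = {p: clr_scan(gm_f, p, grid_bp=config.clr_grid_bp, ancestral=ancestral)
           for p in (a, b)}
    ws = window_stats(gm_f, clr, config)
    thresholds = {p: pool_thresholds(ws, p, config.low_quantile, config.high_quantile)
                  for p in (a, b)}
    regions = {p: flag_and_merge(ws, thresholds[p], p) for p in (a, b)}
    all_regions = pd.concat(regions.values(), ignore_index=True)
    summary = {p: region_summary(regions[p], genome_bp) for p in (a, b)}
    candidates = regions_to_genes(all_regions, annotation)

    gene_stats = genewise_stats(
        gm_f, annotation, ancestral=ancestral,
        upstream_bp=config.upstream_bp, min_snps=config.min_snps_per_gene,
    )
    h_test = {}
    if ancestral is not None:
        for p in (a, b):
            cand = candidates.get(p, set())
            hv = gene_stats[f"h_{p}"]
            in_c = hv[hv.index.isin(cand)].dropna()
            out_c = hv[~hv.index.isin(cand)].dropna()
            if len(in_c) >= 3 and len(out_c) >= 3:
                u, pval = wilcoxon_rank_sum(in_c, out_c)
                h_test[p] = dict(
                    U=u, p=pval, n_candidates=len(in_c), n_rest=len(out_c),
                    median_candidates=float(in_c.median()), median_rest=float(out_c.median()),
                )
            else:
                logger.warning("h_test: too few genes with defined H for pool %s", p)
    else:
        logger.info("run_full_scan: no ancestral table, H-based steps skipped")

    enrichment = {}
    if go_map is not None:
        for p in (a, b):
            enrichment[p] = hypergeom_enrichment(
                candidates.get(p, set()), go_map, fdr=config.fdr
            )

    bins = {p: low_recombination_regions(
        fgt_scan(gm_f, p, bin_sites=config.fgt_bin_sites), config.low_quantile)
        for p in (a, b)}
    low_rec_frac = {}
    for p in (a, b):
        cand_genes = annotation.genes[annotation.genes.index.isin(candidates.get(p, set()))]
        low_rec_frac[p] = candidate_low_rec_overlap(cand_genes, bins[p])

    manifest = dict(
        tool="sweepscan",
        config={k: getattr(config, k) for k in vars(config)},
        seed=config.rng_seed,
        input_digest=_digest(gm),
        n_sites_input=gm.n_sites,
        n_sites_filtered=gm_f.n_sites,
        genome_bp=genome_bp,
        panels=[a, b],
        summary=summary,
        n_candidates={p: len(candidates.get(p, set())) for p in (a, b)},
        shared_candidates=len(candidates.get(a, set()) & candidates.get(b, set())),
        low_rec_fraction_outside=low_rec_frac,
        h_test=h_test,
    )

    results = dict(
        genotypes=gm_f, filter_report=report, clr=clr, windows=ws,
        thresholds=thresholds, regions=all_regions, summary=summary,
        candidates=candidates, gene_stats=gene_stats, h_test=h_test,
        enrichment=enrichment, recomb_bins=bins, low_rec_frac=low_rec_frac,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_outputs(results, out_dir, a, b)
    return results


def _write_outputs(res: dict, out_dir: str, a: str, b: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    write_stats(res["windows"], os.path.join(out_dir, "windows.tsv"))
    for p, table in res["clr"].items():
        write_stats(table, os.path.join(out_dir, f"clr_{p}.tsv"))
    write_regions(res["regions"], os.path.join(out_dir, "regions.tsv"), "TSV")
    if len(res["regions"]):
        write_regions(res["regions"], os.path.join(out_dir, "regions.bed"), "BED")
    write_stats(res["gene_stats"].reset_index(), os.path.join(out_dir, "gene_stats.tsv"))
    res["filter_report"].to_frame().to_csv(
        os.path.join(out_dir, "filter_report.tsv"), sep="\t", index=False
    )
    for p, table in res["enrichment"].items():
        write_stats(table, os.path.join(out_dir, f"enrichment_{p}.tsv"))
    for p, table in res["recomb_bins"].items():
        write_stats(table, os.path.join(out_dir, f"recomb_bins_{p}.tsv"))
    for p in (a, b):
        with open(os.path.join(out_dir, f"candidates_{p}.txt"), "w") as fh:
            for g in sorted(res["candidates"].get(p, set())):
                fh.write(g + "\n")
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(res["manifest"], fh, indent=2, default=float)
    logger.info("run_full_scan: outputs written to %s", out_dir)
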