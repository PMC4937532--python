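# Methods

`sweepscan` screens two diverged, fully inbred germplasm panels for
pool-specific selective sweeps and implements the supporting analyses a
selection screen of this kind needs. This note documents the models, the
parameters that matter, the synthetic test bed, and the numerical choices
where the design was genuinely open.

## The screen

A selective sweep drags linked variation to high frequency around the
selected site, locally depressing nucleotide diversity, skewing the site
frequency spectrum (SFS) toward rare and high-frequency-derived classes,
and — when selection acts in only one pool — inflating differentiation
between pools. No single statistic separates sweeps from drift,
demography or background selection reliably, so the screen requires four
signals to coincide:

1. **π** (per-SNP heterozygosity, unbiased form `2p̂(1−p̂)·n/(n−1)`),
   averaged per panel over sliding windows of 40 SNPs stepping 4 SNPs
   (10 %); a window must fall in the lower 10 % tail of its panel.
2. **Tajima's D** per window per panel (π-based vs Watterson θ, Tajima's
   variance constants at the rounded mean non-missing sample size of the
   window's segregating sites); lower 10 % tail.
3. **A SweepFinder-style composite likelihood ratio (CLR)** on a fixed
   physical grid of non-overlapping 150 kb cells; upper 90 % tail of the
   panel's CLR field (windows inherit the CLR of the cell containing
   their midpoint).
4. **Weir & Cockerham's FST** between the pools per SNP, window-averaged;
   upper 90 % tail.

Windows passing all four thresholds with overlapping-or-abutting
SNP-index ranges merge into candidate regions; genes whose bodies overlap
a region by ≥1 bp become candidate genes for that pool.

All quantile thresholds are empirical (type-7 linear interpolation), per
statistic per panel, computed over windows with defined values only.

### CLR model

At distance `d` from a putative sweep center, a lineage escapes the sweep
with probability `p_e = 1 − exp(−α d)` (α is the sweep intensity in
1/bp). Non-escapees coalesce star-like into one ancestor during the
sweep. A site's post-sweep derived count is modeled by drawing the `e`
escapees plus that ancestor (hypergeometrically) from the genome-wide
background SFS at the panel's modal sample size and copying the
ancestor's allele onto all non-escapees, marginalized over
`e ~ Binomial(n, p_e)` and conditioned on polymorphism (the scan uses
segregating sites only). `CLR = 2(max_α log CL − log CL_null)`, the null
being the background spectrum itself; α is maximized on a 40-point
log-spaced grid spanning `p_e(α, 150 kb)` from 1e−4 to 1−1e−4, refined by
golden section, with α→∞ included so CLR ≥ 0 holds identically.

Without an outgroup the scan folds the sweep-model distribution and uses
the folded (minor-allele) background, symmetrized internally. Empty
background classes are floored at a 0.5 pseudo-count. Sites with
`p_e > 0.999` contribute the null term exactly. Per-site missingness is
handled by projecting the background hypergeometrically to each observed
sample size.

The genome scan discretizes `α·d` into 128 log-spaced buckets
(`1e−4 ≤ α·d ≤ ln 1000`; smaller values use the exact `p_e → 0` limit
distribution, larger are null) and evaluates each (grid point, α) pair
from per-bucket prefix sums over position-sorted sites, so one
chromosome/panel scan costs seconds. The bucketed path and the exact
path (used directly by tests at small n, where it matches exhaustive
enumeration to 1e−12) share the same model code.

### Supporting analyses

- **Fay & Wu's normalized H** contrasts intermediate- against
  high-frequency derived variants (`θπ − θL`, normalized by the standard
  variance with θ estimated by Watterson's θW and θ² by
  `S(S−1)/(a₁²+b_n)`); it requires outgroup polarization and goes
  negative after sweeps. Candidate gene sets are compared against the
  remaining genes with a two-sided Wilcoxon rank-sum test.
- **Four-gamete screen**: adjacent-SNP four-gamete tests (all four
  two-locus gametes ⇒ ≥1 historical recombination) binned 1000 tests per
  bin, expressed as events/Mb; bins in the per-chromosome lower 10 % tail
  flag low-recombination regions, where background selection mimics
  sweeps. The report states what fraction of candidates lies outside
  them. A trailing bin is kept if it holds ≥100 tests.
- **Gene-wise statistics** use the longest protein-coding transcript
  (summed CDS length, ties broken lexicographically) plus 5 kb upstream
  of the strand-aware 5′ end, requiring ≥5 SNPs; partition FST is
  reported for exonic / genic / 500 bp / 5 kb-upstream subsets under the
  same ≥5-SNP rule ("genic" means the transcript span only).
- **GO enrichment**: hypergeometric upper tail over the universe of
  genes with ≥1 term annotation, Benjamini–Yekutieli correction (valid
  under the arbitrary dependence of overlapping gene sets), FDR 0.05.
- **Introgression segment length**: donor marker span plus half the
  distance to each flanking non-donor marker.

### Filters

Array mode: heterozygous calls are masked at read time (inbred lines
contribute one haploid allele); sites with ≥10 % missing calls or
monomorphic across the combined panels are removed. WGS mode: bi-allelic
SNPs with site MQ ≥ 30; genotypes failing GQ > 5 (strict) or coverage
bounds (3–60× for medium-coverage lines, 10–300× for deep lines) are
masked; both members of SNP pairs closer than 3 bp are removed; sites
with >50 % missing calls are removed. The within-set ≥90 % major-allele
filter is available but off by default: it suppresses sequencing
artifacts in near-homozygous single-line data, but applied across a
two-panel set it deletes exactly the differentiated sites the scan needs.
LD pruning (r² on haplotype frequencies, pairwise-complete) walks left to
right dropping sites with r² > 0.8 against the nearest retained site
within a 100-SNP look-back.

## The synthetic test bed

The generator states a desk-scale world rather than running a coalescent;
every feature is analytically controllable and fully deterministic under
a seed.

- **Panels**: 70 + 66 fully homozygous lines on 2 chromosomes of 25 Mb
  with 50,000 SNPs each; 2 % missing calls.
- **Site mixture**: half the sites are shared ancestral polymorphisms —
  ancestral frequency `p₀ ~ Beta(0.5, 0.5)` truncated to (0.02, 0.98),
  panel frequencies Balding–Nichols around `p₀`, the alt allele derived
  with the neutral stationary probability `1 − p₀`. The other half are
  post-split panel-private derived variants at founder frequency `c/30`
  with weight ∝ 1/c up to a ceiling of 7 (young alleles are rare). The
  private fraction and ceiling are solved from the neutrality condition
  `E[θπ] = E[θL]`: divergence drift alone behaves like a bottleneck and
  drives H negative, and the post-split mutation input restores the
  balance a real equilibrium population has. The fraction is consistent
  with the coalescent post-split tree-length estimate (~0.4) for
  `τ = −ln(1−F)`.
- **Differentiation**: Balding–Nichols `F = 0.14` targets the study's
  genome-wide differentiation; the multi-locus (ratio-of-sums) W&C FST of
  the generated data measures 0.140. Founder counts are rounded
  systematically (`round(30p)` carriers) so founder-sampling noise does
  not inflate F.
- **Linkage**: haplotypes copy from 30 founders per panel with geometric
  blocks of mean 50 SNPs; a centromere-like stretch (±8 % of the
  chromosome around its middle) lengthens blocks 15-fold, depressing
  detectable recombination there.
- **Sweeps**: 10 per pool, alternating pools along the chromosomes with
  jittered even spacing. Each sweep picks one pool sample as the sweeper;
  every pool sample draws an exponential escape distance (mean 1/α) on
  each side of the center and carries the sweeper's haplotype inside it —
  exactly the star-like escape model the CLR assumes, with contiguous
  tracts so four-gamete structure stays realistic. Default α = 1e−5:
  affected span (p_e < 0.99) ±0.46 Mb and core (p_e < 0.5) ±70 kb, i.e.
  localized sweeps at the physical scale of the candidate regions this
  kind of screen reports. The truth table records pool, center, α, the
  affected span and the sweeper.
- **Annotation/outgroup**: non-overlapping genes (mean 4 kb, 1–6 exons,
  random strand), a GO map in which a designated term is enriched among
  genes inside sweep cores (20 % vs 2 % background), and an outgroup
  ancestral table equal to the truth with a 1 % polarization flip rate.

What a green test establishes — and what it does not: the generator
matches the scan's own sweep model, so recovery tests validate the
inference machinery, not its robustness to demography, gene conversion,
ascertainment bias, or sweep models with recurrent mutation; its LD comes
from founder copying, not recombination graphs; FST heterogeneity along
the genome is milder than in real elite panels. Null-behaviour tests
bound the false-positive footprint only within this stated world.

## Numerical choices and degenerate inputs

- Undefined statistics propagate as NaN (`NOT_DEFINED`), never silently
  as zero; window means require ≥50 % defined sites; windows with no
  segregating sites have undefined D; quantiles are computed over defined
  values and require ≥10 of them.
- Tajima's D returns exactly 0 whenever the numerator vanishes (covers
  n = 2, where the variance normalization is 0/0 on an exact identity).
- Negative FST estimates are retained (they are part of the estimator's
  sampling distribution and removing them biases window means upward).
- W&C FST follows the 1984 haploid ANOVA form, `a = (MSP − MSG)/n_c`,
  `b = MSG`, with the heterozygosity term zero for haploids.
- Wilcoxon tests use exact enumeration when `min(n) ≤ 10` with no ties,
  otherwise the normal approximation with tie and continuity correction;
  identical groups return p = 1.
- The per-site vs genome-wide FST distinction matters: window statistics
  average per-site ratios, while "genome-wide FST" is the ratio of summed
  variance components (`sfs.genome_fst`); the unweighted mean of per-site
  ratios is systematically lower (≈0.09 for this generator) because
  low-MAF sites contribute noisy small ratios.
- Grid cells are anchored at 0 per chromosome; a trailing partial cell is
  kept when it spans at least half a cell, its point at the partial
  span's center.
- Multi-allelic sites and indels are excluded at read time with logged
  counts (the array platform's handling is not recoverable; bi-allelic
  restriction is the conservative choice).

## Known limitations

- The CLR model ignores recombination-map distances (physical bp only)
  and has no background-selection correction.
- The four-gamete screen tests neighboring SNPs only — a lower bound far
  below the Hudson–Kaplan interval minimum over all pairs.
- `r > 2` populations, per-bp diversity normalization, imputation and GO
  graph propagation are out of scope.
- The exact CLR path returns −inf log-likelihood for a segregating site
  exactly at the tested position with p_e = 0; the scan's bucketed path
  uses the well-defined p_e → 0 limit distribution instead.
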