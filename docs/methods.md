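# Methods notes

## The analysis model

The package analyses a two-lineage transgenerational design: a control and
an exposed lineage, each sampled at F0 sperm, F1 sperm, and F2 liver (both
sexes), with three biological replicates per lineage and tissue. All
methylation inference works on counts of methylated/unmethylated reads at
CpG sites; all expression inference works on per-gene read counts.

### Region construction

CpG sites are filtered at a minimum coverage of 3 per sample (the
convention for calling a site validly covered). Two region types are
tested:

* **Tiles** — fixed windows (default 100 bp, step 100) anchored at
  multiples of the step from coordinate 0. Anchoring is deterministic and
  annotation-independent; with step = window the tiles partition the genome
  and every covered CpG belongs to exactly one tile.
* **Promoters** — strand-aware TSS windows, default −3000/+300: plus strand
  `[tss−3000, tss+300)`, minus strand the mirror image, clamped at the
  contig origin. Promoter regions are keyed by `gene_id`, which is what
  makes cross-generation locus identity well defined; overlapping promoter
  windows of neighbouring genes are deliberately not de-overlapped, so a
  CpG may contribute to two gene-keyed promoters.

A region enters testing only if every sample contributes at least one
covered CpG (configurable via `require_all_samples`); differential tests
need counts on both sides, and this mirrors the unite-across-samples
default of the standard methylKit workflow. Per-region counts are exact
sums of member-site counts (conservation is property-tested).

### Differential methylation

With ≥ 2 replicates per group the default test is a binomial logistic
regression of methylated proportion on the group indicator. Because the
design has a single binary covariate, the MLE is available in closed form
(the group-pooled proportions), so the likelihood-ratio statistic is
computed directly and referred to χ²(1) — no iterative fitting, and the
result is identical to an IRLS-fitted GLM (cross-checked against
statsmodels in the tests). Groups with a single replicate, or complete
separation (a pooled proportion of exactly 0 or 1), fall back to a
two-sided Fisher exact test on pooled counts, computed by exact integer
hypergeometric enumeration (all tables whose point-probability numerator is
≤ the observed one are summed; ties are exact integer comparisons, no
floating-point epsilon).

**Overdispersion.** Biological replicates are more variable than binomial
sampling allows. `call_dmrs` therefore estimates a pooled quasi-binomial
scale φ as the across-region median of the full-model residual deviance per
degree of freedom (floored at 1) and refers LRT/φ to χ²(1). A pooled rather
than per-region scale is used because each region has only ~4 residual
degrees of freedom; the per-region estimate is far too noisy. This is a
deliberate, documented choice (`overdispersion="none"` disables it) and is
what keeps the empirical type-I error at the nominal level on beta-binomial
null data while costing essentially no power at the effect sizes of
interest.

Significance is Benjamini–Hochberg FDR < 0.1 across all regions of one
comparison (BH rather than methylKit's SLIM q-values: deterministic and
well specified; results are labelled accordingly). Significant regions are
labelled P (methylation difference > 0, exposed − control, computed from
pooled within-group counts — coverage-weighted, matching the test's
sufficient statistics) or N (< 0); no minimum |Δ| cutoff is applied by
default. The genome-wide methylation comparison between two samples is a
one-sided Wilcoxon rank-sum on per-tile percentages (exact for small
untied samples, normal approximation with tie correction otherwise).

### Inheritance classification and transmission

A locus (gene-keyed promoter) significant in all compared generations
receives one character per generation: its pattern string. Loci with any
non-significant generation are absent from the common set by construction;
a direction of "none" rejects the locus. The census runs over all 2^k
patterns and sums to the common-set size (tested). Transmission statistics
are pure set algebra — common = F0∩F1∩F2, skipped = (F0∩F2)\F1,
novel-in-F1 = (F1∩F2)\F0 — with every percentage reported against an
explicitly named reference set and rounded half-up to one decimal, so the
identities |F0∩F2| = skipped + common and |F1∩F2| = novel + common hold
exactly. "Skipped" is defined purely by absence from the F1 significant
set, not by evidence of F1 equivalence.

### Expression stage and DMEGs

The built-in DE stage approximates the DESeq2 workflow at a size that can
be fully specified and tested: median-of-ratios size factors; per-gene
method-of-moments NB dispersion from within-group variances of normalized
counts, shrunk on the log scale toward the across-genes median with prior
weight 0.7 (raw moment estimates at n = 3 per group are unusably noisy in
both directions — shrinkage here plays the role of DESeq2/edgeR dispersion
moderation); and a Wald test of the log group-mean ratio with the
delta-method standard error Var(log mean) ≈ (1/n)(1/μ + α) per group.
Dispersion shrinkage priors (apeglm), trended dispersion, and outlier
handling are out of scope — external DESeq2 result tables can be ingested
verbatim and are treated identically downstream. FDR < 0.05; directions
p/n follow the sign of log2FC (exposed over control).

DMEGs are the intersection of inherited-DMP genes with significant DEGs;
genes with direction "none" never enter. Canonical classes: all-P pattern
with direction n → `PPPn`; all-N with p → `NNNp`; everything else "other".

### Enrichment

GSEA uses the weighted Kolmogorov–Smirnov running sum: hits add
|score|^p / Σ_hits |score|^p (p = 1 by default), misses subtract
1/(N − N_hits); the ES is the extremum of largest absolute value, and the
leading edge is the hits at or before (after, for negative ES) the
extremum. The null is a **gene-label permutation** (the entry point is a
ranked list, not sample-level expression — a documented divergence from
the original tool's phenotype permutation). NES divides ES by the mean
|null ES| of matching sign; the permutation FDR pools positive and negative
null NES separately in the style of the original method. P-values count
exceedances in the observed direction over all permutations with a +1
guard, (b+1)/(n_perm+1), so a never-exceeded score reports 1/(n_perm+1)
rather than 0. Default n_perm = 1000, set-size filters 5–2000. The default
ranking metric for DE results is sign(log2FC)·(−log10 p), configurable to
plain log2FC; gene sets come from user-supplied GMT files only (no live
database queries — versioned-database contents are not reproducible).
ORA is the hypergeometric upper tail P(X ≥ k) with BH across queried sets.

### Genomic-location labels

Regions are labelled promoter / exon / intron / intergenic by ≥ 1-bp
overlap with precedence promoter > exon > intron (configurable). Promoters
are the analysis target, hence first. Note a minus-strand promoter's +300
downstream arm reaches into the gene body, so 5′ intronic bases can
legitimately classify as promoter.

## The synthetic generator

The generator emulates the *structure* of the modelled study — sample
roles, lineages, replicate counts, coverage scale, promoter CpG density,
and a planted-pattern plan whose defaults (27 all-hyper loci with
down-coupled expression, 1 all-hypo locus with up-coupled expression, and
8 loci of each mixed pattern) echo the canonical-inheritance analysis the
pipeline exists to perform. Specifics:

* Per-CpG counts are **beta-binomial**: each CpG in each sample draws its
  methylation probability from Beta(μs, (1−μ)s) with precision s = 100
  around the group mean, then binomial reads at Poisson(30) coverage.
  The replicate-level overdispersion this induces is what makes the
  replicate-aware logistic path (and its pooled φ) meaningful.
* Planted epimutations shift the exposed-lineage mean by ±effect_pp
  (default 40 points) uniformly across the promoter's CpGs, in the
  generations the pattern dictates; both F2 liver sexes share the pattern's
  final character. Planted loci start at intermediate baseline methylation
  (uniform on [0.2, 0.8]) so the configured shift is expressible; shifted
  means are clipped into [0.02, 0.98] with a warning. Background promoters
  draw baselines from Beta(2, 2).
* Expression counts are NB (dispersion 0.1) around lognormal base means;
  coupled genes (all planted loci) have the exposed mean scaled by
  2^(∓3) — down if the F2 promoter state is P, up if N — and their base
  mean floored at 100. The strong 8-fold default keeps the canonical
  recovery check a test of the integration set logic rather than of
  borderline DE power at n = 3.
* Generation coupling is simulated at the level of group means; there is
  no meiosis/reprogramming model, no bisulfite-conversion error, no
  sequence-context effect, and no read-level (FASTQ) simulation. The
  generator tests the analysis, not the biology: passing recovery tests
  shows the pipeline's set logic and tests behave as specified under the
  generator's assumptions, not that real WGBS data meet those assumptions.

All randomness flows from a single seed through per-stage
`SeedSequence`-derived generators, so outputs are byte-identical across
runs and independent of stage order.

## Problem sizes and numerical choices

The demonstration pipeline and the acceptance script use 300 genes on 4
chromosomes, 12 CpGs per promoter, 24 methylome samples and 6 expression
samples — a cohort chosen to exercise every code path with tens of
thousands of simulated CpG draws while a full run stays in the seconds
range. Null calibrations use 2000 regions/genes. Exact-oracle sweeps cover
all 2×2 tables with both margins ≤ 12 exhaustively plus 500 random tables
with margins ≤ 40 (agreement demanded at 1e-10), and hypergeometric
configurations over universes ≤ 25.

Degenerate inputs: zero-coverage CpGs are retained with an undefined
percentage flag; zero-margin Fisher tables return p = 1; all-tied rank-sum
comparisons return p = 0.5 with direction "none"; all-zero genes are
excluded from DE with a log line; a gene set disjoint from the ranked list
yields an undefined-flagged enrichment result; empty reference sets make
percentages None rather than NaN.

## Known limitations

* The DE stage is an approximation of DESeq2; p-values for very low counts
  are less accurate than DESeq2's (use `ingest_de_table` with real DESeq2
  output when exactness matters).
* Gene-label permutation GSEA ignores inter-gene correlation, which
  phenotype permutation would preserve.
* Locus identity is gene-keyed for promoters; coordinate-overlap matching
  across samples is only available for tiles.
* Non-CpG contexts (CHG/CHH), CpG-island annotation, smoothing-based DMR
  callers, and allele-resolved inheritance are out of scope.
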