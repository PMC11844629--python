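# epinherit

Analysis toolkit for **transgenerational epimutation studies**: tracking
environmentally induced DNA-methylation changes (epimutations) from an
exposed ancestor's germline into the somatic tissues of unexposed
descendants, and asking whether those inherited promoter marks are coupled
to gene-expression changes and disease-relevant pathways.

It is written for groups running two-lineage (control vs exposed),
multi-generation whole-genome bisulfite + RNA-seq designs — e.g. F0 sperm,
F1 sperm, F2 liver in a fish or rodent model — who want a reproducible,
scriptable pipeline from Bismark CpG coverage files and a count matrix to
inheritance-pattern tables, instead of a chain of one-off notebook steps.

## What it computes

1. **Differential methylation.** CpG sites with coverage ≥ 3 are aggregated
   into 100-bp tiles and strand-aware promoter windows (TSS −3000/+300).
   Each region is tested between lineages: a binomial logistic-regression
   likelihood-ratio test across replicates (with a pooled quasi-binomial
   overdispersion scale), or a pooled two-sided Fisher exact test computed
   by exact hypergeometric enumeration when replicates are unavailable.
   Benjamini–Hochberg FDR < 0.1 defines significance; significant regions
   are labelled **P** (hypermethylated in the exposed lineage) or **N**
   (hypomethylated).
2. **Inheritance classification.** A promoter significant in every compared
   generation gets a pattern string over {P, N} — `NPN` means hypomethylated
   in F0 sperm, hypermethylated in F1 sperm, hypomethylated in F2 liver.
   Set algebra over the per-generation DMP sets yields transmission
   statistics: consistent (F0 ∩ F1 ∩ F2), skipped ((F0 ∩ F2) \ F1), and
   novel-in-F1 ((F1 ∩ F2) \ F0) inheritance, each as a percentage of its
   named parent sets (half-up rounding, one decimal).
3. **Expression integration.** A compact DESeq2-style stage (median-of-ratios
   size factors, moderated method-of-moments NB dispersion, Wald test,
   FDR < 0.05) or an externally supplied DE table labels genes **p** (up) /
   **n** (down). Inherited DMP genes that are also significant DEGs are
   **DMEGs**; the canonical classes are `PPPn` (always hypermethylated,
   expression down) and `NNNp` (always hypomethylated, expression up),
   reflecting the inverse promoter-methylation/expression relationship.
4. **Enrichment.** Weighted Kolmogorov–Smirnov GSEA (gene-label permutation
   null, NES, permutation FDR) against GMT gene sets, plus hypergeometric
   over-representation for pathway-style queries.
5. **Synthetic data.** A beta-binomial methylome + negative-binomial
   transcriptome generator plants truth-tracked heritable epimutations with
   inverse expression coupling, so every stage is testable end to end
   without any sequencing download.

## Worked example

Run the demonstration pipeline on a synthetic cohort (300 genes; 27 loci
planted as consistently hypermethylated with down-coupled expression and one
as the mirror case, among 76 planted loci; 50-point methylation shift, 30×
coverage, 3 replicates per lineage):

```python
from epinherit.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(seed=1, simulation={"effect_pp": 50.0})
report = run_pipeline(config)
print(report["inheritance"]["n_common_all"])
print({k: v for k, v in report["inheritance"]["pattern_census"].items() if v})
print(report["expression"])
```

prints

```
76
{'PPP': 27, 'PPN': 8, 'PNP': 8, 'PNN': 8, 'NPP': 8, 'NPN': 8, 'NNP': 8, 'NNN': 1}
{'n_genes_tested': 300, 'n_significant_degs': 88, 'n_dmegs': 76,
 'n_canonical_hyper_down': 27, 'n_canonical_hypo_up': 1}
```

i.e. all 76 planted three-generation epimutations are recovered with their
exact pattern strings, and the canonical extraction returns exactly the
27 `PPPn` + 1 `NNNp` loci that were planted. The synthetic disease gene set
(built around the down-coupled genes) comes out strongly negatively enriched
in the same run (NES = −2.37, permutation p = 0.001, FDR ≈ 0).

The same stages are available from the shell:

```bash
epinherit simulate --outdir demo --seed 1
epinherit diffmeth --samples demo/samples_F0_sperm.tsv \
    --annotation demo/genes.gtf --out demo/dmp_F0.tsv
epinherit inherit --dmp demo/dmp_F0.tsv --dmp demo/dmp_F1.tsv \
    --dmp demo/dmp_F2.tsv --out demo/patterns.tsv
epinherit run --outdir demo-run --seed 1      # everything at once
```

For real data, point `diffmeth` at your Bismark coverage files and GTF,
`express` at your count matrix (or a DESeq2 results table via `--de-table`),
and `enrich` at a ranked list plus GMT file.

## Layout

```
src/epinherit/
  io_formats.py    Bismark coverage, GTF/BED gene models, GMT gene sets
  methylation.py   coverage filter, tiling, promoter windows, locations
  diffmeth.py      Fisher / logistic tests, BH-FDR, P/N calling
  inheritance.py   pattern strings, census, biotypes, transmission stats
  expression.py    size factors, NB Wald DE, DMEG derivation
  enrichment.py    weighted-KS GSEA, ORA, enrichment comparison
  simulate.py      truth-tracked multi-generation data generator
  pipeline.py      end-to-end orchestration and report
  cli.py           `epinherit` command-line interface
docs/methods.md    model and design notes
```
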