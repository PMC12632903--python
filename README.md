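# mgstates

Statistics for perturbation studies of microglial activation states:
pooled FACS-sorted CRISPRi screens, CROP-seq/CITE-seq single-cell readouts,
and promoter-level differential DNA methylation.

Microglia — the brain's innate immune cells — adopt distinct transcriptional
activation states (homeostatic, disease-associated/DAM, lipid-rich,
antigen-presenting, interferon-responsive, chemokine) whose balance matters
in neurodegeneration. A practical way to find the transcription factors that
drive or suppress these states is to knock every candidate regulator down
with CRISPR interference (CRISPRi) in iPSC-derived microglia and read the
consequences out at increasing resolution: first a sorted-marker screen over
~1600 regulators, then single-cell transcriptomes and surface proteomes for
the hits, then genome-scale methylation for epigenetic regulators. This
package implements the statistics for each of those readouts, together with
synthetic-data generators that plant known effects so every stage can be
validated end to end without any external data.

## What it computes

**Sorted-screen enrichment** (`mgstates.screen`). Cells are sorted into the
top and bottom 30% of a state-marker stain; each sgRNA *i* gets a knockdown
phenotype

> z_i = log2[ (f_i^high) / (f_i^low) ] / sd_NTC

where f are pseudocounted bin frequencies and sd_NTC is the standard
deviation of the non-targeting control (NTC) guides (after one pass removing
NTC outliers with |z| > 5). Gene scores use a "drop first" rule — the guide
with the largest |z| is discarded to guard against single-guide artifacts —
and the remaining signed z values are Stouffer-combined. Random groups of
NTC guides ("quasi-genes") are scored identically to form an empirical null,
and Benjamini-Hochberg correction runs jointly over genes and quasi-genes.

**Guide assignment** (`mgstates.guides`). Each (cell, sgRNA) pair is tested
with an upper-tail hypergeometric test of the guide's UMIs within the cell
against the pooled library, plus a log-odds ratio of within-cell vs
library-wide guide odds. A cell is assigned to its majority guide only when
that guide passes log-odds > 1 and BH-adjusted p < 0.05 and no other guide
passes; ties and multi-guide cells are ambiguous and excluded.

**QC and normalisation** (`mgstates.preprocess`). Cells with < 200 counts or
> 8% mitochondrial reads and genes seen in < 10 cells are removed; RNA and
ADT counts are log1p-normalised to a common target sum of 10,000.

**State signature scores and shifts** (`mgstates.signatures`). Per-cell
UCell scores: genes ranked within each cell by decreasing expression, ranks
clipped at r_max (default 1500), and the clipped Mann-Whitney U of the
signature genes mapped to [0, 1]. Perturbation effects are median score
differences vs pooled NTC cells with Mann-Whitney tests (BH over the full
target × state grid), plus median percentile shifts (the median percentile
of perturbed cells within the NTC distribution, minus 50) with bootstrap
CIs.

**Perturbation scores and weighted DE** (`mgstates.perturb`). A
Mixscale-style continuous knockdown score: an initial Wilcoxon DEG set
defines a signed effect vector, each cell's expression is projected onto it,
and scores are z-normalised against NTC cells (whose reported score is 0 by
definition). The score then enters per-gene negative-binomial regressions
both as covariate and as likelihood weight, so strongly perturbed cells
dominate the estimate.

**Protein-state correlations** (`mgstates.cite`), **Fisher gene-set
overlap** (`mgstates.overlap`), and **promoter methylation**
(`mgstates.methylation`): strand-combining of symmetric CpG counts, coverage
filtering, technical-replicate merging, an arcsine-sqrt Wald test per CpG,
aggregation over TSS ± 500 bp windows, and hypo/hyper classification by
minimum FDR and mean difference sign.

## Worked example

```python
from mgstates import ScreenEnrichment
from mgstates.simulate import simulate_screen

counts, truth = simulate_screen(
    n_genes=200, depth=500_000,
    effect_spec={"GENE0007": 1.5, "GENE0042": -1.2}, seed=11,
)
res = ScreenEnrichment(counts).fit(n_quasi=500, seed=11)
print(res.summary())
print(res.hits()[["gene", "log2fc", "p_value", "fdr", "phenotype_score"]])
```

prints

```
CRISPRi screen enrichment
=========================================
sgRNAs                     1250
targeting genes             200
quasi-genes                 500
NTC retained / removed   250 / 0
NTC sd (log2 ratio)      0.1063
hits at FDR<0.01          2 (1 up, 1 down)

    gene    log2fc       p_value           fdr  phenotype_score
GENE0007  2.186866 4.940656e-324 3.458460e-321       700.805476
GENE0042 -1.742897 5.755944e-236 2.014580e-233      -405.564938
```

The two planted regulators — a logistic sorting shift of +1.5 (knockdown
increases the marker) and −1.2 (knockdown decreases it) — are the only two
hits: `log2fc` is the drop-first mean guide phenotype, `fdr` the BH-adjusted
Stouffer p over genes and quasi-genes jointly, and `phenotype_score`
= log2fc × (−log10 FDR) ranks hits by combined effect and confidence.
`res.plot_volcano()` draws the corresponding volcano with quasi-genes in
black.

A command-line interface mirrors the library
(`mgstates screen|assign|score|shift|de|methyl|simulate-*`); run
`mgstates --help` for details.

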