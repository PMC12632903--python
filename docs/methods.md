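# Methods

This note documents the statistical models, their assumptions, the defaults
that matter, and the design choices that were genuinely open. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Sorted-screen enrichment

**Model.** A pooled CRISPRi library is sorted into a high and a low bin on a
marker stain and sequenced per bin. For sgRNA *i* with counts (h_i, l_i) and
raw bin totals (H, L), the phenotype is

    r_i = log2( ((h_i + c) / H) / ((l_i + c) / L) ),    c = 0.5

The pseudocount c guards individual zero counts; 0.5 is standard screen
practice and only matters for guides near zero in one bin. Under the null,
r_i is approximately normal with variance set by sequencing depth; all
between-guide abundance variation cancels in the ratio.

**Null.** The guide-level z is r_i / sd_NTC, where sd_NTC is the standard
deviation of non-targeting-control ratios after a single (non-iterative)
outlier pass removing NTCs with |z| > 5 against the initial sd. The z is the
ratio in NTC-sd units with no mean-centering — the retained-NTC mean is
reported as a diagnostic but not subtracted, matching the definition of the
statistic as a normalised log ratio. p-values are two-sided normal tails.

**Gene aggregation ("drop first").** Guides are ranked by |z| descending and
the top one discarded (with ≥ 2 guides; single-guide genes are kept whole
and flagged). This interprets the rule as an off-target guard: the most
extreme guide is the most likely single-guide artifact. The gene log2fc is
the mean retained ratio; the gene p combines the retained signed z values by
Stouffer's method, z_gene = Σ z_k / √m, which is exact under the normal null
used for the guide p-values and preserves direction.

**Quasi-genes.** n_quasi = 1000 random groups of NTC guides (group size =
the modal guides-per-gene, 5) are aggregated identically and enter the BH
family jointly with targeting genes, anchoring the FDR to an empirical
null. Quasi-gene groups are drawn without replacement within a group and
with replacement across groups, so the 1000 quasi-gene phenotypes are
dependent (they share guides from a 250-guide pool); their marginal
distribution matches a null targeting gene's, but two-sample tests that
assume independent draws (e.g. KS) are noisy on any single screen — the
calibration suite therefore summarises the KS comparison by its median over
20 simulated screens.

**Scores.** phenotype_score = log2fc × (−log10 FDR). The alternative literal
product log2fc × FDR (which inverts the ranking of strong hits) can be
emitted with `literal_phenotype_score=True` for compatibility with exports
that use that convention.

## Guide assignment

Per (cell c, guide g): p = upper-tail hypergeometric probability of the
observed guide UMIs k among the cell's n draws from a pool with K guide-g
UMIs of N total, and log-odds = ln[(k/(n−k)) / (K/(N−K))] — within-cell
odds over library-wide odds, the natural-log convention matching the
threshold of 1. Defaults follow the demultiplexing tool conventions: minimum
3 UMIs per cell, guides must appear in ≥ 100 cells (scale this down for
small simulations), log-odds > 1 and BH-adjusted p < 0.05. Assignment
requires the unique majority guide to pass and nothing else to pass;
majority ties and passing minority guides yield "ambiguous", which is how
doublets are excluded. The exact log-odds definition of the upstream tool is
not published; the pooled-frequency baseline used here is a stated choice
consistent with the hypergeometric pool framing. One consequence worth
knowing: with a very small guide library (≈ ≤ 10 guides) a ~30% minority
guide can sit just below the log-odds threshold, so balanced doublets are
only reliably flagged with study-scale libraries (tens of guides).

## QC and normalisation

Filters are applied in a fixed, reported order: cells by total counts
(≥ 200), cells by mitochondrial fraction (≤ 8%, inclusive at the boundary),
then genes by detection (≥ 10 cells). Mitochondrial genes are identified by
a configurable name prefix (default "MT-"). The stricter 1000-count
threshold used for deeper RNA-only runs is a configuration value, not a code
branch. Normalisation is value = log(1 + count · S / total) with S = 10,000
for both RNA and ADT; it commutes with cell subsetting and conserves
Σ expm1 = S per cell. Embedding steps (HVG/PCA/neighbors/Leiden/UMAP, batch
correction, cluster-based cell removal) are outside this package's scope;
the QC report retains barcodes so external blacklists can be applied.

## UCell signature scores

Per cell, all genes are ranked by decreasing expression with average ranks
on ties; ranks > r_max are clipped to r_max + 1; for a signature of n genes
with clipped ranks r_j,

    U' = Σ r_j − n(n+1)/2,    score = max(0, 1 − U' / (n · r_max))

r_max defaults to 1500, the published default for this scoring family; it is
configurable and should stay well below the number of expressed genes.
Because the score is rank-based it is invariant to monotone transforms of
the expression layer (raw and log-normalised values give identical scores).
Appending an all-zero gene leaves scores unchanged exactly when the
zero-expression tie block already lies past r_max — true for genome-scale
matrices, and the regime the property test encodes.

## Shift statistics

Per target × state, perturbed cells are compared to pooled NTC cells (the
NTC guides are pooled, matching the "versus non-targeting controls" design)
by median difference and a two-sided Mann-Whitney test; scipy's "auto"
method gives the exact distribution for small tie-free groups and the
tie-corrected normal approximation otherwise. BH runs over the full
target × state grid of one dataset. Groups under 2 cells are flagged with
p = NA and excluded from the BH family.

Percentile shifts use the mid-rank convention: a perturbed cell's percentile
is 100 × (fraction of NTC strictly below + half the tied fraction); the
shift is the median percentile − 50, bounded in [−50, +50]; the 95% CI is a
percentile bootstrap over perturbed cells with 1000 resamples (the interval
convention was open; the percentile bootstrap is the simplest estimator
consistent with "95% confidence intervals"). Percentile shifts require
≥ 20 NTC cells so the reference distribution is meaningfully resolved.

## Perturbation scores and weighted NB differential expression

**Initial effect.** Target vs NTC per-gene Wilcoxon rank-sum on
log-normalised values (the initial test is unnamed upstream; rank-sum is
robust and assumption-light), BH-corrected; the DEG set is FDR < 0.05 and
requires ≥ 25 target cells. The effect vector w holds mean normalised
differences on the DEG set.

**Score.** s_c = Σ_g w_g (x_cg − x̄^NTC_g) / Σ w_g² over DEG genes only
(genes outside the set cannot move the score); a cell at the NTC mean scores
0 and a cell at NTC mean + w scores 1. Raw scores are z-normalised by the
NTC raw-score mean/sd; reported NTC scores are fixed at 0 by definition.
Heatmap ordering uses max(score, 0).

**Weighted DE.** Per gene: counts ~ NB(μ), log μ = b0 + β·score +
log(total counts). The per-gene dispersion is method-of-moments on
depth-adjusted counts with a floor of 1e-8 (stable at the scales this
package targets; it is deliberately simple and slightly conservative when
real effects inflate the moment estimate). Cell weights enter the likelihood
(GLM frequency weights): 1 for NTC, max(score, ε)/mean for perturbed with
ε = 0.05 so weak or negative scores down-weight rather than delete cells;
the exact score→weight map is unpublished, so this monotone floor-and-
normalise form is a declared choice. All-equal weights reduce exactly to
unweighted NB DE. Wald p on β, BH per target; log2fc = β × mean perturbed
score × log2(e), the fitted fold change at the average perturbed cell.
Targets with no initial effect fall back to a standard two-group NB
regression. Two numerical notes: (i) β is exactly invariant to uniform
library-size rescaling when the offset is shifted or the dispersion held
fixed; re-estimating the dispersion from rescaled counts makes it invariant
only to ~1e-3; (ii) an effect vector whose signs all point one way is
partially absorbed by the library-size offset (composition bias) — an
intrinsic property of offset-based DE, not of the weighting.

## Protein-state correlations

Pearson r between each log-normalised ADT protein and each state score over
the cells shared by both modalities ("per-cell", since the correlations are
computed for all cells). Isotype-control antibodies are excluded via a flag
column and reported separately; proteins pair to genes through a supplied
protein → stable-gene-id map. Zero-variance vectors yield r = NA with a
reason.

## Fisher overlap

Two-sided Fisher's exact test on the 2×2 membership table over a gene
universe, with the conditional-MLE odds ratio. The universe defaults to the
genes detected in the corresponding matrix after QC (the appropriate
universe is analysis-specific and configurable; published overlap p-values
are sensitive to this choice, which is why none are treated as fixed
references here). Raw p is reported, with an optional BH column.

## Promoter methylation

Top/bottom-strand CpG records are summed onto the plus-strand cytosine
coordinate (the bottom-strand record at p+1 pairs with the cytosine at p);
loci under 3 reads are dropped per sample after strand-combining; technical
replicates are summed into one table per sgRNA, giving two samples per
condition. Coordinates: coverage files are 1-based inclusive, TSS BED is
0-based half-open; readers convert.

**Per-CpG test.** Each sample's methylation proportion is arcsine-sqrt
transformed (variance-stabilising for binomial sampling: var ≈ 1/(4n)); the
statistic is the difference of transformed group means over the pooled
binomial standard error, with a two-sided normal tail and BH across loci.
This is a deliberate closed-form replacement for smoothing-based
dispersion-shrinkage testers: it assumes binomial sampling within samples
and borrows no information across loci, so its p-values will diverge from
smoothed ones CpG-by-CpG (typically conservative where biological
between-sample variability is low, anti-conservative where it is high); the
simulation suite verifies its null calibration and power under binomial
truth. The reported effect stays on the proportion scale.

**Aggregation.** CpGs within the closed window [TSS − 500, TSS + 500]
(strand-independent window around the strand-aware TSS coordinate) are
aggregated per gene: mean difference, min p, min FDR, CpG count. Multi-TSS
genes use the union of their windows with each CpG counted once. Class:
hypo if min FDR < 0.05 and mean difference < 0; hyper if ≥ 0; ns otherwise.
Genes with no covered CpG are omitted. Note min-FDR aggregation is an
any-CpG rule: a single significant CpG flags the promoter, and the class
then follows the sign of the window mean.

## Synthetic data

The generators define the conditions under which the pipeline is validated.

*Screen*: guide abundances ~ Dirichlet(5) (moderate library skew); a gene
with logistic shift s sends its guides' cells to the high bin with
probability expit(s) instead of ½; bin counts are multinomial at 2×10⁶
reads per bin, the scale of the screens this models (1619 genes × 5 guides
+ 250 NTCs). Zero shifts give a calibrated null.

*CROP-seq*: NB counts (dispersion 0.3) over a lognormal expression profile
at ~5000 counts/cell; per-target DEG effect vectors (default 30 genes,
log-effect magnitude 1, random signs — composition-neutral) scaled by
per-cell knockdown multipliers ~ Gamma(4, ¼) (mean 1, CV ½ — graded CRISPRi
knockdown rather than on/off). State signatures are co-modulated by a
per-cell N(0,1) latent activity; ADT counts (dispersion 0.5) track a state
latent at a planted correlation, with the signal amplitude solved so the
planted r refers to the measured log-level (the generator absorbs its own
counting noise). Guide UMIs: ~Poisson(20) for the true guide(s), ambient
background multinomial over the library at rate × 20 UMIs, doublets carry
two true guides.

*Methylation*: per-CpG baselines ~ Beta(7, 3) (mean 0.7, typical for
promoters-plus-background averaging), truncated to the range compatible
with any planted difference; methylated reads ~ Binomial(coverage, p) split
across 2 samples × 2 technical replicates × 2 strands so the combine/merge
operations are exercised; per-slice coverage is Poisson(total/4).

What the generators do **not** emulate: UMI collisions and sequencing error,
batch and replicate structure, cross-cell covariance beyond the planted
latents, zero-inflation beyond NB, and real methylation autocorrelation
along the genome. Passing tests therefore demonstrate correctness of the
statistics under their stated sampling assumptions and planted truths, not
robustness to every artifact of real data.

## Problem sizes used in validation

The calibration and power checks run at the screen's native scale (20
simulated screens of 8,345 guides at 2×10⁶ reads/bin for both the null and
the planted-effect arm). Single-cell checks use 2,000 cells for assignment
accuracy, 400 cells/150 genes for NB effect recovery, 20 × 300-cell/100-gene
null runs for false-positive control, and 100 seeds of 300-cells-per-group
shift tests; methylation uses 200 promoters (50 with planted −0.4) over
~3,600 CpGs at 30× per-sample coverage. These sizes were chosen to estimate
each rate with comfortable margin at desk scale.

## Known limitations

- The screen p-values inherit the normal approximation of the guide z;
  heavy-tailed NTC behaviour beyond the |z| > 5 pass is not modelled.
- The per-CpG methylation test ignores biological between-sample dispersion
  (two samples per condition cannot estimate it); promoter-level min-FDR
  aggregation partially compensates by requiring only one strong CpG.
- Weighted NB DE estimates one coefficient per gene independently; no
  shrinkage across genes is applied.
- The guide-assignment log-odds baseline treats the library pool as the
  ambient model; droplet-specific ambient profiles are not estimated.
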