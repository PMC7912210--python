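# Methods

`methdx` implements an integrated methylome–transcriptome biomarker-discovery
workflow for two-group (case/control) blood cohorts profiled on an
Illumina-450K-style methylation array and a log2-scale expression array. This
note records the statistical models, the defaults and why they were chosen,
the synthetic-data generator's assumptions, and the numerical conventions.

## Differential expression

Input is an already-normalized genes × samples log2 matrix (background
correction, normalization and batch handling are upstream of this package).
Per gene, the effect is the case-minus-control mean difference (log2
fold-change) and the pooled within-group variance s² (d = n₁ + n₂ − 2 df) is
shrunk toward an ensemble prior by empirical Bayes:

    s²_post = (d₀·s₀² + d·s²) / (d₀ + d)

The prior degrees of freedom d₀ and prior variance s₀² are estimated from the
distribution of all per-gene variances by the log-variance moments method:
z = log s² minus its known sampling digamma/log terms has residual variance
trigamma(d₀/2), inverted by Newton iteration; the mean of the residuals gives
s₀². When the observed spread of variances does not exceed the sampling
spread, d₀ is infinite and all genes share s₀². The moderated
t = log2FC / SE(s²_post) is referred to a t distribution with d + d₀ df
(normal when d₀ = ∞). With moderation disabled the statistic reduces exactly
to the ordinary equal-variance two-sample t, which is how the implementation
is oracle-tested. Exact p-values from other moderated-t implementations may
differ in the third decimal because the prior estimator differs in detail.

P-values are two-sided throughout. Genes with missing values are dropped with
a warning. Differentially expressed genes (DEGs) require BH-adjusted p < 0.05
and |log2FC| > 0.2, both strict; the two gates are applied jointly after
adjustment (for this rule the order is immaterial). Benjamini–Hochberg
adjustment is the standard step-up with cumulative-min monotonicity
enforcement, order-preserving with the input.

## Differential methylation

Probe beta values are β = M/(M + U + a), with a = 100 stabilising
low-intensity probes; β ∈ [0, 1). Region-level summaries are unweighted means
of member CpGs per (gene, region, sample) over the six gene regions TSS1500,
TSS200, 5′UTR, 1stExon, Body, 3′UTR; gene-level summaries average all CpGs
annotated to the gene. A probe annotated to several genes contributes to each
of them; (gene, region) pairs with no CpGs are absent rather than zero.

Δβ is case minus control, so hypo-methylation in cases is negative.
Differentially methylated genes (DMGs) are called by a pooled decile rule:
the 0.1 and 0.9 empirical quantiles (linear interpolation between order
statistics — the quantile definition is a documented convention, since
several exist) of the combined Δβ vector of all genes *and* all intergenic
CpGs set the thresholds, and a gene must additionally reach a BH-adjusted
p < 0.05 from an equal-variance two-group linear model on its gene-level β
(no moderation here; the per-gene model is deliberately the plain one).
Intergenic CpGs act as an empirical null widening the decile thresholds.

Dominant regions: per gene, the region with the most extreme Δβ in the
gene's direction of differential methylation (argmin for hypo, argmax for
hyper), together with every region whose Δβ lies strictly within 0.005 β
units of that extreme — so a gene can have several dominant regions. The
direction-aware extreme is the default because "smallest Δβ" is ambiguous
for hyper-methylated genes; `extreme="signed-min"` gives the literal signed
minimum instead. Ties in the extreme are broken by the fixed region order
TSS1500, TSS200, 5′UTR, 1stExon, Body, 3′UTR.

## Integration and the published signature

DEG direction × DMG call yields four groups; the biologically concordant
ones under negative methylation–expression coupling are hypo-up
(hypo-methylated, up-regulated) and hyper-down. Region distributions count a
gene in every region whose region-level Δβ lies beyond the pooled decile
thresholds (region-resolved DMG status), so one gene can appear in several
region columns.

The published 46-gene hypo-up / 71-gene hyper-down blood signature for major
depressive disorder ships as checksummed plain-text fixtures, ordered by
expression-classifier importance. Both the raw printed symbols and
canonicalised symbols are stored; the canonical mapping repairs three
typographic artifacts of the source tables (`X4.SEP` → SEPT4, `NKX3.2` →
NKX3-2, `HLA.DQA2` → HLA-DQA2) and nothing else. Loading verifies a SHA-256
manifest and returns the lists in published order.

## Enrichment

A generic over-representation test: upper-tail hypergeometric
P(X ≥ overlap) per gene set, with population = universe size, successes =
set size, draws = query size; BH across sets; enriched iff adj_p < 0.05.
Term databases are user-supplied GMT files — which GO/KEGG release to use,
and whether the universe is the array complement or something narrower, is a
study-level decision the package does not make. The default universe is the
DE table's gene complement.

## Classification

Three feature views per signature: log2 expression, gene-level mean β over
all regions, and mean β over each gene's dominant regions only. Classifiers
are random forests (500 trees by default, √G features per split, fixed
seed); importance is mean decrease in impurity by default with permutation
importance selectable, ties in the ranking broken by gene symbol. Scaled
importance is min–max to [0, 100] (top = 100.00, bottom = 0.00; an all-equal
vector degenerates to zeros with a warning).

Features are added one-by-one in importance order; each prefix size k is
scored by leave-one-out cross-validation (n forests, each scoring only its
held-out sample) and the rank-based AUC of the out-of-fold case
probabilities: AUC = U/(n₁n₀) with ties counted ½, and a two-sided
tie-corrected normal-approximation rank-sum p-value against AUC = 0.5.
best_k is the argmax of the AUC curve, smallest k on ties.

The default protocol ranks importance once on the full data set and
cross-validates only the AUC — this replicates the published procedure but
leaks ranking information and is optimistically biased; `nested=True`
re-ranks within every training fold for the unbiased estimate. The two can
differ substantially on weak signals; reports state which protocol produced
them.

## Synthetic cohorts

The generator emulates a blood case/control study with paired methylation
and expression: bimodal 450K-like probe baselines (two Beta mixture modes,
promoter-proximal CpGs favouring the unmethylated mode, body/3′UTR/
intergenic CpGs the methylated one), log2 expression intensities
N(7, 2²) per gene, and planted effects under negative coupling: hypo-up
genes get Δβ = −`delta_beta_effect` in 1–2 randomly chosen regions (chosen
with probability proportional to CpG count, CpG-rich regions being the
likelier carriers) and log2FC = +`log2fc_effect`; hyper-down genes are
mirrored. Planted CpGs draw mid-range baselines (uniform on [0.3, 0.6]) so
the shift is not censored by clipping to [0, 1 − 10⁻⁶].

Methylation noise has three components, all with defaults in β units:

| component | default | role |
|---|---|---|
| `beta_dispersion` (per probe × sample) | 0.05 | technical/probe-level scatter |
| `beta_gene_sd` (per gene × sample) | 0.03 | biological variation shared by a gene's CpGs |
| `beta_subject_sd` (per sample, global) | 0.04 | subject-level drivers (e.g. cell composition) shared by every CpG |

The correlated components are what keep methylation classifiers imperfect at
the per-sample level even when group-level tests detect every planted gene:
independent probe noise averages away over a 20-gene signature, a shared
subject offset does not. Group-mean detection retains its √n advantage, so
with the default effect size (Δβ = 0.08, diluted at the gene level by the
planted-region fraction) DMG detection succeeds for most planted genes while
per-sample β separation stays partial — reproducing the qualitative pattern
of the real cohorts, where the expression classifier clearly outperformed
both methylation classifiers and the dominant-region view edged out the
all-region view. Because hypo- and hyper-shifted genes move in opposite
directions, classifiers given a mixed-direction gene set can cancel the
shared subject offset by contrasting them; evaluation therefore follows the
per-direction design (hypo-up and hyper-down signatures classified
separately), as the original protocol does.

Default cohort shape is 100 cases / 50 controls with 200 genes and 100
intergenic CpGs, matching the 2:1 design of the emulated methylation cohort.
By default expression and methylation share one sample set; `split_cohorts`
draws disjoint expression and methylation cohorts to mimic studies whose two
data types come from different populations.

What the generator does **not** model: raw-intensity (IDAT/CEL) artifacts,
batch effects, covariates (age/sex), probe cross-reactivity, genomic
autocorrelation of methylation beyond the gene/region structure, and any
dependence between a gene's baseline methylation and its expression level.
Passing recovery tests therefore demonstrates correctness of the pipeline's
logic under a plausible generative model, not performance on real arrays.

## Numerical conventions and edge cases

- Strict inequalities at every published threshold (adj_p < 0.05,
  |log2FC| > 0.2, Δβ beyond the deciles, dominant-region difference < 0.005).
- P-values are clipped into (0, 1] before BH; zero-variance genes get t = 0,
  p = 1 rather than NaN.
- A degenerate Δβ distribution (all values equal) yields quantile thresholds
  equal to that value and therefore zero DMG calls.
- Beta views reject values outside [0, 1); genes lacking dominant-region
  records are dropped from the dominant view with a warning.
- All randomness flows from a single integer seed via NumPy `SeedSequence`
  spawning; identical seeds give bit-identical studies and rankings.
- Pipeline outputs carry a header comment with version, seed and a
  configuration hash (output directory excluded, so relocated reruns remain
  bit-comparable), and a run manifest records SHA-256 checksums of every
  artifact.

## Problem sizes used in the shipped checks

The recovery analyses run on a 150 case / 75 control, 200-gene cohort with
10% hypo-up and 10% hyper-down planted genes; classifier comparisons run at
the default 100/50 cohort on the planted hypo-up signature with 200-tree
forests under full leave-one-out. These sizes give stable Monte-Carlo
estimates for the properties asserted (sensitivities, recovery rates, AUC
ordering) while keeping a complete run in the minutes range on one core.
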