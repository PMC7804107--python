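# Methods

## Synthetic count model

Counts are negative binomial with mean μ and shape r ("dispersion"):
Var = μ + μ²/r. Each gene belongs to one block — program A, program B,
shared, or background — and each cell to one state. Baseline genes have
mean `baseline_mean` (default 0.5, a realistic per-gene UMI load that
produces the zero inflation the binarization stage relies on); a
stimulated cell's own program genes are induced `induction_fold`-fold
(default 4); shared genes are induced by either stimulus at the geometric
mean of the two folds (this exercises the shared-set logic without an
extra parameter). Co-stimulated cells are a mixture of A-dominant,
B-dominant and mixed cells in exact planted fractions (largest-remainder
rounding, then a seeded shuffle). In a dominant cell the opposing
program's mean is `baseline · (1 + (fold − 1) · cross_inhibition)`:
`cross_inhibition = 1` means no inhibition, 0 full silencing. Dropout is
not modeled separately — NB sampling at low means already yields it.

Defaults (1500 cells/condition, 1000 genes of which 200 + 200 program,
50 shared) are the desk-scale study conditions used throughout; they keep
the induced programs a modest fraction of the transcriptome, which
matters for normalization (below). The generator does **not** emulate
batch effects, doublets, ambient RNA, or realistic transcriptome-wide
mean/dispersion distributions, so passing tests demonstrate correctness
of the analysis chain on data with the assumed statistical structure, not
robustness to those artifacts.

## Normalization and its compositional bias

Size factors are median-scaled library sizes, sf_i = total_i /
median(totals) (median exactly 1), with values ln(x/sf + 1). This is a
deliberate simplification of pooled-deconvolution size factors: it is
closed-form, exactly testable, and preserves every downstream contract.
Two consequences are worth knowing. First, size factors are invariant to
rescaling all cells by a common constant, so the *values* shift
predictably rather than staying fixed. Second, library-size factors
carry the usual compositional bias: a cell that induces both programs
has a larger total, so all its per-gene values are deflated relative to
a single-stimulus cell. With program genes a small fraction of the
transcriptome (the default geometry) this shift stays well below the
1.5-fold DE threshold; when program genes dominate the transcriptome it
can masquerade as weak cross-inhibition.

## Differential expression and core genes

Per gene, a two-sided Wilcoxon rank-sum test on normalized values, using
the tie-corrected normal approximation with continuity correction;
genes constant across both groups get p = 1. BH correction is applied
across all genes of a comparison (it agrees exactly with the literal
step-up rule; this is asserted against a brute-force oracle). Fold
change is the ratio of de-logged normalized means with a 1e-9
pseudocount. Core genes require fold change ≥ 1.5, FDR ≤ 0.05 and
detection (count ≥ 1 — the minimal reading of "expressed") in ≥ 15 % of
the stimulated cells; down-calls use the symmetric rule 1/FC ≥ 1.5.
Cross-regulation labels come from the same test applied to co-stimulated
versus own-single-stimulus cells over all genes, then read off at the
UCGs.

## Noise and scores

Fano factors use population moments (ddof = 0) on size-factor-scaled
*linear* counts — log transforms destroy the Poisson calibration F = 1.
A caveat discovered in closed form: for an NB with strong intrinsic
overdispersion, a 50/50 on/off mixture does *not* always raise the Fano
factor relative to full induction — at μ = 2, r = 0.5 the mixture gives
F = 4.85 vs 5.0. The between-mode term (μ₁ − μ₀)²/4 dominates only when
induction is strong relative to 1/r; the noise-shift tests therefore
plant 16-fold induction, where the predicted shift (19.4 vs 17) is
clearly positive. Spearman p-values use the t-approximation on
tie-corrected ranks; constant genes are flagged and their pairs recorded
as ρ = 0, p = 1.

The UCG score is the mean normalized expression over the UCG set minus
the mean over `50 × |UCG|` background genes sampled uniformly (seeded)
from the non-UCG genes. The score formula is a declared choice — it
follows the common control-gene-set construction — and `n_background=0`
gives the plain set mean. Gene sets are processed in sorted-name order on
contiguous arrays, so scores are bit-identical under column permutation.

## Odds ratios

RNA binarization is inclusive (positive iff count ≥ 2); secretion calls
are strict (> threshold), since the threshold percentile itself is
background. For each pair, OR = (n₁₁·n₀₀)/(n₁₀·n₀₁); if any cell is
zero, 0.5 is added to all four cells (Haldane–Anscombe) so log₂(OR)
stays finite for display and masking, and the pair is flagged. The
two-sided Fisher exact p is always computed on the *uncorrected* table
(probability-mass definition, verified exactly against exhaustive
fixed-margin enumeration for all tables with total ≤ 40). Masking sets
log₂(OR) to 0 where p > 0.05; no multiplicity correction is applied
across pairs, and the p matrix is exposed so users can apply their own.

## Dominance classifier

Two binary MLPs (hidden layers (64, 32, 16) — small enough to train on
thousands of cells, large enough to be non-degenerate — tanh activation,
Adam, max 300 iterations), each preceded by per-feature standardization
fitted on the training split. Features are normalized values of either
all genes or the cross-inhibited UCGs (falling back to all UCGs, with a
warning, when no inhibition was detected). The training universe is the
single-stimulus cells *plus control cells as negatives* (configurable).
The control negatives are essential, not cosmetic: with only A-vs-B
training the classifiers are pure discriminators and their response to
cells expressing both programs is unidentifiable — planted mixed cells
then scatter across all four labels. With unstimulated negatives each
classifier must detect the *presence* of its program, and mixed cells
land positive for both. Decision threshold 0.5 on the positive-class
probability (inclusive); the composite label follows (+,−) → A-dominant,
(−,+) → B-dominant, (+,+) → mixed, (−,−) → unclassified. Held-out
accuracy (stratified 80/20 split) and stratified k-fold CV accuracy are
both reported, per classifier.

## Secretion chain

The "moving Gaussian" background is operationalized as, per analyte, the
Gaussian-MLE location (mean) of the `window` (default 50) zero-cell
wells nearest in row-major array order — a contiguous run of the ordered
zero-cell wells centred on the well — subtracted from the raw intensity.
Deviations are accumulated from a reference value so a constant
background normalizes to exactly zero. Window size, ordering and the
subtracted statistic are declared choices; the residual on a linear
drift is bounded by slope · window/2. Thresholds are the 99th percentile
(linear interpolation between order statistics) of normalized zero-cell
wells; the arcsinh transform uses the cofactor-as-divisor convention
asinh(x / (0.8·threshold)), strictly monotone, so calls commute with the
transform. Only single-cell wells (live-cell count exactly 1) enter
calls, fractions, odds ratios and clustering.

Consensus clustering sweeps k-means plus agglomerative clustering with
{average, complete} linkage × {euclidean, cosine} distance over
k = 2…12; the co-occurrence matrix (fraction of partitions placing two
wells together) is linked by average-linkage agglomerative clustering on
1 − co-occurrence, cut at 0.5 (configurable; not published for the
original pipeline). The k range extends to 12 because low-k partitions
systematically merge related profiles and drag pairwise co-occurrence
above the cut; a sweep reaching ~2× the expected number of profile
groups resolves them. Consensus clusters with fewer than 3 members are
discarded (wells labeled −1). Affinity propagation, spectral and Birch
are not in the default sweep, keeping it deterministic and fast. A chip
whose wells are all identical short-circuits to a single unanimous
cluster. The default simulated profile panel (three inflammatory-type,
one resolving, one mixed, remainder silent, on a 5-analyte panel with
IL6/Chi3l3 forced exclusive) mirrors the qualitative structure of a
co-stimulated macrophage secretion experiment.

## Problem sizes and reproducibility

Test and acceptance runs use desk-scale sizes chosen as the package's
study conditions: 500–2000 cells per condition, 300–1000 genes, chips of
2000–5000 wells, 200-replicate null calibrations. Every stochastic step
(generators, background sampling, MLP initialization, splits, k-means)
is seeded; same seed ⇒ byte-identical generator output and identical
fitted weights.

## Known limitations

- Library-size normalization's compositional bias (above).
- Fisher masking at raw p = 0.05 inherits the discreteness of small
  tables (slightly conservative rejection).
- The dominance labels depend on the declared 0.5 decision threshold;
  near-threshold cells flip labels under resampling.
- The consensus cut at 0.5 and the k sweep are defaults, not estimates;
  strongly overlapping secretor profiles can still merge.
- The generators plant idealized structure; none of the results here
  certify behavior on real droplet scRNA-seq or chip data.
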