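# Methods

`neurescence` identifies senescent neurons in single-nucleus RNA-seq
data from the coordinated over-expression of three senescence gene
panels, then characterises them: minimal marker-gene pairs via small
decision trees, differentially expressed genes via two independent
tests, and pathway-level structure via exact set-overlap statistics.
This note records the models, the parameters that matter, and the
design decisions taken where more than one reasonable choice existed.

## Eigengene scoring

An *eigengene* summarises a gene panel as the first principal component
of the panel's expression: a weighted average of member-gene expression,
one score per cell.

**Expression scale.** Counts are transformed to `log2(CPM + 1)` before
scoring (CPM = counts per million: each cell's counts scaled to a
library of 10^6). The raw-count scale is available via
`expression="raw"`; log-CPM is the default because principal components
of raw counts are dominated by a handful of highly expressed genes and
by library-size variation.

**Cell-type balancing.** Neuronal data are dominated by excitatory
cells (roughly 4:1 over inhibitory). Each cell is weighted by
`N_total / N_type(cell)`, so every cell type contributes equal total
weight to the component. The weighted PCA is realised as: per-gene
weighted mean/sd standardisation, scaling each cell's standardised
profile by sqrt(weight), and taking the leading right-singular vector —
algebraically identical to the top eigenvector of the weighted
covariance matrix, which the tests verify against an explicit
eigendecomposition oracle.

**Scores and orientation.** Reported per-cell scores are the
*unweighted* projections of the standardised data onto the loadings:
the weights shape the component, not the reported scores. The
eigenvector sign is arbitrary, so loadings are oriented such that the
average correlation between scores and member-gene expression is
non-negative; "high score" then always means "high panel expression".

**Projection.** A validation dataset is scored with the discovery
loadings, centers and scales, and the projected score vector is rescaled
to the *same Euclidean norm* as the discovery scores (`norm_mode=
"literal"`). This literal rule is dataset-size sensitive — duplicating
every cell divides each score by sqrt(2) — which the test suite
documents; `norm_mode="per_cell_rms"` offers the size-corrected
alternative. Genes missing from the validation data are dropped with a
warning; zero-variance scales are clamped at 1e-12.

## Consensus labeling

For each panel, a cell is positive when its score strictly exceeds the
discovery mean plus three standard deviations, negative when strictly
below the mean, and borderline otherwise (ties are borderline, since
the rule is a strict inequality). The consensus calls a cell
*senescent* only when all three panels are positive and *non-senescent*
only when all three are negative; every other cell is borderline and
excluded from downstream training and evaluation. Validation datasets
are labeled with projected scores against the *discovery* thresholds.
The threshold multiplier (3) and the negative cut (the mean) are
parameters. Cell-type enrichment of the senescent set uses the
upper-tail hypergeometric law over all labeled cells; the reference
population for this test is genuinely ambiguous (all cells vs. all
neurons vs. non-borderline neurons), so the functions take the
population explicitly and default to all labeled cells.

## Dual differential expression

DE runs on excitatory, non-borderline cells: genes are kept when they
have a count of at least 1 in at least 200 cells; expression is
log2-CPM; the minority (senescent) class is upsampled by
`r = round(n_majority / n_minority)` so the groups appear roughly equal.

**Hurdle test.** A two-part likelihood-ratio test per gene: a 1-df
binomial G-test of the detection proportions against the pooled
proportion (with 0·log 0 = 0), plus a 1-df Gaussian LRT
`n · ln(RSS0 / RSS1)` on the positive-expression cells, computed only
when each group has at least two positive cells. Statistics and degrees
of freedom are summed; p-values come from the chi-square. Condition is
the sole covariate; a cellular-detection-rate covariate is a known MAST
refinement that is deliberately omitted here. log2FC is the group mean
difference over all cells (positive = higher in senescent). A gene is
declared DE at BH-adjusted p < 0.01 and |log2FC| > 6. Null calibration
is part of the acceptance suite: on effect-free synthetic data the
type-I error at alpha = 0.05 stays within [0.035, 0.065].

**EMD test.** Per gene, the two groups are histogrammed on 100
equal-width bins spanning the pooled range; the Earth Mover's Distance
is the L1 distance between the normalised CDFs in bin units (the exact
optimal-transport cost for 1-D equal-mass histograms, verified against
an independent transport oracle). Significance is by label permutation.
Permutations act on original cells and are re-expanded: uniform
upsampling leaves normalised histograms unchanged, so replicated cells
never straddle groups. When the number of distinct label assignments is
at most `n_perm + 1`, the full enumeration is used and the p-value is
exact. A per-gene permutation p-value cannot fall below
`1/(n_perm + 1)`, which a BH threshold of 0.01 across thousands of
genes can never clear at practical permutation counts; `null="pooled"`
therefore pools the permutation EMDs across genes (resolution
`1/(n_perm · n_genes)`), and the pipeline demo uses it. A gene is
declared DE at adjusted p < 0.01 and EMD > 30; the EMD threshold is on
the bin-unit scale and configurable, as is the bin count. The upstream
SigEMD method wraps this EMD-plus-permutation core in a
dropout-imputation/Lasso stage that is intentionally not reproduced.

**Intersection.** The final DE set is the intersection of the two
methods' significant genes; its size is tested with the upper-tail
hypergeometric law over the filtered gene universe, computed in log
space so extreme significance (e.g. below 1e-205) is reported as
log10(p).

## Marker-pair decision trees

Small C4.5-family trees select minimal marker pairs: splits maximise
the information gain ratio over observed integer thresholds
(`x <= t`), a split is admissible only when both branches hold at least
`min_cases` cells, depth is capped at 2, and if a fitted tree uses more
than two distinct genes `min_cases` is doubled until it does not —
mirroring how a minimum-cases parameter, set large, caps tree size.
Ties between equal-gain splits resolve to the lowest gene index in pool
order, then the smallest threshold, making refits deterministic. Leaf
classes are the majority label (ties default to non-senescent). In
binary mode any count above zero becomes 1, so every threshold is 0 —
the regime preferred for histology-style markers that should be absent
from negative cells. Trees are trained on the raw (non-upsampled)
class distribution by default: training on the balanced multiset makes
the majority label inside marker-positive branches flip to senescent,
turning the learned rule into a disjunction with visibly degraded
specificity, which contradicts the perfect-specificity regime the
binary marker pair is designed for; an `upsample` flag restores the
balanced variant. Evaluation against eigengene consensus labels
excludes borderline cells; accuracy is `(tp + tn)/total`, with the
literal `tp/total` variant behind a flag. The elimination analysis
refits after removing each round's selected genes, evaluating every
round on all validation datasets with frozen thresholds.

## Set statistics

All tail probabilities are accumulated from log-gamma terms, and
results below double-precision underflow are returned as log10(p)
alongside p. Pathway over-representation intersects each pathway with
the user-supplied universe (default: the post-filter gene set) and
applies BH across pathways at 0.05. The multi-set intersection test
treats each set as uniformly placed in the universe: the running
intersection size is a Markov chain with hypergeometric transitions,
and convolving those conditional laws gives the exact distribution of
the k-fold intersection; for k = 2 it reduces to the plain
hypergeometric tail. Benjamini–Hochberg is used wherever adjusted
p-values are required.

## Synthetic data: what it emulates, and what it does not

The generator produces negative-binomial (gamma–Poisson) counts with
log-normal per-cell size factors; dropout arises from low means rather
than a separate zero-inflation term. Defaults define the study
conditions used throughout the tests:

| parameter | default | rationale |
|---|---|---|
| `n_cells` | 20,000 | discovery-cohort scale at desk size |
| `cell_type_proportions` | 0.79 exc / 0.21 inh | observed neuronal mix |
| `senescent_fraction` | 0.01 | rare planted subpopulation (within excitatory cells) |
| `n_genes` | 3,000 | panels stay a small fraction (~6%) of the transcriptome, as in real data, so the panel shift does not distort library sizes through CPM |
| `panel_sizes` | 22 / 44 / 116 | the three senescence panels as represented in neuronal data |
| `baseline_mean` | 2.0 counts/cell (log-normal, sd 1.0) | expressed genes that survive a 200-cell detection filter |
| `dispersion` | theta = 3 | moderate overdispersion typical of expressed genes |
| `panel_log2_shift` | 2.0 | coordinated panel up-shift in senescent cells |
| `de_log2_shift` / `de_baseline_mean` | 7.0 / 0.05 | DE genes near-silent at baseline — a log2FC above 6 on the CPM scale is only attainable for genes that switch on |
| `marker_p_on` / `marker_p_off` | 0.95 / 0.01 | near-binary marker pair; positive counts are 1 + Poisson(1), i.e. detectable but low |
| `library_size_sd` | 0.2 | modest depth variation after quality filtering |

One seed governs everything through per-stage sub-streams, so identical
(config, seed) pairs are byte-identical; `gene_param_seed` can pin the
gene-level parameters so replicate cohorts (same genes, fresh cells)
can be simulated for reciprocal-validation studies.

Deliberately not emulated: batch effects, doublets, ambient RNA,
cell-type-specific expression programs, and heterogeneous per-gene
panel responses — the planted panel shift is uniform across member
genes. The last point means eigengene *loadings* on synthetic data are
nearly constant across genes; their mean-centred Pearson correlation
between replicate cohorts is therefore noise-dominated even when the
orientation-aligned cosine concordance exceeds 0.95, and the
reproduction script reports the cosine for this reason. Passing tests
demonstrate the statistical machinery recovers planted structure under
these idealised conditions; they do not certify performance on real
tissue, where panel responses are heterogeneous and confounded.

## Numerical choices and degenerate inputs

Ties at labeling thresholds are borderline. Zero-variance genes are
dropped at fit time (warning) and clamped at projection time. Cells
with zero total counts are a hard error for CPM. A gene detected in no
cell gets p = 1 and log2FC = 0, flagged. Degenerate pooled ranges give
EMD = 0, p = 1. Tree leaf-class ties default to non-senescent. The
G-statistic is clipped at 0 against floating-point cancellation.
Permutation p-values use a 1e-12 tolerance when comparing EMDs so
floating-point ties count as ties.

## Problem sizes used in the reproduction script

The script runs the full pipeline at the default study conditions
(20,000 cells x 3,000 genes), a 4,000-cell projected validation cohort,
a replicate cohort for reciprocal validation, a 2,600-gene / 300-cell
null calibration, and exact tail computations at the reference cohort
sizes (44,172 neurons; 475/16,871 classes; 375/576/324 DE sets over
10,768 genes). Everything derives from the single `--seed` argument.
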