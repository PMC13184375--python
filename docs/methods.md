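# Methods

This note documents the statistical model, the defaults, and the numerical
conventions of `atrophyclust`, and states what the synthetic-cohort tests
do and do not demonstrate about real imaging data.

## w-score normalization

For voxel $v$ and subject $i$ with covariate row $x_i$ (intercept, age,
sex, total intracranial volume, scanner manufacturer), the reference model
is the per-voxel OLS fit on $n$ cognitively unimpaired controls,

$$ y_{iv} = x_i^\top \beta_v + \varepsilon_{iv}, \qquad
   w_{iv} = \frac{y_{iv} - x_i^\top \hat\beta_v}{\hat\sigma_v} . $$

All voxels are fitted simultaneously through one least-squares solve.
Choices and conventions:

- **Residual-SD denominator.** $\hat\sigma_v$ uses the residual degrees of
  freedom $n - p$ by default (configurable to $n$). With $n - p$, w-scores
  of *new* subjects drawn from the reference population are nominally
  unit-variance; applied to the fitting cohort itself the per-voxel mean is
  exactly 0 and the ddof-0 SD is $\sqrt{(n-p)/n}$ — both asserted in tests.
- **Covariate encoding.** Sex and scanner are 0/1 columns when the
  reference has two levels; more levels become one-hot against the first
  sorted level. A prediction-time level unseen in the reference raises.
- **Degenerate voxels.** Voxels with $\hat\sigma_v < 10^{-6}$ are set to
  $w = 0$ rather than dropped, keeping matrix geometry identical across
  cohorts; the model reports them in `low_variance_mask`.
- **Analysis mask.** Per channel, voxels with mean reference tissue
  probability ≥ 0.1. Gray and white matter are w-scored with separate
  models and concatenated ("stacked") afterwards.
- **Smoothing.** Isotropic Gaussian, FWHM 8 mm by default,
  $\sigma = \mathrm{FWHM}/(2\sqrt{2\ln 2})$ in voxel units, replicate-edge
  boundary handling (a constant volume is exactly preserved and
  interior-supported signal keeps its sum). Whether smoothing precedes or
  follows w-scoring is a config flag (`smooth_before_wscore`, default
  true), since either order is defensible.

## Sampling adequacy and PCA

The overall KMO index is
$\sum r_{ij}^2 / (\sum r_{ij}^2 + \sum q_{ij}^2)$ over off-diagonal pairs,
with partial correlations $q$ from the inverse correlation matrix. Because
inverting a voxels-by-voxels correlation matrix is infeasible, KMO is
computed on a seeded random subsample of 500 masked voxel columns
(near-constant columns excluded); with more variables than subjects the
partial correlations fall back to a pseudo-inverse, with a warning. The
0/0 case (identity correlation) is defined as 0 — "no sampling adequacy" —
with a warning.

PCA is the thin SVD of the column-centred matrix (equivalent to the dual /
Gram-matrix eigendecomposition; never forms a voxel covariance). Retained
components are those explaining at least `min_var_frac` (default 1%) of
total variance; no fixed component count is imposed, because the retained
number is a property of the data. Loading signs are fixed by making each
component's largest-magnitude loading positive, so outputs are
deterministic across platforms.

## Consensus clustering ensemble

Patient component scores are compared with Manhattan (L1) distance. Two
hierarchical algorithms enter the ensemble:

- **Agglomerative** ("hc"), average linkage by default (configurable),
  with the dendrogram cut at exactly K clusters.
- **DIANA**, implemented from the classical divisive-analysis description:
  repeatedly split the cluster of largest diameter by seeding a splinter
  group with the object of maximal average dissimilarity and moving
  objects while any is closer on average to the splinter than to the
  remainder. Both implementations reproduce R's `stats::hclust` /
  `cluster::diana` partitions on randomized instances (frozen
  cross-checks in the test suite).

Each of 10 replicates draws ⌈0.8 n⌉ patients without replacement (one
seeded draw shared by both algorithms, which reduces ensemble variance).
The consensus matrix holds co-clustering frequencies among co-sampled
pairs; the final partition is an average-linkage recut of
`1 − consensus` at K (a CSPA-style combination chosen because it needs no
label alignment and is deterministic — other consensus functions exist and
could give different partitions on ambiguous data). Pairs never co-sampled
get an uninformative 0.5; a subject never co-sampled with anyone is imputed
from its nearest neighbour in score space. All tie-breaks resolve to the
lowest subject index; final labels are renumbered in order of first
occurrence. A single root seed drives the whole ensemble; stage-level
sub-seeds are derived deterministically from it.

Exact permutation invariance of the final partition holds when the
consensus matrix is tie-free (e.g. binary, as with a single algorithm at
full sampling); when algorithms disagree, tied consensus values make the
recut order-dependent, which is inherent to consensus recutting.

## Cluster number, stability

The Calinski–Harabasz index is computed in Euclidean component-score
space (the standard definition), even though the ensemble clusters on
Manhattan distance. `select_k` reports CH and the assignment for each
candidate K ∈ {2, 3, 4} and flags the maximum but never silently picks:
the index measures separation only, and a user may prefer a different K on
substantive (e.g. clinical) grounds; any override is logged in the run
provenance.

Leave-one-out stability re-runs the complete ensemble with each patient
withheld (fold-specific derived seeds) and compares against the
full-cohort partition on the shared subjects with the Rand and adjusted
Rand indices; the summary is the median with the interquartile range,
clearly labelled as such.

## Characterization

- **Atrophy contrasts.** Per-voxel GLM `[intercept, group, age, sex,
  scanner]` on the (smoothed, masked) tissue maps, t statistic for the
  group term. TIV is deliberately not a covariate at this stage — it
  belongs to the w-scoring model; the contrast stage adjusts only age, sex
  and scanner. Family-wise corrections: permutation max-T (default 1,000
  seeded group-label permutations, exact under exchangeability; the
  corrected p uses the +1 convention, and corrected p ≥ uncorrected p
  always), Bonferroni at 0.05 as a fast alternative, or uncorrected
  p < 0.001. Random-field-theory correction is not implemented.
- **Clinical profiles.** Kruskal–Wallis with the standard tie correction
  per measure (rows with missing values dropped per measure; an all-tied
  measure returns H = 0, p = 1 with a warning); pairwise comparisons use
  unadjusted Wilcoxon rank-sum tests, with p ≥ 0.05 flagged "ns". The
  pairwise procedure is an assumption, documented, not a multiplicity-
  corrected post-hoc family.
- **Composition tables.** Cluster-by-diagnosis counts with nearest-integer
  row percentages that always recompute from the counts; diagnosis groups
  can be merged (e.g. an apraxia-of-speech group pooling AOS-PAA and
  PPAOS).

## Synthetic cohort generator

The generator emulates the *input structure* of a template-space
voxel-based morphometry study: per-subject gray and white
tissue-probability maps (independent noise per channel), a covariate table
(age ~ U(55, 80), sex ~ Bernoulli(½), TIV ~ N(1400, 120²) ml, scanner ~
Bernoulli(½)), and a clinical table mirroring a standard dementia battery
(MoCA, MDS-UPDRS III, PSP rating scale, ASRS, FAB, BNT, letter fluency,
WAB subscores, PPT), each clipped to its instrument range.

Voxel values are `baseline + covariate terms + N(0, noise_sd)`, clipped to
[0, 1]; patients additionally lose `effect_size × noise_sd` inside their
subtype's template — disjoint interior cuboids along the first grid axis.
Defaults: 16×16×16 grid at 2 mm, 100 controls, 3 subtypes × 40 patients,
noise SD 0.05, effect size 2, and small realistic covariate coefficients
(age slope −0.002/yr, sex offset 0.01, TIV 0.02 per SD, scanner offset
0.01). These sizes mirror a three-cluster cohort at desk scale while
keeping the full test suite under a minute per pipeline run.

What it does *not* emulate: registration error, spatially varying
anatomy/baselines, spatially correlated noise, partial-volume effects,
overlapping or graded atrophy patterns, site-by-covariate interactions.
Passing tests therefore demonstrate the correctness and calibration of the
algorithms under the stated generative model, not clustering performance
on real MRI, where separations are far weaker and noise is structured.

One consequence worth noting: because the generator's covariate effects
are global (they move every voxel coherently) while the subtype signal is
focal, raw-map clustering on the default cohort is visibly dragged toward
the confounds, and the raw-vs-w-scored Rand index is well below 1. With
covariate effects set to zero the two partitions agree almost perfectly,
and with a large scanner offset and no subtype signal the raw partition
tracks the scanner while the w-scored one does not — both shown in tests.

## Problem sizes and numerical conventions in the test suite

Tests and the acceptance script use: the default 120-patient cohort for
end-to-end recovery and K selection (5 seeds); a 60-patient separable
cohort for leave-one-out stability; 200 reference subjects (100 fit /
100 held out) for w-score calibration; 200 null simulations of 30
subjects × 256 voxels for family-wise-error control; and ≤ 8-point
instances for exhaustive algorithm-trace comparisons. Oracle agreement is
asserted at 10⁻⁸ (formulas) to 10⁻¹² (distances); statistical checks use
seeded simulations with binomial or Kolmogorov–Smirnov tolerances stated
inline.

## Known limitations

- The consensus-function and linkage choices inside published ensemble
  wrappers vary; a different consensus combination can yield different
  partitions on data without clear structure.
- KMO on a voxel subsample estimates, but does not equal, the full-matrix
  index, which is computationally out of reach.
- Permutation max-T assumes exchangeability of group labels given the
  covariates; strong covariate imbalance between groups weakens this.
- PCA is linear; nonlinear embeddings are out of scope.
- The CLI's staged workspace stores dense matrices (NPZ); very large
  cohorts should use the library API with memory-mapped inputs instead.
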