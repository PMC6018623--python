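# Methods

`lesionlab` is a simulation laboratory for lesion-deficit mapping. It
generates synthetic lesion cohorts with controllable spatial structure,
plants a known ground-truth functional anatomy, and measures how faithfully
two families of inference recover it: mass-univariate voxel-wise testing
(the VLSM tradition) and high-dimensional multivariate modelling (a linear
SVM over all voxels jointly). Because the ground truth is known exactly,
the spatial error of each method is measurable in millimetres, and its
predictive value measurable as out-of-sample ROC performance.

## The core argument being quantified

Lesions are not random scatter. In ischaemic stroke — the dominant source
of focal lesions — which voxels are infarcted together is dictated by the
branching vascular tree, so the voxel-voxel damage covariance is strongly
structured. A voxel-wise test knows nothing of this: voxels collaterally
damaged alongside a truly critical voxel ("parasitic" voxels) acquire
deficit associations of their own, and the centre of mass of the
significant cluster is dragged away from the critical site in a direction
set by the vasculature, not the functional anatomy. Repetition entrenches
rather than cures this, because it is bias, not noise.

The package operationalises this with three experiments:

1. **Mislocalisation field.** For every voxel `t` hit more than `min_hits`
   times in the cohort, label each lesion "affected" iff it covers `t`
   (a noiseless single-voxel ground truth), run the voxel-wise Fisher
   exact test over all eligible voxels, threshold at a
   Bonferroni-corrected alpha, and record the vector from `t` to the
   significant cluster's unweighted centroid. Under spatially random
   single-voxel lesions this error is identically zero; under
   tree-structured lesions it is positive and its direction field traces
   the vascular territories.

2. **Volume-bias map.** At each eligible voxel, Bayesian logistic
   regression of the damage indicator on standardized log lesion volume
   yields an odds ratio per SD of log-volume. The map varies strongly and
   systematically across the synthetic brain, which is exactly why
   entering lesion volume as a covariate in a voxel-wise model
   redistributes bias rather than removing it.

3. **Outcome prediction.** A two-region ground truth (deficit with
   probability 0.9 when at least 20% of either region is damaged) is
   fitted on repeated random 70/30 splits by (a) the Fisher-exact p-field
   plus Fisher's-method scoring of held-out lesions and (b) a linear SVM
   on the binary damage matrix, and compared by averaged ROC curves.

## Statistical machinery

**Fisher's exact test.** Two-sided p by summing hypergeometric
probabilities of all tables with the observed margins no more probable
than the observed table (relative tie tolerance 1e-7, the standard
convention). The engine is a vectorized enumeration with per-margin-pair
memoised tables, because the mislocalisation field needs on the order of
V² tests; it agrees with integer-arithmetic brute-force enumeration to
<1e-12 on every table with total ≤ 30, and with `scipy.stats.fisher_exact`
on random tables. A chi-squared variant with Yates continuity correction
is available (`variant="asymptotic"`), since VLSM practice often blurs
"exact test" with its asymptotic p-value; the exact variant is the
default. Degenerate margins return p = 1.

**Eligibility and correction.** Voxels hit strictly more than `min_hits`
(default 3) times are tested. Bonferroni divides alpha (default 0.01) by
the number of *tested* voxels — untested voxels raise no hypotheses. The
significant "cluster" is the full supra-threshold set (no connected
component analysis), and its centroid is the unweighted mean of member
voxels' world (mm) coordinates; a −log10(p)-weighted centroid exists as an
option but is off by default. Empty clusters are flagged per target voxel
and excluded from magnitude summaries, never interpolated.

**Fisher's-method scoring.** For a held-out lesion, the tested voxels it
covers with training p < 0.001 (uncorrected; deliberately lenient so
weakly significant voxels still contribute) are combined as
X = −2 Σ ln p ~ χ²(2k); the score is −log10 of the upper tail. The tail is
evaluated on the log scale, switching to the upper-incomplete-gamma
continued fraction where `scipy`'s `logsf` underflows, so extreme evidence
yields finite, ordered scores. A lesion covering no sub-threshold voxel
scores 0.

**Linear SVM.** `C = base^cost_exponent` with base 2 and exponent −14 by
default, following the dominant grid-search convention in which the cost
parameter is quoted as a power-of-two exponent (so −14 means C = 2^−14);
the base is configurable. Features are raw
binary voxels restricted to voxels hit at least once in training (zero
columns carry no information; their weight is zero either way — this
restriction is an assumption, flagged as such). No scaling, smoothing, or
dimensionality reduction. The problem is convex; solver tolerance 1e-6
with a hard iteration cap whose breach raises. Positive decision scores
mean deficit.

**ROC averaging.** Per iteration, the ROC sweeps all unique scores (ties
share a threshold); AUC is trapezoidal, identical to Mann-Whitney
concordance with ties counted ½. Curves are averaged vertically on a
101-point FPR grid. Two uncertainty summaries are reported: the 2.5/97.5
percentile spread of per-iteration values (`auc_ci`, also used for the
pointwise TPR bands, widened where necessary so they bracket the mean
curve), and the normal-approximation 95% CI of the *mean* AUC
(`auc_mean_ci`), the construction conventionally drawn alongside a mean
ROC curve. Deficit labels are drawn once per cohort; iterations
vary only in the split. Splits that leave a class absent from either half
are resampled with bounded retries.

**Bayesian logistic regression.** MAP estimation with independent
Cauchy(0, 2.5) prior on the standardized slope and Cauchy(0, 10) on the
intercept — the standard weakly informative default for logistic
coefficients — by damped Newton iteration, with Laplace (curvature) 95%
intervals. The heavy-tailed prior leaves well-identified slopes
essentially untouched (the fit matches unpenalized ML on ample data) while
keeping the mode finite under complete separation; voxels with all-equal
outcomes are flagged as prior-dominated, not dropped. Volume enters as
standardized log mm³; the transform, prior, and interval construction are
this package's own defaults, exposed in config rather than fixed by any
community standard. Standardization makes the map invariant to rescaling
all volumes by a constant.

## The synthetic cohort generator

The generator is a modelling device whose contract is to induce (i)
territory-structured voxel-voxel damage covariance and (ii) anatomically
varying lesion volume — the two features of real lesion data that drive
the biases under study. It is not a fit to any artery atlas, and nothing
downstream sees the tree: inference methods receive only masks and labels.

**Tree growth.** From each of `n_roots` (default 4 — a scaled analogue of
the carotid and vertebrobasilar entry arteries) surface points, segments
bifurcate recursively with random angular jitter (35°) and step length
decaying by 0.7 per level, to depth 5, clipped to the mask bounding box.
Every in-mask voxel is assigned the territory of its nearest segment.

**Lesion growth.** Each lesion seeds on a uniformly chosen segment
(distal segments are more numerous, so occlusions concentrate distally, as
in reality), then grows as a 6-connected region by randomized lowest-cost
flooding where crossing a territory boundary multiplies the step cost by
`territory_penalty` (default 8) — lesions hug their territory but can
bleed across boundaries. Target volumes are log-normal with median
400·0.65^depth voxels and log-SD 0.5: proximal occlusions are large (a
few hundred voxels, ~4% of the synthetic brain), distal ones small,
matching the real stroke-to-brain volume ratio at this scale. A lesion
whose target exceeds its reachable region is truncated and counted with a
warning. One master seed spawns an independent substream per lesion, so
growing the cohort never reshuffles earlier lesions.

**Other modes.** `uniform_single_voxel` (i.i.d. uniform single-voxel
lesions — the random-architecture null) and `gaussian_blob` (spherical
blobs at uniform centres — spatially extended but tree-free).

**Ground-truth regions.** Synthetic critical regions are spheres
(default radius 3.5 voxels, ~175 voxels — a Brodmann-area-scale patch)
centred on the midpoints of *distal* (depth-4) tree segments: cortical
areas live at the vascular periphery, and this placement reproduces the
property that real critical regions (BA39/BA44 and the like) sit inside
commonly infarcted territory without being identical to any territory.

**What the generator does not emulate.** Inter-subject anatomical
variability, white-matter disconnection at a distance, mass effect,
non-ischaemic pathology, registration error, and the sheer spatial
richness of a real vascular atlas. Consequently, passing tests show the
*mechanisms* — structured covariance biases voxel-wise inference, joint
modelling escapes it — at a toy scale; they do not reproduce any
dataset-specific error magnitude or AUC.

## Study conditions (fixed problem sizes)

- Mislocalisation experiments: 32³ grid, 2 mm voxels, spherical mask of
  radius 13 voxels (~9,300 in-mask voxels), 500 tree-structured lesions;
  the uniform control uses 10,000 single-voxel lesions on the same grid so
  that hit-count eligibility (>3) is non-empty (500 single-voxel lesions
  over 9,300 voxels would leave no testable voxel). Paired comparisons run
  20 independent worlds.
- Zero-bias limit: 16³ grid, mask radius 6, 8,000 single-voxel lesions.
- Prediction comparison: two independent 32³ cohorts as above, two
  two-region OR models per cohort (syndromes are posed in pairs so the
  comparison never rests on a single region placement), 50 random 70/30
  splits each — 200 AUC values per method, pooled
  across models and cohorts. Pooling averages out region-placement luck:
  a single cohort occasionally lands its regions where parasitic voxels
  are near-perfect proxies and the two methods tie.
- Calibration: 24³ grid (radius 9), 200 lesions, 200 label permutations;
  null-AUC check over 50 splits; volume-model null coverage over 200
  simulated voxels at N = 500.

These sizes are the package's chosen desk-scale defaults; all are
configurable.

## Calibration of a discrete exact test

Fisher-exact p-values are conservative and discrete: at the modest
per-voxel counts of lesion data, P(p ≤ α) sits well below α and much mass
lies at p = 1. A literal two-sided uniformity test (e.g.
Kolmogorov-Smirnov) against U(0,1) therefore rejects for *any* correctly
implemented exact test. The meaningful calibration property is
one-sided: under label permutation the pooled p-value ECDF must never
exceed the uniform CDF (no anti-conservatism at any level), and
Bonferroni thresholding must control the family-wise error. Both are
asserted in the test suite; the observed ECDF excess is 0.

## Numerical choices and degenerate inputs

- Ties in the two-sided exact sum use a 1e-7 relative tolerance (matching
  the usual floating-point convention); the enumeration oracle shows this
  never costs more than ~1e-13.
- Labels with no contrast (all deficit or none) produce p = 1 everywhere
  with a warning; single-class training sets raise for the SVM.
- Zero-voxel lesions are rejected by default (configurable to warn):
  they carry no information and break the volume predictor.
- Empty significant clusters are flagged per target voxel; summary means
  are over defined voxels only.
- Hemisphere mirroring is available as an optional preprocessing flag
  (off for synthetic grids, where there is no hemispheric asymmetry to
  fold).
- Masks are stored dense; the pairwise co-occurrence matrix behind the
  mislocalisation field is computed sparsely (lesions occupy ~1% of the
  grid).
- All randomness flows from named, hashed substreams of one master seed;
  identical configs and seeds reproduce outputs bit-for-bit.

## Known limitations

- The tree generator's parameters shape the *strength* of the measured
  biases; the package demonstrates orderings and signs, not portable
  magnitudes.
- The Laplace interval for the volume model is a quadratic approximation;
  full posterior sampling is out of scope.
- Mass-univariate variants beyond binary Fisher testing (continuous-score
  VLSM, permutation-based FWE, TFCE) are out of scope, as are nonlinear
  or structured multivariate models.
- The "distortion" options (Gaussian smoothing, lesion-volume covariate)
  exist to demonstrate their distorting effect, not as recommendations.
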