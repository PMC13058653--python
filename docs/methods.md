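# Methods

This note documents the models implemented in `mindgrad`, the synthetic
data they are validated on, the numerical choices that were genuinely
open, and what the tests do and do not show about real data.

## MIND similarity estimation

Each cortical region is a cloud of vertices in 5-D feature space
(CT, GM, SA, MC, SD). Features are z-scored **across all vertices of a
subject** (not per region) using the population SD (ddof = 0) — regional
contrasts are exactly the signal the divergence should see, and the
population convention makes the two-vertex toy case (1, 3) → (−1, +1)
exact. The divergence between regions is the k-NN estimator

    D̂(A‖B) = (d/nₐ) Σᵢ log(νₖ(i)/ρₖ(i)) + log(n_b/(nₐ−1)),

with ρₖ the within-sample and νₖ the cross-sample k-th neighbour
distance, k = 1 by default (the reference formulation for
morphometric-similarity networks; configurable). Numerical choices:

* **Zero neighbour distances** (duplicate points): distances are floored
  at 1e-10 before the log. A floor, unlike random jitter, is
  deterministic and invariant to vertex order, which the test suite
  checks to 1e-12.
* **Negative estimates** are clipped at 0 before symmetrisation so that
  MIND = 1/(1 + D̂sym) never exceeds 1.
* The diagonal is zero by policy and excluded from the weighted degree
  (mean off-diagonal similarity per region).

The estimator carries positive bias at small n in 5-D: with ~300 vertices
per region, two samples of the *same* distribution score MIND ≈ 0.78
rather than 1. This bias is shared across region pairs and cancels in the
relative structure the gradients use; the estimator-consistency test
verifies the error shrinks monotonically with n.

## Gradients

The standard connectivity-gradient recipe: per row, keep the
ceil(fraction·(R−1)) largest off-diagonal entries (fraction 0.1 default;
ties broken toward the lower region index to keep the operation
deterministic); build the normalized-angle affinity between rows of the
sparsified matrix (diagonal zeros included as-is, so profiles are
compared on their off-diagonal structure); embed by diffusion maps with
density-normalisation α = 0.5 and diffusion-time-0 scaling (component i =
λᵢψᵢ, eigenvalues of the density-normalised Markov operator via its
symmetric conjugate). Variance explained is λᵢ over the sum of the
retained nontrivial eigenvalues.

The group template embeds the element-wise **mean matrix** across all
subjects (cases and controls pooled) — the standard toolbox behaviour
where per-subject averaging of embeddings would also have been
defensible. Individual matrices are embedded with identical parameters
and aligned to the template by orthogonal Procrustes rotation
(column-centred, no scaling; variance explained carried over from the
unaligned solution; rank-deficient inputs get an identity rotation with a
warning). Eigenvector sign indeterminacy is resolved once at the
template: each component is oriented so its mean over the highest-degree
decile of regions is positive; individuals inherit the orientation
through alignment.

## Synthetic data

The generator is the package's study design, not a tuning knob:

* **Parcellation** — Fibonacci lattice of R/2 centroids per hemisphere on
  the unit sphere (default 154 per hemisphere, 308 total); the right
  hemisphere mirrors the left in the x coordinate so spin rotations can
  be applied in mirrored pairs. Seven network labels (azimuthal sectors)
  and seven cytoarchitectonic-class labels (polar bands) are spatially
  contiguous by construction. Vertex counts are uniform in [200, 500],
  matching the hundreds of vertices of ~5 cm² parcels.
* **Cohorts** — each region has a fixed 5-D Gaussian (means vary smoothly
  over the sphere; covariances share a feature-correlation structure with
  regional SD modulation; all fixed once per parcellation). Subjects add
  mean offsets of 0.15 feature-SD; cases additionally shift all five
  feature means by `effect_size` pooled SDs inside the effect regions.
  Covariates: age uniform 21–50, sex {0,1}, education normal(14, 2)
  truncated at ≥ 8 years.
* **Gradient-level cohorts** — `generate_gradient_cohort` plants the same
  group shift directly in per-subject principal-gradient maps (smooth
  base map + unit-SD subject noise). Power studies over many seeds
  (e.g. the 100-seed GLM sensitivity check at n = 49/119) use this
  region-level abstraction; the full vertex → MIND → gradient chain is
  exercised end to end in the orchestrated run and its own tests, at the
  package's standard small scale.
* **Annotation maps** — Gaussian process with squared-exponential kernel
  on chordal distance (length-scale `smoothness`, default 0.5), built as
  √0.7 × a mirror-symmetric component plus √0.3 × hemisphere-specific
  components. This decomposition matters: each part's law is invariant
  under mirrored-pair rotations, so the spin-permutation null is exactly
  exchangeable. (A naive GP over both hemispheres in a shared coordinate
  frame carries cross-hemisphere covariance that mirrored rotations do
  not preserve, and we measured the resulting spin test at ~18% type-I
  error instead of 5%.) The 0.7 symmetric weight encodes the strong but
  imperfect homotopy of real molecular maps.
* **Expression** — left-hemisphere regions × genes; a `loading_fraction`
  of genes follows β·target + noise with signed gene-specific loadings
  (|β| uniform in [0.5, 1.5]), the rest is spatially smooth noise; all
  genes z-scored across regions. Loaded genes are assigned to two
  designated classes with probability 0.8, giving the enrichment stage
  ground truth.

What the generator does **not** emulate: cortical folding geometry,
FreeSurfer file formats, scanner/site effects, within-region feature
covariance estimated from real data (the Gaussian model is a stand-in,
not a claim about any dataset), donor sampling sparsity of expression
atlases. Passing tests therefore demonstrate the statistical machinery is
correct and calibrated under the stated model, not that any particular
real-data effect exists.

## Group contrast

Per region, OLS of the aligned principal gradient on [intercept, group,
age, sex, education, age×sex], with age and education mean-centred before
forming the interaction (stable, interpretable main effects). Group is
coded control = 0 / case = 1, so positive t means cases > controls. The
implementation solves the normal equations vectorised across regions;
tests verify it against statsmodels OLS to 1e-8. BH-FDR is applied across
regions, and across the seven labels (separately per label scheme) for
the network/class aggregation. The KS test on subject-level mean
gradients uses the asymptotic two-sample statistic.

## Spin permutation nulls

Per spin, a Haar-random rotation (sign-corrected QR of a Gaussian 3×3,
determinant +1) is applied to left-hemisphere centroids and its
x-mirrored conjugate to the right; each region is reassigned to its
nearest rotated centroid, duplicates permitted (the original
nearest-neighbour variant; exact-permutation alternatives exist but are
not implemented). Conventions fixed for reproducibility: the **first**
map argument is permuted and the annotation held fixed; correlation tests
are two-sided by |r|; p = (1 + #{|r_null| ≥ |r_obs|})/(1 + n_spins) is
never zero. PLS component significance and regression-fit significance
use the one-sided version of the same null (variance explained and R²
are nonnegative, larger = more structure, with the unadjusted R² as the
null statistic since it is monotone in fit).

## PLS decoding

Predictors are z-scored per column and the response centred.  The engine
is scikit-learn's `PLSRegression` (NIPALS, no internal rescaling); the
test suite cross-checks it against the closed form for a univariate
response (first weight vector ∝ X'y), keeping two independent routes to
the same component. Variance explained per component is the increment in
the R² of y on the growing score basis. PLS1 is oriented so its region
scores correlate positively with the response, before any bootstrap.

Bootstrap weight Z-scores resample regions with replacement, refit the
first component (re-standardising predictors within the replicate),
sign-align each replicate to the original weights, and set
Z = w / SD_boot(w); two-sided normal p-values are BH-FDR corrected and
survivors split by weight sign into the PLS1+ / PLS1− sets. Defaults are
20 components, 10,000 bootstrap iterations and 10,000 spins for
full-scale runs; the orchestrated small study and the test suite use 500
and 2,000 respectively so the whole pipeline stays in the minutes range
on one CPU. Transcriptomic decoding consumes left-hemisphere expression
only, with the response subset to left regions.

## Enrichment and importance

Null-ratio enrichment draws size-matched random gene sets from the
background (default: all genes in the expression matrix, the PLS
universe; configurable) and reports enrichment and depletion tails with
the +1 convention, BH-FDR across classes. The toy-scale behaviour matches
the exhaustive hypergeometric tail.

Relative importance uses the exact LMG decomposition — the average over
all predictor orderings of the R² increment when a predictor enters —
computed by subset enumeration (hence the p ≤ 10 guard; the intended
model has four predictors: PLS1 score, two transporter maps, E/I ratio).
Shares are nonnegative and sum to the model R² to 1e-9; percentage shares
normalise to 100%. Uncertainty comes from a region-resampling bootstrap
with percentile intervals; fit significance from the spin null on R².

The E/I ratio z-scores each excitatory and inhibitory map across regions
(population SD), averages within class, and divides. Regions where the
mean inhibitory z-score is within 1e-6 of zero are flagged unstable and
reported as NaN rather than silently dropped — the ratio is genuinely
undefined there.

## Orchestration and determinism

`run_all` executes simulate → mind → gradient → contrast → spatial → pls
→ enrich → importance, each stage reading only files written by earlier
stages. Every stage seed is explicit in the config (derivable from one
master seed via `SeedSequence`); all outputs are headered delimited text
with region-id keys, and the manifest maps each file to its SHA-256 hash
— two runs from one config are hash-identical. The default configuration
(68 regions, 12 + 12 subjects, 500 genes, 500 spins) is the package's
standard small study: every stage is statistically nontrivial and the
full run completes in about 45 seconds on one CPU. At this cohort size
the transcriptomic FDR stage is underpowered (often zero genes survive),
which is the expected behaviour, not a defect; the planted-decoding
benchmark at the generator's reference conditions (loading fraction 0.3,
noise SD 0.3, response = target map) recovers the loaded set with recall
and AUROC near 1.

## Known limitations

* The KL estimator's small-sample bias makes absolute MIND values
  scale-dependent; comparisons should stay within a fixed vertex budget.
* Spin reassignment with duplicates is not a bijection, so jointly
  spinning two maps preserves their pairing but not the correlation
  coefficient exactly (it is exact for bijective spins).
* The diffusion embedding assumes a connected affinity graph; the
  normalized-angle kernel effectively guarantees this (affinities ≥ 0.5),
  but raw thresholded matrices may not be connected.
* LMG enumeration is exponential in the number of predictors; beyond
  p = 10 a sampling-of-orderings variant would be needed.
* Enrichment treats gene classes as given labels; it does not model
  expression-level class structure.
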