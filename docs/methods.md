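# Methods

`langasym` implements a lifespan analysis of hemispheric specialization
from resting-state functional connectivity: per-subject principal
connectivity gradients, homotopic asymmetries of gradient and regional
volume, nonlinear hemisphere-by-age trajectory modeling, clustering of
asymmetry trajectories, and permutation-based brain–behavior canonical
correlation. Real cohorts of this design are restricted-access, so the
package ships a synthetic-cohort generator with planted, recoverable
ground truth; every stage is validated as a recovery problem against that
truth or against an independent oracle.

## Connectivity gradients

For each subject, a regional BOLD table (timepoints × regions) is reduced
to the first connectivity gradient G1:

1. **Correlation.** Pearson correlation between all region pairs.
2. **Row sparsification** (`density = 0.10`): each row keeps its top 10%
   of off-diagonal connections by signed value; ties at the threshold are
   kept, the diagonal is zeroed, and the result is allowed to be
   asymmetric. Ranking signed values means negative correlations rarely
   survive, matching the convention of the gradient literature.
3. **Normalized-angle affinity**: `1 − arccos(cos_sim(row_i, row_j))/π`,
   mapping cosine similarity into [0, 1] with 0.5 at orthogonality.
4. **Diffusion-map embedding** with anisotropic normalization
   `W′ = D^−α W D^−α`, `α = 0.5`, diffusion time 0 (components scaled by
   `λ/(1−λ)`). The decomposition goes through the symmetric conjugate of
   the Markov operator, so eigenvalues are exact and the trivial constant
   eigenvector is identified and dropped. Variance explained per
   component is its eigenvalue as a fraction of the non-negative
   non-trivial spectrum.
5. **Group reference and alignment.** The reference is the embedding of
   the element-wise mean connectivity matrix (a generalized-Procrustes
   refinement over individual embeddings is available as
   `reference_mode="iterative-mean"`). Successive diffusion eigenvalues
   of parcel-level connectomes lie close together, so the leading
   eigenvectors of any single cohort are defined only up to rotation
   within their span; the reference is therefore rotated so its first
   component best matches an external **template gradient**
   (`align_to_template`) — for real data a published gradient map, for
   synthetic cohorts the planted loading. This mirrors the usual practice
   of aligning a study's group gradient to the literature gradient and is
   what makes the frame reproducible across cohorts. Without a template,
   a configurable anchor set of transmodal regions fixes only the sign.
   Individual embeddings are then aligned to the reference by orthogonal
   Procrustes rotation (no scaling), iterated 10 times against the fixed
   reference.
6. **Min–max normalization** of each subject's aligned G1 to [0, 100]
   over the whole brain.

## Homotopic asymmetry

For each homotopic pair, gradient asymmetry is `G1(left) − G1(right)` on
the normalized scale (positive = leftward). Volume asymmetry is the
difference of TIV-normalized volumes `vL/TIV − vR/TIV`; a laterality
quotient `(L−R)/(L+R)` is available by configuration. The difference form
was chosen for consistency with the gradient asymmetry; the proportion
normalization (rather than a residual method) is an explicit assumption.

## Hemispheric age trajectories

Per pair, a factor-smooth penalized-spline model is fitted to the long
table with one left and one right row per subject:

    value = β₀ + β_hemi·[hemi=L] + sex + site
            + f(age) + f_Δ(age)·[hemi=L] + b_subject + ε

Both smooths use a cubic B-spline basis with `k = 6` basis functions
(interior knots at age quantiles, boundary knots at the observed range), a
second-derivative curvature penalty computed exactly by two-point
Gauss–Legendre quadrature per inter-knot interval, and a sum-to-zero
identifiability constraint. The subject intercepts `b` are a
ridge-penalized dummy block. All three smoothing parameters are selected
by REML through the mixed-model representation; because each subject
contributes exactly two rows, the subject block's cross-product is `2I`
and is absorbed by a Schur complement, reducing each REML evaluation to
dense algebra in the ~14-dimensional fixed-plus-smooth space (hundreds of
fits per second, which is what makes the calibration simulations cheap).
Log smoothing parameters are clipped to ±18 to keep the penalized system
well conditioned; curvature penalties are rescaled to unit mean diagonal
so the clip is scale-free. With noiseless data the residual variance is
floored at a tiny multiple of `var(y)` rather than zero.

With one observation per subject and hemisphere, the subject intercept and
the residual are separated only through the within-subject contrast; the
fitted variance components should not be interpreted individually on such
data (the fitted curves and their covariance are unaffected).

**Interaction test.** The Hemisphere × Age interaction is tested on the
within-subject differences `d_i = y_iL − y_iR`, in which the subject
intercept, the shared age smooth and all subject-level covariates cancel
exactly, leaving `d_i = const + f_Δ(age_i) + noise`. The test is the
classical F-test of the (unpenalized) difference-smooth basis in that
paired regression — exact under Gaussian noise. A Wald statistic referred
to the data-selected effective degrees of freedom of the penalized
difference smooth was implemented first and rejected: its null rejection
rate at α = 0.05 was 0.095 in a 200-replicate simulation, the familiar
anticonservatism of conditioning on an estimated effective df. The exact
paired test calibrates at the nominal level and its p-values are uniform
under the null, which also makes Benjamini–Hochberg behave as advertised
across pairs.

**Asymmetry trajectories.** The demeaned asymmetry curve is the
difference of zero-centered hemispheric predictions on a 100-point age
grid spanning the observed ages, at reference covariate levels (first
site, female, subject effect 0) — demeaning makes the curve invariant to
that choice, which is asserted as a test. Pointwise confidence bands come
from `x^T V x` with the Bayesian coefficient covariance. No extrapolation
outside the observed age range is allowed. The fitted curves were
cross-checked against the reference R implementation (`mgcv`, cubic
regression splines, REML): demeaned asymmetry trajectories agree to
within ~2 × 10⁻⁵ on a shared test dataset despite the different basis and
knot placement.

## Trajectory clustering

Significant pairs' demeaned trajectories (BH-FDR `q < 0.05`) are compared
by the sum of squared differences over the common age grid — note this
dissimilarity does not satisfy the triangle inequality, which PAM does not
require. Clustering is PAM (BUILD + SWAP) on the provided dissimilarities
with a deterministic multi-start: BUILD is restarted from every possible
first medoid and the lowest-cost SWAP result kept. Single-start classical
PAM (verified to coincide with R's `cluster::pam` on a failing example)
lands in a local optimum on roughly 8–10% of small random problems;
multi-start reached the exhaustive optimum in 2000/2000 trials at the
problem sizes used here, at a cost factor of n that is negligible for tens
of trajectories. The cluster count k is chosen over 2..7 by the mean
silhouette width computed on the same dissimilarities.

For a two-cluster solution the **crossover age** is the linearly
interpolated first sign change of the difference of the cluster-mean
trajectories (all crossings are recorded; the earliest is reported). When
silhouette selects more than two clusters — typically when a flat group of
weakly changing pairs joins the two drift clusters — the crossover is
computed between the two largest-amplitude cluster means, and the summary
records which clusters were used. The Sørensen–Dice index
`2|A∩B|/(|A|+|B|)` (1 for two empty sets) quantifies the stability of the
significant-pair classification between cohorts or subsamples.

## Brain–behavior CCA

Per cluster, the brain set stacks the cluster's gradient and
normalized-volume asymmetries (subjects × pairs). Variables are
standardized and PCA-reduced; the retained count is the elbow of the
cumulative explained-variance curve — the point of maximum perpendicular
distance to the chord joining its endpoints (kneedle construction; the
cumulative rather than per-component curve is what reproduces the
documented worked example, and a straight-line curve retains one component
with a warning). Both sets are then residualized on sex, age and MMSE by
OLS (residuals exactly orthogonal to the design), and CCA is computed by
the whitened cross-covariance SVD (QR of each centered set, SVD of
`Qx^T Qy`), giving exact canonical correlations, unit-variance variates,
loadings as variable–variate Pearson correlations, and per-mode variance
explained as the mean squared loading × 100. scikit-learn's iterative CCA
serves as an independent cross-check in the tests, never as the
implementation.

**Permutation inference** (default 1,000 permutations) permutes subject
rows of the residualized behavior set — simple exchangeability is
appropriate because the covariates were removed beforehand; more elaborate
exchangeability structures are out of scope. Each mode k is scored by the
Wilks-type tail statistic `−log Π_{j≥k}(1 − r_j²)`, robust to trailing
modes. Uncorrected p-values use each mode's own permutation distribution
with the `(1 + #exceed)/(1 + n_perm)` estimator; family-wise error control
is step-down max-statistic (mode k compared against the permutation
suffix-maximum over modes ≥ k) with monotonicity enforced across modes.
Calibration was verified by simulation: the mode-1 FWER rejection rate at
α = 0.05 over 500 independent-data experiments falls within [0.03, 0.07].

## Synthetic cohorts and what they do (not) emulate

The generator plants every quantity the pipeline is supposed to recover;
all randomness flows from a single integer seed through independent named
streams, so each table is reproducible in isolation.

- **Phenotype.** Ages uniform over [18, 88] (uniform, not
  demography-shaped, so trajectory fits are equally constrained across the
  range — the merged multi-cohort design this emulates was itself
  approximately uniform); sex balanced; site uniform over `n_sites`; MMSE
  from a truncated distribution concentrated at 28–30 (quartiles 28 and
  30), used only as a residualization covariate.
- **Gradient structure.** Each region has a planted position g ∈ [0, 100]
  along the unimodal→transmodal continuum, mapped to an angle
  θ = (g/100)(π/2); its series is `cos θ·s₁ + sin θ·s₂ + σε` with two
  shared standard-normal latent series per subject. Expected correlation
  is then `cos(θᵢ − θⱼ)/(1 + σ²)`: a smooth one-dimensional manifold whose
  diffusion coordinate is monotone in the planted position, making
  gradient recovery oracle-checkable. (A single shared factor cannot
  serve here: all correlation rows become proportional, sparsification
  leaves them collinear, and the affinity degenerates.) Base positions
  are evenly spaced; pairs of interest occupy the central slots, where the
  recovered coordinate is most uniform in the planted position, and
  filler pairs extend to the poles, anchoring each subject's min–max
  normalization. Per-subject positional jitter (sd 2 gradient units)
  models individual topographic variability.
- **Age drifts.** The planted asymmetry of a cluster-1 pair decreases
  with age (its right-hemisphere position rises, the left stays put);
  cluster-2 mirrors it (left rises); null pairs stay constant. The drift
  shape `u(a) ∝ (a − c) + γ(a − c)²` has mean zero over the age range and
  a single root at the crossover age c (γ solves the mean-zero condition
  in closed form and vanishes when c is the midpoint), so the demeaned
  cluster-mean trajectories intersect exactly once, at c — the property
  the crossover estimator is tested against. `effect_size` (default 10
  normalized-gradient units) is the maximal drift over the age range;
  `noise_sd = 0.5` gives a 4:1 signal-to-noise variance ratio, a moderate
  value for parcel-averaged BOLD; `n_timepoints = 200` matches typical
  resting-state scan lengths.
- **Brain–behavior mode.** A standard-normal subject score z shifts each
  interest pair's asymmetry by ±`mode_strength`·z (sign by cluster) and
  adds `volume_mode_strength`·z to its normalized-volume asymmetry; the
  four behavior scores are `w·z + noise` with weights (0.8, 0.6, 0.3,
  0.2), all oriented so that values near zero mean worse performance
  (reaction-time-like scores are stored inverted). A separate direct
  harness (`generate_cca_dataset`) plants an exact population canonical
  correlation in closed form for CCA-specific tests.
- **Volumes.** Lognormal TIV (~1.45 L) and per-pair lognormal volumes
  with a planted leftward normalized asymmetry on pairs of interest plus
  the mode component and measurement noise.

Not emulated: hemodynamic autocorrelation, scanner/site effects on the
BOLD signal itself (site enters only as a phenotype covariate),
non-Gaussian behavior distributions (skew, ceilings), voxel-level
structure, and head-motion artifacts. Passing recovery tests therefore
demonstrates the correctness and calibration of the estimators under the
planted model, not robustness to those real-data complications. The first
gradient of the synthetic cohorts carries ~11% of the connectivity
variance — the two-latent construction is deliberately minimal, and this
fraction is below the ~20% typical of real cortex-wide connectomes.

## Problem sizes and numerical defaults

The default synthetic cohort is 200 subjects, 48 regions (16 pairs of
interest: roughly 40% cluster 1, 40% cluster 2, 20% null), 200 timepoints
— small enough that the full pipeline runs in seconds while leaving every
stage statistically identifiable. Recovery harnesses scale up where the
property under test needs it (600 subjects for cluster recovery, 554 for
CCA loading recovery). Calibration simulations use 200 replicates for the
interaction test and 500 replicate experiments at 200 permutations for
the CCA FWER. Ties in SWAP are broken toward the lowest item index;
eigenvector signs are fixed by template or anchors; every random draw is
seeded.

## Known limitations

- The trajectory model is cross-sectional: age effects are
  between-subject differences, not within-subject change.
- Gradients beyond G1 are computed and stored for alignment but not
  analyzed.
- The elbow rule returns one component for straight-line variance curves;
  analyses needing a fixed dimensionality can override the retained count.
- FWER-corrected p-values for modes beyond the first inherit the usual
  conservatism of step-down max-statistic schemes under simple row
  permutation.
- The template-rotation step requires an external gradient map (or the
  planted loading in simulation); without one, the reference frame of a
  single cohort is stable only when the leading eigenvalue gap is large
  relative to cohort noise.
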