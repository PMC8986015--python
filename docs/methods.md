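# Methods

`morphosex` implements a landmark-based analysis of sexual dimorphism of the
human sacrum: generalized Procrustes superimposition with bending-energy
semilandmark sliding, shape- and form-space statistics, classical
osteometric indices of the first sacral vertebra, and linear-discriminant
sex classification with leave-one-out cross-validation. A synthetic
population generator with exported ground truth makes the whole pipeline
exercisable and testable without access to skeletal specimens.

## Superimposition

Configurations of k landmarks in 3D are centered, scaled to unit centroid
size (CS = root summed squared distances from the centroid; scaling is
optional), and rotated by least squares onto an iteratively re-estimated
consensus. Rotations are proper (det +1); reflections are excluded by
default, the standard geometric-morphometrics convention, with an
`allow_reflection` escape hatch.

Numerical choices:

* The consensus is initialized from the normalized mean of the centered
  (and scaled) configurations *as digitized*, falling back to the first
  configuration if that mean degenerates (e.g. inputs in adversarially
  scrambled orientations). This makes an already-superimposed sample an
  exact fixed point — re-running the alignment converges in one iteration
  and changes nothing — which would not hold with a first-specimen
  initialization.
* The consensus is re-scaled to unit centroid size every iteration.
  Consequently the sample mean of the aligned shapes is *proportional* to
  the consensus (equal up to a factor 1/‖mean‖ ≈ 1 + residual variance);
  results are tolerance-equivalent to normalizing once at the end.
* Convergence: RMS consensus change < 1e-10 or 200 iterations. The
  procedure is deterministic; identical inputs give bit-identical outputs.

Procrustes distances between specimens are measured in the common GPA frame
(this is what the permutation tests use). A separate pairwise
ordinary-Procrustes fit is provided for oracle checks.

Form space augments the flattened shape coordinates with an unweighted
column of ln CS; centering happens inside PCA.

## Thin-plate spline and semilandmark sliding

The TPS kernel is U(r) = r² log r² in 2D and U(r) = −r in 3D. The minus
sign in 3D matters: −r/(8π) is the fundamental solution of the biharmonic
equation, and −r is the conditionally positive definite choice, making the
bending-energy quadratic form positive semidefinite with the affine
deformations as its null space. (With +r the form is negative semidefinite
and the sliding minimization is unbounded.)

The bending-energy matrix is the upper-left k×k block of the inverse of the
bordered kernel system. When the reference is degenerate for the full
affine basis — e.g. a coplanar configuration in 3D, where the z column of
the affine block vanishes — the dependent affine columns are dropped by
pivoted QR before inversion. This keeps planar toy references well-posed;
the energy then annihilates exactly the affine maps expressible on the
reference.

Sliding: per outer pass the sample is GPA-aligned, the bending-energy model
is built from the current reference (sample consensus by default), and each
specimen's semilandmarks are moved along their local unit tangents to
minimize the bending energy of the reference→specimen deformation. Tangents
are central differences of the neighboring curve-chain points (declared
fixed anchors included), one-sided at chain ends. All of a specimen's
sliding parameters are solved jointly — the problem is an exact linear
solve, so per-pass energy never increases. Displacements are mapped back
through the inverse similarity transform, so the returned configurations
live in the original coordinate frames and fixed landmarks are bit-
identical to the input.

Known behavior: semilandmarks slide along straight tangent lines without
re-projection onto a surface (no meshes are assumed), and the spacing of
points along nearly-straight curve stretches is only weakly constrained by
bending energy. The outer iteration therefore converges slowly along a
collective reparametrization mode (moves decay geometrically, roughly ×0.85
per pass). Three outer passes — the conventional choice, configurable —
remove the bulk of the tangential digitizing jitter without chasing that
flat direction; exact outer-loop stationarity is *not* a contract of the
implementation, only per-pass energy decrease is.

## Shape statistics

* **PCA** is a centered SVD; p = min(n−1, columns) components retained.
* **Variance-explained regressions** fit all shape columns on one predictor
  block (numeric lnCS, binary sex, dummy-coded origin) and report
  100·SS_model/SS_total summed over columns, optionally with an add-one
  permutation p-value (predictor rows shuffled).
* **Allometry correction** follows the two-stage protocol: regress shape on
  lnCS, keep the residuals, regress residuals on binary sex. Both the sex
  share of the residual variance and the same sum of squares as a share of
  the *original* total (the figure usually quoted) are reported.
* **Permutation test of group mean difference**: statistic is the
  Procrustes (Euclidean) distance between group mean configurations;
  p = (#{perm ≥ obs}+1)/(B+1); exhaustive enumeration available for tiny
  samples (p then counts the identity split, so p > 0). Default B = 10,000
  as in the original analysis; calibration tests scale down to B = 199.
* **Procrustes ANOVA**: sequential (type-I) sums of squares over all shape
  columns in declared factor order, with p-values by residual randomization
  (RRPP): for each term, the reduced-model residuals are permuted, added
  back to the reduced fit, and the term's F statistic recomputed. The
  interaction (two factors) enters last. Rank-deficient designs raise an
  error naming the aliased term.
* **Univariate statistics**: two-sided pooled-variance t-tests. Cohen's D
  is reported in two conventions, because published sacral summary tables
  rarely state theirs: (a) pooled within-group SD; (b) mean difference over
  the *total-sample* SD reconstructed from group n/mean/SD (within +
  between variance, n-weighted). Convention (b) reproduces the published
  sacral effect sizes used as benchmarks (1.46 European corpus width, 1.05
  complete-sample corpus depth); a summary-statistics mode allows those
  reproductions without raw data.

## Osteometrics

SW (sacral width), CW (corpus width) and CD (corpus depth) are chord
distances between template-registered landmark pairs on the raw, unscaled
configuration; the registry is part of the editable template, so anatomical
fidelity is configuration, not code. Indices: CBI = 100·CW/SW,
CAI = 100·√(CW·CD)/SW, corpus area = CW·CD. The square-root CAI is the form
consistent with a dimensionless index in the low 30s (the linear form would
be ~12 at typical dimensions and carries units). CW ≥ SW warns rather than
fails.

## Classification

Two-class LDA with pooled covariance; the positive class is female
throughout. Priors default to equal, with proportional priors available;
the choice is echoed in every report. A singular pooled covariance triggers
ridge regularization (λ = 1e-8·trace/p) with a warning. Leave-one-out
cross-validation refits the model for each held-out specimen and reports
the cross-validated confusion counts, per-class correct percentages,
sensitivity/specificity/precision, and the prevalence-weighted accuracy
sens·prev + spec·(1−prev), which equals raw accuracy when the prevalence is
the sample prevalence. ROC curves are staircases over all distinct score
thresholds; AUC is the two-sample rank statistic with ties counted half,
which equals the trapezoidal ROC area to machine precision. Box's M uses
the standard chi-square approximation.

Per-PC feature selection (two-sample t-test at α = 0.05 by default, a
permutation variant is provided) is performed once on the full sample,
*outside* the cross-validation folds, mirroring the original procedure;
this is optimistic, and honest selection inside folds is a one-line change
for users who want it.

## Synthetic data: the stated world

`make_template` builds a deterministic, bilaterally symmetric sacrum-like
reference: an elliptical corpus rim, alae flanges out to the sacral-width
endpoints, curved anterior/dorsal midlines, auricular patches, and apex —
44 fixed landmarks plus 56 semilandmarks on 7 curves (superior articular ×2,
dorsal crest, lateral crests ×2, auricular outlines ×2), with SW/CW/CD
endpoints registered at 113/48/30 mm and named regional subsets
(fixed-only, corpus, auricular, S1, S1+S2).

Deformation modes (alae widening, corpus scaling, elongation, promontory
protrusion, sagittal curvature, canal expansion) are built from the
template geometry, projected orthogonal to the similarity transforms of the
reference, and orthonormalized. A specimen's unit-size shape is

    reference + (sex sign)·(d_shape/2)·sex_field + group_offset
              + a·(lnCS − mean lnCS)·allometric_field
              + isotropic landmark noise + tangential semilandmark jitter,

then scaled by a lognormally drawn centroid size. Defaults are fixed once:

* cell sizes mirror the study's known-sex composition (155 specimens over
  five geographic groups);
* landmark noise SD 0.5% of centroid size, tangential jitter 0.5%;
* within-cell lnCS SD 0.05 (≈ the published within-group sacral-width CV),
  male/female size ratio from the published sacral-width means
  (113.7/112.3), small-bodied groups offset down in lnCS;
* d_shape, the allometric scale and the group-offset magnitudes are derived
  once from the published marginal variance shares (sex 2.2%, lnCS 1.7%,
  origin 3.7%) under an orthogonal-effects accounting. Because the default
  world couples group, sex and size (small-bodied groups are flatter and
  smaller; the allometric mode is sagittal curvature), the *marginal*
  regression shares on a simulated default sample come out somewhat higher
  than those targets (e.g. lnCS ≈ 6%) — exactly the kind of confounding the
  real analysis contends with.

Measurement simulation draws per-sex correlated Gaussians for SW/CW/CD with
the published complete-sample means/SDs and correlations (CW–CD 0.70,
SW–CW 0.42; SW–CD set to 0.30, a value consistent with the published
SW–corpus-area correlation of 0.55). Note that 0.70 is the *within-sex*
correlation parameter; the pooled two-sex sample correlation is ≈ 0.75
because both variables are dimorphic. Indices are computed downstream,
never generated.

### What a green test does and does not establish

The generator reproduces the *statistical structure* the analysis assumes —
effect magnitudes, size coupling, group structure, digitizing noise — not
sacral biology. In particular it has no within-sex correlated biological
shape variation beyond the modeled effects, so classification accuracies on
default synthetic data (≈95% for selected PCs) exceed the published
specimen-based ones (≈72–87%); the published headline accuracies depend on
the actual specimens and are out of reach without them. Green calibration
tests establish that the machinery is unbiased and correctly sized, and
that published arithmetic (weighted accuracies, effect sizes) is reproduced
exactly from printed inputs.

A related high-dimensional caveat: with ~300 coordinate dimensions and
samples of a few hundred, a sex effect of Mahalanobis size Δ = 2 has a
covariance eigenvalue at the noise bulk edge, so unsupervised PCA cannot
isolate its direction; classifier-calibration checks therefore operate on
score-level two-Gaussian data (or on the known generator direction), and
the pipeline-level Δ = 3 check uses n = 800 where the eigenvalue separates
from the bulk.

## Limitations

* No missing-landmark estimation, weighted/robust Procrustes, or surface
  (patch) semilandmarks; sliding uses tangent lines, not mesh projection.
* Box's M relies on the chi-square approximation (adequate for the feature
  counts used here); no permutation version.
* The anatomical landmark definitions are placeholders with correct counts,
  roles and measurement geometry; users with real data should edit the
  exported template YAML to their protocol.
* Multiple-testing correction across measurement tables is intentionally
  absent (unadjusted p-values, matching the emulated reporting style).
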