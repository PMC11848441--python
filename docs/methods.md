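# Methods

This note records the models behind `morphotraj`, the defaults that matter,
what the synthetic generator does and does not emulate, and the numerical
decisions made where the design was genuinely open.

## 1. Synthetic data model

The generator produces single-cell morphological feature tables with the
statistical structure the analysis assumes: a latent bifurcating
differentiation process observed through noisy high-dimensional features.

**Latent state.** Each cell carries a differentiation time `t ∈ [0, 10]`
(arbitrary units) and a branch label `pre / hep / bil`, with `branch = pre`
iff `t ≤ t_b_true` (default 3.0, deliberately on the same scale as the
branching pseudotime used for lineage assignment in HepaRG work). Past the
branch a cell commits to the hepatocyte-like fate with probability `p_hep`
(default 0.5 — bi-potent HepaRG cultures robustly reach a 50:50 fate mix).

**Features.** For a cell at state `(t, branch)`:

    x = W_pre · φ(t) + D_branch · max(0, t − t_b_true) + ε,
    ε ~ N(0, noise_sd² I)

with `φ` a fixed 3-component monotone degree-1 I-spline basis in `t`
(knots at t = 10/3 and 20/3), `W_pre` (n_features × 3, entries N(0,1))
shared by all branches, and branch-specific divergence loadings
`D_hep, D_bil` (entries N(0, 0.3²)) linear in `t − t_b_true` so that the
true branch point is identifiable. Loadings are drawn from a fixed internal
generator, independent of the sampling seed, so atlas and screen
simulations share one feature geometry — the prerequisite for merging them.
Defaults: 788 features, `noise_sd = 0.8`. Three designated marker features
deterministically track the cell-area, nuclear-area and
mitochondrial-intensity analogs (hepatocyte-like: increasing;
biliary-like: decreasing), mirroring how the two fates are identified
morphologically in real data; the same quantities appear as the
`cell_area` / `nuclear_area` metadata columns (with multiplicative
log-normal noise scaled to `noise_sd`).

**Time course (atlas).** 20 equally spaced timepoints, equal cell counts
(the fixed imaging schedule), one plate per timepoint, 16 wells × 4 fields.
Cells at a timepoint are *asynchronous*: `t ~ N(t_nominal, t_jitter_sd)`
clipped to [0, 10], `t_jitter_sd = 0.4` (≈ ¾ of the inter-timepoint
spacing). Without asynchrony every timepoint collapses to a tight bead in
the embedding and the bead chains can coil arbitrarily, which no real
differentiating culture does; with it the atlas forms the continuum the
method is designed for. Timepoint-1 cells (t ≈ 0) carry the
`progenitor_control` role and double as anchors.

**Screening plate.** 384 wells: 16 wells per control class (differentiated
/ undifferentiated / spiked-in progenitor controls in columns 22–24),
treatments from A1, 4 images per well, 100 cells per well (a scaled-down
well; real wells hold thousands — scaling keeps the full-plate pipeline
fast while preserving every statistical contrast, and per-treatment cell
counts can be raised where a test needs them). Latent-time centers:
progenitors 0.15 (spiked in 24 h before fixation), undifferentiated
controls 1.0 (slow drift over the 8-day assay), differentiated controls 5.0
(partial differentiation — past the branch but far from terminal); per-well
latent SD 0.5. A treatment's realized effect is its `CompoundEffect`
scaled by the 4PL fraction `f(dose; EC50, hill)`: the latent center moves
`f · accel` of the way from the undifferentiated toward the differentiated
center (beyond it for `accel > 1`), commitment probability shifts by
`f · Δp_hep`, and the well loses `f · toxicity` of its cells. QC-failing
images are truncated to 2 cells; doublets are convex feature combinations
(λ ~ U(0.4, 0.6)) of two same-well cells with *summed* area channels (two
touching cells segmented as one object have additive area — the mixing
rule for non-area features is this package's convention).

**What it does not emulate.** The morphological covariance structure of
real cells (the Gaussian noise model is a stand-in, not a claim of
realism), pixel-level image formation, staining/optics physics, cell-cycle
structure, spatial within-well effects, or plate-position artifacts.
Passing tests therefore demonstrate that the *analysis* recovers what the
*assumed generative structure* encodes; they do not certify performance on
real Cell Painting data.

## 2. Well-level screen analysis

* **Normalization**: per plate, per feature, robust z-scores
  `z = (x − median_ref)/(1.4826 · MAD_ref)`; reference wells are either all
  samples on the plate (screening mode, the default) or the negative
  controls (validation mode). Zero-MAD features are dropped and logged.
* **Feature selection**: drop missing and zero-variance features, then
  greedy correlation pruning in input order (keep the first of any pair
  with |r| > 0.9).
* **Distances**: `d_P = 1 − r(well, median control profile)`;
  `d_E` = Euclidean distance to the differentiated-control centroid in a
  PCA basis (fit on all wells, truncated at 90 % cumulative variance),
  divided by the RMS distance of the control wells themselves to that
  centroid. The division is this package's choice of units: well-to-well
  scatter in a screen is dominated by binomial fate-mix noise summed over
  hundreds of features, so absolute PC distances scale with plate design
  and feature count, whereas control-scatter units put an on-phenotype
  well near 1 and make a fixed threshold (1.7) transferable. The
  `sqrt(n_components)` scaling is retained as an option.
* **Hit call**: strict conjunction `d_P < θ_P and d_E < θ_E`
  (defaults 0.9, 1.7).
* **Assay QC**: Z′ on the scalar d_P of positive vs negative control wells
  (a multiparametric Z′ is undefined; the scalar reduction mirrors how Z′
  is paired with distance QC in practice), per-class CV% of d_P, and a
  3-class random forest on normalized control profiles scored on a
  stratified 50 % held-out split.
* **Dose-response**: variable-slope 4PL fitted by Levenberg–Marquardt
  least squares with a deterministic multi-start (9 logEC50 starts across
  the tested dose range × hill ∈ {+1, −1}); the mirrored parameterization
  (bottom↔top, −hill) traces the same curve and is folded to hill > 0.
  Flat data (response span ≤ 1e−9) is reported as flat with an
  unidentifiable hill rather than a spurious curve. AUC is the trapezoid of
  the mean response over log₁₀ dose.

## 3. Single-cell preprocessing

* **Down-sampling**: per (timepoint | treatment) group, uniform without
  replacement to a 15,000-cell cap.
* **Anchor standardization**: per dataset, each feature is centered on the
  median and scaled by 1.4826·MAD of that dataset's progenitor-control
  cells (≥ 200 required). MAD is chosen over SD for consistency with the
  robust z-scores at the well level. After the transform all datasets'
  anchor centroids coincide at the origin; no graph-based batch correction
  is applied (the anchors make it unnecessary by construction).
* **Doublet removal**: balanced three-class random forest
  (Progenitor / Doublet / Inlier; majority classes down-sampled to the
  minority count, ≥ 10 examples per class). Inputs are the morphology
  features plus the two area channels — segmentation doublets betray
  themselves chiefly through summed areas. In tests the labels come from
  synthetic truth; on real data they are user-provided.
* **Embedding**: PCA to 10 components (full SVD — deterministic, and
  `transform()` exactly round-trips `fit_transform()`, which the
  randomized solver does not guarantee), then 2-D UMAP
  (n_neighbors 15, min_dist 0.1, fixed random_state). The frozen model
  maps new cells by k-nearest-neighbour (k = 10) inverse-distance
  interpolation in PC space against the stored atlas embedding; an exact
  match inherits the atlas coordinate. This out-of-sample map is a pure
  deterministic function of the frozen model — repeated calls agree
  bitwise and atlas cells reproduce their own coordinates — which UMAP's
  native transform does not guarantee on training data.

## 4. Trajectory inference

* **Clustering**: full-covariance Gaussian mixtures on the 2-D embedding,
  K selected by minimum BIC over 2–10 with 5 seeded restarts per K.
* **Backbone**: minimum spanning tree over cluster centroids. The start is
  the cluster with the lowest median progression covariate (imaging
  timepoint); end candidates are MST leaves ranked by that covariate, and
  among the top four the pair with the largest mutual centroid distance is
  chosen — one terminal fate per arm. Lineage 1 is named Hepatocyte by the
  morphological marker (larger mean cell area of its end cluster).
* **Principal curves**: per lineage, initialize at the centroid polyline
  and iterate (a) exact orthogonal projection of the lineage's cells onto
  the discretized curve (200 arc-uniform points), (b) coordinate-wise
  penalized cubic B-spline regression on arc length (interior knots at arc
  quantiles spaced 0.1 × range apart; second-difference penalty bisected to
  a fixed 5 effective degrees of freedom), (c) arc-length
  reparameterization; converged when the mean point displacement
  falls below 1e−3. The fixed, small df is essential: the projection step
  correlates residuals with arc, so data-driven smoothness selection
  (GCV-style) systematically under-smooths and the curve chases cell noise
  laterally — a box-kernel local average and a GCV-tuned spline both
  produced self-consistent zigzag curves with ~2× inflated arc length on
  the synthetic atlas.
* **Branch point**: located from the cells, not the curves. Binning cells
  by their nearest-curve arc, the distance D(s) between the mean positions
  of cells nearer curve 1 and cells nearer curve 2 sits at a selection-noise
  floor before the branch and grows once the fates separate; a hinge fit
  D(s) = a + b(s − s₀)₊ places s₀ at the kink. The fit uses the floor and
  early rise only (past roughly half the maximum divergence the profile
  saturates), and because the exact cut is arbitrary the estimate is the
  median over cuts at 40–80 % of the maximum. Curve-to-curve divergence
  was rejected as the signal because the independently fitted curves lean
  apart slightly *before* the branch (global splines pulled by their own
  post-branch cells), biasing any threshold on it early, while
  threshold-on-population rules are biased late by detection lag.
* **Splice**: both curves are cut at the branch arc and their (near
  coincident) pre-branch portions averaged pointwise — the discrete
  analogue of slingshot's root-side shrinkage — giving a verbatim shared
  segment (`shared_arc`) and short bridges to each lineage's remainder.
  The branch pseudotime `t_b` is then calibrated on the final geometry as
  the median final pseudotime of the cells the estimator localized at the
  branch, so `t_b` is directly comparable with cell pseudotimes
  (the splice slightly rescales arcs; `shared_arc ≤ t_b`, the difference
  being the bridge region).
* **Cell states**: per-lineage pseudotime = arc length of the exact
  nearest-point projection, clamped to [0, curve length] (beyond-terminus
  cells are flagged terminal); weights `w_l = min(1, d²_min/d²_l)` with
  0/0 := 1, so the nearest lineage scores exactly 1 and equidistant
  (pre-branch) cells score 1 on all lineages.
* **Labels**: Progenitor if pseudotime ≤ t_b; otherwise Hepatocyte if
  (w₁ = 1, w₂ < 1) and Biliary for the opposite weighting. A post-branch
  all-1 tie is labelled Progenitor and counted — the rule would otherwise
  leave it undefined. `t_b` can be overridden (e.g. to a published value)
  through the pipeline config.
* **Projection of treated cells** uses the same exact nearest-point
  machinery against the frozen curves; nothing is refitted.

## 5. Perturbation statistics

Lineage composition is tabulated per treatment and replicate (fractions sum
to 1), with mean ± SD across replicates. Each treatment is tested against
the pooled differentiated-control composition with a Pearson goodness-of-fit
statistic Σ(O−E)²/E (expected counts = reference fractions × treatment
total; zero-expectation categories dropped with a warning;
df = non-zero categories − 1; upper-tail chi-square p). Per-replicate
statistics are emitted alongside the pooled reference so both conventions
are available. Pseudotime distributions along a chosen lineage are compared
with the two-sided Wilcoxon rank-sum test; Shapiro–Wilk normality (on a
≤ 5,000-cell subsample) is *reported next to* the rank-sum result rather
than used to switch tests — the rank-sum test is valid either way, and
gating on normality would make the analysis path data-dependent. Shared-grid
density summaries accompany each comparison for lineage-progression plots.
No multiple-testing correction is applied across compounds.

## 6. Orchestration and reproducibility

`PipelineConfig` is a flat, YAML-round-trippable record of every tunable
(thresholds θ_P = 0.9, θ_E = 1.7, cap = 15,000, n_pcs = 10, K range 2–10,
smoother span/df, t_b override) with one explicit seed per stochastic stage
(simulation, down-sampling, doublet training, embedding, clustering, QC
split). `run_pipeline` writes a fixed directory layout (simulate/, profiles/,
models/, states/, reports/) plus a manifest recording the package version,
mode, full config and stage timings; re-running with the same config
reproduces all outputs exactly. Stages run individually against persisted
artifacts and fail by naming the missing artifact. The `morphotraj` console
script exposes one subcommand per stage.

## 7. Problem sizes in tests and acceptance runs

Unit tests exercise the pipeline at 20 × 250 cells × 200 features (the
smallest size at which the embedding geometry matches the full-scale
behavior); the acceptance script and acceptance tests run the trajectory
analysis at the study scale, 20 × 1,000 cells × 788 features, a full
384-well screen (fate-enricher wells at 5,000 cells so each replicate
supports a well-powered composition test), 100 dose-response simulations,
and 1,000 chi-square calibration draws. These sizes are the package's
validation conditions, chosen to exercise every stage at realistic signal
strength.

## 8. Known limitations

* Two terminal fates only; trees with more lineages are out of scope.
* Trajectory inference operates on the 2-D embedding; structure that UMAP
  does not preserve is invisible to it, and the branch location inherits
  the embedding's local arc distortions (branch recovery on synthetic data
  is within ~±8 % across seeds and scales, not exact).
* The Euclidean hit threshold is meaningful only in the documented
  control-scatter units; other software's thresholds do not transfer.
* The doublet classifier needs labelled examples; no unsupervised doublet
  score is provided.
* The chi-square test treats the reference composition as fixed; with very
  small reference cell counts its type-I error would inflate.
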