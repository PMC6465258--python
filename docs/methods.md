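# Methods

## Problem and model

Diffuse hematologic marrow infiltration lowers and roughens the normally
bright, fatty T1 signal of adult vertebral marrow, but because the change is
global and repetitive it is easy to miss by eye. `marrowtex` implements the
full analysis chain for discriminating such diffusely infiltrated marrow from
normal marrow on sagittal T1-weighted lumbar-spine images with a support
vector machine over raw pixels, together with the statistics used to compare
the classifier against human readers and to estimate how much training data a
target accuracy requires. Patient images are replaced by a seeded synthetic
phantom, so every stage of the pipeline is testable and exactly reproducible.

The pipeline is:

1. **Normalization.** Each volume is normalized by an internal reference:
   the scalar mean intensity of the annulus fibrosus of the most cranial
   non-degenerated intervertebral disk is subtracted from every voxel. The
   disk is split into five equal-width bins along its anterior–posterior
   extent; the outer two bins are the annulus. Subtraction of a scalar makes
   the map idempotent and exactly invariant to global intensity offsets,
   which is precisely the inter-scanner nuisance it exists to remove. (A
   pixelwise subtraction is ill-defined when the annulus and the image have
   different voxel counts, so the scalar reading is the only coherent one.)
2. **Segmentation.** Marrow is segmented by a 3D GrowCut cellular automaton.
   Every voxel `p` holds a label `l_p` and a strength `θ_p ∈ [0, 1]`; seeds
   start at strength 1, everything else at 0. Per iteration a neighbor `q`
   (26-connectivity in 3D) conquers `p` when `g(|I_p − I_q|)·θ_q > θ_p`,
   where `g(x) = clip(1 − x/Δ, ε, 1−ε)` with `Δ` the volume intensity range
   and `ε = 10⁻⁶`; `p` then adopts `l_q` and strength `g·θ_q`. Updates are
   synchronous (Jacobi-style) so the result does not depend on voxel visit
   order; iteration stops at the first pass without a label change. The
   upper clip at `1−ε` guarantees seeds are never conquered. Seeds are
   derived automatically from the ground-truth anatomy by morphological
   erosion (foreground: each vertebral body; background: everything else),
   standing in for the interactive seeding a user would perform.
3. **Features.** For each of the six vertebral bodies S1–L1, a rectangular
   window of fixed, population-minimal size (the smallest per-level in-slice
   bounding box over all subjects, height and width minimized independently)
   is centered on the level's marrow centroid in the mid-sagittal slice and
   read from the normalized image at 1, 3 or 9 consecutive slices centered
   on the mid-sagittal slice. All window pixels are used — a mask-restricted
   read could not guarantee a fixed dimension. Blocks are flattened
   row-major and concatenated level-major then slice-major, giving dimension
   `6 · height · width · n_slices`. Columns are min–max scaled to [0, 1]
   with statistics fitted on the training matrix only (constant columns map
   to 0; out-of-range test values are preserved, not clipped).
4. **Classification.** Soft-margin C-SVM (scikit-learn `SVC`, the libsvm
   solver) with three kernels: 3rd-order polynomial, tangent hyperbolic, and
   radial basis function, all with `coef0 = 0`. `(C, γ)` are chosen by
   exhaustive grid search maximizing pooled stratified 5-fold
   cross-validation accuracy, ties broken toward the smallest `C`, then the
   smallest `γ`; the final model is refit on the whole training set. The
   default grids are the canonical practical-guide ranges
   `C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵}`, `γ ∈ {2⁻¹⁵, 2⁻¹³, …, 2³}`. The decision
   threshold is score 0 (exposed as a parameter). Grid search is applied
   uniformly to all three kernels.
5. **Evaluation.** Accuracy, sensitivity and specificity carry Wilson score
   95% intervals. AUC follows the Mann–Whitney definition (ties one half),
   with DeLong variance for its CI and the paired DeLong test for comparing
   two correlated AUCs on the same subjects. Classifier-vs-reader label
   disagreement uses McNemar's test — exact two-sided binomial below 25
   discordant pairs, chi-square with continuity correction above — and
   Cohen's kappa with the conventional qualitative bands (≤0 poor, then
   slight/fair/moderate/substantial/almost-perfect in 0.2 steps). Ordinal
   reader confidence (0 definitely absent … 4 definitely present) binarizes
   at 3 (0–2 negative, 3–4 positive).
6. **Learning curve.** Mean performance versus training size is fit with the
   inverse power law `y = (1 − a) − b·xᶜ` (`a` minimum achievable error, `b`
   learning rate, `c` decay rate) by weighted Levenberg–Marquardt
   (`scipy.optimize.least_squares`, analytic Jacobian, tolerances 10⁻¹⁰,
   initialization `a₀ = 1 − max(y)`, `b₀ = 1`, `c₀ = −0.5`, unit weights).
   Goodness of fit: `SSE = Σ wᵢ(yᵢ − ŷᵢ)²` and `RMSE = √(SSE/(n − m))` with
   `m = 3`. The curve inverts in closed form:
   `x* = ((1 − a − target)/b)^{1/c}`, reported as the smallest integer
   strictly greater than `x*`. Delta-method 95% bounds around the curve
   include the residual variance term by default (prediction bounds for a
   new observation, as MATLAB's `predint` draws them); confidence bounds for
   the mean curve are available via `include_observation_noise=False`.

## The phantom

The generator emulates the statistical structure the classifier exploits,
not MR physics. Geometry is a stylized 2D-extruded spine: six rectangular
vertebral bodies (S1 most caudal) separated by lens-shaped disks sharing one
anterior–posterior column band, plus a posterior soft-tissue band, extruded
across all sagittal slices. Ground-truth labels are exact by construction.

Intensities (arbitrary units): disk nucleus 120, annulus 40, soft tissue 55,
background 0. Marrow is `mean + sd · F` where `F` is a unit-SD stationary
Gaussian random field (white noise smoothed with an isotropic Gaussian of
scale `texture_corr_len = 2` voxels) — the simplest stationary texture with
controllable granularity. Defaults: normal marrow mean 100, SD 5; diseased
mean 70, SD 12 (diffusely lowered and roughened). Scanner heterogeneity is a
per-subject global affine map with offset ~ U(−20, 20) and scale
~ U(0.8, 1.2) — exactly the nuisance family that disk normalization should
(partially) remove — plus i.i.d. Gaussian noise with SD 3, i.e. 10% of the
default 30-unit class contrast. Optional focal confounds: fracture-like
collapse (row extent shrinks to 60%, intensity drops), hemangioma-like
bright blob, Modic-like endplate band. Each subject draws from an
independent child RNG stream spawned from the cohort seed, so cohorts are
bit-reproducible and order-independent.

Default volume shape is (9, 256, 192) — nine slices so the largest feature
setting (9 consecutive slices) is exercisable at realistic in-plane
resolution.

What the phantom does **not** model: relaxometry and bias fields, k-space or
vendor-specific filtering artifacts, realistic vertebral shape and
degenerative anatomy, age/sex dependence of marrow cellularity, and any
quantitative claim about real diseased-texture parameters (no published
quantitative characterization exists; the defaults are plausible effect
sizes, not estimates). Passing tests therefore demonstrate that the
implementation is correct and that the pipeline behaves sensibly under its
own stated assumptions — not that the reported clinical performance would be
reproduced on patients.

## Study designs

`orchestrate` reproduces three designs on a 180:180 training pool and a
fixed 45:62 control:diseased test set (the published cohort split):
a kernel × slice-count sweep on one fixed balanced 180-subject draw; a
training-size sweep with repeated (default 30) class-balanced random subsets
per size, whose per-repetition records allow every highest/lowest/mean±SD
aggregate to be recomputed; and an SVM-vs-reader comparison in which
simulated readers produce 0–4 confidence scores hitting a requested
sensitivity/specificity operating point in expectation. A single master seed
drives everything through `SeedSequence(master, spawn_key=(stage, …))`, so
conditions can run in any order and full reruns are byte-identical.

## Problem sizes used by the test suite and acceptance script

End-to-end runs use a (3, 64, 48) phantom (one-slice features, dimension
720) and reduced grids `C ∈ {2⁻³, 1, 2³, 2⁶}`, `γ ∈ {2⁻⁷, 2⁻⁵, 2⁻³}` — the
package's own choice of a desk-scale configuration that exercises every
stage of the full 467-subject design. The full-size default phantom is used
where geometry matters (the segmentation Dice check). The learning-curve
demonstration uses a moderate-contrast cohort (diseased mean 96, SD 7,
vendor scale U(0.75, 1.25)) so accuracy genuinely grows with training size
rather than saturating immediately; sizes 40–320 with 3 repetitions.

## Numerical choices and edge cases

* GrowCut: `g` clipped to `[ε, 1−ε]`, `ε = 10⁻⁶`; equal-attack ties resolved
  by the first neighbor in lexicographic offset order (deterministic);
  synchronous updates; non-convergence at `max_iters` returns the mask with
  `converged=False` rather than raising; zero intensity range is an error.
* Disk splitting uses integer bin assignment `⌊(col − min)·5 / extent⌋`
  clipped to [0, 4]: bins partition the disk exactly for any extent ≥ 5.
* Windows and slice stacks are clamped to image bounds (with a warning) so
  the declared feature dimension is always realized.
* Learning-curve fits exclude x = 0 anchor points (the model is undefined
  there for c < 0); they are recorded with the curve data as chance-level
  anchors. Fits require at least 4 positive-size points so the residual
  degrees of freedom are positive. A fit with `b ≤ 0` or `c ≥ 0` is returned
  but flagged not well-behaved, and inversion refuses it.
* `required_sample_size` returns the smallest integer strictly greater than
  `x*`, with a small relative tolerance so that inverting a value that lies
  exactly on the curve at a non-integer `x₀` returns `⌈x₀⌉`.
* Cohen's kappa for two constant, identical raters is defined as 1.0 and
  flagged degenerate.
* Volumes persist to NIfTI as float32 (labels int16); in-memory arithmetic
  is float64.

## Known limitations

GrowCut here is the vanilla formulation; no edge-smoothness term or
post-processing. The simulated readers are statistically calibrated but have
no perceptual model; their ROC shape comes from a fixed confidence-allocation
rule. The phantom's vendor model is purely affine, so disk normalization
removes more of it than it could on real multi-vendor data. Learning-curve
extrapolation far beyond the largest observed size inherits all the usual
risks of power-law extrapolation; the reported asymptote can exceed 1 when
the observed range is still rising steeply.
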