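# Methods

## Model and inference

A subject's `N` scans are vertices of a graph with a latent subject template
at the centre. The latent transform of node `n` maps template-space points
to timepoint-`n` points; it is estimated in two sequential stages — a rigid
transform (head repositioning) and a stationary-velocity-field (SVF)
diffeomorphism (tissue change) — both parameterised in the log domain, where
inversion is negation and composition is addition to first order in the
Baker–Campbell–Hausdorff series. The observations are `K` pairwise
registrations between timepoints; each is modelled, in the log domain, as a
Laplacian-noise corruption of the difference of the two latents it connects,
`R = W T + ζ` with the `K × N` incidence matrix `W`. A zero-centred Laplace
prior on `Σ_n T_n` (weight `b_T/b_Z`, default 1) pins the template to the
centre of the timepoints and removes the rank-1 gauge freedom of a connected
graph. The default graph is the full pairwise set `K = N(N−1)/2`; any
connected subset with `K ≥ N` is accepted (`subsample_graph`).

The MAP problem separates over spatial locations and coordinates into small
least-absolute-deviations fits,

    minimise  (b_T/b_Z)·|Σ_n T_n| + Σ_k |R_k − (W T)_k| ,

each solved as a linear program with split variables (HiGHS dual simplex,
feasibility tolerance 1e−7). Rigid parameters are location-independent, so
the rigid stage is six LPs; the SVF stage solves one LP per coordinate and
control point on a lattice with stride 8 voxels (1/8 resolution) and
upsamples the solved lattices trilinearly to the full grid.

**Degenerate optima and the minimum-norm selection.** On a full pairwise
graph every node has even degree, so the LAD optimum is generically a flat
face rather than a point (the weighted-median tie phenomenon), and a bare
simplex solver returns an ordering-dependent vertex — which would break the
method's defining property of invariance to timepoint relabelling. The
solver therefore selects the minimum-Euclidean-norm point of the optimal
face. On the face the auxiliary split variables are pinned to the residual
magnitudes, so this selection is strictly convex and symmetric in the nodes,
hence unique and exactly permutation-equivariant. It is computed by
least-distance programming (Lawson–Hanson NNLS reduction) over the optimal
slab `cost ≤ f* + ε`, with a deterministic ladder of slab widths
(`ε/(1+|f*|)` from 1e−11 to 1e−8) and a fallback to the simplex vertex if
the projection is rejected by the feasibility check. In randomised stress
tests the relabelling discrepancy is at the 1e−12–1e−9 level; without the
selection it reaches 1e−1.

## Rigid log/exp

Closed forms on SE(3): the angle is `φ = arccos((tr U − 1)/2)`, the rotation
generator comes from the skew part scaled by `φ/(2 sin φ)`, and the
translation generator is `d = V⁻¹ t` with the left Jacobian
`V = I + (1−cos φ)/φ² Q + (φ−sin φ)/φ³ Q²` and
`V⁻¹ = I − Q/2 + (1/φ²)(1 − φ sin φ / (2(1−cos φ))) Q²`. All
`sin φ/φ`-type coefficients switch to 4th-order Taylor expansions below
`φ = 1e−5`. Logs are canonical (`|q| ∈ [0, π)`); angles within `1e−6` of π
raise an error rather than branch-selecting, since longitudinal
intra-subject rotations are degrees, not half-turns. Both maps are verified
in the tests against `scipy.linalg.expm/logm` applied to the 4×4 homogeneous
generator.

## Velocity fields, resampling, Jacobians

Fields store world-mm vectors at the voxels of an `ImageGrid` (shape + 4×4
voxel→world affine, RAS). `exp(t·v)` uses scaling-and-squaring: scale by
`t/2ⁿ`, then self-compose `n` times; `n` starts at 8 and grows until the
maximum scaled step is under half a voxel. Composition is exact
(`(a∘b)(x) = b(x) + a(x + b(x))`, trilinear, clamp-to-edge). The 48³ Euler
cross-check (2¹² steps) agrees to ~2e−3 voxel RMS.

`resample_image` pulls an image through an ordered chain of point maps with
exactly one interpolation of the source — the invariant behind the "no
double resampling" rule: every emitted product is traced back to the
original scans through concatenated transforms. Outside-source samples fill
with 0; one-hot label resampling is trilinear per channel with an argmax at
the end (ties to the lowest label id).

Jacobian determinants use central differences in voxel space mapped through
the inverse affine; the one-voxel border replicates the interior.

## Subject space and template

After the rigid stage the subject space is an isotropic RAS grid covering
the rigidly-mapped corners of every timepoint plus a 5-voxel margin per
face, centred at the world origin. Its spacing defaults to the finest input
spacing (1 mm for clinical T1w data; a coarse phantom keeps its own
spacing). Template fusion: voxelwise **median** intensity (the MAP fusion
under Laplacian image noise, and markedly more outlier-robust than the
mean), **mean** mask (tissue probability, stored as a probability and
thresholded at 0.5 only on demand), and argmax of the **mean one-hot**
segmentations. Even-`N` medians use the midpoint of the central pair. Every
timepoint enters symmetrically, so the template is exactly invariant to
timepoint order.

## Stationary trajectory and TBM

A per-voxel, per-coordinate ordinary-least-squares line through the latent
SVFs against acquisition time (years from baseline) gives an intercept field
`c` (the offset of the template from the time origin) and a slope field `T̂`
(deformation rate per year). OLS is used because it is closed-form and the
voxelwise linear model does not specify a loss; the fit is exact for `N = 2`.
Evaluation at time `t` exponentiates `t·T̂` (optionally `c + t·T̂`);
prediction warps the template through `exp(−(c + t·T̂))` in one
interpolation, so interpolated or extrapolated images show no accumulation
blur. `predict_image` includes the intercept by default (it places the
template at its own time origin) and exposes `include_intercept=False` for
the pure rate model; TBM maps are the Jacobian determinant of the
trajectory integrated over 1 year (values < 1 = contraction).

## Label fusion

Images are first scaled so the mean white-matter intensity is 110; the
Gaussian intensity kernel (σ = 3) is interpreted on that normalised scale.
For reference timepoint `n`, every other timepoint's image and one-hot
labelmap are pulled into space `n` through the concatenated chain
`rigid_n⁻¹ → exp(−T_n) → exp(T_{n′}) → rigid_{n′}` (one interpolation),
weighted per voxel by `exp(−ΔI²/2σ²)` and averaged; the output is the
argmax. The reference's own weight is identically 1, so it always
contributes at least as much as any other timepoint — with only two
timepoints the fusion therefore cannot override the reference, and its
test–retest benefit appears when the retest pair is embedded in a longer
series. Weights are per-voxel (not global), matching the intensity
-difference reading; no brain-mask restriction is applied to the kernel by
default.

## Evaluation statistics

Symmetrised percent change `SPC = 100·2(V₂−V₁)/(V₁+V₂)` and its absolute
value ASPC; trajectory smoothness as the ℓ2-norm of consecutive
finite differences of a volume series; the longitudinal sample-size formula
`m = 2(z_{1−α} + z_P)² σ²(1−ρ) / (N s_x² d²)` with one-sided α (the printed
`(z_α + z_{1−P})²` equals `(z_{1−α} + z_P)²` by quantile symmetry) and the
method-comparison ratio `R = 100·σ₁²(1−ρ₁)/(σ₂²(1−ρ₂))`; and a voxelwise
two-sample pooled-variance t-test (two-sided — group maps show both
expansion and contraction) with Benjamini–Hochberg FDR across in-mask,
non-degenerate voxels.

## Synthetic phantom: what it emulates and what it does not

The default phantom is a scaled-down head: 48³ voxels at 3 mm (144 mm field
of view) with nested ellipsoids — a GM-like shell (intensity 70, −0.8 %/yr
diffuse loss), WM core (110, so the fusion normalisation is exercised
unchanged), a hippocampus-like structure (85, −3 %/yr), a ventricle-like
structure (30, +6 %/yr) and a cerebellum-like structure (95) placed off the
plane of the other centroids so that label-centroid rigid alignment is
well-conditioned in all six degrees of freedom. The coarse-grid/anatomical-
size design keeps volumes desk-sized while the millimetre scale of atrophy
displacements stays realistic. Five sessions at 0, 0.35, 0.9, 1.4 and 2.0
years emulate an uneven clinical follow-up.

Atrophy is generated as a per-year slope SVF: inside each changing
structure a linear field `(δ/3)(x−c)` with `δ = ln(1 + rate/100)`, windowed
by a smooth plateau equal to 1 over the dilated structure, so its flow
multiplies the structure volume by exactly `1 + rate/100` per year. Latent
fields are `(t_n − t̄)·slope` plus a small smooth per-timepoint fluctuation
(0.1 mm), both mean-subtracted so `Σ T_n = 0` holds identically (the
drift-free condition). Rigid jitters (±2°, ±2 mm) are drawn in the log
domain and mean-subtracted likewise. Images are one-interpolation warps of
the template plus Gaussian intensity noise (sd 3 ≈ 3 % of white matter);
labelmaps additionally traverse an independent smooth 1 mm error warp that
emulates cross-sectional segmentation error. Pairwise "registrations" are
the exact log-domain compositions plus i.i.d. Laplace noise (b = 0.25 mm, a
mid-range figure for learned SVF registration), optionally with a seeded
fraction of 10× gross outlier edges. One seeded generator fixes everything
bitwise.

Not emulated: MRI physics (bias fields, Rician noise, contrast change
across scanners), spatially correlated registration error, non-linear
(accelerating) atrophy, and cortical folding geometry. Tests passing on the
phantom therefore demonstrate the estimator's statistical behaviour under
its own model assumptions — unbiasedness, robustness, graph-density
scaling — not registration accuracy on real tissue contrast.

## Built-in registration backends

The framework is registration-agnostic; transforms from external tools plug
in through text affines and 4-D NIfTI velocity fields. Two simple built-in
backends make the pipeline self-contained: (i) rigid alignment by
orthogonal Procrustes on shared label centroids (SVD with determinant
correction, so reflections are never returned; fewer than 3 shared labels
or collinear centroids raise a degenerate-geometry error); and (ii) an SSD
demons-style SVF optimiser — stabilised symmetric-gradient force, update
capped at half a voxel, fluid smoothing (σ = 2 voxels) of the update plus a
light diffusion smoothing (σ/4) of the field, over a factor-2 pyramid
(2 levels, 80 iterations). On noise-free phantoms it removes ≥ 95 % of the
SSD and recovers known smooth deformations to < 0.5 voxel RMS; it is a
deliberately simple stand-in, not a replacement for a modern learned
registrar.

## Numerical choices and problem sizes

LP feasibility tolerance 1e−7; minimum-norm tie-break as above; argmax ties
to the lowest label; clamp-to-edge for field lookups, zero-fill for image
resampling; trajectory fit rejects all-equal times; SPC rejects
non-positive volume sums. The test-suite and acceptance-script experiments
run on the 48³ default phantom (5 timepoints, full 10-edge graph), 24³–40³
grids for operator-level checks, and 10 phantom seeds for the smoothness
comparison — sizes chosen so the whole suite runs in minutes on one CPU
while every property is exercised at its native dimensionality.

## Known limitations

The first-order BCH linearisation underlies both the graph model and the
additive composition of intercept and slope; it is accurate for the small
intra-subject deformations of adult longitudinal imaging and degrades for
large morphological change (development, resection). Rotations near π are
rejected rather than resolved. The slope field recovered from noisy
registrations is reliable where atrophy displacement is large relative to
the registration noise; at b = 0.25 mm and AD-like effect sizes the
voxelwise slope correlation with the generating field is ≈ 0.6, rising
above 0.9 only when the registration noise scale drops below ≈ 0.05 mm —
volume-level and region-level statistics remain informative well before
voxel-level slope maps do. `b_T` and `b_Z` are not estimated from data; only
their ratio enters, fixed at 1 by default.
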