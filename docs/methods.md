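# Methods

This note documents the models, parameter choices and numerical details
behind `vesiflow`, and what the synthetic benchmarks do and do not show
about real microscopy data.

## Coordinate and unit conventions

Stacks are `(frame, row, column)` arrays, 0-based, pixel centers on the
integer grid. Angle arithmetic uses image coordinates x = column
(rightward), y = row (downward); angles are `atan2(y, x)` in (−π, π].
Because both the to-center angle α and the flow angle β are computed in
the same frame, their difference — the only quantity the classifier
uses — is independent of the handedness of this convention.

Flow is reported in pixels/frame throughout. The frame interval and
pixel size are carried as metadata only; converting to physical units is
a presentation step, since nothing in the estimation depends on them.

## Optical flow

Dense single-level Lucas–Kanade. For each adjacent frame pair, both
frames are Gaussian pre-smoothed (`smoothing_sigma`, default 1.0 px;
0 disables, which the equation-level oracle tests use), spatial
gradients are central differences of the two-frame mean (symmetric in
the pair, reflect boundary), and the temporal derivative is the plain
frame difference. The per-pixel 2×2 weighted normal-equations system is
solved over a (2r+1)² window, default r = 7 with a Gaussian weight
profile (σ = r/2); the window is normalised so ΣW² = 1, making the
structure tensor a weighted *mean* of gradient products and the
degeneracy threshold independent of window size.

A pixel is flagged invalid when the smaller structure-tensor eigenvalue
falls below `eigenvalue_min` (default 1e-4, in squared-gradient units of
the input intensity scale); invalid pixels carry (0, 0) and are excluded
downstream. At image borders the window is truncated; the vectorised
implementation reproduces the truncated per-pixel solve exactly because
zero-padding the gradient *products* before the windowed correlation is
algebraically identical to summing over the in-image window only.

No pyramidal or iterative refinement is used: the linearisation is
trusted only for displacements up to roughly the spot width (~2 px per
frame for diffraction-limited vesicles). Faster transport needs a
shorter frame interval, not a different solver.

## Cell-center estimation

The per-pixel temporal standard deviation (sample STD, N−1 denominator)
is low where nothing moves: near the cell center early in endocytosis,
and everywhere in the dark background. The quiet mask keeps pixels with
σ strictly below σ̄ − σ_s, where σ̄ and σ_s are the mean and sample STD
(mn−1) of the σ distribution; the center is the unweighted centroid of
that mask, in continuous (row, col) coordinates, with no rounding. Ties
at the threshold are excluded (strict inequality). An empty mask (e.g. a
constant stack, where σ ≡ 0 and σ < 0 never holds) raises an estimation
error; the failure is always reported, never silently defaulted.

Because dark background is as quiet as the cell center, the default
"masked" mode restricts both the σ statistics and the mask to the cell
foreground. The foreground is Otsu's threshold applied to the *log* of
the temporal mean image: on the raw mean, a bright vesicle-rich
periphery forms its own intensity mode and Otsu then separates
bright-from-dim, cutting the dim quiet interior — exactly the region the
estimator needs — out of the foreground. The log compresses spot
brightness so the split falls between background and cell instead. The
unrestricted "literal" mode applies the rule to every pixel and is what
the exactness tests check against brute-force recomputation.

## Direction classification

α is the angle of the pixel-to-center vector, β the flow angle; the
wrapped difference Δ = min(|α−β|, 2π−|α−β|) ∈ [0, π] classifies the
pixel: Inward for Δ ≤ π/2 (closed interval, so exactly tangential motion
counts as Inward), Outward for Δ > π/2. Two numerical details:

* Deltas within 1e-12 rad of π/2 are snapped onto the boundary, so
  analytically tangential fields — whose computed Δ lands a few ulps
  either side of π/2 — classify consistently as Inward. An optional
  `tangential_band` (default 0) instead *excludes* a band around π/2
  for users who prefer not to count tangential motion at all.
* Pixels are excluded when the flow is invalid, when the pixel sits on
  the center (α undefined), or when the flow magnitude is below
  `magnitude_min` (default 0.1 px/frame). The magnitude floor suppresses
  noise-floor flows, which otherwise split ~evenly between the two
  classes and dilute the proportions; it is deliberately conservative
  and config-exposed.

Per-frame summaries report both the number of solvable-flow pixels and
the number of classified (above-magnitude) vectors, since "detected" can
reasonably mean either; proportions are NaN, not zero, for frames with
no classified vector.

The sensitivity analysis displaces the center to n_angles = 8 evenly
spaced positions on circles of radius 1, 2, 5 and 10 px (defaults),
recomputes the maps, and reports the percentage of pixels (classified
under both centers) whose label flips, plus the mean |Δ| error, pooled
over frames. Displacements landing outside the image are skipped and
logged. Aggregation over angles pools flip/compared *counts* rather than
averaging percentages, so displacement directions with more classified
pixels weigh proportionally.

## Polar transform

Images are resampled on an (R, θ) grid about the center: R spans
[0, r_max] in n_r uniform samples — the first row is exactly R = 0, the
center value repeated across angles — and θ spans [0, 2π) in n_theta
uniform bins measured from +x toward +y. Defaults: r_max = distance to
the nearest image edge, n_r = ⌈r_max⌉ + 1 (one sample per pixel of
radius, endpoints included), n_theta = 360. Continuous planes use
bilinear (or nearest) interpolation via `scipy.ndimage.map_coordinates`;
categorical label planes are always nearest-neighbour — interpolating
category codes is meaningless, so this is forced, not optional. Samples
falling outside the image get a dedicated fill value (NaN for
continuous planes, Excluded for labels) and are counted.

## Rendering

The diverging encoding maps Δ to colormap position Δ/π exactly —
monotone and invertible — on a red–white–blue palette (default
matplotlib `RdBu`; any diverging palette can be substituted): red
extreme = straight at the center, blue extreme = straight away, neutral
midpoint = tangential. By default Δ alone drives the color; an optional
mode fades weak flows toward the neutral midpoint in proportion to
magnitude/`magnitude_ceiling`. The HSV encoding maps flow orientation
linearly onto the hue circle and clipped magnitude onto saturation, and
is exactly invertible below the magnitude ceiling (the decode helper
exists to prove it). Both renders mark the identical pixel set —
invalid flow — as background.

## Synthetic data

The generator emulates a mid-plane confocal cross-section of one cell:
a uniform disk (cell body) over dark background, with each vesicle an
isotropic Gaussian spot (σ default 1.5 px — quantum dots are
sub-resolution, so a Gaussian PSF is the standard approximation).
Motion per frame: a radial step of `radial_speed` toward or away from
the true center plus per-axis N(0, diffusion_sigma²) jitter, or jitter
alone for diffusive vesicles; inward steps never overshoot the center,
inward vesicles freeze within 1 px of it, and outward vesicles clamp
onto the cell boundary (clamping, not reflection, avoids manufacturing
spurious reversed flow at the rim). Noise is additive Gaussian read
noise (default 5 % of spot amplitude) with optional Poisson shot noise,
applied after rendering; negative values are clipped at zero. A scene's
seed fully determines the stack and the ground truth.

Two named study scenes fix the benchmark conditions:

* `radial_scene` — 50 vesicles split evenly inward/outward at
  1.5 px/frame, jitter 0.2 px/frame, default noise, 128×128×20. Used
  for direction-recovery and sensitivity benchmarks.
* `peripheral_scene` — 350 diffusive vesicles with small (0.5 px/frame)
  jitter tethered in the outer annulus (0.55–1.0 of the cell radius),
  60 frames. Used for center-recovery benchmarks. Two constraints shaped
  it: the jitter must stay small (a larger random walk migrates spots
  ~15 px into the interior over the movie and erases the quiet core the
  estimator assumes), and the annulus must be densely covered (sparse or
  short movies leave quiet pockets between spots whose asymmetry biases
  the centroid by several pixels).

What passing these benchmarks does *not* show: the generator has no
photobleaching or blinking, no axial (3-D) motion — vesicles leaving
the focal plane are a known failure mode of any 2-D flow method — no
microtubule-geometry correlations between trajectories, and a noise
model far simpler than a real EMCCD's. Results on the synthetic scenes
bound the method's behaviour under its own assumptions, not its accuracy
on arbitrary real cells.

Benchmark evaluation protocol: direction-label accuracy is scored on
classified pixels within 2·psf_sigma of a vesicle whose ground-truth
motion over that frame pair is inward (resp. outward, by the sign of the
change in distance to the true center, tolerance 0.25 px). Pixels near
vesicles of both classes at once, or near static vesicles, carry no
single ground-truth direction and are excluded from the denominator.

## Problem sizes

The bundled benchmarks use 128×128 movies: 20 seeds × 60 frames for
center recovery, 10 seeds × 20 frames for direction recovery, 3 seeds ×
6 frames for the sensitivity curve — small enough to run in seconds to
tens of seconds on one CPU while leaving the per-seed statistics (10⁴–10⁵
scored pixels) stable.

## Known limitations

* Displacements beyond ~2 px/frame violate the single-level LK
  linearisation; there is deliberately no pyramid.
* The center estimator assumes the quiet-core intensity structure of
  early endocytosis; late-stage movies with a bright, busy perinuclear
  region will defeat it (an MTOC channel, if available, is the better
  center source).
* Tangential motion is ambiguous by construction (Δ = π/2) and counts
  as Inward under the closed-interval rule unless a tangential exclusion
  band is configured.
* One cell per field is assumed; neighbouring cells bias both the Otsu
  foreground and the centroid.
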