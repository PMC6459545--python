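# Methods

This note records the models, conventions, parameter choices and known
limitations behind fibramorph's estimators, and what the synthetic phantoms
do and do not establish about real micro-CT data.

## Coordinate and angle conventions

Volumes are numpy arrays indexed `(z, y, x)`; exported tables use 0-based
`x, y, z` columns. A fiber axis is parameterized by azimuth θ ∈ (−90°, 90°]
(in the XY plane, from +x toward +y) and elevation φ ∈ [0°, 90°] (tilt out
of the XY plane; φ = 90° is along Z), with unit direction

    d(θ, φ) = (cos φ cos θ, cos φ sin θ, sin φ)    as (x, y, z).

Fibers are orientations, not vectors: `v` and `−v` are identical.
`vector_to_angles` canonicalizes the sign (flip so x > 0; if x = 0 so
y > 0) and uses φ = asin(|z|). Because elevation is unsigned, a (θ, φ) pair
identifies an axis only up to reflection through the XY plane; the phantom
generator always emits the z ≥ 0 representative, so ground-truth
comparisons are unambiguous. Azimuth differences are always measured with
180° wraparound: Δθ = min(|Δ|, 180° − |Δ|).

## Phantom generator

Each fiber is a straight, solid circular cylinder: a voxel is foreground
when its centre lies within diameter/2 of the axis segment (boundary
included — the rasterization equivalent of propagating a filled disk along
the axis). Candidates are sampled from uniform ranges in the fixed order
θ, φ, diameter, length fraction, gap, seed point, all from one PCG64 stream,
so phantoms are bit-reproducible from `rng_seed`.

Default ranges follow the benchmark conditions used throughout validation:
512³ voxels, 20–100 fibers, diameters 3–20 voxels, lengths 20–80% of the
minimum side, inter-fiber gaps 3–10 voxels, and rejection of candidates
with more than 50% of their coordinates outside the volume. Choices the
benchmark description leaves open, fixed here:

- **Placement**: the segment is centred on a seed point sampled uniformly
  in the volume; fibers may protrude through the border up to the
  outside-fraction threshold.
- **Outside fraction** is evaluated on a deterministic point sample of the
  cylinder (axis points at unit spacing, each with four surface offsets),
  so a fiber wider than the volume is rejected just like one that runs out
  of it.
- **Gap**: sampled per candidate fiber and enforced against the union of
  all existing fibers, by testing the candidate's (radius + gap)-inflated
  capsule against current occupancy. This guarantees a voxel-to-voxel
  separation of at least the later fiber's gap between any two fibers.
- **Stop rules**: `max_fibers` (target drawn from `n_fibers_range` unless
  given), `volume_fraction`, or `max_failed_attempts`; a failed-attempt
  budget (default 100) acts as a safety limit in every mode. A degenerate
  configuration (e.g. diameter exceeding the volume) therefore terminates
  with an empty phantom and a warning, not an exception.
- Where intersections are allowed, overlap voxels carry the label of the
  most recently added fiber.

Contamination adds i.i.d. Gaussian noise of width σ_agn to the float-cast
binary volume and then smooths with an isotropic Gaussian of width
σ_smooth, in that order, emulating detector noise followed by finite
system resolution.

What the phantoms do **not** emulate: curved or intertwined fibers, beam
hardening and reconstruction artifacts, partial-volume gray levels at real
material interfaces, anisotropic voxels, and surface-attached particles.
Passing the phantom suite therefore demonstrates correctness of the
estimators' geometry and their noise response, not segmentation quality on
experimental scans.

## Segmentation and skeletonization

Foreground is *strictly above* the threshold (Otsu or fixed), making
binarization bit-reproducible. Skeletons come from scikit-image's 3D
parallel thinning (Lee's method); the implementation and version are
recorded in `SkeletonVolume.method`. Known limitation of that thinning:
perfectly symmetric even-width objects aligned with the lattice (e.g. an
axis-aligned cylinder whose axis lies exactly between voxel rows) can be
eroded away entirely. Fibers at generic orientations — including all three
benchmark compositions — are unaffected.

## Structure-tensor orientation

Gradients are Gaussian derivatives at σ = 1 voxel (default; the smallest
width that suppresses rasterization staircase without blurring thin,
3-voxel fibers). The tensor is averaged **uniformly** (boxcar) over a cubic
window of side `window_vox` centred on each skeleton voxel; windows are
clipped at the volume border and averaged over their valid part. Averaging
uses per-component summed-area tables in float64, so a window sweep costs
little more than a single pass, and window sums are exact to ~1e−10
relative error. The fiber axis is the eigenvector of the smallest
eigenvalue (gradients on a tube's surface are perpendicular to its axis).
Voxels with vanishing tensor trace (< 1e−12) or a degenerate smallest
eigenpair are omitted and counted in `n_skipped` rather than fabricated.

The default window of 32 voxels sits on the error plateau identified by the
window sweep (error falls steeply from window 4 to 20, then flattens); the
window must straddle the thickest fibers (20 voxels) to see their surface
on both sides. Near φ = 90° the azimuth of an axis is intrinsically
ill-conditioned (at the pole it is undefined); the angular-range scan
therefore also reports the geodesic axis error, which is well-conditioned
everywhere.

## Fourier/PCA orientation (2D)

The image is mean-subtracted and multiplied by a separable Hann window
before the FFT — without it, spectral leakage from non-periodic borders
smears energy along the frequency axes and biases the principal axis by a
degree or two. The power spectrum (DC removed) weights its frequency
coordinates; the spectral second-moment matrix is eigen-decomposed and the
image orientation is perpendicular to the major axis. The anisotropy score
1 − λ₂/λ₁ is near 0 for isotropic textures (white noise: ≈ 0.04 at
128² pixels) and near 1 for stripes; results with anisotropy < 0.1 should
be treated as unreliable direction estimates.

## Ray-cast diameter

At each oriented skeleton voxel an orthonormal basis {u, v} ⊥ d is built
deterministically (u = normalize(d × e) with e the coordinate axis least
parallel to d; v = d × u). 16 rays (default) march in the {u, v} plane in
0.5-voxel steps, sampling the binary volume by nearest-voxel lookup — this
keeps the binary semantics exact, and the half-voxel step bounds the
per-ray discretization error by half a voxel. A ray stops at its first
sample outside foreground at distance t; opposite rays a, b give the chord
t_a + t_b − step (the −step centres the estimate between the last inside
and first outside samples). The diameter is the mean chord over pairs whose
rays both stayed within the volume; pairs with an out-of-bounds ray are
discarded, and a voxel whose rays are all still in foreground at
`max_march_vox` (default: half the longest side — larger than any structure
of interest) is recorded as censored at that value. Expected accuracy on
cylinders is within one voxel; exact lattice placement of the axis
contributes ±0.5 voxel of wobble.

## Porosity and counting

Porosity is exact voxel counting on the labeled volume (background fraction
plus per-label fractions; they sum to 1 by construction). Object counting
labels binary input by connected components (default 26-connectivity, the
standard choice for particle counting) and reports voxel count, centroid,
bounding box and the equivalent-sphere diameter (6V/π)^(1/3) as the
headline size metric.

## Color mapping and statistics

`geo2rgb` fixes hue = (θ + 90°)/180°, saturation = 1,
value = 0.3 + 0.7·φ/90° — the 0.3 floor keeps in-plane fibers visible in
renders; the mapping is deterministic and injective on a 10° grid.
Rendering itself is left to external viewers; the package emits per-voxel
RGB tables. Tukey's HSD post-hoc (via statsmodels) compares all group
pairs after the usual studentized-range construction; groups with fewer
than two observations are rejected by name.

## Validation protocol and problem sizes

Angular error against ground truth assigns each estimated voxel the angles
of the fiber whose label it carries, falling back to the nearest labeled
voxel for skeleton drift or noise-induced voxels; the summary is the
mean ± std of per-voxel absolute errors (azimuth wraparound-aware). The
noise sweep runs contaminate → Otsu → skeletonize → orient (tensor input is
the contaminated grayscale volume), with the per-σ noise seed derived as
`rng_seed + index`. Under this pipeline, σ_agn ≥ 1.0 produces spurious
foreground components whose skeleton voxels dominate the mean error; how a
segmentation step should treat such components is application-specific, so
the sweep reports the uncleaned pipeline's behavior. Degradation is
monotone in σ_agn in all compositions.

Problem sizes: the headline accuracy checks and `scripts/acceptance.py` run
the full 512³ benchmark conditions (about 80 s per phantom on one CPU,
peaking near 4 GB via float32 gradients and one float64 summed-area table
at a time). The window/noise sweeps and diameter checks in the test suite
use proportionally reduced phantoms (160³–256³ with correspondingly fewer
fibers), which preserve fiber geometry (diameters, gaps, window size) while
keeping the suite fast; the angular-range scan uses 64³ single-fiber
volumes with the estimator evaluated on interior axis voxels, isolating it
from end effects and thinning.
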