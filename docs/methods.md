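# Methods

This note documents the models and procedures implemented in `spinetrack`,
the parameter choices that matter, what the synthetic scenes do and do not
emulate, and the numerical conventions a user relying on the outputs should
know.

## Two-view geometry and the error metric

Cameras are metric pinholes: focal lengths `(fx, fy)` and principal point in
pixels, an orthonormal world-to-camera rotation, and a centre in
millimetres. Pixel coordinates are 0-based, origin top-left, x rightward,
y downward, pixel centres on integers; the x-axis is chosen along the line
connecting the two cameras. For a calibrated rig the fundamental matrix is
computed as `F = [e′]ₓ P2 P1⁺` and normalised to unit Frobenius norm with
its largest-magnitude element positive, so numerical comparisons are
deterministic. Without calibration, `F` can be estimated from ≥ 8
correspondences by the normalised 8-point algorithm with rank-2 enforcement;
metric (millimetre) triangulation always requires the calibrated path —
the estimated `F` supports rectification and the epipolar filter only.

Rectification follows the projective (epipole-to-infinity) scheme: the
second view is warped by `H′ = T⁻¹ G R T` (centre translation, rotation of
the epipole onto the x-axis, epipole-to-infinity map `G`), and the first by
`H = A H′ M` where `F = [e′]ₓ M` and the row-preserving affinity `A`
minimises the summed squared horizontal disparity of the seed
correspondences by linear least squares. Output translations use a shared
vertical offset so row alignment is preserved. Two special cases:

* Input already rectified (F has the canonical form with zeros in row 1 and
  column 1): the identity pair is returned — warping would only resample.
* An epipole inside either image makes the projective warp unbounded and is
  rejected.

For a calibrated rig the pipeline synthesises its own seed correspondences
by back-projecting a view-1 pixel grid at two depths bracketing the rig's
convergence distance (2.5× the baseline for parallel rigs) and re-projecting
into view 2. These are exact correspondences of the rig regardless of the
actual scene.

The 3D position of a matched pair is the **midpoint** of the shortest
segment `Vp` between the two back-projected rays, and the **triangulation
error is `|Vp|` in millimetres**. This is a self-diagnosing metric: it
needs no ground truth, but it measures ray consistency, not 3D accuracy.
In rectified frames with integer-row detections, wrong matches on the same
row produce coplanar rays and hence zero `|Vp|` — the metric is blind to
pure along-row mismatches, which is why the synthetic validation also
checks recovery against ground-truth landmarks. Rays with
`|sin(angle)| < 1e-8` are rejected rather than returning an unstable
midpoint.

## Preprocessing

CLAHE uses per-tile histograms clipped at `ceil(clip · tile_pixels)` with
the excess redistributed uniformly (the uniform target histogram), and
bilinear blending between tile mappings. Defaults: clip 0.03, 8×8 tiles
(the tile grid is a common toolbox convention; it is configurable).
A consequence worth knowing: on a tile whose histogram is concentrated in a
few levels, clipping forces the mapping toward identity, while sparse
intensity tails (small bright features on a textured background) are
compressed — contrast enhancement is not monotone in feature contrast.

Otsu's threshold is the 8-bit level maximising between-class variance,
lowest level on ties; segmentation takes the Otsu foreground, grows an
8-connected region from the seed (default: centroid of the largest
foreground component, snapped onto it), multiplies the image by the binary
mask and crops to the mask bounding box. The bounding-box crop replaces
interactive cropping so the pipeline runs unattended; detected coordinates
are shifted back to full-frame pixels afterwards. Enhancement runs after
rectification and before thresholding.

## Detectors

All four detectors are implemented here, because their internals are the
subject of the comparison; none delegates to an external implementation.

**Hessian blobs (SURF-style).** Box-filter approximations of the
second-order Gaussian derivatives on an integral image, combined as
`det = Lxx·Lyy − (0.9·Lxy)²`, responses normalised by filter area. Octave
`o` (0-based) uses filter sizes `3·2^(o+1)·k + 3`, `k = 1..n_scales`;
keypoints are 3×3×3 non-maxima over position and scale with response at
least the feature threshold (default 600 on 8-bit intensities). The scale
label is `σ = L / 5.4`, calibrated on the response peak of this pyramid to
an isotropic Gaussian blob (a blob of scale `s` is selected by filter size
`≈ 5.4 s`); the textbook equivalence `1.2·L/9` describes the best-fitting
Gaussian derivative kernel, not the selection peak of an area-normalised
box pyramid, and would mislabel selected scales by ~40%. Orientation is the
sliding-π/3-sector maximum of Gaussian-weighted Haar responses on a
radius-6σ disc (flat patches fall back to 0); the descriptor sums
orientation-aligned Haar responses `(Σdx, Σ|dx|, Σdy, Σ|dy|)` over a 4×4
grid of subregions in a 20σ window — 64 values, unit-normalised. Keypoints
whose window leaves the image are dropped.

**MSER.** An explicit threshold sweep (step: percentage of the intensity
range, default 0.3% ⇒ every grey level) labels extremal components at every
level; components are tracked through their root pixel (raster-first
minimum-intensity pixel) and emitted where the relative area change per
step is a local minimum, at most 0.3, with area inside [100, 800] px².
Both polarities are swept. Regions are summarised by the second-moment
ellipse. For matching, each region becomes a keypoint at its ellipse centre
with equivalent scale `0.4·√(area/π)`, described by the same 64-d
descriptor, so all detectors share one matching path.

**FAST.** Segment test on the 16-pixel Bresenham circle of radius 3: a
corner needs `arc_length` contiguous circle pixels all brighter than
`I(p)+T` or all darker than `I(p)−T`, with the 3-of-4 compass pretest
applied when it is exact (arc ≥ 12 — any 12-run covers three compass
positions). `T = min_contrast·255` (default 0.2 ⇒ 51 grey levels);
non-maximum suppression on the summed-excursion score with raster
tie-breaks, and acceptance at `score ≥ min_quality · max score` (default
0.1). Geometry note: a right-angle corner darkens exactly 11 of the 16
circle pixels, so the classical default arc of 12 cannot fire on
axis-aligned rectangle corners; the test suite exercises that fixture at
arc 11, where exactly the four corners appear. FAST keypoints are matched
upright (orientation 0) at a fixed descriptor scale of 2 px — the views are
rectified, so relative rotation between views is small.

**ORB.** FAST corners (internal threshold 20 grey levels, the classical
default — the benchmark setup does not state one) on a 1.2× image pyramid
of 8 levels, strongest `n_features` kept (default 1500; unbounded output on
speckled scenes makes dense Hamming matching needlessly quadratic).
Orientation is the intensity-centroid angle `atan2(m01, m10)` over a
radius-15 disc; the 256-bit descriptor compares pairs of pixels of a 5×5
box-smoothed patch at a fixed seeded pseudo-random test pattern (points
within radius 13, so rotated tests stay inside the patch), rotated by the
keypoint orientation. Coordinates are mapped back to level-0 pixels.

## Matching and outlier rejection

Matching is mutual-best and one-to-one: normalised cross-correlation for
real-valued descriptors (higher better), Hamming distance for binary
(lower better); ties break toward the lower second-view index, pairs are
returned best-first. NCC on raw bits is available (`metric="ncc"`) for
strict fidelity with pipelines that correlate every descriptor type, but
Hamming is the default for binary descriptors. No ratio test or score
floor is applied by default. The epipolar filter only flags pairs — it
never re-matches: in rectified mode a pair survives if `|y1 − y2| ≤ 1 px`
(configurable), in general mode if the symmetric point-to-epipolar-line
distance given `F` is within tolerance.

## Synthetic scenes: what they emulate, what they do not

`make_scene` builds a deterministic scene per seed: a heightfield surface at
a 1 m working distance, a procedural albedo (bright central band as the
exposed-spine proxy, multi-scale noise texture, hard-edged elliptical blobs
sized for the MSER area window), landmarks, and a two-camera metric rig
(defaults: baseline 400 mm, focal 1000 px, 10° vergence, 640×480 — declared
plausible stand-ins for a surgical camera rig, not measured values).
Rendering casts per-pixel rays against the analytic heightfield (fixed-point
iteration on depth), applies Lambertian shading × a global illumination
scalar, and adds Gaussian pixel noise (default σ = 2 grey levels) before
8-bit clipping. Ground-truth projections are computed analytically with the
projection model, never estimated from the rasterisation.

Two presets:

* **default** (`surface="ridge"`, landmarks at texture extrema): used for
  all stochastic experiments — noise calibration, illumination effects, the
  four-detector benchmark.
* **validation** (`make_validation_scene`): a fronto-parallel plane viewed
  by a parallel rig whose pixel disparity `f·B/Z = 240` is an exact integer
  and a whole number of CLAHE tiles, with a textureless band that is flat
  across the entire stereo overlap and analytic Gaussian peak landmarks at
  integer-pixel view-1 projections (per-landmark widths and satellite bumps
  make each descriptor unique). View 2 is then an exact integer translation
  of view 1, every stage of the pipeline is translation-equivariant, and
  the full chain recovers landmark positions to machine precision. This is
  the scene on which "the pipeline is geometrically exact" is a meaningful,
  testable statement; any looser scene conflates detector localisation
  noise with geometric error.

What passing on these scenes does **not** show: robustness to specular
highlights, blood, retractors and occlusion; lens distortion (not
modelled — the camera is an ideal pinhole); rolling illumination gradients;
non-rigid tissue motion; real tissue texture statistics. Clinical accuracy
claims require clinical images.

`planted_correspondence_set` bypasses rendering entirely: exact projections
of random surface points, isotropic Gaussian pixel noise, and an exact count
of planted outliers displaced in y by at least 10× the epipolar tolerance.
It calibrates the triangulation-error scale: at 0.5 px noise on the default
rig the 500-point mean agrees with a 50 000-point Monte-Carlo estimate
within a few percent, and error means increase monotonically over
σ ∈ {0, 0.25, 0.5, 1} px.

## Statistics

`summarize` reports per-group mean, sample SD (NA for a single value),
median and IQR of triangulation errors, and max/min/mean/median/IQR of
per-frame inlier counts; frames with zero inliers count toward inlier
statistics but contribute no errors. Quantiles use linear (type-7)
interpolation — median/IQR values from other conventions differ at the
margins. Error CDFs carry a distribution-free Dvoretzky–Kiefer–Wolfowitz
band, half-width `sqrt(ln(2/α)/(2n))`; at n = 100 and 95% confidence this
is ≈ 0.1358. Timing tables give per-stage mean ± sample SD and a
frames-per-second figure as 1/(mean detection time); absolute timings are
hardware-dependent and only ratios between detectors are meaningful.

## Problem sizes and defaults used in validation

The shipped validation (test suite and `scripts/acceptance.py`) uses
640×480 scenes with 20 landmarks, 500-point planted sets against a
50 000-point Monte-Carlo oracle, two frame pairs per detector for the
benchmark, and 10 paired seeds at 320×240 for the illumination comparison —
sizes chosen so a complete run finishes in about a minute on one CPU while
keeping Monte-Carlo error well below the tolerances being checked.

## Known limitations

* The midpoint method is optimal in no statistical sense; it was chosen for
  robustness and simplicity, and `|Vp|` underestimates 3D error for
  same-row mismatches (see above).
* Detector positions are integer-pixel (no subpixel interpolation); on real
  images localisation noise of ±0.5 px maps to ≈ 0.5 mm at the default
  working geometry, which dominates the error budget.
* The MSER sweep recomputes connected components per threshold level; it is
  the slowest detector (~5 s per 640×480 view) and would need a union-find
  component tree for video rates.
* Grayscale only; colour inputs are converted to luminance (or rejected in
  strict mode).
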