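# spinetrack

Markerless stereo localization of spinal features for navigated surgery
research.

Optical surgical-navigation systems usually track the spine indirectly,
through a dynamic reference frame clamped to a vertebra or markers glued to
the skin. `spinetrack` implements the alternative: detect anatomical
features of the exposed spine directly in two calibrated grey-scale camera
views, match them between views, and triangulate their 3D positions — so
spine motion can be estimated without any attached markers. It is aimed at
researchers evaluating feature-based patient tracking, and ships a synthetic
stereo-scene generator so every stage can be validated end to end without
clinical images.

## What it computes

Given a calibrated stereo rig (cameras `C1`, `C2`) and an image pair:

1. **Rectification.** The fundamental matrix `F` (with `x2ᵀ F x1 = 0`) is
   taken from calibration or estimated by the normalised 8-point algorithm;
   projective rectifying homographies `H, H′` map the epipoles to infinity
   and minimise the residual disparity `Σᵢ d(H xᵢ, H′ x′ᵢ)²`, so
   corresponding points share image rows.
2. **Preprocessing.** Contrast-limited adaptive histogram equalisation
   (clip limit 0.03, uniform target histogram), Otsu thresholding and
   8-connected region growing segment the bright spine band; detection runs
   on the cropped region and coordinates are projected back to full-frame
   pixels.
3. **Detection.** Four interchangeable detectors, parameterised as in the
   benchmark setup: a SURF-style Hessian-determinant blob detector
   (`det(H) = Lxx·Lyy − (0.9·Lxy)²` via integral-image box filters,
   threshold 600, 4 octaves × 6 scales, 64-d Haar descriptor), MSER
   (threshold sweep, area window 100–800 px², maximal area variation 0.3),
   FAST (16-pixel segment test, contiguous arc 12, corner quality 0.1,
   contrast 0.2) and ORB (oriented FAST over a 1.2× pyramid of 8 levels,
   256-bit rotated binary descriptor).
4. **Matching.** Mutual-best one-to-one matching by normalised
   cross-correlation (Hamming distance for binary descriptors), then
   epipolar outlier rejection: in rectified frames a pair survives only if
   `|y1 − y2| ≤ 1 px`.
5. **Triangulation.** Each surviving pair is back-projected; the 3D point is
   the midpoint of the shortest segment `Vp` between the rays `C1x1` and
   `C2x2`, and `|Vp|` in millimetres is the triangulation error.
6. **Statistics.** Per-group mean ± SD, median and IQR of the errors,
   inlier-count statistics, per-stage timings, and empirical error CDFs with
   a 95% Dvoretzky–Kiefer–Wolfowitz confidence band.

## Worked example

```bash
spinetrack simulate --out demo --seed 0 --preset validation
spinetrack run --manifest demo/manifest.csv --calibration demo/calibration.json \
    --detector fast --out demo/run
spinetrack report --points demo/run/points.csv --out demo/report
```

`simulate` renders a stereo pair of a textured surface with 20 ground-truth
landmarks and writes the calibration and landmark table. `run` prints

```
processed 1 frame pair(s) -> demo/run
```

and `report` prints (one line, reformatted):

```json
{"n": 43, "mean_mm": 7.16e-13, "sd_mm": 4.78e-13, "median_mm": 6.11e-13,
 "iqr_mm": 6.69e-13, "fraction_below_0.5mm": 1.0, "dkw_half_width": 0.2071}
```

Here `n` is the number of matched inliers that were triangulated, `mean_mm`
their mean triangulation error — at machine precision on this zero-noise
validation scene, confirming the geometric chain is exact — and
`fraction_below_0.5mm` the share of features localised better than half a
millimetre, the usual clinical acceptability line. The same commands with
`--preset default` (a ridged, noisy scene with converging cameras) and
`--detector surf|mser|fast|orb` reproduce the four-detector comparison on
realistic renders; typical mean errors there are 0.2–0.4 mm.

The library mirrors the CLI: `make_scene`/`render_views`,
`process_frame_pair`, `summarize`, `error_cdf` (see docstrings).

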