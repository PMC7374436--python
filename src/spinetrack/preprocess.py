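"""Spine-region preprocessing.

Contrast-limited adaptive histogram equalisation (CLAHE, uniform target
histogram), Otsu thresholding, region-growing segmentation of the spine and
ROI cropping with back-projection of detected coordinates to full-frame
pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import EmptyMaskError, PreprocessError

__all__ = [
    "PreprocessResult",
    "clahe",
    "tile_clipped_histograms",
    "otsu_threshold",
    "segment_spine",
    "crop_and_backproject",
]

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structure


@dataclass
class PreprocessResult:
    """Segmentation output: enhanced (masked) image, mask, ROI and offset.

    ``roi`` is (x, y, width, height) in full-frame pixels; ``offset`` is the
    (x, y) shift from ROI-local to full-frame coordinates.
    """

    enhanced: np.ndarray
    mask: np.ndarray
    roi: tuple[int, int, int, int]
    offset: tuple[int, int]

    def cropped(self) -> np.ndarray:
        x, y, w, h = self.roi
        return self.enhanced[y : y + h, x : x + w]


# --------------------------------------------------------------------------- #
# CLAHE
# --------------------------------------------------------------------------- #


def _nbins_and_max(img: np.ndarray) -> tuple[int, int]:
    if img.dtype == np.uint8:
        return 256, 255
    if img.dtype == np.uint16:
        return 65536, 65535
    raise PreprocessError(f"unsupported image dtype {img.dtype} (expect uint8/uint16)")


def _tile_edges(n: int, tiles: int) -> np.ndarray:
    return np.linspace(0, n, tiles + 1).round().astype(int)


def tile_clipped_histograms(
    img: np.ndarray, clip_limit: float, tile_grid: tuple[int, int]
) -> list[list[np.ndarray]]:
    """Per-tile histograms after clipping, before excess redistribution.

    Each bin is at most ``ceil(clip_limit * tile_pixels)``.  Exposed so the
    clipping contract can be audited externally.
    """
    _validate_clahe_args(img, clip_limit, tile_grid)
    nbins, _ = _nbins_and_max(img)
    gr, gc = tile_grid
    rows = _tile_edges(img.shape[0], gr)
    cols = _tile_edges(img.shape[1], gc)
    out: list[list[np.ndarray]] = []
    for i in range(gr):
        row: list[np.ndarray] = []
        for j in range(gc):
            tile = img[rows[i] : rows[i + 1], cols[j] : cols[j + 1]]
            hist = np.bincount(tile.ravel(), minlength=nbins).astype(float)
            clip = math.ceil(clip_limit * tile.size)
            row.append(np.minimum(hist, clip))
        out.append(row)
    return out


def _validate_clahe_args(img, clip_limit, tile_grid) -> None:
    if img.ndim != 2 or img.size == 0:
        raise PreprocessError("clahe expects a non-empty single-channel image")
    if not (0.0 < clip_limit <= 1.0):
        raise PreprocessError(f"clip_limit must be in (0, 1], got {clip_limit}")
    gr, gc = tile_grid
    if gr < 1 or gc < 1 or gr > img.shape[0] or gc > img.shape[1]:
        raise PreprocessError(f"tile grid {tile_grid} incompatible with image {img.shape}")


def clahe(
    img: np.ndarray, clip_limit: float = 0.03, tile_grid: tuple[int, int] = (8, 8)
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalisation.

    Per-tile histograms are clipped at ``ceil(clip_limit * tile_pixels)`` and
    the excess is redistributed uniformly over all bins (uniform target
    histogram); the per-tile equalisation maps are blended bilinearly between
    tile centres.  Output stays in the input bit-depth range.
    """
    _validate_clahe_args(img, clip_limit, tile_grid)
    nbins, vmax = _nbins_and_max(img)
    gr, gc = tile_grid
    rows = _tile_edges(img.shape[0], gr)
    cols = _tile_edges(img.shape[1], gc)

    clipped = tile_clipped_histograms(img, clip_limit, tile_grid)
    luts = np.empty((gr, gc, nbins))
    for i in range(gr):
        for j in range(gc):
            hist = clipped[i][j]
            npix = (rows[i + 1] - rows[i]) * (cols[j + 1] - cols[j])
            hist = hist + (npix - hist.sum()) / nbins  # uniform redistribution
            cdf = np.cumsum(hist)
            luts[i, j] = cdf / cdf[-1] * vmax

    # bilinear blending between tile centres
    rc = (rows[:-1] + rows[1:] - 1) / 2.0
    cc = (cols[:-1] + cols[1:] - 1) / 2.0
    yy = np.arange(img.shape[0], dtype=float)
    xx = np.arange(img.shape[1], dtype=float)

    def _coords(pos: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        i1 = np.searchsorted(centers, pos)  # centers[i1-1] <= pos-ish
        i0 = np.clip(i1 - 1, 0, len(centers) - 1)
        i1 = np.clip(i1, 0, len(centers) - 1)
        denom = centers[i1] - centers[i0]
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(denom > 0, (pos - centers[i0]) / np.where(denom > 0, denom, 1), 0.0)
        return i0, i1, np.clip(w, 0.0, 1.0)

    r0, r1, wr = _coords(yy, rc)
    c0, c1, wc = _coords(xx, cc)

    v = img
    top = (1 - wc)[None, :] * luts[r0[:, None], c0[None, :], v] + wc[None, :] * luts[
        r0[:, None], c1[None, :], v
    ]
    bot = (1 - wc)[None, :] * luts[r1[:, None], c0[None, :], v] + wc[None, :] * luts[
        r1[:, None], c1[None, :], v
    ]
    out = (1 - wr)[:, None] * top + wr[:, None] * bot
    return np.clip(np.rint(out), 0, vmax).astype(img.dtype)


# --------------------------------------------------------------------------- #
# Otsu threshold
# --------------------------------------------------------------------------- #


def otsu_threshold(img: np.ndarray) -> int:
    """Threshold level maximising between-class variance (8-bit levels).

    The returned level t separates classes ``<= t`` and ``> t``; the lowest
    level among maximisers is returned.  A constant image raises.
    """
    img = np.asarray(img)
    if img.dtype != np.uint8:
        raise PreprocessError("otsu_threshold expects an 8-bit image")
    hist = np.bincount(img.ravel(), minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise PreprocessError("constant image: degenerate histogram for Otsu")
    n = hist.sum()
    p = hist / n
    levels = np.arange(256)
    w0 = np.cumsum(p)
    mu = np.cumsum(p * levels)
    mu_t = mu[-1]
    w1 = 1.0 - w0
    with np.errstate(invalid="ignore", divide="ignore"):
        between = (mu_t * w0 - mu) ** 2 / (w0 * w1)
    between[~np.isfinite(between)] = -1.0
    return int(np.argmax(between))  # argmax returns the lowest maximiser


# --------------------------------------------------------------------------- #
# Segmentation
# --------------------------------------------------------------------------- #


def segment_spine(img: np.ndarray, seed: tuple[int, int] | None = None) -> PreprocessResult:
    """Segment the bright spine region of an enhanced image.

    Otsu foreground -> 8-connected region growing from ``seed`` (default: the
    centroid of the largest foreground component, snapped to that component)
    -> binary mask.  The enhanced image is multiplied by the mask and the ROI
    is the mask bounding box.

    Parameters
    ----------
    seed : optional (x, y) pixel inside the desired region.
    """
    try:
        t = otsu_threshold(img)
    except PreprocessError as exc:  # constant image: nothing to segment
        raise EmptyMaskError(f"no foreground: {exc}") from exc
    fg = img > t
    if not fg.any():
        raise EmptyMaskError("empty foreground after Otsu thresholding")
    lab, nlab = ndimage.label(fg, structure=_EIGHT)

    if seed is None:
        sizes = np.bincount(lab.ravel())[1:]
        biggest = int(np.argmax(sizes)) + 1
        ys, xs = np.nonzero(lab == biggest)
        cy, cx = int(round(ys.mean())), int(round(xs.mean()))
        if lab[cy, cx] == biggest:
            seed_rc = (cy, cx)
        else:  # centroid fell off the component: snap to its nearest pixel
            d2 = (ys - cy) ** 2 + (xs - cx) ** 2
            k = int(np.argmin(d2))
            seed_rc = (int(ys[k]), int(xs[k]))
    else:
        sx, sy = seed
        if not (0 <= sy < img.shape[0] and 0 <= sx < img.shape[1]) or not fg[sy, sx]:
            raise PreprocessError(f"seed {seed} is not a foreground pixel")
        seed_rc = (sy, sx)

    mask = (lab == lab[seed_rc]).astype(np.uint8)
    ys, xs = np.nonzero(mask)
    x0, x1 = int(xs.min()), int(xs.max())
    y0, y1 = int(ys.min()), int(ys.max())
    roi = (x0, y0, x1 - x0 + 1, y1 - y0 + 1)
    enhanced = (img * mask).astype(img.dtype)
    return PreprocessResult(enhanced=enhanced, mask=mask, roi=roi, offset=(x0, y0))


def crop_and_backproject(result: PreprocessResult, keypoints: list) -> list:
    """Shift ROI-local keypoints back to full-frame pixel coordinates.

    Accepts objects with a ``position`` attribute (returned re-positioned via
    ``dataclasses.replace``) or bare (x, y) pairs.  Scale and orientation are
    untouched.  A keypoint outside the ROI raises.
    """
    import dataclasses

    ox, oy = result.offset
    _, _, w, h = result.roi
    out = []
    for kp in keypoints:
        pos = kp.position if hasattr(kp, "position") else kp
        x, y = float(pos[0]), float(pos[1])
        if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
            raise PreprocessError(f"keypoint ({x}, {y}) outside ROI of size {(w, h)}")
        newpos = (x + ox, y + oy)
        if hasattr(kp, "position"):
            out.append(dataclasses.replace(kp, position=newpos))
        else:
            out.append(newpos)
    return out
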