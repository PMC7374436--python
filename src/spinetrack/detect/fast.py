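"""FAST corner detection (segment test on a 16-pixel Bresenham circle).

A candidate pixel p is a corner iff at least ``arc_length`` *contiguous*
pixels on the radius-3 circle are all brighter than I(p)+T or all darker than
I(p)-T.  A high-speed pretest on the four compass pixels (reject unless at
least three agree) is applied first; for arc lengths >= 12 it never changes
the result because any contiguous run of 12 among 16 covers three of the four
equally spaced compass positions.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .common import FastConfig, Keypoint

__all__ = ["CIRCLE_OFFSETS", "fast_corner_mask", "fast_score", "fast_detect"]

# (dr, dc) offsets of the 16-pixel Bresenham circle of radius 3, clockwise.
CIRCLE_OFFSETS: list[tuple[int, int]] = [
    (-3, 0), (-3, 1), (-2, 2), (-1, 3), (0, 3), (1, 3), (2, 2), (3, 1),
    (3, 0), (3, -1), (2, -2), (1, -3), (0, -3), (-1, -3), (-2, -2), (-3, -1),
]
_COMPASS = (0, 4, 8, 12)  # top, right, bottom, left


def _shifted_ring(img: np.ndarray) -> np.ndarray:
    """Stack of the 16 circle neighbours for every pixel, shape (16, H, W).

    Uses wrap-around rolls; callers must discard the 3-pixel border.
    """
    return np.stack([np.roll(img, (-dr, -dc), axis=(0, 1)) for dr, dc in CIRCLE_OFFSETS])


def _rot16(b: np.ndarray, k: int) -> np.ndarray:
    return ((b << k) | (b >> (16 - k))) & np.uint32(0xFFFF)


def _has_run(bits: np.ndarray, n: int) -> np.ndarray:
    """True where the 16-bit circular mask has a contiguous run of >= n bits."""
    m = bits.copy()
    for k in range(1, n):
        m &= _rot16(bits, k)
    return m > 0


def fast_corner_mask(
    img: np.ndarray, threshold: float, arc_length: int = 12, pretest: bool = True
) -> np.ndarray:
    """Boolean pre-NMS corner mask of the FAST segment test.

    ``threshold`` is T in grey levels.  Pixels within 3 of the border are
    never corners.
    """
    I = np.asarray(img, dtype=np.float64)
    if I.shape[0] < 7 or I.shape[1] < 7:
        return np.zeros(I.shape, dtype=bool)
    ring = _shifted_ring(I)
    bright = ring > I + threshold
    dark = ring < I - threshold

    weights = (np.uint32(1) << np.arange(16, dtype=np.uint32))[:, None, None]
    b_bits = (bright.astype(np.uint32) * weights).sum(axis=0).astype(np.uint32)
    d_bits = (dark.astype(np.uint32) * weights).sum(axis=0).astype(np.uint32)

    mask = _has_run(b_bits, arc_length) | _has_run(d_bits, arc_length)

    if pretest and arc_length >= 12:
        nb = bright[list(_COMPASS)].sum(axis=0)
        nd = dark[list(_COMPASS)].sum(axis=0)
        mask &= (nb >= 3) | (nd >= 3)

    mask[:3, :] = mask[-3:, :] = False
    mask[:, :3] = mask[:, -3:] = False
    return mask


def fast_score(img: np.ndarray, threshold: float) -> np.ndarray:
    """Corner score: the larger of the summed brighter/darker excursions
    beyond T over the circle."""
    I = np.asarray(img, dtype=np.float64)
    ring = _shifted_ring(I)
    sb = np.clip(ring - I - threshold, 0, None).sum(axis=0)
    sd = np.clip(I - threshold - ring, 0, None).sum(axis=0)
    return np.maximum(sb, sd)


def fast_detect(img: np.ndarray, config: FastConfig | None = None) -> list[Keypoint]:
    """FAST corners with non-maximum suppression.

    T = ``min_contrast`` x 255; after 3x3 NMS on the corner score, corners
    scoring below ``min_quality`` x (max score in image) are dropped.  Ties
    between equal-score neighbours break in raster order.
    """
    cfg = config or FastConfig()
    I = np.asarray(img, dtype=np.float64)
    T = cfg.min_contrast * 255.0
    corners = fast_corner_mask(I, T, cfg.arc_length)
    if not corners.any():
        return []
    score = np.where(corners, fast_score(I, T), 0.0)

    local_max = score >= ndimage.maximum_filter(score, size=3)
    cand = corners & local_max
    smax = score[cand].max()
    cand &= score >= cfg.min_quality * smax

    # raster tie-break: drop a candidate whose 3x3 neighbourhood contains an
    # earlier equal-score candidate
    keep = np.zeros_like(cand)
    rs, cs = np.nonzero(cand)
    taken = set()
    for r, c in zip(rs, cs):  # np.nonzero is already raster-ordered
        clash = False
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (r + dr, c + dc) in taken and score[r + dr, c + dc] == score[r, c]:
                    clash = True
        if not clash:
            keep[r, c] = True
            taken.add((r, c))

    rs, cs = np.nonzero(keep)
    return [
        Keypoint(position=(float(c), float(r)), scale=2.0, orientation=0.0,
                 response=float(score[r, c]))
        for r, c in zip(rs, cs)
    ]
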