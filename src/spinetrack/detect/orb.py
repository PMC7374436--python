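"""ORB: FAST corners on an image pyramid with intensity-centroid orientation
and a rotation-steered 256-bit binary descriptor.

The patch orientation is theta = atan2(m01, m10) from the first-order
intensity moments of a radius-15 disc; the descriptor performs 256 binary
intensity comparisons on a 5x5 box-smoothed patch, with the (fixed,
pseudo-random) test pattern rotated by theta.  Keypoint coordinates are
mapped back to level-0 pixels.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .common import Descriptor, Keypoint, OrbConfig
from .fast import fast_corner_mask, fast_score

__all__ = ["orb_orientation", "orb_test_pattern", "orb_detect_describe"]

_PATCH_RADIUS = 15
_PATTERN_RADIUS = 13  # rotated tests stay inside the patch
_MARGIN = _PATCH_RADIUS + 2


def _disc_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    rr, cc = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    m = rr * rr + cc * cc <= radius * radius
    return rr[m], cc[m]


_DISC_R, _DISC_C = _disc_offsets(_PATCH_RADIUS)


def orb_orientation(img: np.ndarray, r: int, c: int) -> float:
    """Intensity-centroid orientation of the radius-15 patch at (r, c)."""
    patch = img[r + _DISC_R, c + _DISC_C].astype(float)
    m10 = float((patch * _DISC_C).sum())  # x moment
    m01 = float((patch * _DISC_R).sum())  # y moment
    return float(np.arctan2(m01, m10)) % (2 * np.pi)


def orb_test_pattern(n_bits: int = 256, seed: int = 20200629) -> np.ndarray:
    """Fixed pseudo-random BRIEF test pattern, shape (n_bits, 2, 2) as
    (point, (dr, dc)); all points lie within radius 13 of the centre."""
    rng = np.random.default_rng(seed)
    pts = np.empty((n_bits, 2, 2), dtype=np.int64)
    for k in range(n_bits):
        for j in range(2):
            while True:
                p = np.rint(rng.normal(0.0, _PATCH_RADIUS / 2.5, size=2)).astype(int)
                if p[0] ** 2 + p[1] ** 2 <= _PATTERN_RADIUS**2:
                    pts[k, j] = p
                    break
    return pts


_PATTERN = orb_test_pattern()


def _describe(smoothed: np.ndarray, r: int, c: int, theta: float, n_bits: int) -> np.ndarray:
    ct, st = np.cos(theta), np.sin(theta)
    pat = _PATTERN[:n_bits].astype(float)
    dr = pat[:, :, 0]
    dc = pat[:, :, 1]
    # rotate (dc, dr) by theta in image coordinates (x right, y down)
    rdc = np.rint(ct * dc - st * dr).astype(int)
    rdr = np.rint(st * dc + ct * dr).astype(int)
    a = smoothed[r + rdr[:, 0], c + rdc[:, 0]]
    b = smoothed[r + rdr[:, 1], c + rdc[:, 1]]
    return a < b


def orb_detect_describe(
    img: np.ndarray, config: OrbConfig | None = None
) -> tuple[list[Keypoint], list[Descriptor]]:
    """Detect oriented FAST corners over a scale pyramid and describe them.

    Emits fewer pyramid levels with a warning when the image is too small for
    the full pyramid.
    """
    cfg = config or OrbConfig()
    base = np.asarray(img, dtype=np.float64)
    kps: list[Keypoint] = []
    descs: list[Descriptor] = []
    levels_used = 0
    for lev in range(cfg.n_levels):
        s = cfg.scale_factor**lev
        if lev == 0:
            im = base
        else:
            im = ndimage.zoom(base, 1.0 / s, order=1, grid_mode=True, mode="nearest")
        if min(im.shape) < 2 * _MARGIN + 7:
            break
        levels_used += 1
        corners = fast_corner_mask(im, cfg.fast_threshold, arc_length=12)
        if not corners.any():
            continue
        score = np.where(corners, fast_score(im, cfg.fast_threshold), 0.0)
        local = score >= ndimage.maximum_filter(score, size=3)
        cand = corners & local
        cand[:_MARGIN, :] = cand[-_MARGIN:, :] = False
        cand[:, :_MARGIN] = cand[:, -_MARGIN:] = False
        if not cand.any():
            continue
        smoothed = ndimage.uniform_filter(im, size=5, mode="nearest")
        rs, cs = np.nonzero(cand)
        if len(rs) > cfg.n_features:  # strongest first within the level
            order = np.argsort(-score[rs, cs], kind="stable")[: cfg.n_features]
            rs, cs = rs[order], cs[order]
        for r, c in zip(rs, cs):
            theta = orb_orientation(im, r, c)
            bits = _describe(smoothed, r, c, theta, cfg.descriptor_bits)
            kps.append(
                Keypoint(
                    position=(float(c) * s, float(r) * s),
                    scale=float(s) * 3.0,
                    orientation=theta,
                    response=float(score[r, c]),
                )
            )
            descs.append(Descriptor(kind="binary256", values=bits))
    if levels_used < cfg.n_levels:
        warnings.warn(
            f"image too small for {cfg.n_levels} pyramid levels; used {levels_used}",
            stacklevel=2,
        )
    if len(kps) > cfg.n_features:  # global cap, strongest first
        order = np.argsort([-k.response for k in kps], kind="stable")[: cfg.n_features]
        kps = [kps[i] for i in order]
        descs = [descs[i] for i in order]
    return kps, descs
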