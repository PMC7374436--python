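"""Maximally stable extremal regions via an explicit threshold sweep.

The 8-bit image is thresholded at every level of a sweep (step expressed as a
percentage of the full intensity range); connected extremal components are
tracked across levels through their root pixel (the raster-first minimum-
intensity pixel).  A region is emitted at the level where its relative area
change per step is a local minimum and does not exceed the configured
variation; emitted regions are filtered to the configured pixel-area window.
Both polarities are swept (dark regions on the image, bright regions on its
inversion), matching the classic MSER+/- pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .common import MserConfig

__all__ = ["MserRegion", "mser_detect"]

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class MserRegion:
    """One maximally stable extremal region."""

    pixel_set: np.ndarray  # (n, 2) array of (row, col)
    threshold_at_max_stability: int
    stability: float
    ellipse: tuple[tuple[float, float], tuple[float, float], float]
    polarity: str  # 'dark' | 'bright'

    @property
    def area(self) -> int:
        return len(self.pixel_set)


def _ellipse_from_pixels(pix: np.ndarray):
    """Bounding ellipse from second moments: ((cx, cy), (major, minor), angle)."""
    ys = pix[:, 0].astype(float)
    xs = pix[:, 1].astype(float)
    cx, cy = xs.mean(), ys.mean()
    cov = np.cov(np.stack([xs, ys]), bias=True) + 1e-9 * np.eye(2)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    axes = (2.0 * np.sqrt(max(evals[0], 0.0)), 2.0 * np.sqrt(max(evals[1], 0.0)))
    angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return (float(cx), float(cy)), axes, angle


def _sweep(img: np.ndarray, levels: np.ndarray, cfg: MserConfig) -> list[tuple[int, int, float]]:
    """One-polarity sweep; returns (root_flat_index, level, stability) of the
    maximally stable components."""
    H, W = img.shape
    npix = H * W
    flat = img.ravel().astype(np.int64)
    key = flat * npix + np.arange(npix)  # min-intensity with raster tie-break

    labs: dict[int, np.ndarray] = {}
    areas: dict[int, np.ndarray] = {}

    def level_data(i: int):
        if i not in labs:
            lab, _ = ndimage.label(img <= levels[i], structure=_EIGHT)
            labs[i] = lab.ravel()
            areas[i] = np.bincount(labs[i])
        # keep a sliding window to bound memory
        for j in list(labs):
            if j < i - 1:
                del labs[j], areas[j]
        return labs[i], areas[i]

    chains: dict[int, list[tuple[int, int, float]]] = {}
    for i in range(len(levels)):
        lab, area = level_data(i)
        nlab = len(area) - 1
        if nlab == 0:
            continue
        # root pixel of each component: raster-first minimum intensity
        root_key = ndimage.minimum(key, labels=lab, index=np.arange(1, nlab + 1))
        roots = (np.atleast_1d(root_key).astype(np.int64) % npix)
        a_here = area[1:]
        # areas of the containing component one step down/up (prev first:
        # requesting level i+1 advances the window past i-1)
        if i == 0:
            a_prev = np.zeros_like(a_here)
        elif (i - 1) in labs:
            lab_p, area_p = labs[i - 1], areas[i - 1]
            lp = lab_p[roots]
            a_prev = np.where(lp > 0, area_p[lp], 0)
        else:  # window already advanced; recompute
            lab_pm, _ = ndimage.label(img <= levels[i - 1], structure=_EIGHT)
            lab_p = lab_pm.ravel()
            area_p = np.bincount(lab_p)
            lp = lab_p[roots]
            a_prev = np.where(lp > 0, area_p[lp], 0)
        if i + 1 < len(levels):
            lab_n, area_n = level_data(i + 1)
            a_next = area_n[lab_n[roots]]
        else:
            a_next = a_here
        psi = (a_next - a_prev) / a_here
        for r, a, p in zip(roots, a_here, psi):
            chains.setdefault(int(r), []).append((i, int(a), float(p)))

    picks: list[tuple[int, int, float]] = []
    lo, hi = cfg.area_range
    for root, ch in chains.items():
        # collapse runs of unchanged area: keep the first level of each run
        coll: list[tuple[int, int, float]] = []
        for lev, a, p in ch:
            if coll and coll[-1][1] == a:
                if p < coll[-1][2]:
                    coll[-1] = (coll[-1][0], a, p)
                continue
            coll.append((lev, a, p))
        for k, (lev, a, p) in enumerate(coll):
            if p > cfg.max_area_variation or not (lo <= a <= hi):
                continue
            left_ok = k == 0 or p <= coll[k - 1][2]
            right_ok = k == len(coll) - 1 or p <= coll[k + 1][2]
            if left_ok and right_ok:
                picks.append((root, lev, p))
    return picks


def mser_detect(img: np.ndarray, config: MserConfig | None = None) -> list[MserRegion]:
    """Detect maximally stable extremal regions of both polarities."""
    cfg = config or MserConfig()
    img = np.asarray(img)
    if img.dtype != np.uint8:
        raise ValueError("mser_detect expects an 8-bit image")
    step = max(1, int(round(cfg.threshold_step / 100.0 * 255.0)))
    levels = np.arange(0, 256, step)

    regions: list[MserRegion] = []
    for polarity, work in (("dark", img), ("bright", (255 - img).astype(np.uint8))):
        picks = _sweep(work, levels, cfg)
        # group by level so each labelling is recomputed once
        by_level: dict[int, list[tuple[int, float]]] = {}
        for root, lev, p in picks:
            by_level.setdefault(lev, []).append((root, p))
        for lev, items in sorted(by_level.items()):
            lab, _ = ndimage.label(work <= levels[lev], structure=_EIGHT)
            labf = lab.ravel()
            for root, p in items:
                pix = np.argwhere(lab == labf[root])
                thr = int(levels[lev]) if polarity == "dark" else int(255 - levels[lev])
                regions.append(
                    MserRegion(
                        pixel_set=pix,
                        threshold_at_max_stability=thr,
                        stability=p,
                        ellipse=_ellipse_from_pixels(pix),
                        polarity=polarity,
                    )
                )
    regions.sort(key=lambda r: (r.ellipse[0][1], r.ellipse[0][0], r.area))
    return regions
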