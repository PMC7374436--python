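"""SURF-style Hessian blob detector with Haar-wavelet descriptor.

Second-order Gaussian derivatives are approximated by box filters on an
integral image; the interest measure is the approximated Hessian determinant

    det(H_approx) = Lxx * Lyy - (0.9 * Lxy)**2,

with the constant 0.9 compensating the box approximation.  Keypoints are
3x3x3 non-maxima of det over position and scale; orientation comes from a
sliding-sector maximum of Haar responses and the descriptor is the classic
64-vector of per-subregion Haar sums.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from ..exceptions import SpinetrackError
from .common import Descriptor, Keypoint, SurfConfig, integral_image

__all__ = [
    "ScaleSpaceResponse",
    "filter_sizes",
    "hessian_det",
    "surf_detect",
    "surf_orient",
    "surf_describe",
    "surf_detect_describe",
]

log = logging.getLogger(__name__)

_HESSIAN_WEIGHT = 0.9


@dataclass(frozen=True)
class ScaleSpaceResponse:
    """Box-filter second-derivative maps and the determinant map at one scale."""

    Lxx: np.ndarray
    Lxy: np.ndarray
    Lyy: np.ndarray
    det_map: np.ndarray
    filter_size: int
    sigma: float


def filter_sizes(octave: int, n_scales: int) -> list[int]:
    """Box filter side lengths for octave o (0-based): 3 * 2^(o+1) * k + 3,
    i.e. 9, 15, 21, ... at octave 0, doubling the stride per octave."""
    return [3 * (2 ** (octave + 1)) * k + 3 for k in range(1, n_scales + 1)]


_SCALE_PER_SIZE = 1.0 / 5.4


def sigma_for_size(L: int) -> float:
    """Blob scale selected by filter size L (sigma = L / 5.4).

    Calibrated on the response peak of the area-normalised box pyramid to an
    isotropic Gaussian blob: a blob of scale s maximises the determinant at
    filter size L ~ 5.4 s.  (The textbook shape-equivalence 1.2 L / 9 refers
    to the best-fitting Gaussian derivative, not the selection peak.)
    """
    return _SCALE_PER_SIZE * L


def _boxes(S: np.ndarray, shape: tuple[int, int], boxes) -> np.ndarray:
    """Sum of offset boxes for every pixel; boxes are (dr0, dc0, dr1, dc1, w)
    half-open offsets relative to the pixel.  Border rows/cols where any box
    leaves the image are zero."""
    H, W = shape
    out = np.zeros((H, W))
    rmin = max(0, -min(b[0] for b in boxes))
    rmax = min(H, H - max(b[2] for b in boxes))
    cmin = max(0, -min(b[1] for b in boxes))
    cmax = min(W, W - max(b[3] for b in boxes))
    if rmin >= rmax or cmin >= cmax:
        raise SpinetrackError("box filter larger than image")
    r = np.arange(rmin, rmax)[:, None]
    c = np.arange(cmin, cmax)[None, :]
    acc = np.zeros((rmax - rmin, cmax - cmin))
    for dr0, dc0, dr1, dc1, w in boxes:
        acc += w * (
            S[r + dr1, c + dc1] - S[r + dr0, c + dc1] - S[r + dr1, c + dc0] + S[r + dr0, c + dc0]
        )
    out[rmin:rmax, cmin:cmax] = acc
    return out


def hessian_det(img: np.ndarray, sigma: float | None = None, filter_size: int | None = None
                ) -> ScaleSpaceResponse:
    """Hessian-determinant response at one scale.

    Box-filter approximations of Lxx, Lyy, Lxy normalised by the filter area,
    combined as ``Lxx*Lyy - (0.9*Lxy)**2``.  Provide ``sigma`` (snapped to the
    nearest representable filter size) or ``filter_size`` directly (must be
    3*(2k+1) for integer k >= 1).
    """
    if filter_size is None:
        if sigma is None:
            raise ValueError("provide sigma or filter_size")
        k = max(1, round((sigma / _SCALE_PER_SIZE - 3.0) / 6.0))
        filter_size = 6 * k + 3
    L = int(filter_size)
    if L < 9 or L % 6 != 3:
        raise ValueError(f"filter size must be 9, 15, 21, ... got {L}")
    img = np.asarray(img, dtype=np.float64)
    if L > min(img.shape):
        raise SpinetrackError(f"filter size {L} exceeds image {img.shape}")
    S = integral_image(img)
    lobe = L // 3
    b = L // 2  # half width
    hl = lobe // 2

    # Dxx: full (2*lobe-1) x L box minus 3x the central (2*lobe-1) x lobe box
    dxx_boxes = [
        (-(lobe - 1), -b, lobe, b + 1, 1.0),
        (-(lobe - 1), -hl, lobe, hl + 1, -3.0),
    ]
    dyy_boxes = [(c0, r0, c1, r1, w) for (r0, c0, r1, c1, w) in dxx_boxes]
    # Dxy: four lobe x lobe boxes in the quadrants, offset 1 from the axes
    dxy_boxes = [
        (-lobe, 1, 0, lobe + 1, 1.0),
        (1, -lobe, lobe + 1, 0, 1.0),
        (-lobe, -lobe, 0, 0, -1.0),
        (1, 1, lobe + 1, lobe + 1, -1.0),
    ]

    inv_area = 1.0 / (L * L)
    Lxx = _boxes(S, img.shape, dxx_boxes) * inv_area
    Lyy = _boxes(S, img.shape, dyy_boxes) * inv_area
    Lxy = _boxes(S, img.shape, dxy_boxes) * inv_area
    det = Lxx * Lyy - (_HESSIAN_WEIGHT * Lxy) ** 2
    return ScaleSpaceResponse(Lxx=Lxx, Lxy=Lxy, Lyy=Lyy, det_map=det,
                              filter_size=L, sigma=sigma_for_size(L))


def surf_detect(img: np.ndarray, config: SurfConfig | None = None) -> list[Keypoint]:
    """Hessian-blob keypoints: 3x3x3 scale-space non-maximum suppression of
    the determinant pyramid; emitted keypoints have response >= the feature
    threshold."""
    cfg = config or SurfConfig()
    img = np.asarray(img, dtype=np.float64)
    kps: list[Keypoint] = []
    seen: set[tuple[int, int, int]] = set()
    for octave in range(cfg.n_octaves):
        sizes = [L for L in filter_sizes(octave, cfg.n_scales) if L <= min(img.shape)]
        if len(sizes) < 3:
            break
        stack = np.stack([hessian_det(img, filter_size=L).det_map for L in sizes])
        maxf = ndimage.maximum_filter(stack, size=3, mode="constant", cval=-np.inf)
        for si in range(1, len(sizes) - 1):
            cand = (stack[si] >= cfg.feature_threshold) & (stack[si] == maxf[si])
            rs, cs = np.nonzero(cand)
            for r, c in zip(rs, cs):
                key = (int(r), int(c), sizes[si])
                if key in seen:  # octaves overlap in filter size
                    continue
                seen.add(key)
                kps.append(Keypoint(position=(float(c), float(r)),
                                    scale=sigma_for_size(sizes[si]),
                                    response=float(stack[si, r, c])))
    kps.sort(key=lambda k: (k.position[1], k.position[0], k.scale))
    return kps


def _haar_many(
    S: np.ndarray, rs: np.ndarray, cs: np.ndarray, size: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Axis-aligned Haar responses (dx, dy) of side ``size`` centred at the
    integer points (rs, cs); the third return is a validity mask (False where
    the window leaves the image)."""
    h = size // 2
    H, W = S.shape[0] - 1, S.shape[1] - 1
    r0 = rs - h
    r1 = r0 + size
    c0 = cs - h
    c1 = c0 + size
    valid = (r0 >= 0) & (c0 >= 0) & (r1 <= H) & (c1 <= W)
    r0c = np.where(valid, r0, 0)
    r1c = np.where(valid, r1, 0)
    c0c = np.where(valid, c0, 0)
    c1c = np.where(valid, c1, 0)
    cm = c0c + size // 2
    rm = r0c + size // 2
    right = S[r1c, c1c] - S[r0c, c1c] - S[r1c, cm] + S[r0c, cm]
    left = S[r1c, cm] - S[r0c, cm] - S[r1c, c0c] + S[r0c, c0c]
    bottom = S[r1c, c1c] - S[rm, c1c] - S[r1c, c0c] + S[rm, c0c]
    top = S[rm, c1c] - S[r0c, c1c] - S[rm, c0c] + S[r0c, c0c]
    return right - left, bottom - top, valid


def _haar(S: np.ndarray, r: int, c: int, size: int) -> tuple[float, float] | None:
    dx, dy, ok = _haar_many(S, np.array([r]), np.array([c]), size)
    if not ok[0]:
        return None
    return float(dx[0]), float(dy[0])


def surf_orient(img: np.ndarray, kp: Keypoint, integral: np.ndarray | None = None) -> float:
    """Dominant orientation: Haar responses on a radius-6-sigma disc, Gaussian
    weighted, summed in a sliding pi/3 sector; the direction of the longest
    summed vector wins.  A flat patch returns 0.0.

    ``integral`` may carry a precomputed summed-area table of ``img``.
    """
    s = kp.scale
    S = integral if integral is not None else integral_image(np.asarray(img, dtype=np.float64))
    cx, cy = kp.position
    size = max(2, int(round(4 * s)))
    ii, jj = np.mgrid[-6:7, -6:7]
    disc = ii * ii + jj * jj <= 36
    ii, jj = ii[disc], jj[disc]
    rs = np.rint(cy + jj * s).astype(int)
    cs = np.rint(cx + ii * s).astype(int)
    dxa, dya, ok = _haar_many(S, rs, cs, size)
    if not ok.any():
        return 0.0
    w = np.exp(-(ii * ii + jj * jj) / (2 * 2.5**2))[ok]
    dx = w * dxa[ok]
    dy = w * dya[ok]
    mag = np.hypot(dx, dy)
    if mag.max() < 1e-12:
        return 0.0
    ang = np.arctan2(dy, dx)
    best_mag, best_dir = -1.0, 0.0
    for start in np.linspace(0, 2 * np.pi, 72, endpoint=False):
        d = (ang - start) % (2 * np.pi)
        sel = d < np.pi / 3
        if not sel.any():
            continue
        vx, vy = dx[sel].sum(), dy[sel].sum()
        m = vx * vx + vy * vy
        if m > best_mag:
            best_mag, best_dir = m, float(np.arctan2(vy, vx)) % (2 * np.pi)
    return best_dir


def surf_describe(img: np.ndarray, kp: Keypoint, integral: np.ndarray | None = None
                  ) -> Descriptor | None:
    """64-d descriptor: an oriented 20-sigma window split into a 4x4 grid of
    subregions, each contributing (sum dx, sum |dx|, sum dy, sum |dy|) of
    Gaussian-weighted, orientation-aligned Haar responses; unit-normalised.

    Returns None (keypoint dropped, reason logged) when the window leaves the
    image.  ``integral`` may carry a precomputed summed-area table.
    """
    s = kp.scale
    theta = kp.orientation
    ct, st = np.cos(theta), np.sin(theta)
    S = integral if integral is not None else integral_image(np.asarray(img, dtype=np.float64))
    size = max(2, int(round(2 * s)))
    idx = np.arange(20)
    gi, gj = np.meshgrid(idx, idx, indexing="ij")  # sample grid, spacing sigma
    u = (gi.ravel() - 9.5) * s
    v = (gj.ravel() - 9.5) * s
    x = kp.position[0] + u * ct - v * st
    y = kp.position[1] + u * st + v * ct
    rs = np.rint(y).astype(int)
    cs = np.rint(x).astype(int)
    dxa, dya, ok = _haar_many(S, rs, cs, size)
    if not ok.all():
        log.debug("surf_describe: window out of bounds for kp at %s", kp.position)
        return None
    w = np.exp(-(u * u + v * v) / (2 * (3.3 * s) ** 2))
    dx_i = w * dxa
    dy_i = w * dya
    # rotate responses into the keypoint frame
    du = ct * dx_i + st * dy_i
    dv = -st * dx_i + ct * dy_i
    vec = np.zeros((4, 4, 4))
    bi = gi.ravel() // 5
    bj = gj.ravel() // 5
    np.add.at(vec, (bi, bj, 0), du)
    np.add.at(vec, (bi, bj, 1), np.abs(du))
    np.add.at(vec, (bi, bj, 2), dv)
    np.add.at(vec, (bi, bj, 3), np.abs(dv))
    flat = vec.ravel()
    n = np.linalg.norm(flat)
    if n > 1e-12:
        flat = flat / n
    return Descriptor(kind="real64", values=flat)


def surf_detect_describe(
    img: np.ndarray, config: SurfConfig | None = None
) -> tuple[list[Keypoint], list[Descriptor]]:
    """Detect, orient and describe; keypoints whose descriptor window leaves
    the image are dropped."""
    kps = surf_detect(img, config)
    S = integral_image(np.asarray(img, dtype=np.float64))
    out_k, out_d = [], []
    for kp in kps:
        kp = replace(kp, orientation=surf_orient(img, kp, integral=S))
        d = surf_describe(img, kp, integral=S)
        if d is not None:
            out_k.append(kp)
            out_d.append(d)
    return out_k, out_d
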