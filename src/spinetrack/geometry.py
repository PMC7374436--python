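"""Metric two-view geometry.

Pinhole cameras in millimetre world units, fundamental-matrix computation and
estimation, projective (epipole-to-infinity) rectification, and midpoint
triangulation.  The triangulation error of a correspondence is the length of
the shortest segment Vp connecting the two back-projected rays; the
reconstructed 3D point is the midpoint of that segment.

Conventions
-----------
* Pixel coordinates are 0-based, origin at the top-left, x rightward,
  y downward; pixel centres sit on integer coordinates.
* ``rotation`` maps world to camera coordinates; the camera looks along its
  +z axis.
* The fundamental matrix satisfies ``x2ᵀ F x1 = 0`` and is normalised to unit
  Frobenius norm with its largest-magnitude element positive, so comparisons
  are deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import (
    BehindCameraError,
    DegenerateRigError,
    EstimationError,
    GeometryError,
    ParallelRaysError,
    RectificationError,
)

__all__ = [
    "CameraModel",
    "StereoRig",
    "RectifyingPair",
    "TriangulationResult",
    "project",
    "fundamental_from_cameras",
    "estimate_fundamental",
    "compute_rectification",
    "triangulate_midpoint",
    "triangulate_rays",
    "apply_homography",
    "warp_image",
    "normalize_fundamental",
    "epipoles_from_fundamental",
    "load_calibration",
    "save_calibration",
]


# --------------------------------------------------------------------------- #
# Domain types
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class CameraModel:
    """Metric pinhole camera.

    Parameters
    ----------
    focal : (fx, fy) in pixels.
    principal_point : (cx, cy) in pixels.
    rotation : 3x3 orthonormal world-to-camera rotation.
    center : camera centre in world coordinates (mm).
    """

    focal: tuple[float, float]
    principal_point: tuple[float, float]
    rotation: np.ndarray
    center: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        C = np.asarray(self.center, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "center", C)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise GeometryError("rotation must be orthonormal (RᵀR = I)")
        fx, fy = self.focal
        if fx <= 0 or fy <= 0:
            raise GeometryError("focal components must be positive")

    @property
    def K(self) -> np.ndarray:
        """3x3 intrinsic matrix."""
        fx, fy = self.focal
        cx, cy = self.principal_point
        return np.array([[fx, 0.0, cx], [0.0, fy, cy], [0.0, 0.0, 1.0]])

    @property
    def P(self) -> np.ndarray:
        """3x4 projection matrix K [R | -R C]."""
        return self.K @ np.hstack([self.rotation, -self.rotation @ self.center[:, None]])

    def ray(self, x: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
        """World-frame ray (origin, unit direction) through pixel ``x``."""
        xh = np.array([x[0], x[1], 1.0])
        d_cam = np.linalg.solve(self.K, xh)
        d = self.rotation.T @ d_cam
        return self.center, d / np.linalg.norm(d)

    def to_dict(self) -> dict:
        fx, fy = self.focal
        cx, cy = self.principal_point
        return {
            "fx": float(fx),
            "fy": float(fy),
            "cx": float(cx),
            "cy": float(cy),
            "R": [float(v) for v in self.rotation.ravel()],
            "C": [float(v) for v in self.center],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        return cls(
            focal=(float(d["fx"]), float(d["fy"])),
            principal_point=(float(d["cx"]), float(d["cy"])),
            rotation=np.asarray(d["R"], dtype=float).reshape(3, 3),
            center=np.asarray(d["C"], dtype=float),
        )


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array(
        [[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]]
    )


def normalize_fundamental(F: np.ndarray) -> np.ndarray:
    """Scale F to unit Frobenius norm with positive largest-|.| element."""
    F = np.asarray(F, dtype=float)
    n = np.linalg.norm(F)
    if n == 0:
        raise GeometryError("zero fundamental matrix")
    F = F / n
    idx = np.unravel_index(np.argmax(np.abs(F)), F.shape)
    if F[idx] < 0:
        F = -F
    return F


def epipoles_from_fundamental(F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-norm homogeneous epipoles (e, e') with F e = 0 and Fᵀ e' = 0."""
    _, _, Vt = np.linalg.svd(F)
    e = Vt[-1]
    _, _, Vt2 = np.linalg.svd(F.T)
    ep = Vt2[-1]
    return e / np.linalg.norm(e), ep / np.linalg.norm(ep)


@dataclass(frozen=True)
class StereoRig:
    """Calibrated two-camera rig with derived epipolar geometry."""

    cam1: CameraModel
    cam2: CameraModel
    F: np.ndarray = field(init=False)
    e: np.ndarray = field(init=False)
    e_prime: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        F = fundamental_from_cameras(self.cam1, self.cam2)
        e, ep = epipoles_from_fundamental(F)
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "e", e)
        object.__setattr__(self, "e_prime", ep)

    @property
    def baseline(self) -> float:
        return float(np.linalg.norm(self.cam2.center - self.cam1.center))


@dataclass
class RectifyingPair:
    """Pair of rectifying homographies (H for view 1, H' for view 2)."""

    H: np.ndarray
    H_prime: np.ndarray
    size1: tuple[int, int]  # (width, height) of the rectified first view
    size2: tuple[int, int]
    residual_disparity: float  # mean |y1 - y2| of the input correspondences, px

    def __post_init__(self) -> None:
        for M in (self.H, self.H_prime):
            if abs(np.linalg.det(M)) < 1e-12:
                raise RectificationError("rectifying homography is singular")

    def to_dict(self) -> dict:
        return {
            "H": [float(v) for v in np.asarray(self.H).ravel()],
            "H_prime": [float(v) for v in np.asarray(self.H_prime).ravel()],
            "size1": list(self.size1),
            "size2": list(self.size2),
            "residual_disparity_px": float(self.residual_disparity),
        }


@dataclass(frozen=True)
class TriangulationResult:
    """Midpoint triangulation of one correspondence.

    ``point3d`` is the midpoint of the shortest segment Vp between the two
    back-projected rays; ``error_mm`` is the length of Vp.
    """

    point3d: np.ndarray
    error_mm: float
    ray_points: tuple[np.ndarray, np.ndarray]
    image_points: tuple[np.ndarray, np.ndarray]


# --------------------------------------------------------------------------- #
# Operations
# --------------------------------------------------------------------------- #


def project(camera: CameraModel, X: Sequence[float]) -> np.ndarray:
    """Perspective projection of world point ``X`` (mm) to pixels.

    Raises
    ------
    BehindCameraError
        If ``X`` has non-positive depth in the camera frame.
    """
    X = np.asarray(X, dtype=float).reshape(3)
    Xc = camera.rotation @ (X - camera.center)
    if Xc[2] <= 1e-12:
        raise BehindCameraError(f"point {X} is behind the camera (depth {Xc[2]:.3g})")
    fx, fy = camera.focal
    cx, cy = camera.principal_point
    return np.array([fx * Xc[0] / Xc[2] + cx, fy * Xc[1] / Xc[2] + cy])


def fundamental_from_cameras(cam1: CameraModel, cam2: CameraModel) -> np.ndarray:
    """Fundamental matrix of a calibrated rig (x2ᵀ F x1 = 0), normalised.

    Raises
    ------
    DegenerateRigError
        If the camera centres coincide (no epipolar geometry).
    """
    if np.linalg.norm(cam2.center - cam1.center) < 1e-9:
        raise DegenerateRigError("camera centres coincide; rig is degenerate")
    P1, P2 = cam1.P, cam2.P
    # epipole in view 2: image of C1
    ep = P2 @ np.append(cam1.center, 1.0)
    F = _skew(ep) @ P2 @ np.linalg.pinv(P1)
    return normalize_fundamental(F)


def estimate_fundamental(pts1: np.ndarray, pts2: np.ndarray) -> np.ndarray:
    """Normalised 8-point estimate of F with rank-2 enforcement.

    Parameters
    ----------
    pts1, pts2 : (n, 2) arrays of corresponding pixels, n >= 8.
    """
    pts1 = np.asarray(pts1, dtype=float).reshape(-1, 2)
    pts2 = np.asarray(pts2, dtype=float).reshape(-1, 2)
    if pts1.shape != pts2.shape:
        raise EstimationError("point lists must have equal length")
    n = pts1.shape[0]
    if n < 8:
        raise EstimationError(f"need at least 8 correspondences, got {n}")

    def _norm_transform(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        c = p.mean(axis=0)
        d = np.sqrt(((p - c) ** 2).sum(axis=1)).mean()
        if d < 1e-12:
            raise EstimationError("degenerate point configuration (coincident points)")
        s = np.sqrt(2.0) / d
        T = np.array([[s, 0, -s * c[0]], [0, s, -s * c[1]], [0, 0, 1]])
        q = (p - c) * s
        return q, T

    q1, T1 = _norm_transform(pts1)
    q2, T2 = _norm_transform(pts2)
    A = np.column_stack(
        [
            q2[:, 0] * q1[:, 0],
            q2[:, 0] * q1[:, 1],
            q2[:, 0],
            q2[:, 1] * q1[:, 0],
            q2[:, 1] * q1[:, 1],
            q2[:, 1],
            q1[:, 0],
            q1[:, 1],
            np.ones(n),
        ]
    )
    _, s, Vt = np.linalg.svd(A)
    # A degenerate configuration (e.g. all points collinear) leaves a null
    # space of dimension > 1: the two smallest singular values both vanish.
    if s[-2] < 1e-8 * max(s[0], 1.0):
        raise EstimationError("degenerate point configuration for 8-point estimation")
    Fn = Vt[-1].reshape(3, 3)
    U, d, Vt2 = np.linalg.svd(Fn)
    Fn = U @ np.diag([d[0], d[1], 0.0]) @ Vt2  # rank-2 enforcement
    F = T2.T @ Fn @ T1
    return normalize_fundamental(F)


def apply_homography(H: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Apply a 3x3 homography to (n, 2) points."""
    pts = np.asarray(pts, dtype=float).reshape(-1, 2)
    ph = np.hstack([pts, np.ones((len(pts), 1))]) @ np.asarray(H, dtype=float).T
    return ph[:, :2] / ph[:, 2:3]


_F_CANONICAL = normalize_fundamental(
    np.array([[0.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]])
)


def _is_canonical_rectified(F: np.ndarray, atol: float = 1e-10) -> bool:
    Fn = normalize_fundamental(F)  # defined up to sign when elements tie
    return bool(
        np.allclose(Fn, _F_CANONICAL, atol=atol) or np.allclose(-Fn, _F_CANONICAL, atol=atol)
    )


def _rot2(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def compute_rectification(
    F: np.ndarray,
    pts1: np.ndarray,
    pts2: np.ndarray,
    image_sizes: tuple[tuple[int, int], tuple[int, int]],
) -> RectifyingPair:
    """Projective rectification (Hartley) from F and seed correspondences.

    ``H_prime`` maps the second-view epipole e' to the point at infinity via a
    centre translation, rotation onto the x-axis and the epipole-to-infinity
    map G; the matching ``H`` is ``A·H'·M`` where ``F = [e']ₓ M`` and the
    affine row-preserving ``A`` minimises the sum of squared horizontal
    disparities of the correspondences.  Output translations place both
    rectified frames at non-negative coordinates with a *shared* vertical
    offset, preserving row alignment.

    Already-rectified input (canonical F) returns identity homographies.

    Parameters
    ----------
    image_sizes : ((w1, h1), (w2, h2)) of the two source images.
    """
    F = np.asarray(F, dtype=float)
    s = np.linalg.svd(F, compute_uv=False)
    if s[2] > 1e-6 * s[0]:
        raise RectificationError("F must have rank 2")
    pts1 = np.asarray(pts1, dtype=float).reshape(-1, 2)
    pts2 = np.asarray(pts2, dtype=float).reshape(-1, 2)
    (w1, h1), (w2, h2) = image_sizes

    if _is_canonical_rectified(F):
        res = float(np.mean(np.abs(pts1[:, 1] - pts2[:, 1]))) if len(pts1) else 0.0
        return RectifyingPair(np.eye(3), np.eye(3), (w1, h1), (w2, h2), res)

    e, ep = epipoles_from_fundamental(F)

    def _inside(eh: np.ndarray, w: int, h: int) -> bool:
        if abs(eh[2]) < 1e-12 * np.linalg.norm(eh[:2]):
            return False
        x, y = eh[0] / eh[2], eh[1] / eh[2]
        return 0 <= x <= w - 1 and 0 <= y <= h - 1

    if _inside(e, w1, h1) or _inside(ep, w2, h2):
        raise RectificationError("epipole inside the image; projective warp unbounded")

    # H' : translate image-2 centre to origin, rotate e' onto +x, send to infinity
    T = np.array([[1.0, 0.0, -(w2 - 1) / 2.0], [0.0, 1.0, -(h2 - 1) / 2.0], [0.0, 0.0, 1.0]])
    ept = T @ ep
    if abs(ept[2]) > 1e-12:
        ept = ept / ept[2]
        theta = -np.arctan2(ept[1], ept[0])
        R = _rot2(theta)
        f = (R @ ept)[0]
        G = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [-1.0 / f, 0.0, 1.0]])
    else:  # epipole already at infinity: rotate its direction onto x, no G
        theta = -np.arctan2(ept[1], ept[0])
        R = _rot2(theta)
        G = np.eye(3)
    Hp = np.linalg.inv(T) @ G @ R @ T

    # Compatible homography for view 1: F = [e']ₓ M with M = [e']ₓ F + e' vᵀ
    M = _skew(ep) @ F + np.outer(ep, np.ones(3))
    H0 = Hp @ M

    if len(pts1) >= 3:
        p1h = apply_homography(H0, pts1)
        p2h = apply_homography(Hp, pts2)
        Amat = np.column_stack([p1h[:, 0], p1h[:, 1], np.ones(len(p1h))])
        abc, *_ = np.linalg.lstsq(Amat, p2h[:, 0], rcond=None)
    else:
        abc = np.array([1.0, 0.0, 0.0])
    A = np.array([[abc[0], abc[1], abc[2]], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    H = A @ H0

    # Output framing: per-view x offset, shared y offset (keeps rows aligned).
    def _corners(w: int, h: int) -> np.ndarray:
        return np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], dtype=float)

    c1 = apply_homography(H, _corners(w1, h1))
    c2 = apply_homography(Hp, _corners(w2, h2))
    ty = -min(c1[:, 1].min(), c2[:, 1].min())
    tx1, tx2 = -c1[:, 0].min(), -c2[:, 0].min()
    H = np.array([[1, 0, tx1], [0, 1, ty], [0, 0, 1.0]]) @ H
    Hp = np.array([[1, 0, tx2], [0, 1, ty], [0, 0, 1.0]]) @ Hp
    c1 = apply_homography(H, _corners(w1, h1))
    c2 = apply_homography(Hp, _corners(w2, h2))
    size1 = (int(np.ceil(c1[:, 0].max())) + 1, int(np.ceil(c1[:, 1].max())) + 1)
    size2 = (int(np.ceil(c2[:, 0].max())) + 1, int(np.ceil(c2[:, 1].max())) + 1)

    if len(pts1):
        y1 = apply_homography(H, pts1)[:, 1]
        y2 = apply_homography(Hp, pts2)[:, 1]
        residual = float(np.mean(np.abs(y1 - y2)))
    else:
        residual = 0.0
    return RectifyingPair(H, Hp, size1, size2, residual)


def warp_image(img: np.ndarray, H: np.ndarray, output_size: tuple[int, int]) -> np.ndarray:
    """Warp ``img`` by homography ``H`` into a (width, height) canvas.

    Bilinear inverse mapping; pixels mapping outside the source are 0.
    An exact identity (or pure integer translation) warp is resampling-free.
    """
    from scipy.ndimage import map_coordinates

    w, h = output_size
    Hinv = np.linalg.inv(np.asarray(H, dtype=float))
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    den = Hinv[2, 0] * xx + Hinv[2, 1] * yy + Hinv[2, 2]
    xs = (Hinv[0, 0] * xx + Hinv[0, 1] * yy + Hinv[0, 2]) / den
    ys = (Hinv[1, 0] * xx + Hinv[1, 1] * yy + Hinv[1, 2]) / den
    out = map_coordinates(img.astype(float), [ys, xs], order=1, cval=0.0)
    if np.issubdtype(img.dtype, np.integer):
        info = np.iinfo(img.dtype)
        out = np.clip(np.rint(out), info.min, info.max).astype(img.dtype)
    return out


def triangulate_rays(
    o1: np.ndarray, d1: np.ndarray, o2: np.ndarray, d2: np.ndarray
) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Closest points of two rays; returns (midpoint, distance, p1, p2).

    Raises
    ------
    ParallelRaysError
        If the rays are parallel within |sin angle| < 1e-8.
    """
    o1 = np.asarray(o1, float)
    d1 = np.asarray(d1, float)
    o2 = np.asarray(o2, float)
    d2 = np.asarray(d2, float)
    u1 = d1 / np.linalg.norm(d1)
    u2 = d2 / np.linalg.norm(d2)
    cr = np.cross(u1, u2)
    if np.linalg.norm(cr) < 1e-8:
        raise ParallelRaysError("rays are parallel; no unique midpoint")
    w0 = o1 - o2
    a, b, c = 1.0, float(u1 @ u2), 1.0
    d = float(u1 @ w0)
    e = float(u2 @ w0)
    den = a * c - b * b
    s = (b * e - c * d) / den
    t = (a * e - b * d) / den
    p1 = o1 + s * u1
    p2 = o2 + t * u2
    mid = 0.5 * (p1 + p2)
    return mid, float(np.linalg.norm(p1 - p2)), p1, p2


def triangulate_midpoint(
    rig: StereoRig, x1: Sequence[float], x2: Sequence[float]
) -> TriangulationResult:
    """Midpoint triangulation of pixel correspondence (x1, x2).

    The 3D point is the midpoint of the shortest segment Vp between the rays
    C1x1 and C2x2; ``error_mm`` is |Vp|.
    """
    o1, d1 = rig.cam1.ray(x1)
    o2, d2 = rig.cam2.ray(x2)
    mid, dist, p1, p2 = triangulate_rays(o1, d1, o2, d2)
    return TriangulationResult(
        point3d=mid,
        error_mm=dist,
        ray_points=(p1, p2),
        image_points=(np.asarray(x1, float), np.asarray(x2, float)),
    )


# --------------------------------------------------------------------------- #
# Calibration I/O
# --------------------------------------------------------------------------- #


def load_calibration(path) -> StereoRig:
    """Load a StereoRig from a YAML or JSON calibration file.

    Expected layout: ``{"cam1": {fx, fy, cx, cy, R, C}, "cam2": {...}}`` with
    R row-major (9 floats) and C in mm.
    """
    import yaml

    with open(path) as fh:
        text = fh.read()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    return StereoRig(
        cam1=CameraModel.from_dict(data["cam1"]),
        cam2=CameraModel.from_dict(data["cam2"]),
    )


def save_calibration(rig: StereoRig, path) -> None:
    with open(path, "w") as fh:
        json.dump({"cam1": rig.cam1.to_dict(), "cam2": rig.cam2.to_dict()}, fh, indent=2)
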