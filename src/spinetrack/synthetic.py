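"""Synthetic stereo scenes with known geometry and ground-truth landmarks.

Emulates the intraoperative setting the pipeline is designed for: a ridged,
textured surface (spine proxy) inside a brighter central band, viewed by two
converging metric cameras, rendered with Lambertian shading, a global
illumination scalar and additive Gaussian pixel noise.  All geometry is
analytic, so ground-truth projections are computed with :func:`project`
rather than estimated from the rasterisation — every pipeline stage can be
validated end to end without patient data.

Two surface presets exist:

* ``ridge`` (default): a smooth central ridge with periodic bumps, verging
  cameras, multi-scale texture plus elliptical blobs sized for the MSER area
  window.  Used for all stochastic experiments.
* ``flat`` + ``landmark_style='peak'``: an exact-geometry validation preset —
  fronto-parallel plane, parallel rig whose pixel disparity f*B/Z is an exact
  integer, and landmark features rendered analytically at integer-pixel
  projections.  View 2 is then an exact integer translation of view 1 and the
  full pipeline can be checked for exact (sub-micrometre) recovery.

Default rig: baseline 400 mm, focal 1000 px, working distance 1000 mm, 10
degrees of vergence.  These are declared plausible stand-ins for a surgical
camera rig, not clinical values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage

from .exceptions import GeometryError
from .geometry import CameraModel, StereoRig, project

__all__ = [
    "SyntheticScene",
    "make_scene",
    "make_validation_scene",
    "render_views",
    "planted_correspondence_set",
]


@dataclass
class SyntheticScene:
    """A fully specified stereo scene; identical seeds give identical scenes."""

    rig: StereoRig
    landmarks: np.ndarray  # (n, 3) world mm, on the surface
    height: Callable[[np.ndarray, np.ndarray], np.ndarray]  # h(x, y) mm
    height_grad: Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]
    albedo: Callable[[np.ndarray, np.ndarray], np.ndarray]  # reflectance in [0, 1]
    working_distance: float
    image_size: tuple[int, int]  # (width, height)
    illumination: float
    noise_sigma: float
    seed: int
    meta: dict = field(default_factory=dict)

    def surface_z(self, x, y):
        """World z of the surface at lateral position (x, y)."""
        return self.working_distance - self.height(np.asarray(x, float), np.asarray(y, float))


def _camera(center, yaw_rad: float, focal: float, image_size) -> CameraModel:
    """Camera at ``center`` looking along +z rotated by ``yaw_rad`` about y."""
    ca, sa = np.cos(yaw_rad), np.sin(yaw_rad)
    R = np.array([[ca, 0.0, -sa], [0.0, 1.0, 0.0], [sa, 0.0, ca]])
    w, h = image_size
    return CameraModel(
        focal=(focal, focal),
        principal_point=((w - 1) / 2.0, (h - 1) / 2.0),
        rotation=R,
        center=np.asarray(center, float),
    )


def _texture_grid(rng, shape):
    """Band-limited multi-scale noise, zero mean, unit std."""
    g = np.zeros(shape)
    for sigma, w in ((1.5, 0.4), (4.0, 0.35), (12.0, 0.25)):
        g += w * ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    g -= g.mean()
    s = g.std()
    return g / s if s > 0 else g


def make_scene(
    n_landmarks: int = 20,
    image_size: tuple[int, int] = (640, 480),
    baseline_mm: float = 400.0,
    focal_px: float = 1000.0,
    working_distance_mm: float = 1000.0,
    vergence_deg: float = 10.0,
    ridge_height_mm: float = 30.0,
    noise_sigma: float = 2.0,
    illumination: float = 1.0,
    surface: str = "ridge",
    landmark_style: str = "extrema",
    seed: int = 0,
) -> SyntheticScene:
    """Build a deterministic synthetic scene.

    ``landmark_style='extrema'`` places landmarks at local maxima of the
    texture (so detectors can plausibly find them); ``'peak'`` adds analytic
    Gaussian peak features at integer-pixel view-1 projections (exact-
    geometry validation).  Raises :class:`GeometryError` when the requested
    geometry cannot place ``n_landmarks`` visible in both views.
    """
    if not (0.0 <= vergence_deg < 90.0):
        raise GeometryError(f"infeasible vergence {vergence_deg} deg")
    rng = np.random.default_rng(seed)
    w, h = image_size
    wd = working_distance_mm
    half_verg = np.deg2rad(vergence_deg) / 2.0
    cam1 = _camera((-baseline_mm / 2.0, 0.0, 0.0), +half_verg, focal_px, image_size)
    cam2 = _camera((+baseline_mm / 2.0, 0.0, 0.0), -half_verg, focal_px, image_size)
    rig = StereoRig(cam1, cam2)

    mm_per_px = wd / focal_px
    ext_x = mm_per_px * (w / 2.0) + baseline_mm / 2.0 + 150.0
    ext_y = mm_per_px * (h / 2.0) + 150.0
    res = max(0.5, mm_per_px)  # mm per texel (~1 texel per pixel at the surface)
    gx = np.arange(-ext_x, ext_x + res, res)
    gy = np.arange(-ext_y, ext_y + res, res)
    band_half = 120.0  # mm half-width of the bright central band

    noise_tex = _texture_grid(rng, (len(gy), len(gx)))
    X, Y = np.meshgrid(gx, gy)
    if landmark_style == "extrema":
        band = 1.0 / (1.0 + (X / band_half) ** 6)
    else:
        # exact-geometry preset: the band is flat across the whole stereo
        # overlap (its edges fall in each view's non-overlap margin), so
        # adaptive equalisation is near-identity around the landmarks and
        # both views see identical band content
        overlap_half = mm_per_px * w / 2.0 - baseline_mm / 2.0
        band = 1.0 / (1.0 + (X / (overlap_half + 60.0)) ** 40)

    # elliptical blobs sized to pass the MSER area window (given mm_per_px),
    # each evaluated only on a local window around its centre
    blob_field = np.zeros_like(X)
    r_px = np.sqrt(np.array([100.0, 800.0]) / np.pi)  # 5.6 .. 16 px
    r_mm = r_px * mm_per_px
    n_blobs = 60 if landmark_style == "extrema" else 0
    for _ in range(n_blobs):
        bx = rng.uniform(-band_half, band_half)
        by = rng.uniform(-(mm_per_px * h / 2.0), mm_per_px * h / 2.0)
        a = rng.uniform(r_mm[0] * 1.2, r_mm[1] * 0.8)
        b = rng.uniform(r_mm[0] * 1.2, a)
        ang = rng.uniform(0, np.pi)
        amp = rng.choice([-1.0, 1.0]) * rng.uniform(0.2, 0.35)
        ca, sa = np.cos(ang), np.sin(ang)
        half = 2.5 * a
        j0 = max(0, int((bx - half + ext_x) / res))
        j1 = min(len(gx), int((bx + half + ext_x) / res) + 2)
        i0 = max(0, int((by - half + ext_y) / res))
        i1 = min(len(gy), int((by + half + ext_y) / res) + 2)
        Xw, Yw = X[i0:i1, j0:j1], Y[i0:i1, j0:j1]
        u = (Xw - bx) * ca + (Yw - by) * sa
        v = -(Xw - bx) * sa + (Yw - by) * ca
        r2 = (u / a) ** 2 + (v / b) ** 2
        blob_field[i0:i1, j0:j1] += amp * 0.5 * (1.0 - np.tanh((r2 - 1.0) * 4.0))

    # the validation preset keeps the band darker and textureless so the peak
    # features retain detection contrast after adaptive equalisation (the
    # clip limit forces a near-identity map on a concentrated histogram)
    tex_amp = 0.18 if landmark_style == "extrema" else 0.0
    band_gain = 0.45 if landmark_style == "extrema" else 0.30
    base_grid = 0.15 + band_gain * band
    detail_grid = band * (tex_amp * noise_tex + blob_field)
    albedo_grid = np.clip(base_grid + detail_grid, 0.02, 1.0)

    # surface
    if surface == "ridge":
        rh = ridge_height_mm

        def height(x, y):
            return rh * np.exp(-(x**2) / (2 * 45.0**2)) * (1 + 0.25 * np.cos(2 * np.pi * y / 60.0))

        def height_grad(x, y):
            e = np.exp(-(x**2) / (2 * 45.0**2))
            m = 1 + 0.25 * np.cos(2 * np.pi * y / 60.0)
            hx = rh * e * m * (-x / 45.0**2)
            hy = rh * e * (-0.25 * 2 * np.pi / 60.0) * np.sin(2 * np.pi * y / 60.0)
            return hx, hy

    elif surface == "flat":

        def height(x, y):
            return np.zeros_like(np.asarray(x, float))

        def height_grad(x, y):
            z = np.zeros_like(np.asarray(x, float))
            return z, z

    else:
        raise ValueError(f"unknown surface {surface!r}")

    peaks: list[tuple[float, float, float, float]] = []  # (x, y, amp, sigma_mm)

    def albedo(x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        ci = (y + ext_y) / res
        cj = (x + ext_x) / res
        base = ndimage.map_coordinates(base_grid, [ci, cj], order=1, mode="nearest")
        detail = ndimage.map_coordinates(detail_grid, [ci, cj], order=1, mode="nearest")
        val = base
        if peaks:
            # each peak sits on a dark, texture-free pedestal: the bright
            # centre keeps a large detection contrast even after adaptive
            # equalisation, and by radial symmetry the response maximum of
            # any detector stays at the analytic centre
            supp = np.ones_like(val)
            peak_term = np.zeros_like(val)
            for px, py, amp, sig in peaks:
                r2 = (x - px) ** 2 + (y - py) ** 2
                peak_term += amp * np.exp(-r2 / (2 * sig**2))
                r = np.sqrt(r2)
                supp *= 0.5 * (1.0 + np.tanh((r - 7.0 * mm_per_px) / (1.5 * mm_per_px)))
            val = base + detail * supp + peak_term
        else:
            val = val + detail
        return np.clip(val, 0.0, 1.0)

    # landmarks
    margin_px = 40.0
    def _visible(P) -> bool:
        try:
            for cam in (cam1, cam2):
                u, v = project(cam, P)
                if not (margin_px <= u <= w - 1 - margin_px and margin_px <= v <= h - 1 - margin_px):
                    return False
        except GeometryError:
            return False
        return True

    landmarks: list[np.ndarray] = []
    if landmark_style == "extrema":
        sm = ndimage.gaussian_filter(albedo_grid, 2.0)
        footprint = int(round(12.0 / res))
        local = sm == ndimage.maximum_filter(sm, size=2 * footprint + 1)
        sel = local & (np.abs(X) < band_half - 20.0) & (np.abs(Y) < ext_y - 80.0)
        ii, jj = np.nonzero(sel)
        order = np.argsort(-sm[ii, jj])
        chosen: list[tuple[float, float]] = []
        for k in order:
            x0, y0 = float(gx[jj[k]]), float(gy[ii[k]])
            if any((x0 - cx) ** 2 + (y0 - cy) ** 2 < 25.0**2 for cx, cy in chosen):
                continue
            P = np.array([x0, y0, wd - float(height(x0, y0))])
            if not _visible(P):
                continue
            chosen.append((x0, y0))
            landmarks.append(P)
            if len(landmarks) == n_landmarks:
                break
    elif landmark_style == "peak":
        # integer-pixel view-1 projections on the plane z = wd
        d = focal_px * baseline_mm / wd  # pixel disparity, exact on the plane
        if abs(d - round(d)) > 1e-9:
            raise GeometryError(
                "peak landmarks need an integer plane disparity f*B/Z; "
                f"got {d}"
            )
        if vergence_deg != 0.0 or surface != "flat":
            raise GeometryError("peak landmarks require the flat parallel preset")
        cx, cy = cam1.principal_point
        attempts = 0
        taken: list[tuple[int, int]] = []
        lo_u = int(margin_px + d) + 1  # must stay inside view 2 as well
        hi_u = int(w - 1 - margin_px) - 1
        while len(taken) < n_landmarks and attempts < 20000:
            attempts += 1
            u = int(rng.integers(lo_u, hi_u))
            v = int(rng.integers(int(margin_px) + 1, int(h - 1 - margin_px)))
            x0 = (u - cx) * mm_per_px - baseline_mm / 2.0
            if abs(x0) > band_half - 15.0:
                continue
            if any(abs(u - tu) < 40 and abs(v - tv) < 40 for tu, tv in taken):
                continue
            if any((u - tu) ** 2 + (v - tv) ** 2 < 48**2 for tu, tv in taken):
                continue
            taken.append((u, v))
            y0 = (v - cy) * mm_per_px
            # amplitude keeps base+peak below the clip point (a clipped
            # plateau would leave the detector maximum ambiguous); the width
            # varies per landmark and three satellite bumps at random polar
            # offsets give every landmark a unique descriptor signature
            sig_mm = (1.4 + 0.05 * (len(taken) % 6)) * mm_per_px
            peaks.append((x0, y0, 0.5, sig_mm))
            landmarks.append(np.array([x0, y0, wd]))
            for _ in range(3):
                ang = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(9.0, 14.0) * mm_per_px
                peaks.append(
                    (x0 + rad * np.cos(ang), y0 + rad * np.sin(ang),
                     rng.uniform(0.15, 0.3), 1.2 * mm_per_px)
                )
    else:
        raise ValueError(f"unknown landmark_style {landmark_style!r}")

    if len(landmarks) < n_landmarks:
        raise GeometryError(
            f"infeasible geometry: only {len(landmarks)} of {n_landmarks} "
            "landmarks visible in both views"
        )

    return SyntheticScene(
        rig=rig,
        landmarks=np.array(landmarks),
        height=height,
        height_grad=height_grad,
        albedo=albedo,
        working_distance=wd,
        image_size=image_size,
        illumination=illumination,
        noise_sigma=noise_sigma,
        seed=seed,
        meta={
            "surface": surface,
            "landmark_style": landmark_style,
            "baseline_mm": baseline_mm,
            "focal_px": focal_px,
            "vergence_deg": vergence_deg,
            "band_half_mm": band_half,
            "mm_per_px": mm_per_px,
        },
    )


def make_validation_scene(n_landmarks: int = 20, seed: int = 0, **overrides) -> SyntheticScene:
    """Exact-geometry preset: flat plane, parallel rig with integer pixel
    disparity, analytic peak landmarks at integer-pixel projections, zero
    noise."""
    kwargs = dict(
        n_landmarks=n_landmarks,
        # disparity f*B/Z = 240 px: an exact integer and a whole number of
        # 80 px CLAHE tiles, so enhancement is shift-equivariant too
        baseline_mm=240.0,
        focal_px=1000.0,
        working_distance_mm=1000.0,
        vergence_deg=0.0,
        noise_sigma=0.0,
        surface="flat",
        landmark_style="peak",
        seed=seed,
    )
    kwargs.update(overrides)
    return make_scene(**kwargs)


def render_views(scene: SyntheticScene):
    """Render both camera views and return (img1, img2, ground_truth).

    Per-pixel ray casting against the analytic heightfield (fixed-point
    iteration on the depth), texture lookup, Lambertian shading scaled by the
    illumination factor, then additive Gaussian noise clipped to 8 bits.
    ``ground_truth`` holds the exact landmark projections computed with
    :func:`project` under keys ``'x1'`` and ``'x2'``.
    """
    w, h = scene.image_size
    wd = scene.working_distance
    imgs = []
    for view_idx, cam in enumerate((scene.rig.cam1, scene.rig.cam2)):
        fx, fy = cam.focal
        cx, cy = cam.principal_point
        uu, vv = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        d_cam = np.stack([(uu - cx) / fx, (vv - cy) / fy, np.ones_like(uu)])
        d = np.einsum("ij,jhw->ihw", cam.rotation.T, d_cam)
        C = cam.center
        zs = np.full_like(uu, wd)
        for _ in range(8):
            s = (zs - C[2]) / d[2]
            x = C[0] + s * d[0]
            y = C[1] + s * d[1]
            zs = wd - scene.height(x, y)
        alb = scene.albedo(x, y)
        hx, hy = scene.height_grad(x, y)
        shade = 1.0 / np.sqrt(1.0 + hx**2 + hy**2)
        img = 255.0 * scene.illumination * alb * shade
        if scene.noise_sigma > 0:
            nrng = np.random.default_rng([scene.seed, 101 + view_idx])
            img = img + nrng.normal(0.0, scene.noise_sigma, size=img.shape)
        imgs.append(np.clip(np.rint(img), 0, 255).astype(np.uint8))

    x1 = np.array([project(scene.rig.cam1, P) for P in scene.landmarks])
    x2 = np.array([project(scene.rig.cam2, P) for P in scene.landmarks])
    return imgs[0], imgs[1], {"x1": x1, "x2": x2}


def planted_correspondence_set(
    scene: SyntheticScene,
    pixel_noise_sigma: float,
    outlier_fraction: float,
    seed: int,
    n_points: int = 500,
    outlier_min_displacement: float = 10.0,
):
    """Ground-truth projections of random surface points with isotropic pixel
    noise and a planted fraction of gross y-displaced outliers.

    Returns ``(pts1, pts2, outlier_mask)``; exactly
    ``round(outlier_fraction * n_points)`` entries are outliers, displaced in
    y by at least ``outlier_min_displacement`` pixels (default 10x the 1 px
    epipolar tolerance).
    """
    if not (0.0 <= outlier_fraction < 1.0):
        raise ValueError("outlier_fraction must be in [0, 1)")
    rng = np.random.default_rng([seed, 7])
    w, h = scene.image_size
    band_half = scene.meta.get("band_half_mm", 120.0)
    pts1, pts2 = [], []
    guard = 0
    while len(pts1) < n_points and guard < 100 * n_points:
        guard += 1
        x = rng.uniform(-band_half, band_half)
        y = rng.uniform(-band_half * 1.2, band_half * 1.2)
        P = np.array([x, y, float(scene.surface_z(x, y))])
        try:
            p1 = project(scene.rig.cam1, P)
            p2 = project(scene.rig.cam2, P)
        except GeometryError:
            continue
        if not all(5 <= p[0] <= w - 6 and 5 <= p[1] <= h - 6 for p in (p1, p2)):
            continue
        pts1.append(p1)
        pts2.append(p2)
    if len(pts1) < n_points:
        raise GeometryError("could not place the requested correspondences in both frusta")
    pts1 = np.array(pts1)
    pts2 = np.array(pts2)
    if pixel_noise_sigma > 0:
        pts1 = pts1 + rng.normal(0, pixel_noise_sigma, pts1.shape)
        pts2 = pts2 + rng.normal(0, pixel_noise_sigma, pts2.shape)
    n_out = int(round(outlier_fraction * n_points))
    outlier = np.zeros(n_points, dtype=bool)
    if n_out:
        idx = rng.choice(n_points, size=n_out, replace=False)
        outlier[idx] = True
        sign = np.where(rng.random(n_out) < 0.5, -1.0, 1.0)
        pts2[idx, 1] += sign * (
            outlier_min_displacement * 2.0 + rng.uniform(0, 30.0, n_out)
        )
    return pts1, pts2, outlier
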