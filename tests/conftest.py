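import numpy as np
import pytest
from scipy import ndimage

from spinetrack.geometry import CameraModel, StereoRig
from spinetrack.synthetic import make_scene, make_validation_scene, render_views


def make_verging_rig(
    baseline: float = 400.0,
    focal: float = 1000.0,
    vergence_deg: float = 10.0,
    image_size: tuple[int, int] = (640, 480),
) -> StereoRig:
    """Two converging metric cameras on the x-axis (test helper)."""
    w, h = image_size
    half = np.deg2rad(vergence_deg) / 2.0

    def cam(cx_mm, yaw):
        ca, sa = np.cos(yaw), np.sin(yaw)
        R = np.array([[ca, 0, -sa], [0, 1, 0], [sa, 0, ca]])
        return CameraModel(
            focal=(focal, focal),
            principal_point=((w - 1) / 2, (h - 1) / 2),
            rotation=R,
            center=np.array([cx_mm, 0.0, 0.0]),
        )

    return StereoRig(cam(-baseline / 2, half), cam(baseline / 2, -half))


@pytest.fixture(scope="session")
def verging_rig() -> StereoRig:
    return make_verging_rig()


@pytest.fixture(scope="session")
def default_scene():
    return make_scene(seed=1)


@pytest.fixture(scope="session")
def default_render(default_scene):
    return render_views(default_scene)


@pytest.fixture(scope="session")
def validation_scene():
    return make_validation_scene(seed=0)


@pytest.fixture(scope="session")
def validation_render(validation_scene):
    return render_views(validation_scene)


def textured_image(seed: int, shape=(96, 96), n_blobs: int = 5) -> np.ndarray:
    """Gentle background texture with strong elliptical blobs (uint8)."""
    rng = np.random.default_rng(seed)
    img = 120.0 + 6.0 * ndimage.gaussian_filter(rng.standard_normal(shape), 2.0)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    placed = []
    tries = 0
    while len(placed) < n_blobs and tries < 200:
        tries += 1
        cy = rng.uniform(16, shape[0] - 16)
        cx = rng.uniform(16, shape[1] - 16)
        r = rng.uniform(7.5, 13.0)
        if any((cy - py) ** 2 + (cx - px) ** 2 < (r + pr + 4) ** 2 for py, px, pr in placed):
            continue
        placed.append((cy, cx, r))
        sgn = 1.0 if rng.random() < 0.5 else -1.0
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        img[mask] = 120.0 + sgn * rng.uniform(85, 110)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def wedge_image(seed: int, shape=(160, 160), n: int = 14) -> np.ndarray:
    """Bright acute wedges on a dark field: corner features with sharply
    defined intensity-centroid orientations (float image)."""
    rng = np.random.default_rng(seed)
    img = np.full(shape, 70.0)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    tips = []
    for _ in range(n * 3):
        if len(tips) >= n:
            break
        ty = rng.uniform(40, shape[0] - 40)
        tx = rng.uniform(40, shape[1] - 40)
        if any((ty - a) ** 2 + (tx - b) ** 2 < 34**2 for a, b in tips):
            continue
        tips.append((ty, tx))
        ang = rng.uniform(0, 2 * np.pi)
        half = np.deg2rad(rng.uniform(25, 35))
        length = rng.uniform(18, 26)
        dy, dx = yy - ty, xx - tx
        r = np.hypot(dy, dx)
        d = dx * np.cos(ang) + dy * np.sin(ang)
        img[(d > np.cos(half) * r) & (r < length) & (r > 0)] = 200.0
    return img


def rotation_matched_orientation_shifts(k1, k2, shape, angle_deg: float, max_dist: float = 1.0):
    """Pair keypoints detected before/after an in-place image rotation and
    return the absolute deviations (rad) of their orientation shifts from the
    rotation angle.  ndimage.rotate(+a) moves points by R(-a) about the
    centre in x-right/y-down coordinates."""
    c = (shape[0] - 1) / 2.0
    a = np.deg2rad(angle_deg)
    Rm = np.array([[np.cos(a), np.sin(a)], [-np.sin(a), np.cos(a)]])
    p2 = np.array([kp.position for kp in k2]) if k2 else np.zeros((0, 2))
    lim = shape[0] - 32
    out = []
    for kp in k1:
        q = Rm @ (np.array(kp.position) - c) + c
        if not (32 <= q[0] <= lim and 32 <= q[1] <= lim) or not len(p2):
            continue
        d = np.linalg.norm(p2 - q, axis=1)
        j = int(np.argmin(d))
        if d[j] > max_dist:
            continue
        dt = (k2[j].orientation - kp.orientation + a) % (2 * np.pi)
        out.append(min(dt, 2 * np.pi - dt))
    return np.asarray(out)


def random_points_in_front(rng, rig, n: int) -> np.ndarray:
    """Random 3D points visible in front of both cameras of a verging rig."""
    return np.column_stack(
        [rng.uniform(-100, 100, n), rng.uniform(-100, 100, n), rng.uniform(600, 1400, n)]
    )
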