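"""Hessian-determinant blob detection, orientation assignment and the 64-d
Haar descriptor."""

import numpy as np
import pytest
from scipy import ndimage

from spinetrack.detect.common import Keypoint, SurfConfig
from spinetrack.detect.surf import (
    filter_sizes,
    hessian_det,
    sigma_for_size,
    surf_describe,
    surf_detect,
    surf_orient,
)
from spinetrack.exceptions import SpinetrackError
from spinetrack.matching import ncc


def gaussian_blob(s: float, size: int = 129, amp: float = 200.0) -> np.ndarray:
    y, x = np.mgrid[:size, :size] - (size - 1) / 2.0
    return amp * np.exp(-(x**2 + y**2) / (2 * s**2))


def smooth_texture(seed: int, shape=(161, 161), sigma: float = 2.0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return ndimage.gaussian_filter(rng.uniform(0, 255, shape), sigma)


class TestHessianDet:
    def test_determinant_identity_elementwise(self):
        """det map equals Lxx*Lyy - (0.9*Lxy)^2 recomputed from the stored
        response maps."""
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 255, (64, 64))
        for L in (9, 15, 27):
            r = hessian_det(img, filter_size=L)
            recomputed = r.Lxx * r.Lyy - (0.9 * r.Lxy) ** 2
            assert np.abs(r.det_map - recomputed).max() < 1e-12

    def test_flat_image_zero_response(self):
        r = hessian_det(np.full((64, 64), 100.0), filter_size=9)
        assert np.abs(r.det_map).max() < 1e-9

    def test_blob_argmax_position_and_scale(self):
        """Position argmax at the blob centre; the pyramid picks the schedule
        size nearest the dense-grid optimum."""
        for s in (3.0, 4.0, 6.0):
            img = gaussian_blob(s)
            c = (img.shape[0] - 1) // 2
            dense = {}
            for L in range(9, 70, 6):  # dense oracle over a coarse scale grid
                d = hessian_det(img, filter_size=L).det_map
                idx = np.unravel_index(np.argmax(d), d.shape)
                assert idx == (c, c)
                dense[L] = d[c, c]
            L_star = max(dense, key=dense.get)
            kps = surf_detect(img, SurfConfig(feature_threshold=50.0))
            assert kps, "no keypoints on the blob"
            top = max(kps, key=lambda k: k.response)
            assert abs(top.position[0] - c) <= 2 and abs(top.position[1] - c) <= 2
            schedule = sorted({L for o in range(4) for L in filter_sizes(o, 6)})
            nearest = min(schedule, key=lambda L: abs(L - L_star))
            assert top.scale == pytest.approx(sigma_for_size(nearest))

    def test_filter_too_large_rejected(self):
        with pytest.raises(SpinetrackError):
            hessian_det(np.zeros((10, 10)), filter_size=15)

    def test_sigma_snaps_to_valid_size(self):
        r = hessian_det(np.zeros((64, 64)), sigma=sigma_for_size(21))
        assert r.filter_size == 21


class TestSurfDetect:
    def test_flat_image_no_keypoints(self):
        assert surf_detect(np.full((96, 96), 80.0)) == []

    def test_single_blob_single_location(self):
        img = gaussian_blob(4.0)
        kps = surf_detect(img, SurfConfig(feature_threshold=50.0))
        c = (img.shape[0] - 1) / 2.0
        assert kps
        for kp in kps:  # all detections collapse onto the blob centre
            assert abs(kp.position[0] - c) <= 2 and abs(kp.position[1] - c) <= 2

    def test_default_threshold_respected(self, default_render):
        img1, _, _ = default_render
        kps = surf_detect(img1.astype(float), SurfConfig())
        assert kps
        assert all(kp.response >= 600.0 for kp in kps)

    def test_translation_equivariance(self):
        big = smooth_texture(5, (120, 120), 1.5)
        dy, dx = 6, 4
        a = big[: 120 - dy, : 120 - dx]
        b = big[dy:, dx:]
        cfg = SurfConfig(feature_threshold=20.0, n_octaves=2)
        pa = {(kp.position, round(kp.scale, 6)) for kp in surf_detect(a, cfg)}
        pb = {(kp.position, round(kp.scale, 6)) for kp in surf_detect(b, cfg)}
        margin = 45  # border band where octave-1 filters leave the image
        interior = [((x, y), s) for (x, y), s in pa
                    if margin <= x < 120 - dx - margin and margin <= y < 120 - dy - margin]
        assert interior, "fixture produced no interior keypoints"
        for (x, y), s in interior:
            assert ((x - dx, y - dy), s) in pb


class TestSurfOrient:
    def test_horizontal_ramp(self):
        ramp = np.tile(np.arange(64, dtype=float) * 4, (64, 1))
        theta = surf_orient(ramp, Keypoint(position=(32, 32), scale=2.0))
        assert min(abs(theta), abs(theta - np.pi), abs(theta - 2 * np.pi)) < 0.05

    def test_rotation_by_90_degrees(self):
        img = smooth_texture(6, (64, 64), 2.0)
        rot = np.rot90(img, k=-1).copy()
        kp = Keypoint(position=(31.5, 31.5), scale=2.0)
        t1 = surf_orient(img, kp)
        t2 = surf_orient(rot, kp)
        d = (t2 - t1) % (2 * np.pi)
        assert min(abs(d - np.pi / 2), abs(d - np.pi / 2 - 2 * np.pi)) < 0.1

    def test_flat_patch_fallback(self):
        theta = surf_orient(np.full((64, 64), 50.0), Keypoint(position=(32, 32), scale=2.0))
        assert theta == 0.0


class TestSurfDescribe:
    def test_unit_norm_and_length(self):
        img = smooth_texture(7)
        d = surf_describe(img, Keypoint(position=(80, 80), scale=3.0))
        assert d.kind == "real64"
        assert d.values.shape == (64,)
        assert np.linalg.norm(d.values) == pytest.approx(1.0)

    def test_identical_patches_correlate_perfectly(self):
        img = smooth_texture(8)
        kp = Keypoint(position=(80, 80), scale=3.0)
        a = surf_describe(img, kp)
        b = surf_describe(img.copy(), kp)
        assert ncc(a.values, b.values) == pytest.approx(1.0)

    def test_window_out_of_bounds_dropped(self):
        img = smooth_texture(9, (64, 64))
        assert surf_describe(img, Keypoint(position=(2, 2), scale=3.0)) is None

    def test_rotation_beats_empirical_null(self):
        """Descriptor of a 30-degree-rotated patch (with re-estimated
        orientation) correlates above the 95th percentile of random-patch
        descriptors."""
        rng_seeds = iter(range(100, 400))
        base = smooth_texture(3)
        kp0 = Keypoint(position=(80, 80), scale=3.0)
        kp0 = Keypoint(position=(80, 80), scale=3.0,
                       orientation=surf_orient(base, kp0))
        d0 = surf_describe(base, kp0)
        rot = ndimage.rotate(base, 30.0, reshape=False, order=1, mode="nearest")
        kpr = Keypoint(position=(80, 80), scale=3.0)
        kpr = Keypoint(position=(80, 80), scale=3.0,
                       orientation=surf_orient(rot, kpr))
        dr = surf_describe(rot, kpr)
        s_rot = ncc(d0.values, dr.values)
        nulls = []
        for _ in range(200):
            img = smooth_texture(next(rng_seeds))
            kpn = Keypoint(position=(80, 80), scale=3.0)
            kpn = Keypoint(position=(80, 80), scale=3.0,
                           orientation=surf_orient(img, kpn))
            nulls.append(ncc(d0.values, surf_describe(img, kpn).values))
        assert s_rot > np.percentile(nulls, 95)
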