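"""NCC/Hamming descriptor matching and epipolar outlier rejection."""

import numpy as np
import pytest

from spinetrack.detect.common import Descriptor, Keypoint
from spinetrack.exceptions import MatchingError
from spinetrack.matching import (
    MatchSet,
    epipolar_filter,
    hamming,
    match_descriptors,
    ncc,
)


def real_descs(n: int, seed: int) -> list[Descriptor]:
    rng = np.random.default_rng(seed)
    vals = rng.standard_normal((n, 64))
    vals /= np.linalg.norm(vals, axis=1, keepdims=True)
    return [Descriptor(kind="real64", values=v) for v in vals]


class TestNcc:
    def test_self_correlation(self):
        v = np.arange(10.0)
        assert ncc(v, v) == pytest.approx(1.0)

    def test_anticorrelation(self):
        v = np.arange(10.0)
        assert ncc(v, -v) == pytest.approx(-1.0)

    def test_orthogonal_zero_mean(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        assert ncc(a, b) == pytest.approx(0.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(MatchingError):
            ncc(np.ones(8), np.arange(8.0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(MatchingError):
            ncc(np.arange(8.0), np.arange(9.0))


class TestMatchDescriptors:
    def test_planted_permutation_recovery(self):
        """200 distinct descriptors in permuted order are re-identified for
        at least 99% of rows."""
        D1 = real_descs(200, 1)
        rng = np.random.default_rng(2)
        perm = rng.permutation(200)
        D2 = [D1[i] for i in perm]
        ms = match_descriptors(D1, D2)
        inv = np.empty(200, dtype=int)
        inv[perm] = np.arange(200)
        correct = sum(1 for i, j in ms.pairs if inv[i] == j)
        assert correct >= 0.99 * 200
        assert len(ms) >= 0.99 * 200

    def test_empty_inputs(self):
        assert len(match_descriptors([], real_descs(3, 3))) == 0
        assert len(match_descriptors(real_descs(3, 3), [])) == 0

    def test_tie_breaks_to_lower_index(self):
        d = Descriptor(kind="real64", values=np.tile([1.0, -1.0], 32))
        ms = match_descriptors([d], [d, Descriptor(kind="real64", values=d.values.copy())])
        assert len(ms) == 1
        assert tuple(ms.pairs[0]) == (0, 0)

    def test_mixed_kinds_rejected(self):
        b = Descriptor(kind="binary256", values=np.zeros(256, bool))
        with pytest.raises(MatchingError):
            match_descriptors(real_descs(2, 4), [b, b])

    def test_one_to_one(self):
        D1 = real_descs(50, 5)
        D2 = real_descs(60, 6)
        ms = match_descriptors(D1, D2)
        assert len(np.unique(ms.pairs[:, 0])) == len(ms)
        assert len(np.unique(ms.pairs[:, 1])) == len(ms)

    def test_symmetry_up_to_transpose(self):
        D1 = real_descs(40, 7)
        D2 = real_descs(40, 8)
        f = match_descriptors(D1, D2)
        r = match_descriptors(D2, D1)
        assert {(i, j) for i, j in f.pairs} == {(j, i) for i, j in r.pairs}

    def test_hamming_matching_of_binary(self):
        rng = np.random.default_rng(9)
        bits = rng.random((30, 256)) < 0.5
        D1 = [Descriptor(kind="binary256", values=b) for b in bits]
        perm = rng.permutation(30)
        D2 = [D1[i] for i in perm]
        ms = match_descriptors(D1, D2)
        assert ms.metric == "hamming"
        inv = np.empty(30, int)
        inv[perm] = np.arange(30)
        assert all(inv[i] == j for i, j in ms.pairs)
        assert (ms.scores == 0).all()

    def test_ncc_on_bits_strict_mode(self):
        rng = np.random.default_rng(10)
        bits = rng.random((10, 256)) < 0.5
        D = [Descriptor(kind="binary256", values=b) for b in bits]
        ms = match_descriptors(D, list(D), metric="ncc")
        assert ms.metric == "ncc"
        assert np.allclose(ms.scores, 1.0)


def kps_at(points) -> list[Keypoint]:
    return [Keypoint(position=(float(x), float(y))) for x, y in points]


class TestEpipolarFilter:
    def test_gross_outlier_flagged(self):
        k1 = kps_at([(10, 10), (20, 20)])
        k2 = kps_at([(8, 10.2), (18, 70)])  # second pair: 50 px y-disparity
        ms = MatchSet(pairs=[(0, 0), (1, 1)], scores=[1.0, 1.0], metric="ncc")
        out = epipolar_filter(ms, k1, k2, mode="rectified", tol_px=1.0)
        assert list(out.inlier_flags) == [True, False]
        assert out.y_disparities[1] == pytest.approx(50.0)

    def test_pure_subset_operation(self):
        k1 = kps_at([(0, 0), (1, 1), (2, 2)])
        k2 = kps_at([(0, 5), (1, 1.5), (2, 2.1)])
        ms = MatchSet(pairs=[(0, 0), (1, 1), (2, 2)], scores=[0.9, 0.8, 0.7],
                      metric="ncc")
        out = epipolar_filter(ms, k1, k2, tol_px=1.0)
        assert np.array_equal(out.pairs, ms.pairs)
        assert np.array_equal(out.scores, ms.scores)
        assert out.n_inliers == 2

    def test_empty_matchset_passthrough(self):
        ms = MatchSet(pairs=np.empty((0, 2), int), scores=np.empty(0), metric="ncc")
        out = epipolar_filter(ms, [], [], tol_px=1.0)
        assert len(out) == 0

    def test_general_mode_uses_line_distance(self, verging_rig):
        from spinetrack.geometry import project

        rng = np.random.default_rng(11)
        X = np.column_stack([rng.uniform(-80, 80, 10), rng.uniform(-80, 80, 10),
                             rng.uniform(700, 1300, 10)])
        p1 = [project(verging_rig.cam1, x) for x in X]
        p2 = [project(verging_rig.cam2, x) for x in X]
        ms = MatchSet(pairs=[(i, i) for i in range(10)], scores=np.ones(10),
                      metric="ncc")
        out = epipolar_filter(ms, kps_at(p1), kps_at(p2), mode="general",
                              tol_px=0.5, F=verging_rig.F)
        assert out.inlier_flags.all()
        # displace one point far off its epipolar line
        p2[3] = p2[3] + np.array([0.0, 30.0])
        out2 = epipolar_filter(ms, kps_at(p1), kps_at(p2), mode="general",
                               tol_px=0.5, F=verging_rig.F)
        assert not out2.inlier_flags[3]
        assert out2.inlier_flags.sum() == 9

    def test_general_mode_requires_f(self):
        ms = MatchSet(pairs=[(0, 0)], scores=[1.0], metric="ncc")
        with pytest.raises(MatchingError):
            epipolar_filter(ms, kps_at([(0, 0)]), kps_at([(0, 0)]), mode="general")

    def test_planted_outlier_fraction_removed_exactly(self, default_scene):
        """On a tolerance-separated construction the filter removes exactly
        the planted outliers and keeps at least 99% of true matches."""
        from spinetrack.synthetic import planted_correspondence_set

        p1, p2, outlier = planted_correspondence_set(
            default_scene, pixel_noise_sigma=0.0, outlier_fraction=0.2,
            seed=12, n_points=100)
        assert outlier.sum() == 20
        k1, k2 = kps_at(p1), kps_at(p2)
        ms = MatchSet(pairs=[(i, i) for i in range(100)], scores=np.ones(100),
                      metric="ncc")
        # zero-noise ground truth is not rectified: use the general constraint
        out = epipolar_filter(ms, k1, k2, mode="general", tol_px=1.0,
                              F=default_scene.rig.F)
        assert not out.inlier_flags[outlier].any()
        assert out.inlier_flags[~outlier].mean() >= 0.99

    def test_one_to_one_violation_rejected(self):
        with pytest.raises(MatchingError):
            MatchSet(pairs=[(0, 0), (0, 1)], scores=[1.0, 0.9], metric="ncc")
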