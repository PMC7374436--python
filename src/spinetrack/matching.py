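"""Descriptor matching between two views and epipolar outlier removal.

Real-valued descriptors are compared by normalized cross-correlation (NCC,
higher is better); binary descriptors by Hamming distance (lower is better).
Matching is mutual-best and one-to-one.  The epipolar filter flags pairs
violating the epipolar constraint: |y1 - y2| in rectified coordinates, or
point-to-epipolar-line distance given F.  A strict NCC-on-bits mode is
available for fidelity with pipelines that correlate all descriptor types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import MatchingError
from .detect.common import Descriptor, Keypoint

__all__ = ["MatchSet", "ncc", "hamming", "match_descriptors", "epipolar_filter"]


@dataclass
class MatchSet:
    """Index pairs between two keypoint sets with scores and inlier flags."""

    pairs: np.ndarray  # (n, 2) int: (index_view1, index_view2)
    scores: np.ndarray  # matching metric per pair
    metric: str  # 'ncc' | 'hamming'
    inlier_flags: np.ndarray = field(default=None)
    y_disparities: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.scores = np.asarray(self.scores, dtype=float).reshape(-1)
        if self.inlier_flags is None:
            self.inlier_flags = np.ones(len(self.pairs), dtype=bool)
        if self.y_disparities is None:
            self.y_disparities = np.full(len(self.pairs), np.nan)
        for side in (0, 1):
            idx = self.pairs[:, side]
            if len(np.unique(idx)) != len(idx):
                raise MatchingError("matching must be one-to-one within each view")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_inliers(self) -> int:
        return int(self.inlier_flags.sum())

    def inlier_pairs(self) -> np.ndarray:
        return self.pairs[self.inlier_flags]


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation of two equal-length vectors, in [-1, 1]."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise MatchingError("ncc requires equal-length vectors")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-15 or nb < 1e-15:
        raise MatchingError("undefined correlation: zero-variance vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    """Hamming distance between two equal-length bit vectors."""
    a = np.asarray(a, dtype=bool).ravel()
    b = np.asarray(b, dtype=bool).ravel()
    if a.shape != b.shape:
        raise MatchingError("hamming requires equal-length bit vectors")
    return int(np.count_nonzero(a != b))


def _stack(descs: list[Descriptor]) -> tuple[np.ndarray, str]:
    kinds = {d.kind for d in descs}
    if len(kinds) != 1:
        raise MatchingError(f"mixed descriptor kinds: {sorted(kinds)}")
    kind = kinds.pop()
    return np.stack([d.values for d in descs]), kind


def match_descriptors(
    D1: list[Descriptor], D2: list[Descriptor], metric: str | None = None
) -> MatchSet:
    """Mutual-best one-to-one matching between two descriptor sets.

    ``metric`` defaults to NCC for real-valued and Hamming for binary
    descriptors; ``metric='ncc'`` on binary descriptors correlates the bits
    as floats.  Pairs are sorted best-first; equal candidate scores break
    toward the lower second-view index.
    """
    if not D1 or not D2:
        return MatchSet(pairs=np.empty((0, 2), int), scores=np.empty(0),
                        metric=metric or "ncc")
    A, kind1 = _stack(D1)
    B, kind2 = _stack(D2)
    if kind1 != kind2:
        raise MatchingError(f"descriptor kinds differ: {kind1} vs {kind2}")
    if metric is None:
        metric = "hamming" if kind1 == "binary256" else "ncc"

    if metric == "ncc":
        A = A.astype(float)
        B = B.astype(float)
        A = A - A.mean(axis=1, keepdims=True)
        B = B - B.mean(axis=1, keepdims=True)
        na = np.linalg.norm(A, axis=1, keepdims=True)
        nb = np.linalg.norm(B, axis=1, keepdims=True)
        if (na < 1e-15).any() or (nb < 1e-15).any():
            raise MatchingError("zero-variance descriptor in NCC matching")
        S = (A / na) @ (B / nb).T
        better = S  # higher is better
    elif metric == "hamming":
        pa = np.packbits(A.astype(bool), axis=1)
        pb = np.packbits(B.astype(bool), axis=1)
        lut = np.unpackbits(np.arange(256, dtype=np.uint8)[:, None], axis=1).sum(1)
        S = lut[np.bitwise_xor(pa[:, None, :], pb[None, :, :])].sum(axis=2).astype(float)
        better = -S  # lower distance is better
    else:
        raise MatchingError(f"unknown metric {metric!r}")

    best2 = np.argmax(better, axis=1)  # ties -> lower index_view2
    best1 = np.argmax(better, axis=0)
    i1 = np.arange(len(D1))
    mutual = best1[best2[i1]] == i1
    pairs = np.column_stack([i1[mutual], best2[mutual]])
    scores = S[pairs[:, 0], pairs[:, 1]]
    order = np.argsort(-scores if metric == "ncc" else scores, kind="stable")
    return MatchSet(pairs=pairs[order], scores=scores[order], metric=metric)


def epipolar_filter(
    matches: MatchSet,
    kps1: list[Keypoint],
    kps2: list[Keypoint],
    mode: str = "rectified",
    tol_px: float = 1.0,
    F: np.ndarray | None = None,
) -> MatchSet:
    """Flag matches violating the epipolar constraint; nothing is re-matched.

    ``rectified`` mode keeps pairs with |y1 - y2| <= tol_px; ``general`` mode
    needs F and keeps pairs whose symmetric point-to-epipolar-line distance
    is <= tol_px.  Returns a new MatchSet with updated flags (a pure subset:
    pairs and scores are unchanged).
    """
    if len(matches) == 0:
        return MatchSet(pairs=matches.pairs.copy(), scores=matches.scores.copy(),
                        metric=matches.metric)
    p1 = np.array([kps1[i].position for i in matches.pairs[:, 0]], dtype=float)
    p2 = np.array([kps2[j].position for j in matches.pairs[:, 1]], dtype=float)
    ydisp = np.abs(p1[:, 1] - p2[:, 1])
    if mode == "rectified":
        dist = ydisp
    elif mode == "general":
        if F is None:
            raise MatchingError("general mode requires the fundamental matrix F")
        F = np.asarray(F, dtype=float)
        x1 = np.hstack([p1, np.ones((len(p1), 1))])
        x2 = np.hstack([p2, np.ones((len(p2), 1))])
        l2 = x1 @ F.T  # epipolar lines in view 2
        l1 = x2 @ F  # epipolar lines in view 1
        d2 = np.abs((x2 * l2).sum(1)) / np.hypot(l2[:, 0], l2[:, 1])
        d1 = np.abs((x1 * l1).sum(1)) / np.hypot(l1[:, 0], l1[:, 1])
        dist = np.maximum(d1, d2)
    else:
        raise MatchingError(f"unknown mode {mode!r}")
    return MatchSet(
        pairs=matches.pairs.copy(),
        scores=matches.scores.copy(),
        metric=matches.metric,
        inlier_flags=dist <= tol_px,
        y_disparities=ydisp,
    )
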