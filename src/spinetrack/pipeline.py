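"""End-to-end frame-pair processing and evaluation statistics.

``process_frame_pair`` runs the full chain on one stereo pair:
rectify -> enhance (CLAHE) -> segment -> detect/describe -> match ->
epipolar-filter -> triangulate the inliers, recording per-stage wall time.
``summarize`` reduces many frame pairs to the benchmark statistics
(mean +/- SD, median/IQR of the triangulation error; max/min/mean/median/IQR
of inlier counts), ``error_cdf`` builds empirical CDFs with a
Dvoretzky-Kiefer-Wolfowitz confidence band, and ``timing_report`` tabulates
per-stage execution times.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detect import DetectorConfig, detect_and_describe
from .exceptions import SpinetrackError
from .geometry import (
    RectifyingPair,
    StereoRig,
    TriangulationResult,
    apply_homography,
    compute_rectification,
    triangulate_midpoint,
    warp_image,
)
from .matching import MatchSet, epipolar_filter, match_descriptors
from .preprocess import clahe, crop_and_backproject, segment_spine

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "FramePairResult",
    "RunSummary",
    "rig_seed_correspondences",
    "process_frame_pair",
    "summarize",
    "error_cdf",
    "EmpiricalCdf",
    "timing_report",
]


@dataclass
class PipelineConfig:
    """Tunable knobs of the frame-pair pipeline."""

    detector_config: DetectorConfig = field(default_factory=DetectorConfig)
    clahe_clip: float = 0.03
    clahe_tiles: tuple[int, int] = (8, 8)
    epipolar_tol_px: float = 1.0
    metric: str | None = None  # None = NCC for real, Hamming for binary
    rectify: bool = True
    enhance: bool = True


@dataclass
class FramePairResult:
    """Output of one stereo frame pair under one detector."""

    detector_name: str
    matches: MatchSet
    triangulations: list[TriangulationResult]
    inlier_count: int
    stage_times: dict[str, float]
    group: str = ""
    frame_id: str = ""

    def __post_init__(self) -> None:
        if len(self.triangulations) != self.inlier_count:
            raise SpinetrackError("triangulations must cover exactly the inliers")

    @property
    def errors_mm(self) -> np.ndarray:
        return np.array([t.error_mm for t in self.triangulations])


def _working_depth(rig: StereoRig) -> float:
    """Depth along camera-1's optical axis of the rig's convergence point,
    or 2.5x the baseline for (near-)parallel axes."""
    o1 = rig.cam1.center
    d1 = rig.cam1.rotation.T @ np.array([0.0, 0.0, 1.0])
    o2 = rig.cam2.center
    d2 = rig.cam2.rotation.T @ np.array([0.0, 0.0, 1.0])
    cr = np.cross(d1, d2)
    if np.linalg.norm(cr) < 1e-6:
        return 2.5 * rig.baseline
    from .geometry import triangulate_rays

    _, _, p1, _ = triangulate_rays(o1, d1, o2, d2)
    return float(abs((p1 - o1) @ d1))


def rig_seed_correspondences(
    rig: StereoRig, image_size: tuple[int, int], n_grid: int = 7
) -> tuple[np.ndarray, np.ndarray]:
    """Seed correspondences for rectification of a calibrated rig.

    A grid of view-1 pixels is back-projected at two depths bracketing the
    rig's convergence distance and re-projected into view 2, giving exact
    correspondences with realistic depth-induced disparity spread.
    """
    from .exceptions import BehindCameraError
    from .geometry import project

    w, h = image_size
    z0 = _working_depth(rig)
    us = np.linspace(w * 0.1, w * 0.9, n_grid)
    vs = np.linspace(h * 0.1, h * 0.9, n_grid)
    p1_out, p2_out = [], []
    for v in vs:
        for u in us:
            o, d = rig.cam1.ray((u, v))
            for frac in (0.7, 1.3):
                X = o + frac * z0 * d
                try:
                    p2 = project(rig.cam2, X)
                except BehindCameraError:
                    continue
                p1_out.append((u, v))
                p2_out.append(p2)
    return np.asarray(p1_out, float), np.asarray(p2_out, float)


def process_frame_pair(
    img1: np.ndarray,
    img2: np.ndarray,
    rig: StereoRig,
    config: PipelineConfig | None = None,
    detector_name: str = "fast",
    group: str = "",
    frame_id: str = "",
) -> FramePairResult:
    """Run the full localization chain on one rectifiable stereo pair.

    Detected coordinates are carried back from the cropped, rectified frames
    to the original pixels before metric triangulation, so ``errors_mm`` are
    in world millimetres.  Zero surviving inliers yield a valid result with
    empty triangulations and a logged warning.
    """
    cfg = config or PipelineConfig()
    times: dict[str, float] = {}

    t0 = time.perf_counter()
    if cfg.rectify:
        p1s, p2s = rig_seed_correspondences(rig, (img1.shape[1], img1.shape[0]))
        rect = compute_rectification(
            rig.F, p1s, p2s,
            ((img1.shape[1], img1.shape[0]), (img2.shape[1], img2.shape[0])),
        )
        r1 = warp_image(img1, rect.H, rect.size1)
        r2 = warp_image(img2, rect.H_prime, rect.size2)
    else:
        rect = RectifyingPair(np.eye(3), np.eye(3),
                              (img1.shape[1], img1.shape[0]),
                              (img2.shape[1], img2.shape[0]), 0.0)
        r1, r2 = img1, img2

    if cfg.enhance:
        r1 = clahe(r1, cfg.clahe_clip, cfg.clahe_tiles)
        r2 = clahe(r2, cfg.clahe_clip, cfg.clahe_tiles)
    seg1 = segment_spine(r1)
    seg2 = segment_spine(r2)
    crop1, crop2 = seg1.cropped(), seg2.cropped()
    times["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    kps1, d1 = detect_and_describe(crop1, detector_name, cfg.detector_config)
    kps2, d2 = detect_and_describe(crop2, detector_name, cfg.detector_config)
    times["detect"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    matches = match_descriptors(d1, d2, metric=cfg.metric)
    # coordinates in the rectified full frames for the epipolar test
    full1 = crop_and_backproject(seg1, kps1) if kps1 else []
    full2 = crop_and_backproject(seg2, kps2) if kps2 else []
    matches = epipolar_filter(matches, full1, full2, mode="rectified",
                              tol_px=cfg.epipolar_tol_px)
    times["match"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    Hinv1 = np.linalg.inv(rect.H)
    Hinv2 = np.linalg.inv(rect.H_prime)
    triangulations: list[TriangulationResult] = []
    for i, j in matches.inlier_pairs():
        x1 = apply_homography(Hinv1, np.asarray(full1[i].position))[0]
        x2 = apply_homography(Hinv2, np.asarray(full2[j].position))[0]
        triangulations.append(triangulate_midpoint(rig, x1, x2))
    times["triangulate"] = time.perf_counter() - t0

    n_in = matches.n_inliers
    if n_in == 0:
        log.warning("frame %s (%s): zero matched inliers", frame_id, detector_name)
    return FramePairResult(
        detector_name=detector_name,
        matches=matches,
        triangulations=triangulations,
        inlier_count=n_in,
        stage_times=times,
        group=group,
        frame_id=frame_id,
    )


# --------------------------------------------------------------------------- #
# Statistics
# --------------------------------------------------------------------------- #


def _iqr(v: np.ndarray) -> float:
    """Interquartile range with linear (type-7) quantile interpolation."""
    q1, q3 = np.percentile(v, [25, 75])
    return float(q3 - q1)


@dataclass
class RunSummary:
    """Grouped evaluation statistics of a benchmark run."""

    error_stats: pd.DataFrame  # per group: n, mean, sd, median, iqr of error_mm
    inlier_stats: pd.DataFrame  # per group: max, min, mean, median, iqr of inliers

    def to_dict(self) -> dict:
        def _clean(df: pd.DataFrame) -> dict:
            return {str(k): {c: (None if pd.isna(x) else float(x)) for c, x in row.items()}
                    for k, row in df.to_dict("index").items()}

        return {"error_stats": _clean(self.error_stats),
                "inlier_stats": _clean(self.inlier_stats)}


def summarize(results: list[FramePairResult], group_by: str = "detector_name") -> RunSummary:
    """Per-group mean/SD/median/IQR of triangulation errors and
    max/min/mean/median/IQR of per-frame inlier counts.

    Groups holding a single error value report the sample SD as NA.  Frames
    with zero inliers contribute to the inlier statistics but no errors.
    """
    if not results:
        raise ValueError("summarize needs at least one result")
    groups: dict[str, list[FramePairResult]] = {}
    for r in results:
        groups.setdefault(str(getattr(r, group_by)), []).append(r)

    err_rows, inl_rows = {}, {}
    for g in sorted(groups):
        rs = groups[g]
        errs = np.concatenate([r.errors_mm for r in rs]) if rs else np.array([])
        if errs.size:
            err_rows[g] = {
                "n": float(errs.size),
                "mean": float(errs.mean()),
                "sd": float(errs.std(ddof=1)) if errs.size > 1 else np.nan,
                "median": float(np.median(errs)),
                "iqr": _iqr(errs),
            }
        else:
            err_rows[g] = {"n": 0.0, "mean": np.nan, "sd": np.nan,
                           "median": np.nan, "iqr": np.nan}
        counts = np.array([r.inlier_count for r in rs], dtype=float)
        inl_rows[g] = {
            "max": float(counts.max()),
            "min": float(counts.min()),
            "mean": float(counts.mean()),
            "median": float(np.median(counts)),
            "iqr": _iqr(counts),
        }
    return RunSummary(
        error_stats=pd.DataFrame(err_rows).T,
        inlier_stats=pd.DataFrame(inl_rows).T,
    )


@dataclass
class EmpiricalCdf:
    """Empirical CDF with a distribution-free DKW confidence band."""

    x: np.ndarray  # sorted values
    y: np.ndarray  # CDF at x (reaches 1)
    band_lower: np.ndarray
    band_upper: np.ndarray
    half_width: float
    confidence: float

    def fraction_below(self, threshold: float) -> float:
        """Fraction of values <= threshold."""
        return float(np.searchsorted(self.x, threshold, side="right") / len(self.x))


def error_cdf(errors: np.ndarray, confidence: float = 0.95) -> EmpiricalCdf:
    """Empirical CDF of triangulation errors with a DKW confidence band.

    The band half-width is ``sqrt(ln(2 / alpha) / (2 n))`` at the requested
    confidence (Dvoretzky-Kiefer-Wolfowitz inequality), clipped to [0, 1].
    """
    errors = np.sort(np.asarray(errors, dtype=float).ravel())
    if errors.size == 0:
        raise ValueError("error_cdf needs at least one value")
    n = errors.size
    y = np.arange(1, n + 1) / n
    alpha = 1.0 - confidence
    hw = float(np.sqrt(np.log(2.0 / alpha) / (2.0 * n)))
    return EmpiricalCdf(
        x=errors,
        y=y,
        band_lower=np.clip(y - hw, 0.0, 1.0),
        band_upper=np.clip(y + hw, 0.0, 1.0),
        half_width=hw,
        confidence=confidence,
    )


def timing_report(results: list[FramePairResult]) -> pd.DataFrame:
    """Per-detector, per-stage mean +/- SD execution times (seconds).

    ``fps`` is 1 / mean detection time.  Missing stages report NA.
    """
    rows = []
    dets = sorted({r.detector_name for r in results})
    stages = ("preprocess", "detect", "match", "triangulate")
    for det in dets:
        rs = [r for r in results if r.detector_name == det]
        row: dict[str, float] = {"detector": det}
        for st in stages:
            ts = np.array([r.stage_times[st] for r in rs if st in r.stage_times])
            row[f"{st}_mean_s"] = float(ts.mean()) if ts.size else np.nan
            row[f"{st}_sd_s"] = float(ts.std(ddof=1)) if ts.size > 1 else np.nan
        row["fps"] = (1.0 / row["detect_mean_s"]) if row.get("detect_mean_s") else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("detector")
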