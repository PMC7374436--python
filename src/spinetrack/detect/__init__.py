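"""The four benchmarked feature detectors: SURF-style Hessian blobs, MSER
regions, FAST corners and ORB oriented binary features."""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .common import (
    Descriptor,
    DetectorConfig,
    FastConfig,
    Keypoint,
    MserConfig,
    OrbConfig,
    SurfConfig,
    box_sum,
    integral_image,
)
from .fast import fast_corner_mask, fast_detect, fast_score
from .mser import MserRegion, mser_detect
from .orb import orb_detect_describe, orb_orientation, orb_test_pattern
from .surf import (
    ScaleSpaceResponse,
    hessian_det,
    surf_describe,
    surf_detect,
    surf_detect_describe,
    surf_orient,
)

DETECTOR_NAMES = ("surf", "mser", "fast", "orb")

__all__ = [
    "DETECTOR_NAMES",
    "Keypoint",
    "Descriptor",
    "DetectorConfig",
    "SurfConfig",
    "MserConfig",
    "FastConfig",
    "OrbConfig",
    "integral_image",
    "box_sum",
    "hessian_det",
    "ScaleSpaceResponse",
    "surf_detect",
    "surf_orient",
    "surf_describe",
    "surf_detect_describe",
    "mser_detect",
    "MserRegion",
    "fast_detect",
    "fast_corner_mask",
    "fast_score",
    "orb_detect_describe",
    "orb_orientation",
    "orb_test_pattern",
    "detect_and_describe",
    "mser_keypoint",
]


def mser_keypoint(region: MserRegion) -> Keypoint:
    """Keypoint proxy of an MSER region: ellipse centre, equivalent scale
    0.4 * sqrt(area / pi) (so the descriptor window spans the region)."""
    (cx, cy), _, _ = region.ellipse
    r_eq = np.sqrt(region.area / np.pi)
    return Keypoint(position=(cx, cy), scale=max(1.0, 0.4 * r_eq),
                    response=1.0 - region.stability)


def detect_and_describe(
    img: np.ndarray, detector: str, config: DetectorConfig | None = None
) -> tuple[list[Keypoint], list[Descriptor]]:
    """Run one named detector and return matched keypoint/descriptor lists.

    SURF, MSER and FAST keypoints carry the real-valued 64-d descriptor (MSER
    and FAST at their proxy scales, upright for FAST); ORB carries its own
    256-bit binary descriptor.
    """
    from .surf import surf_describe, surf_orient

    cfg = config or DetectorConfig()
    if detector == "surf":
        return surf_detect_describe(img, cfg.surf)
    if detector == "orb":
        return orb_detect_describe(img, cfg.orb)
    S = integral_image(np.asarray(img, dtype=float))
    if detector == "fast":
        kps = fast_detect(img, cfg.fast)  # upright: views are rectified
    elif detector == "mser":
        kps = [mser_keypoint(r) for r in mser_detect(img, cfg.mser)]
        kps = [replace(kp, orientation=surf_orient(img, kp, integral=S)) for kp in kps]
    else:
        raise ValueError(f"unknown detector {detector!r}; choose from {DETECTOR_NAMES}")
    out_k, out_d = [], []
    for kp in kps:
        d = surf_describe(img, kp, integral=S)
        if d is not None:
            out_k.append(kp)
            out_d.append(d)
    return out_k, out_d
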