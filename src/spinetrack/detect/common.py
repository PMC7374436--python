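"""Shared detector types: keypoints, descriptors, configs, integral images."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..exceptions import SpinetrackError

__all__ = [
    "Keypoint",
    "Descriptor",
    "SurfConfig",
    "MserConfig",
    "FastConfig",
    "OrbConfig",
    "DetectorConfig",
    "integral_image",
    "box_sum",
]


@dataclass(frozen=True)
class Keypoint:
    """Detected feature: position (x, y) px, scale sigma px, orientation rad,
    detector response."""

    position: tuple[float, float]
    scale: float = 1.0
    orientation: float = 0.0
    response: float = 0.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("keypoint scale must be positive")
        object.__setattr__(self, "orientation", float(self.orientation) % (2 * np.pi))


@dataclass(frozen=True)
class Descriptor:
    """Real-valued 64-d (SURF family) or 256-bit binary (ORB) descriptor."""

    kind: str  # 'real64' | 'binary256'
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if self.kind == "real64":
            if v.shape != (64,):
                raise ValueError(f"real64 descriptor must have 64 values, got {v.shape}")
            object.__setattr__(self, "values", v.astype(float))
        elif self.kind == "binary256":
            if v.shape != (256,):
                raise ValueError(f"binary256 descriptor must have 256 bits, got {v.shape}")
            object.__setattr__(self, "values", v.astype(bool))
        else:
            raise ValueError(f"unknown descriptor kind {self.kind!r}")


@dataclass
class SurfConfig:
    feature_threshold: float = 600.0
    n_octaves: int = 4
    n_scales: int = 6


@dataclass
class MserConfig:
    threshold_step: float = 0.3  # percent of the full intensity range per step
    area_range: tuple[int, int] = (100, 800)  # px^2
    max_area_variation: float = 0.3


@dataclass
class FastConfig:
    min_quality: float = 0.1  # NMS acceptance: score >= quality * max score
    min_contrast: float = 0.2  # T = min_contrast * 255
    arc_length: int = 12
    circle_size: int = 16


@dataclass
class OrbConfig:
    scale_factor: float = 1.2
    n_levels: int = 8
    descriptor_bits: int = 256
    fast_threshold: float = 20.0  # grey levels, internal FAST gate per level
    n_features: int = 1500  # keep the strongest corners across the pyramid


@dataclass
class DetectorConfig:
    """Per-algorithm parameter block (defaults follow the benchmark setup)."""

    surf: SurfConfig = field(default_factory=SurfConfig)
    mser: MserConfig = field(default_factory=MserConfig)
    fast: FastConfig = field(default_factory=FastConfig)
    orb: OrbConfig = field(default_factory=OrbConfig)

    def __post_init__(self) -> None:
        if self.surf.feature_threshold <= 0 or self.fast.min_contrast <= 0:
            raise ValueError("detector thresholds must be positive")
        lo, hi = self.mser.area_range
        if not lo < hi:
            raise ValueError("MSER area_range must satisfy min < max")
        if self.fast.arc_length > self.fast.circle_size:
            raise ValueError("arc_length cannot exceed circle_size")


def integral_image(img: np.ndarray) -> np.ndarray:
    """Zero-padded summed-area table of shape (H+1, W+1).

    ``S[r, c]`` is the sum of ``img[:r, :c]``; any axis-aligned box sum is
    then four lookups (see :func:`box_sum`).
    """
    img = np.asarray(img)
    if img.size == 0:
        raise SpinetrackError("integral_image: empty image")
    S = np.zeros((img.shape[0] + 1, img.shape[1] + 1), dtype=np.float64)
    np.cumsum(np.cumsum(img, axis=0, dtype=np.float64), axis=1, out=S[1:, 1:])
    return S


def box_sum(S: np.ndarray, r0: int, c0: int, r1: int, c1: int) -> float:
    """Sum of img[r0:r1, c0:c1] from the summed-area table ``S``."""
    return float(S[r1, c1] - S[r0, c1] - S[r1, c0] + S[r0, c0])
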