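"""File I/O: images, manifests, configuration and result tables.

Images are 8-bit/16-bit grayscale PNG/TIFF.  Colour inputs are converted to
luminance (ITU-R BT.601 weights) with a warning, or rejected in strict mode
(the target cameras are gray-scale).  Numeric CSV outputs carry explicit
units in their headers; JSON keeps full double precision.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .exceptions import SpinetrackError

__all__ = [
    "read_gray_image",
    "write_gray_image",
    "load_manifest",
    "load_images",
    "write_keypoints_csv",
    "write_matches_csv",
    "write_summary_json",
]


def read_gray_image(path, strict: bool = False) -> np.ndarray:
    """Read a grayscale image; colour inputs become luminance with a warning."""
    img = iio.imread(path)
    if img.ndim == 3:
        if strict:
            raise SpinetrackError(f"{path}: colour image rejected in strict grayscale mode")
        warnings.warn(f"{path}: colour image converted to luminance", stacklevel=2)
        rgb = img[..., :3].astype(float)
        img = (0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2])
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    if img.dtype not in (np.uint8, np.uint16):
        raise SpinetrackError(f"{path}: unsupported dtype {img.dtype}")
    return img


def write_gray_image(path, img: np.ndarray) -> None:
    iio.imwrite(path, img)


def load_manifest(path) -> pd.DataFrame:
    """Manifest: CSV or JSON with columns frame_id, path_view1, path_view2
    and optional group."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path)
    required = {"frame_id", "path_view1", "path_view2"}
    missing = required - set(df.columns)
    if missing:
        raise SpinetrackError(f"manifest {path} missing columns {sorted(missing)}")
    if "group" not in df.columns:
        df["group"] = ""
    return df


def load_images(manifest_path, strict: bool = False) -> Iterator[tuple]:
    """Yield (frame_id, img1, img2, group) per manifest row, in order.

    Per-row failures raise with the offending row identified.
    """
    df = load_manifest(manifest_path)
    root = Path(manifest_path).parent
    for _, row in df.iterrows():
        fid = str(row["frame_id"])
        try:
            p1 = Path(row["path_view1"])
            p2 = Path(row["path_view2"])
            img1 = read_gray_image(p1 if p1.is_absolute() else root / p1, strict=strict)
            img2 = read_gray_image(p2 if p2.is_absolute() else root / p2, strict=strict)
        except (OSError, SpinetrackError) as exc:
            raise SpinetrackError(f"manifest row {fid!r}: {exc}") from exc
        if img1.dtype != img2.dtype:
            raise SpinetrackError(f"manifest row {fid!r}: bit depth mismatch")
        yield fid, img1, img2, str(row["group"])


def _fmt(v: float) -> str:
    return f"{v:.6g}"


def write_keypoints_csv(path, keypoints) -> None:
    rows = [
        {
            "x_px": _fmt(kp.position[0]),
            "y_px": _fmt(kp.position[1]),
            "scale_px": _fmt(kp.scale),
            "orientation_rad": _fmt(kp.orientation),
            "response": _fmt(kp.response),
        }
        for kp in keypoints
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_matches_csv(path, matches, kps1, kps2) -> None:
    rows = []
    for k in range(len(matches)):
        i, j = matches.pairs[k]
        rows.append(
            {
                "idx1": int(i),
                "x1_px": _fmt(kps1[i].position[0]),
                "y1_px": _fmt(kps1[i].position[1]),
                "idx2": int(j),
                "x2_px": _fmt(kps2[j].position[0]),
                "y2_px": _fmt(kps2[j].position[1]),
                "score": _fmt(matches.scores[k]),
                "y_disparity_px": _fmt(matches.y_disparities[k]),
                "inlier": bool(matches.inlier_flags[k]),
            }
        )
    pd.DataFrame(
        rows,
        columns=["idx1", "x1_px", "y1_px", "idx2", "x2_px", "y2_px",
                 "score", "y_disparity_px", "inlier"],
    ).to_csv(path, index=False)


def write_summary_json(path, summary, extra: dict | None = None) -> None:
    payload = summary.to_dict()
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
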