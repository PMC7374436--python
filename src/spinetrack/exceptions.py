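"""Exception hierarchy for spinetrack."""


class SpinetrackError(Exception):
    """Base class for all spinetrack errors."""


class GeometryError(SpinetrackError, ValueError):
    """Invalid or degenerate two-view geometry."""


class BehindCameraError(GeometryError):
    """A 3D point has non-positive depth in the camera frame."""


class DegenerateRigError(GeometryError):
    """Camera centres coincide; no epipolar geometry exists."""


class EstimationError(GeometryError):
    """Fundamental-matrix estimation failed (too few or degenerate points)."""


class RectificationError(GeometryError):
    """Rectifying homographies cannot be computed (e.g. epipole inside image)."""


class ParallelRaysError(GeometryError):
    """Back-projected rays are parallel; no unique midpoint."""


class PreprocessError(SpinetrackError, ValueError):
    """Invalid input to a preprocessing operation."""


class EmptyMaskError(PreprocessError):
    """Segmentation produced an empty foreground."""


class MatchingError(SpinetrackError, ValueError):
    """Invalid descriptor matching input."""
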