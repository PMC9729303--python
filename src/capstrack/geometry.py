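"""Pose representations and label transforms.

Coordinate convention used throughout the package: the origin is the
top-left pixel center, ``x`` increases rightward along columns, ``y``
increases downward along rows, 0-based.  Orientation ``theta`` is the angle
of the capsule's long axis with respect to horizontal, measured
counter-clockwise as displayed (from +x toward -y, i.e. toward the top of
the screen), folded into [0, 180) because the capsule is symmetric
end-to-end.  This visual-CCW convention is the one under which the standard
image-rotation matrix (see :mod:`capstrack.augment`) adds its rotation
angle to ``theta``.

The capsule is annotated by four corner points of its bounding
quadrilateral; those annotations are converted to a centroid + orientation
pose label.  Pixel poses are converted to millimetres with the probe scale
factor (mm per pixel), which is acquisition metadata and always an input,
never a constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

__all__ = [
    "Units",
    "StateLabel",
    "PoseLabel",
    "CornerAnnotation",
    "ImageFrame",
    "DegenerateAnnotationError",
    "normalize_angle",
    "angular_distance",
    "corners_to_pose",
    "pose_to_mm",
    "pose_to_pixels",
    "resize_pose_update",
]


class Units(str, Enum):
    """Units of a pose's centroid coordinates."""

    PIXEL = "pixel"
    MM = "mm"


class StateLabel(str, Enum):
    """Mechanism state of the sampling capsule.

    ``CLOSED``: capsule sealed, full stadium-shaped echo visible.
    ``OPEN``: sampling cavity exposed, the echo splits into two halves.
    ``LOST``: capsule not visualizable in the field of view (out-of-plane
    motion or occlusion), or only an irregular fragment is visible.
    """

    CLOSED = "closed"
    OPEN = "open"
    LOST = "lost"


class DegenerateAnnotationError(ValueError):
    """Raised when a corner annotation is too degenerate to define a pose."""


def normalize_angle(theta: float) -> float:
    """Fold an angle in degrees into [0, 180)."""
    t = float(theta) % 180.0
    # guard against -1e-16 % 180 -> 180.0 under floating point
    return 0.0 if t >= 180.0 else t


@dataclass(frozen=True)
class PoseLabel:
    """In-plane 2D pose: centroid (x, y) and long-axis orientation theta.

    ``theta`` is in degrees in [0, 180); ``units`` tags whether (x, y) are
    pixels or millimetres.
    """

    x: float
    y: float
    theta: float
    units: Units = Units.PIXEL

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta", normalize_angle(self.theta))

    @property
    def xy(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class CornerAnnotation:
    """Four corner points (col, row) in pixels, ordered around the capsule."""

    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        pts = tuple((float(p[0]), float(p[1])) for p in self.points)
        if len(pts) != 4:
            raise ValueError(f"expected 4 corner points, got {len(pts)}")
        object.__setattr__(self, "points", pts)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float)

    def transformed(self, matrix: np.ndarray) -> "CornerAnnotation":
        """Apply a 2x3 affine matrix (acting on (x, y, 1)) to the corners."""
        m = np.asarray(matrix, dtype=float)
        pts = self.as_array()
        homo = np.hstack([pts, np.ones((4, 1))])
        return CornerAnnotation(tuple(map(tuple, homo @ m.T)))

    def shifted(self, dx: float, dy: float) -> "CornerAnnotation":
        return CornerAnnotation(tuple((x + dx, y + dy) for x, y in self.points))

    def inside(self, w: int, h: int, margin: float = 0.0) -> bool:
        pts = self.as_array()
        return bool(
            (pts[:, 0] >= margin).all()
            and (pts[:, 0] <= w - 1 - margin).all()
            and (pts[:, 1] >= margin).all()
            and (pts[:, 1] <= h - 1 - margin).all()
        )


@dataclass(frozen=True)
class ImageFrame:
    """8-bit grayscale image plus the probe scale factor (mm per pixel)."""

    pixels: np.ndarray
    scale_factor: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"pixels must be a 2D array, got shape {px.shape}")
        if not (math.isfinite(self.scale_factor) and self.scale_factor > 0):
            raise ValueError(f"scale_factor must be finite and > 0, got {self.scale_factor}")
        object.__setattr__(self, "pixels", px)

    @property
    def h(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def w(self) -> int:
        return int(self.pixels.shape[1])


# ---------------------------------------------------------------------------
# label transforms
# ---------------------------------------------------------------------------

#: minimum long/short edge-length ratio below which the long axis is ambiguous
AXIS_RATIO_TOL = 1.05


def corners_to_pose(corners: CornerAnnotation) -> PoseLabel:
    """Convert a four-corner annotation to a centroid + orientation pose.

    The centroid is the mean of the four points.  The long axis is the line
    joining the midpoints of the two short edges of the quadrilateral; its
    angle w.r.t. the +x image axis, folded into [0, 180), is ``theta``.

    Raises
    ------
    DegenerateAnnotationError
        If the quadrilateral has (near-)zero extent or the long and short
        edges are indistinguishable (edge-length ratio below 1.05), making
        the orientation ambiguous.
    """
    pts = corners.as_array()
    centroid = pts.mean(axis=0)

    # edges 0..3 join consecutive corners; (0, 2) and (1, 3) are opposite
    edges = np.roll(pts, -1, axis=0) - pts
    lengths = np.linalg.norm(edges, axis=1)
    pair_means = np.array([(lengths[0] + lengths[2]) / 2.0, (lengths[1] + lengths[3]) / 2.0])
    if pair_means.min() <= 0 or not np.isfinite(pair_means).all():
        raise DegenerateAnnotationError("quadrilateral has a zero-length edge pair")
    ratio = pair_means.max() / pair_means.min()
    if ratio < AXIS_RATIO_TOL:
        raise DegenerateAnnotationError(
            f"long/short edge ratio {ratio:.4f} below {AXIS_RATIO_TOL}; orientation ambiguous"
        )

    # the SHORT edges are the pair with the smaller mean length; the long
    # axis joins their midpoints
    short_pair = int(np.argmin(pair_means))  # 0 -> edges (0, 2), 1 -> edges (1, 3)
    i, j = (0, 2) if short_pair == 0 else (1, 3)
    mid_i = (pts[i] + pts[(i + 1) % 4]) / 2.0
    mid_j = (pts[j] + pts[(j + 1) % 4]) / 2.0
    axis = mid_j - mid_i
    if np.linalg.norm(axis) < 1e-12:
        raise DegenerateAnnotationError("short-edge midpoints coincide; zero-area annotation")

    # visual-CCW angle: y grows downward in pixel coords, so negate dy
    theta = math.degrees(math.atan2(-axis[1], axis[0]))
    return PoseLabel(float(centroid[0]), float(centroid[1]), normalize_angle(theta), Units.PIXEL)


def pose_to_mm(pose: PoseLabel, scale_factor: float) -> PoseLabel:
    """Convert a pixel pose to millimetres using the probe scale factor.

    The centroid is multiplied by ``scale_factor`` (mm/pixel); the
    orientation is unchanged (angles are invariant under isotropic scaling).
    """
    if pose.units is not Units.PIXEL:
        raise ValueError("pose_to_mm expects a pose in pixel units")
    if not (math.isfinite(scale_factor) and scale_factor > 0):
        raise ValueError(f"scale_factor must be > 0, got {scale_factor}")
    return PoseLabel(pose.x * scale_factor, pose.y * scale_factor, pose.theta, Units.MM)


def pose_to_pixels(pose: PoseLabel, scale_factor: float) -> PoseLabel:
    """Inverse of :func:`pose_to_mm`."""
    if pose.units is not Units.MM:
        raise ValueError("pose_to_pixels expects a pose in mm units")
    if not (math.isfinite(scale_factor) and scale_factor > 0):
        raise ValueError(f"scale_factor must be > 0, got {scale_factor}")
    return PoseLabel(pose.x / scale_factor, pose.y / scale_factor, pose.theta, Units.PIXEL)


def resize_pose_update(pose: PoseLabel, w: int, h: int, target: int = 224) -> PoseLabel:
    """Update a pose label for resizing a w x h image to target x target.

    Coordinates scale per axis: x' = target*x/w, y' = target*y/h.  The
    orientation transforms as a direction, tan(theta') = (w/h) * tan(theta),
    implemented by mapping the unit direction vector through the anisotropic
    scaling so theta = 90 deg maps to exactly 90 deg.
    """
    if pose.units is not Units.PIXEL:
        raise ValueError("resize_pose_update expects a pose in pixel units")
    if w <= 0 or h <= 0:
        raise ValueError(f"image dims must be positive, got w={w}, h={h}")
    if target <= 0:
        raise ValueError(f"target must be positive, got {target}")
    sx = target / float(w)
    sy = target / float(h)
    if pose.theta in (0.0, 90.0):  # axes map to axes exactly
        theta_new = pose.theta
    else:
        t = math.radians(pose.theta)
        theta_new = math.degrees(math.atan2(math.sin(t) * sy, math.cos(t) * sx))
    return PoseLabel(pose.x * sx, pose.y * sy, normalize_angle(theta_new), Units.PIXEL)


def angular_distance(a: float, b: float) -> float:
    """Distance between two orientations in degrees, 180-degree periodic.

    Returns min(|a-b|, 180-|a-b|) in [0, 90]; inputs are normalized into
    [0, 180) first.
    """
    d = abs(normalize_angle(a) - normalize_angle(b))
    return min(d, 180.0 - d)


def rotate_pose(pose: PoseLabel, matrix: np.ndarray, delta_deg: float) -> PoseLabel:
    """Pose label after an in-plane rotation by ``delta_deg``.

    The centroid is mapped through the 2x3 affine ``matrix``; theta is
    additive mod 180 (the long axis rotates rigidly with the image).
    """
    m = np.asarray(matrix, dtype=float)
    x, y = m @ np.array([pose.x, pose.y, 1.0])
    return replace(pose, x=float(x), y=float(y), theta=normalize_angle(pose.theta + delta_deg))
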