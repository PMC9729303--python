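"""Pose-label-preserving dataset expansion: small rotations, shifts, crops.

Each base image is rotated about the image center by a ladder of small
angles (default 0.5 deg to 5 deg in 0.5 deg steps, counter-clockwise as
displayed) and shifted by sampled integer offsets (t_x in [-10, 10], t_y in
[-10, 12] px), with the pose labels transformed exactly: rotation adds the
angle to theta (mod 180) and maps the centroid through the same affine
matrix that warps the pixels; shifts translate the centroid and leave theta
untouched.  Black borders injected by the warps are removed by a central
crop so the network cannot use them as features.

The rotation matrix about center (c_x, c_y) with scale c is

    [[ alpha, beta, (1-alpha)*c_x - beta*c_y],
     [-beta, alpha,  beta*c_x + (1-alpha)*c_y]],   alpha = c*cos(theta),
                                                   beta  = c*sin(theta),

the standard image-rotation form in which positive angles rotate the
displayed image counter-clockwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .geometry import CornerAnnotation, ImageFrame, PoseLabel, rotate_pose
from .synthetic import DatasetManifest, ManifestRecord

logger = logging.getLogger("capstrack.augment")

__all__ = [
    "AugmentPlan",
    "AugmentedSample",
    "SampleRejectedError",
    "rotation_matrix",
    "translation_matrix",
    "warp_affine",
    "rotate_with_labels",
    "shift_with_labels",
    "crop_borders",
    "resize_with_labels",
    "augment_dataset",
]

DEFAULT_ROTATION_ANGLES = tuple(round(0.5 * k, 1) for k in range(1, 11))


class SampleRejectedError(ValueError):
    """The transformed capsule leaves the valid image region."""


@dataclass(frozen=True)
class AugmentPlan:
    """Expansion plan mirroring the acquisition-time augmentation protocol."""

    rotation_angles: tuple[float, ...] = DEFAULT_ROTATION_ANGLES
    shift_range_x: tuple[int, int] = (-10, 10)
    shift_range_y: tuple[int, int] = (-10, 12)
    crop_margin: int = 16
    scale: float = 1.0
    center: tuple[float, float] | None = None  # None -> image center (w/2, h/2)
    shifts_per_image: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for a in self.rotation_angles:
            if not 0.0 < a <= 5.0:
                raise ValueError(f"rotation angles must be in (0, 5] deg, got {a}")
        if self.crop_margin < 0:
            raise ValueError("crop margin must be >= 0")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if self.shifts_per_image < 0:
            raise ValueError("shifts_per_image must be >= 0")


@dataclass
class AugmentedSample:
    """A transformed frame with its exactly-updated labels."""

    frame: ImageFrame
    pose: PoseLabel | None
    corners: CornerAnnotation | None = None


def rotation_matrix(theta: float, c: float = 1.0, c_x: float = 0.0,
                    c_y: float = 0.0) -> np.ndarray:
    """2x3 affine rotation matrix about (c_x, c_y), scale ``c``, in degrees."""
    if c <= 0:
        raise ValueError("scale must be > 0")
    alpha = c * math.cos(math.radians(theta))
    beta = c * math.sin(math.radians(theta))
    return np.array([
        [alpha, beta, (1.0 - alpha) * c_x - beta * c_y],
        [-beta, alpha, beta * c_x + (1.0 - alpha) * c_y],
    ], dtype=float)


def translation_matrix(t_x: float, t_y: float) -> np.ndarray:
    """2x3 affine translation matrix."""
    return np.array([[1.0, 0.0, t_x], [0.0, 1.0, t_y]], dtype=float)


def warp_affine(image: np.ndarray, matrix: np.ndarray, order: int = 1,
                cval: float = 0.0) -> np.ndarray:
    """Resample ``image`` under a forward 2x3 affine map on (x, y) points.

    ``order`` 1 is bilinear (images), 0 nearest-neighbour (masks); regions
    with no source pixel are filled with ``cval`` (black borders).
    """
    m = np.asarray(matrix, dtype=float)
    a, t = m[:, :2], m[:, 2]
    # convert the forward (x, y) map to scipy's inverse (row, col) map
    swap = np.array([[0.0, 1.0], [1.0, 0.0]])
    a_rc = swap @ a @ swap
    t_rc = swap @ t
    inv = np.linalg.inv(a_rc)
    out = ndimage.affine_transform(
        np.asarray(image, dtype=float), inv, offset=-inv @ t_rc,
        order=order, mode="constant", cval=cval,
    )
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    elif np.asarray(image).dtype == bool:
        out = out > 0.5
    return out


def _plan_center(plan: AugmentPlan, frame: ImageFrame) -> tuple[float, float]:
    return plan.center if plan.center is not None else (frame.w / 2.0, frame.h / 2.0)


def rotate_with_labels(frame: ImageFrame, pose: PoseLabel | None, delta: float,
                       plan: AugmentPlan, corners: CornerAnnotation | None = None,
                       ) -> AugmentedSample:
    """Rotate a frame by ``delta`` degrees CCW about the plan center.

    theta gains ``delta`` (mod 180); the centroid and corner annotation map
    through the same matrix.  Raises :class:`SampleRejectedError` if the
    transformed corner annotation leaves the image.
    """
    c_x, c_y = _plan_center(plan, frame)
    m = rotation_matrix(delta, plan.scale, c_x, c_y)
    new_corners = corners.transformed(m) if corners is not None else None
    if new_corners is not None and not new_corners.inside(frame.w, frame.h):
        raise SampleRejectedError(f"rotation by {delta} deg pushes the capsule out of frame")
    pixels = warp_affine(frame.pixels, m, order=1)
    new_pose = rotate_pose(pose, m, delta) if pose is not None else None
    return AugmentedSample(ImageFrame(pixels, frame.scale_factor), new_pose, new_corners)


def shift_with_labels(frame: ImageFrame, pose: PoseLabel | None, t_x: float, t_y: float,
                      corners: CornerAnnotation | None = None) -> AugmentedSample:
    """Translate a frame by (t_x, t_y) px; centroid shifts, theta unchanged."""
    m = translation_matrix(t_x, t_y)
    new_corners = corners.shifted(t_x, t_y) if corners is not None else None
    if new_corners is not None and not new_corners.inside(frame.w, frame.h):
        raise SampleRejectedError(f"shift ({t_x}, {t_y}) pushes the capsule out of frame")
    pixels = warp_affine(frame.pixels, m, order=1)
    new_pose = (replace(pose, x=pose.x + t_x, y=pose.y + t_y) if pose is not None else None)
    return AugmentedSample(ImageFrame(pixels, frame.scale_factor), new_pose, new_corners)


def crop_borders(frame: ImageFrame, pose: PoseLabel | None, margin: int,
                 corners: CornerAnnotation | None = None) -> AugmentedSample:
    """Central crop removing a ``margin``-px band on every side.

    Centroid coordinates drop by ``margin``; theta is unchanged.  Raises
    :class:`SampleRejectedError` if the corner annotation intrudes into the
    cropped band.
    """
    m = int(margin)
    if m < 0:
        raise ValueError("margin must be >= 0")
    if 2 * m >= min(frame.w, frame.h):
        raise ValueError(f"margin {m} too large for a {frame.w}x{frame.h} frame")
    if m == 0:
        return AugmentedSample(frame, pose, corners)
    if corners is not None and not corners.inside(frame.w, frame.h, margin=m):
        raise SampleRejectedError("capsule annotation lies inside the cropped band")
    pixels = frame.pixels[m:frame.h - m, m:frame.w - m]
    new_pose = replace(pose, x=pose.x - m, y=pose.y - m) if pose is not None else None
    new_corners = corners.shifted(-m, -m) if corners is not None else None
    return AugmentedSample(ImageFrame(pixels, frame.scale_factor), new_pose, new_corners)


def resize_with_labels(frame: ImageFrame, pose: PoseLabel | None, target: int = 224,
                       ) -> AugmentedSample:
    """Resize to target x target with the anisotropic pose-label update."""
    from skimage.transform import resize as sk_resize

    from .geometry import resize_pose_update

    out = sk_resize(frame.pixels.astype(float), (target, target), order=1,
                    preserve_range=True, anti_aliasing=True)
    pixels = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    # isotropic physical scale no longer holds after anisotropic resize; keep
    # the horizontal scale as the nominal factor
    scale = frame.scale_factor * frame.w / target
    new_pose = resize_pose_update(pose, frame.w, frame.h, target) if pose is not None else None
    return AugmentedSample(ImageFrame(pixels, scale), new_pose, None)


# ---------------------------------------------------------------------------
# dataset-level expansion
# ---------------------------------------------------------------------------

def _load_gray(path: str) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"))


def augment_dataset(manifest: DatasetManifest, plan: AugmentPlan, out_dir: str | Path,
                    seed: int | None = None,
                    images: dict[str, np.ndarray] | None = None) -> DatasetManifest:
    """Expand a base manifest with rotation and shift variants.

    The output contains every base record plus, per base image, one rotated
    copy per angle in the plan and ``plan.shifts_per_image`` shifted copies
    with integer offsets sampled uniformly from the plan ranges.  Variants
    are border-cropped by ``plan.crop_margin``.  Every variant record links
    to its base image (``base_path``) and carries the transformed labels.
    Samples whose transformed capsule leaves the valid region are rejected,
    counted and logged — never silently dropped.

    ``images`` optionally maps record paths to in-memory arrays (used with
    manifests from :func:`capstrack.synthetic.render_dataset_arrays`);
    otherwise images are read from disk and variants written under
    ``out_dir``.
    """
    seed = plan.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    in_memory = images is not None
    out = Path(out_dir)
    if not in_memory:
        out.mkdir(parents=True, exist_ok=True)

    out_records: list[ManifestRecord] = list(manifest.records)
    out_images: dict[str, np.ndarray] = {} if in_memory else None
    rejected = 0

    def emit(pixels: np.ndarray, base: ManifestRecord, sample: AugmentedSample,
             kind: str, param: str, name: str) -> None:
        rec = ManifestRecord(
            path=(f"mem://{name}" if in_memory else str(out / name)),
            state=base.state, pose=sample.pose, corners=sample.corners,
            split=base.split, scale_factor=base.scale_factor,
            base_path=base.base_id, aug_kind=kind, aug_param=param,
        )
        if in_memory:
            out_images[rec.path] = pixels
        else:
            Image.fromarray(pixels, mode="L").save(rec.path)
        out_records.append(rec)

    for base in manifest.records:
        pixels = images[base.path] if in_memory else _load_gray(base.path)
        frame = ImageFrame(pixels, base.scale_factor)
        stem = Path(base.path.replace("mem://", "")).stem

        for angle in plan.rotation_angles:
            try:
                s = rotate_with_labels(frame, base.pose, angle, plan, base.corners)
                s = crop_borders(s.frame, s.pose, plan.crop_margin, s.corners)
            except SampleRejectedError as exc:
                rejected += 1
                logger.warning("rejected %s rot %.1f: %s", base.path, angle, exc)
                continue
            emit(s.frame.pixels, base, s, "rotate", f"{angle:g}", f"{stem}_rot{angle:.1f}.png")

        for k in range(plan.shifts_per_image):
            t_x = int(rng.integers(plan.shift_range_x[0], plan.shift_range_x[1] + 1))
            t_y = int(rng.integers(plan.shift_range_y[0], plan.shift_range_y[1] + 1))
            try:
                s = shift_with_labels(frame, base.pose, t_x, t_y, base.corners)
                s = crop_borders(s.frame, s.pose, plan.crop_margin, s.corners)
            except SampleRejectedError as exc:
                rejected += 1
                logger.warning("rejected %s shift (%d, %d): %s", base.path, t_x, t_y, exc)
                continue
            emit(s.frame.pixels, base, s, "shift", f"{t_x},{t_y}",
                 f"{stem}_shift{k}_{t_x}_{t_y}.png")

    if rejected:
        logger.info("augmentation rejected %d samples out of bounds", rejected)
    if in_memory:
        for rec in manifest.records:
            out_images.setdefault(rec.path, images[rec.path])
        return DatasetManifest(out_records, images=out_images)
    return DatasetManifest(out_records)
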