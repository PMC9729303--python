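"""Evaluation metrics: position error, orientation error, state accuracy.

Position error (PE) defaults to the mean Euclidean distance between ground
truth and predicted centroids in millimetres.  A "literal" radial mode —
the mean absolute difference of the centroid ranges |sqrt(x_GT^2+y_GT^2) -
sqrt(x^2+y^2)| — is always co-reported: as a range difference it vanishes
for distinct points at equal distance from the origin, so by the reverse
triangle inequality it never exceeds the Euclidean error.

Orientation error (OE) defaults to the 180-degree-wrapped angular distance
(orientation is end-to-end symmetric; angle ambiguity otherwise inflates
errors near horizontal); the unwrapped |difference| is co-reported.  The
success rate is the fraction of orientation predictions within a +/-10
degree threshold.

State classification is summarised by accuracy (correct detections over
total, equivalently trace(confusion)/N), a 3x3 confusion matrix, and
one-vs-rest precision / recall / F1 per class.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from .geometry import StateLabel, angular_distance
from .model import STATE_CLASSES, TrackingResult, hierarchical_predict
from .synthetic import DatasetManifest

logger = logging.getLogger("capstrack.evaluate")

__all__ = [
    "MetricsReport",
    "position_error",
    "orientation_metrics",
    "state_accuracy",
    "confusion_matrix",
    "precision_recall_f1",
    "evaluate_tracker",
]

SUCCESS_THRESHOLD_DEG = 10.0


def position_error(gt: np.ndarray, pred: np.ndarray, mode: str = "euclidean") -> float:
    """Mean centroid error over samples, in the units of the inputs.

    ``euclidean``: mean of ||P_GT - P||.  ``literal``: mean of
    | ||P_GT|| - ||P|| | (difference of ranges from the image origin).
    """
    g = np.atleast_2d(np.asarray(gt, dtype=float))
    p = np.atleast_2d(np.asarray(pred, dtype=float))
    if g.shape != p.shape:
        raise ValueError(f"length/shape mismatch {g.shape} vs {p.shape}")
    if g.shape[0] == 0:
        raise ValueError("empty input")
    if mode == "euclidean":
        return float(np.linalg.norm(g - p, axis=1).mean())
    if mode == "literal":
        return float(np.abs(np.linalg.norm(g, axis=1) - np.linalg.norm(p, axis=1)).mean())
    raise ValueError(f"unknown mode {mode!r}")


def orientation_metrics(gt: np.ndarray, pred: np.ndarray,
                        threshold: float = SUCCESS_THRESHOLD_DEG,
                        wrap: bool = True) -> dict[str, float]:
    """OE statistics and success rate.

    Per-sample error is the 180-periodic angular distance when ``wrap`` is
    on (default), else the plain |difference|.  Returns mean, median,
    population std and the fraction of errors <= threshold.
    """
    g = np.atleast_1d(np.asarray(gt, dtype=float))
    p = np.atleast_1d(np.asarray(pred, dtype=float))
    if g.shape != p.shape:
        raise ValueError("length mismatch")
    if g.size == 0:
        raise ValueError("empty input")
    if wrap:
        errors = np.array([angular_distance(a, b) for a, b in zip(g, p)])
    else:
        errors = np.abs(g - p)
    return {
        "mean": float(errors.mean()),
        "median": float(np.median(errors)),
        "std": float(errors.std()),  # population (divide by N)
        "success_rate": float((errors <= threshold).mean()),
    }


def _as_states(labels) -> list[StateLabel]:
    out = []
    for s in labels:
        try:
            out.append(StateLabel(s))
        except ValueError as exc:
            raise ValueError(f"unknown state label {s!r}") from exc
    return out


def confusion_matrix(gt_states, pred_states) -> np.ndarray:
    """3x3 count matrix; rows ground truth, columns prediction, in the
    class order closed / open / lost."""
    g = _as_states(gt_states)
    p = _as_states(pred_states)
    if len(g) != len(p):
        raise ValueError("length mismatch")
    m = np.zeros((3, 3), dtype=int)
    for a, b in zip(g, p):
        m[STATE_CLASSES.index(a), STATE_CLASSES.index(b)] += 1
    return m


def state_accuracy(gt_states, pred_states) -> float:
    """Correct detections over total: (N_closed + N_open + N_lost) / N."""
    g = _as_states(gt_states)
    p = _as_states(pred_states)
    if len(g) != len(p) or not g:
        raise ValueError("inputs must be equal-length and nonempty")
    return sum(a is b for a, b in zip(g, p)) / len(g)


def precision_recall_f1(gt_states, pred_states) -> tuple[dict, np.ndarray]:
    """One-vs-rest precision/recall/F1 per class plus the confusion matrix.

    Zero-division convention: a metric whose denominator is zero (no
    predictions, or no instances, of that class) is reported as 0 with a
    warning.
    """
    m = confusion_matrix(gt_states, pred_states)
    per_class = {}
    for i, cls in enumerate(STATE_CLASSES):
        tp = m[i, i]
        pred_n = m[:, i].sum()
        gt_n = m[i, :].sum()
        if pred_n == 0:
            logger.warning("no predictions for class %s; precision set to 0", cls.value)
        if gt_n == 0:
            logger.warning("no instances of class %s; recall set to 0", cls.value)
        precision = tp / pred_n if pred_n else 0.0
        recall = tp / gt_n if gt_n else 0.0
        f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
        per_class[cls.value] = {"precision": float(precision), "recall": float(recall),
                                "f1": float(f1), "support": int(gt_n)}
    return per_class, m


@dataclass
class MetricsReport:
    """Full evaluation summary of the hierarchical tracker on one split."""

    n: int
    accuracy: float
    per_class: dict
    confusion: np.ndarray
    pe_euclidean_mm: float | None = None
    pe_literal_mm: float | None = None
    pe_euclidean_px: float | None = None
    per_axis_median_mm: tuple[float, float] | None = None
    oe_wrapped: dict | None = None
    oe_literal: dict | None = None
    n_pose_evaluated: int = 0
    n_closed_misgated: int = 0
    per_frame: list = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "accuracy": self.accuracy,
            "per_class": self.per_class,
            "confusion": self.confusion.tolist(),
            "pe_euclidean_mm": self.pe_euclidean_mm,
            "pe_literal_mm": self.pe_literal_mm,
            "pe_euclidean_px": self.pe_euclidean_px,
            "per_axis_median_mm": self.per_axis_median_mm,
            "oe_wrapped": self.oe_wrapped,
            "oe_literal": self.oe_literal,
            "n_pose_evaluated": self.n_pose_evaluated,
            "n_closed_misgated": self.n_closed_misgated,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "MetricsReport":
        d = dict(d)
        d["confusion"] = np.asarray(d["confusion"], dtype=int)
        if d.get("per_axis_median_mm") is not None:
            d["per_axis_median_mm"] = tuple(d["per_axis_median_mm"])
        return cls(**d)

    def table(self) -> str:
        lines = [f"N = {self.n}   accuracy = {self.accuracy:.4f}",
                 f"{'state':<8}{'precision':>10}{'recall':>10}{'F1':>10}{'support':>10}"]
        for cls, row in self.per_class.items():
            lines.append(f"{cls:<8}{row['precision']:>10.2f}{row['recall']:>10.2f}"
                         f"{row['f1']:>10.2f}{row['support']:>10d}")
        if self.oe_wrapped is not None:
            lines.append(
                f"pose (n={self.n_pose_evaluated}, mis-gated closed={self.n_closed_misgated}): "
                f"PE {self.pe_euclidean_mm:.3f} mm (literal {self.pe_literal_mm:.3f}), "
                f"OE {self.oe_wrapped['mean']:.2f} deg "
                f"(success {100 * self.oe_wrapped['success_rate']:.1f}%)")
        return "\n".join(lines)


def evaluate_tracker(manifest: DatasetManifest, state_model, orientation_model,
                     centroid_model, scale_factor: float | None = None,
                     images: dict[str, np.ndarray] | None = None) -> MetricsReport:
    """Run the hierarchical workflow over a manifest split and score it.

    State metrics cover every frame.  Pose metrics cover frames whose
    ground-truth state is closed AND whose predicted state is closed (the
    workflow gate); closed frames excluded by mis-gating are counted in
    ``n_closed_misgated``.  If no frame passes the gate the pose metrics
    are reported as absent (None), not NaN.
    """
    images = images if images is not None else manifest.images
    gt_states, pred_states = [], []
    gt_xy, pred_xy, gt_theta, pred_theta = [], [], [], []
    scales = []
    misgated = 0
    per_frame = []
    for rec in manifest:
        if images is not None and rec.path in images:
            px = images[rec.path]
        else:
            px = np.asarray(Image.open(rec.path).convert("L"))
        sf = scale_factor if scale_factor is not None else rec.scale_factor
        result: TrackingResult = hierarchical_predict(
            px, state_model, orientation_model, centroid_model, sf)
        gt_states.append(rec.state)
        pred_states.append(result.state)
        per_frame.append((rec.path, result))
        if rec.state is StateLabel.CLOSED:
            if result.state is StateLabel.CLOSED and result.has_pose:
                gt_xy.append(rec.pose.xy)
                pred_xy.append(result.pose_px.xy)
                gt_theta.append(rec.pose.theta)
                pred_theta.append(result.pose_px.theta)
                scales.append(sf)
            else:
                misgated += 1

    per_class, conf = precision_recall_f1(gt_states, pred_states)
    report = MetricsReport(
        n=len(gt_states),
        accuracy=state_accuracy(gt_states, pred_states),
        per_class=per_class,
        confusion=conf,
        n_closed_misgated=misgated,
        per_frame=per_frame,
    )
    if gt_xy:
        g = np.asarray(gt_xy)
        p = np.asarray(pred_xy)
        s = np.asarray(scales)[:, None]
        g_mm, p_mm = g * s, p * s
        report.pe_euclidean_px = position_error(g, p, "euclidean")
        report.pe_euclidean_mm = position_error(g_mm, p_mm, "euclidean")
        report.pe_literal_mm = position_error(g_mm, p_mm, "literal")
        ax = np.abs(g_mm - p_mm)
        report.per_axis_median_mm = (float(np.median(ax[:, 0])), float(np.median(ax[:, 1])))
        report.oe_wrapped = orientation_metrics(gt_theta, pred_theta, wrap=True)
        report.oe_literal = orientation_metrics(gt_theta, pred_theta, wrap=False)
        report.n_pose_evaluated = len(gt_xy)
    return report
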