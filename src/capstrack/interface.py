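"""Manifest I/O, run configuration, seed derivation and logging.

The dataset manifest is a UTF-8 CSV ('.' decimal) with header

    path,state,x_px,y_px,theta_deg,c0x,c0y,c1x,c1y,c2x,c2y,c3x,c3y,
    split,scale_mm_per_px,base_path,aug_kind,aug_param

Pose and corner columns are empty for lost-state records.  A JSON mirror
of the same records is also supported.  Run configuration is a YAML file
with nested sections (phantom / augment / network / train / evaluate)
whose keys mirror the corresponding config dataclasses; every stochastic
stage derives its seed deterministically from the global seed plus the
stage name.
"""

from __future__ import annotations

import csv
import json
import logging
import math
import sys
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .augment import AugmentPlan
from .geometry import CornerAnnotation, PoseLabel, StateLabel, Units
from .model import AttentionConfig, NetworkConfig
from .synthetic import DatasetManifest, ManifestRecord, PhantomConfig
from .train import TrainConfig

__all__ = [
    "MANIFEST_COLUMNS",
    "ManifestError",
    "read_manifest",
    "write_manifest",
    "import_corner_annotations",
    "RunConfig",
    "derive_seed",
    "setup_logging",
    "write_history",
]

MANIFEST_COLUMNS = (
    "path", "state", "x_px", "y_px", "theta_deg",
    "c0x", "c0y", "c1x", "c1y", "c2x", "c2y", "c3x", "c3y",
    "split", "scale_mm_per_px", "base_path", "aug_kind", "aug_param",
)


class ManifestError(ValueError):
    """Raised for malformed manifests; message lists offending line numbers."""


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    """Serialize a manifest to the documented CSV dialect (or JSON mirror
    when the path ends in .json)."""
    path = Path(path)
    rows = []
    for rec in manifest:
        pose = rec.pose
        corners = rec.corners.as_array().ravel() if rec.corners is not None else [""] * 8
        rows.append({
            "path": rec.path,
            "state": rec.state.value,
            "x_px": "" if pose is None else repr(pose.x),
            "y_px": "" if pose is None else repr(pose.y),
            "theta_deg": "" if pose is None else repr(pose.theta),
            **{f"c{i // 2}{'xy'[i % 2]}": ("" if isinstance(v, str) else repr(float(v)))
               for i, v in enumerate(corners)},
            "split": rec.split,
            "scale_mm_per_px": repr(rec.scale_factor),
            "base_path": rec.base_path,
            "aug_kind": rec.aug_kind,
            "aug_param": rec.aug_param,
        })
    if path.suffix == ".json":
        path.write_text(json.dumps(rows, indent=1))
        return
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=MANIFEST_COLUMNS)
        writer.writeheader()
        writer.writerows(rows)


def _parse_row(row: dict, line: int) -> ManifestRecord:
    missing = [c for c in MANIFEST_COLUMNS if c not in row]
    if missing:
        raise ManifestError(f"line {line}: missing columns {missing}")
    try:
        state = StateLabel(row["state"])
    except ValueError:
        raise ManifestError(f"line {line}: state {row['state']!r} not in closed/open/lost")

    def num(col: str) -> float:
        try:
            return float(row[col])
        except (TypeError, ValueError):
            raise ManifestError(f"line {line}: non-numeric value {row[col]!r} in {col}")

    pose = None
    if any(str(row[c]).strip() != "" for c in ("x_px", "y_px", "theta_deg")):
        theta = num("theta_deg")
        if not 0.0 <= theta < 180.0:
            raise ManifestError(f"line {line}: theta {theta} outside [0, 180)")
        pose = PoseLabel(num("x_px"), num("y_px"), theta, Units.PIXEL)

    corners = None
    corner_cols = [f"c{i}{a}" for i in range(4) for a in "xy"]
    if any(str(row[c]).strip() != "" for c in corner_cols):
        vals = [num(c) for c in corner_cols]
        corners = CornerAnnotation(tuple((vals[2 * i], vals[2 * i + 1]) for i in range(4)))

    split = row["split"] or "none"
    if split not in ("train", "val", "test", "none"):
        raise ManifestError(f"line {line}: invalid split tag {split!r}")
    scale = num("scale_mm_per_px")
    if not (math.isfinite(scale) and scale > 0):
        raise ManifestError(f"line {line}: scale_mm_per_px must be > 0, got {scale}")
    try:
        return ManifestRecord(
            path=row["path"], state=state, pose=pose, corners=corners, split=split,
            scale_factor=scale, base_path=row["base_path"] or "",
            aug_kind=row["aug_kind"] or "", aug_param=str(row["aug_param"] or ""),
        )
    except ValueError as exc:
        raise ManifestError(f"line {line}: {exc}")


def read_manifest(path: str | Path) -> DatasetManifest:
    """Parse and validate a manifest CSV (or its JSON mirror).

    Malformed rows raise :class:`ManifestError` naming the offending line.
    """
    path = Path(path)
    if path.suffix == ".json":
        rows = json.loads(path.read_text())
        records = [_parse_row(r, i + 1) for i, r in enumerate(rows)]
        return DatasetManifest(records)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ManifestError("empty manifest file")
        missing = [c for c in MANIFEST_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ManifestError(f"manifest header missing columns {missing}")
        records = [_parse_row(row, line) for line, row in enumerate(reader, start=2)]
    return DatasetManifest(records)


def import_corner_annotations(path: str | Path, scale_factor: float,
                              split: str = "none") -> DatasetManifest:
    """Import externally annotated frames from a minimal corner-point CSV.

    Expected header: ``path,state,c0x,c0y,c1x,c1y,c2x,c2y,c3x,c3y`` with
    empty corner cells for lost frames.  Poses are derived from the corner
    annotations (centroid + long-axis orientation), which is how manually
    annotated acquisitions are converted to training labels.  This adapter
    is a convenience for bringing real B-mode datasets into the manifest
    format; nothing in the package requires external data.
    """
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for line, row in enumerate(reader, start=2):
            try:
                state = StateLabel(row["state"])
            except (KeyError, ValueError):
                raise ManifestError(f"line {line}: bad state {row.get('state')!r}")
            corner_cols = [f"c{i}{a}" for i in range(4) for a in "xy"]
            pose = corners = None
            if state is not StateLabel.LOST:
                try:
                    vals = [float(row[c]) for c in corner_cols]
                except (KeyError, TypeError, ValueError):
                    raise ManifestError(f"line {line}: invalid corner coordinates")
                corners = CornerAnnotation(
                    tuple((vals[2 * i], vals[2 * i + 1]) for i in range(4)))
                from .geometry import corners_to_pose

                pose = corners_to_pose(corners)
            records.append(ManifestRecord(path=row["path"], state=state, pose=pose,
                                          corners=corners, split=split,
                                          scale_factor=scale_factor))
    return DatasetManifest(records)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from the global seed."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Nested configuration for a full pipeline run."""

    seed: int = 0
    out_dir: str = "runs"
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    augment: AugmentPlan = field(default_factory=AugmentPlan)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    evaluate: dict = field(default_factory=dict)

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        kw: dict[str, Any] = {}
        kw["seed"] = int(raw.get("seed", 0))
        kw["out_dir"] = str(raw.get("out_dir", "runs"))
        if "phantom" in raw:
            sect = dict(raw["phantom"])
            for key in ("layer_brightness", "capsule_contrast", "open_gap_frac"):
                if key in sect:
                    sect[key] = tuple(sect[key])
            kw["phantom"] = PhantomConfig(**sect)
        if "augment" in raw:
            sect = dict(raw["augment"])
            for key in ("rotation_angles", "shift_range_x", "shift_range_y", "center"):
                if key in sect and sect[key] is not None:
                    sect[key] = tuple(sect[key])
            kw["augment"] = AugmentPlan(**sect)
        if "network" in raw:
            sect = dict(raw["network"])
            attn = {k: sect.pop(k) for k in ("reduction", "bias", "index") if k in sect}
            if "tiny_channels" in sect:
                sect["tiny_channels"] = tuple(sect["tiny_channels"])
            if attn:
                sect["attention_cfg"] = AttentionConfig(**attn)
            kw["network"] = NetworkConfig(**sect)
        if "train" in raw:
            sect = dict(raw["train"])
            if "split_ratios" in sect:
                sect["split_ratios"] = tuple(sect["split_ratios"])
            kw["train"] = TrainConfig(**sect)
        kw["evaluate"] = dict(raw.get("evaluate", {}))
        return cls(**kw)


# ---------------------------------------------------------------------------
# logging
# ---------------------------------------------------------------------------

class _JsonlHandler(logging.Handler):
    def __init__(self, path: str | Path):
        super().__init__()
        self.fh = open(path, "a", encoding="utf-8")

    def emit(self, record: logging.LogRecord) -> None:
        self.fh.write(json.dumps({
            "ts": self.format(record).split(" ", 1)[0] if self.formatter else record.created,
            "created": record.created,
            "level": record.levelname,
            "name": record.name,
            "msg": record.getMessage(),
        }) + "\n")
        self.fh.flush()


def setup_logging(verbose: bool = False, jsonl_path: str | Path | None = None) -> None:
    """Timestamped lines to stderr plus an optional JSONL event log."""
    root = logging.getLogger("capstrack")
    root.setLevel(logging.DEBUG if verbose else logging.INFO)
    root.handlers = [h for h in root.handlers if not isinstance(h, (logging.StreamHandler,
                                                                    _JsonlHandler))]
    stream = logging.StreamHandler(sys.stderr)
    stream.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root.addHandler(stream)
    if jsonl_path is not None:
        root.addHandler(_JsonlHandler(jsonl_path))


def write_history(history: list[dict], path: str | Path) -> None:
    """Per-epoch training history as CSV (stage, epoch, losses, lr, best)."""
    cols = ["stage", "epoch", "train_loss", "val_loss", "lr", "best"]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols)
        writer.writeheader()
        for row in history:
            writer.writerow({c: row.get(c, "") for c in cols})
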