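"""Losses, dataset splitting and two-stage transfer-learning training.

Training follows a two-stage scheme: in stage 1 the convolutional backbone
is frozen and only the randomly initialised layers (attention module and
output head) are trained; in stage 2 the backbone is unfrozen down to a
fine-tuning depth ``ft_depth`` = i, meaning convolutional blocks 1..i (the
stem belongs to block 1) stay frozen while deeper blocks adapt.  Freezing
is a parameter-level contract: frozen parameters remain bit-identical, and
frozen batch-norm layers keep using (and never update) their running
statistics.

Classification tasks use the mean cross-entropy over samples; the centroid
regression uses a mean-squared-error-style loss L = (1/2N) sum ||y - t||^2
(a literal mode with the unsquared norm is also provided).  Orientation
targets can optionally be softened by a circular Gaussian over the 180
degree bins, which shares gradient mass with neighbouring angles — useful
when training from scratch on small datasets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace as dc_replace


import numpy as np
from PIL import Image

from . import nn
from .geometry import StateLabel, resize_pose_update
from .model import STATE_CLASSES, Network, encode_orientation
from .synthetic import DatasetManifest, ManifestRecord

logger = logging.getLogger("capstrack.train")

__all__ = [
    "TrainConfig",
    "split_dataset",
    "cross_entropy_loss",
    "centroid_loss",
    "orientation_targets",
    "manifest_arrays",
    "two_stage_train",
    "calibrate_centroid_head",
    "set_freeze",
]

#: total epoch counts used by the full-scale reference runs
#: (state / centroid / orientation)
FULL_SCALE_EPOCHS = {"state": 65, "centroid": 102, "orientation": 60}


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the two-stage procedure.

    Defaults are the full-scale values: Adam, stage-1 learning rate 1e-4,
    stage-2 fine-tuning rate 1e-5, batch size 32, dropout 0.5, 7:2:1 split,
    fine-tuning depth 2 (blocks 1-2 frozen in stage 2), early stopping on
    validation loss.  ``tiny_preset`` returns the desk-scale recipe for
    training the small backbone from random initialisation.
    """

    stage1_lr: float = 1e-4
    stage2_lr: float = 1e-5
    stage1_epochs: int = 15
    stage2_epochs: int = 50
    batch_size: int = 32
    ft_depth: int = 2
    patience: int = 10
    dropout: float = 0.5
    weight_decay: float = 0.0
    split_ratios: tuple[float, float, float] = (0.7, 0.2, 0.1)
    label_smoothing_sigma: float = 0.0
    centroid_loss_mode: str = "squared"
    monitor: str = "loss"  # early-stopping quantity: "loss" or "metric"
    stratify_by_state: bool = True
    leakage_guard: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stage1_lr <= 0 or self.stage2_lr <= 0:
            raise ValueError("learning rates must be > 0")
        if self.ft_depth < 0:
            raise ValueError("ft_depth must be >= 0")
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")
        if self.centroid_loss_mode not in ("squared", "literal"):
            raise ValueError(f"unknown centroid loss mode {self.centroid_loss_mode!r}")
        if self.monitor not in ("loss", "metric"):
            raise ValueError(f"unknown early-stopping monitor {self.monitor!r}")

    @classmethod
    def tiny_preset(cls, task: str, seed: int = 0) -> "TrainConfig":
        """Recipe for the tiny backbone trained from scratch on synthetic data.

        With a randomly initialised backbone stage 1 mainly settles the
        head, so it is short; stage 2 trains everything (ft_depth 0) at a
        from-scratch learning rate.  Orientation uses a 4-degree circular
        label smoothing (neighbouring angle bins share evidence), a lower
        dropout and weight decay, and early stopping monitors the validation
        task metric rather than the smoothed cross-entropy.
        """
        per_task = {
            "state": dict(stage2_epochs=12),
            "orientation": dict(stage2_lr=1e-3, stage2_epochs=28,
                                label_smoothing_sigma=4.0, dropout=0.3,
                                weight_decay=1e-4, patience=12),
            "centroid": dict(stage2_lr=1e-3, stage2_epochs=30, patience=15,
                             batch_size=16),
        }
        kw = dict(stage1_lr=2e-3, stage2_lr=2e-3, stage1_epochs=2, ft_depth=0,
                  patience=8, monitor="metric", seed=seed)
        kw.update(per_task[task])
        return cls(**kw)


# ---------------------------------------------------------------------------
# dataset splitting
# ---------------------------------------------------------------------------

def _largest_remainder(n: int, ratios: tuple[float, ...]) -> list[int]:
    exact = [n * r for r in ratios]
    base = [int(math.floor(e)) for e in exact]
    rem = n - sum(base)
    order = sorted(range(len(ratios)), key=lambda i: exact[i] - base[i], reverse=True)
    for i in order[:rem]:
        base[i] += 1
    return base


def split_dataset(manifest: DatasetManifest,
                  ratios: tuple[float, float, float] = (0.7, 0.2, 0.1),
                  seed: int = 0, stratify_by_state: bool = False,
                  leakage_guard: bool = True,
                  ) -> tuple[DatasetManifest, DatasetManifest, DatasetManifest]:
    """Split into train/val/test manifests; pure function of (manifest, seed).

    Sizes follow largest-remainder rounding of the ratios.  With
    ``leakage_guard`` every augmented variant stays in the same split as its
    base image.  With ``stratify_by_state`` the ratios are applied per
    state.  Raises if any split comes out empty.
    """
    if len(manifest) == 0:
        raise ValueError("cannot split an empty manifest")
    rng = np.random.default_rng(seed)

    # unit of assignment: base-image groups (leakage guard) or single records
    groups: dict[str, list[ManifestRecord]] = {}
    for rec in manifest:
        key = rec.base_id if leakage_guard else rec.path
        groups.setdefault(key, []).append(rec)
    keys = sorted(groups)

    def assign(keys_subset: list[str]) -> list[list[str]]:
        keys_subset = list(keys_subset)
        rng.shuffle(keys_subset)
        sizes = _largest_remainder(len(keys_subset), ratios)
        out, pos = [], 0
        for s in sizes:
            out.append(keys_subset[pos:pos + s])
            pos += s
        return out

    parts: list[list[str]] = [[], [], []]
    if stratify_by_state:
        for state in STATE_CLASSES:
            state_keys = [k for k in keys if groups[k][0].state is state]
            if not state_keys:
                continue
            for i, chunk in enumerate(assign(state_keys)):
                parts[i].extend(chunk)
    else:
        parts = assign(keys)

    names = ("train", "val", "test")
    manifests = []
    for name, part in zip(names, parts):
        recs = [dc_replace(groups[k][i], split=name)
                for k in part for i in range(len(groups[k]))]
        if not recs:
            raise ValueError(f"split {name!r} is empty; dataset too small for ratios {ratios}")
        manifests.append(DatasetManifest(recs, images=manifest.images))
    return tuple(manifests)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

LOG_EPS = 1e-12


def cross_entropy_loss(pred_probs: np.ndarray, targets: np.ndarray) -> float:
    """Mean over samples of -sum_k t_k log y_k (natural log).

    Zero predicted probabilities at a true class are clamped at 1e-12 (and
    logged) because the loss is undefined at 0.
    """
    p = np.asarray(pred_probs, dtype=float)
    t = np.asarray(targets, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    if p.shape[0] == 0:
        raise ValueError("empty batch")
    clamped = (p <= LOG_EPS) & (t > 0)
    if clamped.any():
        logger.warning("cross_entropy_loss clamped %d zero probabilities", int(clamped.sum()))
    return float(-(t * np.log(np.maximum(p, LOG_EPS))).sum(axis=1).mean())


def centroid_loss(pred: np.ndarray, target: np.ndarray, mode: str = "squared") -> float:
    """Centroid regression loss L = (1/2N) sum ||y - t||^2.

    ``mode='literal'`` uses the unsquared Euclidean norm instead,
    L = (1/2N) sum ||y - t||.
    """
    y = np.atleast_2d(np.asarray(pred, dtype=float))
    t = np.atleast_2d(np.asarray(target, dtype=float))
    if y.shape != t.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {t.shape}")
    n = y.shape[0]
    if n == 0:
        raise ValueError("empty batch")
    norms = np.linalg.norm(y - t, axis=1)
    if mode == "squared":
        return float((norms ** 2).sum() / (2 * n))
    if mode == "literal":
        return float(norms.sum() / (2 * n))
    raise ValueError(f"unknown mode {mode!r}")


def orientation_targets(thetas: np.ndarray, sigma: float = 0.0) -> np.ndarray:
    """Target distributions over the 180 one-degree bins.

    ``sigma`` = 0 gives one-hot targets at the nearest integer degree;
    otherwise a circular (180-periodic) Gaussian of that width, normalised
    per sample.
    """
    ks = np.array([encode_orientation(t) for t in np.atleast_1d(thetas)])
    n = len(ks)
    if sigma <= 0:
        out = np.zeros((n, 180), dtype=np.float32)
        out[np.arange(n), ks] = 1.0
        return out
    bins = np.arange(180)
    d = np.abs(bins[None, :] - ks[:, None])
    d = np.minimum(d, 180 - d)
    out = np.exp(-0.5 * (d / sigma) ** 2)
    return (out / out.sum(axis=1, keepdims=True)).astype(np.float32)


# ---------------------------------------------------------------------------
# arrays from manifests
# ---------------------------------------------------------------------------

def _load_pixels(rec: ManifestRecord, images: dict[str, np.ndarray] | None) -> np.ndarray:
    if images is not None and rec.path in images:
        return images[rec.path]
    return np.asarray(Image.open(rec.path).convert("L"))


def manifest_arrays(manifest: DatasetManifest, task: str, net: Network,
                    images: dict[str, np.ndarray] | None = None,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Preprocessed input tensors and targets for one task.

    Pose tasks use closed-capsule records only (the workflow estimates pose
    for closed capsules); labels are updated for the resize to the network
    input size.  Targets: state -> class index; orientation -> angle in
    degrees (binned later, possibly smoothed); centroid -> (x, y) in
    network-input pixels.
    """
    images = images if images is not None else manifest.images
    size = net.config.resolved_input_size
    xs, ys = [], []
    for rec in manifest:
        if task in ("orientation", "centroid") and rec.state is not StateLabel.CLOSED:
            continue
        px = _load_pixels(rec, images)
        xs.append(net.preprocess(px))
        if task == "state":
            ys.append(STATE_CLASSES.index(rec.state))
        else:
            h, w = px.shape
            pose = resize_pose_update(rec.pose, w, h, size)
            ys.append(pose.theta if task == "orientation" else (pose.x, pose.y))
    if not xs:
        raise ValueError(f"no usable records for task {task!r}")
    return np.stack(xs), np.asarray(ys, dtype=np.float32)


# ---------------------------------------------------------------------------
# freezing and the two-stage loop
# ---------------------------------------------------------------------------

def set_freeze(net: Network, frozen_blocks: int | None) -> None:
    """Set trainable flags: ``None`` freezes the whole backbone (stage 1);
    an integer i freezes convolutional blocks 1..i (stage 2, FT depth i)."""
    for p in net.head_params():
        p.trainable = True
    if frozen_blocks is None:
        for p in net.backbone_params():
            p.trainable = False
        return
    for idx in range(1, net.n_blocks + 1):
        flag = idx > frozen_blocks
        for p in net.block_params(idx):
            p.trainable = flag


def _targets_for(task: str, y: np.ndarray, config: TrainConfig) -> np.ndarray:
    if task == "state":
        t = np.zeros((len(y), 3), dtype=np.float32)
        t[np.arange(len(y)), y.astype(int)] = 1.0
        return t
    if task == "orientation":
        return orientation_targets(y, config.label_smoothing_sigma)
    return np.asarray(y, dtype=np.float32)


def _batch_loss_grad(task: str, out: np.ndarray, targets: np.ndarray,
                     config: TrainConfig) -> tuple[float, np.ndarray]:
    n = out.shape[0]
    if task in ("state", "orientation"):
        probs = nn.softmax(out, axis=1)
        loss = cross_entropy_loss(probs, targets)
        return loss, ((probs - targets) / n).astype(np.float32)
    diff = out - targets
    if config.centroid_loss_mode == "squared":
        loss = centroid_loss(out, targets, "squared")
        return loss, (diff / n).astype(np.float32)
    loss = centroid_loss(out, targets, "literal")
    norms = np.maximum(np.linalg.norm(diff, axis=1, keepdims=True), 1e-12)
    return loss, (diff / norms / (2 * n)).astype(np.float32)


def _eval_pass(net: Network, task: str, x: np.ndarray, targets: np.ndarray,
               y_raw: np.ndarray, config: TrainConfig) -> tuple[float, float]:
    """Validation loss plus a task metric (state: error rate; orientation:
    mean wrapped error in degrees; centroid: mean euclidean error in px)."""
    from .geometry import angular_distance

    losses, total, outs = 0.0, 0, []
    for i in range(0, len(x), 256):
        out = net.forward(x[i:i + 256], train=False)
        loss, _ = _batch_loss_grad(task, out, targets[i:i + 256], config)
        losses += loss * len(out)
        total += len(out)
        outs.append(out)
    out = np.concatenate(outs)
    if task == "state":
        metric = float((out.argmax(axis=1) != y_raw.astype(int)).mean())
    elif task == "orientation":
        pred = out.argmax(axis=1).astype(float)
        metric = float(np.mean([angular_distance(a, b) for a, b in zip(pred, y_raw)]))
    else:
        metric = float(np.linalg.norm(out - y_raw, axis=1).mean())
    return losses / total, metric


def _snapshot(net: Network) -> tuple[dict, dict]:
    params = {k: p.data.copy() for k, p in net.named_params().items()}
    buffers = {k: v.copy() for k, v in net.named_buffers().items()}
    return params, buffers


def _restore(net: Network, snap: tuple[dict, dict]) -> None:
    params, buffers = snap
    for k, p in net.named_params().items():
        p.data = params[k].copy()
    for k, v in net.named_buffers().items():
        v[...] = buffers[k]


def _run_stage(net: Network, task: str, stage: int, lr: float, epochs: int,
               data: tuple, config: TrainConfig, rng: np.random.Generator,
               history: list[dict]) -> None:
    x_train, t_train, x_val, t_val, y_val = data
    opt = nn.Adam(net.params(), lr=lr, weight_decay=config.weight_decay)
    best = (math.inf, _snapshot(net), -1)
    since_best = 0
    frozen = [k for k, p in net.named_params().items() if not p.trainable]
    logger.info("stage %d: lr=%g epochs=%d frozen_params=%d", stage, lr, epochs, len(frozen))

    for epoch in range(epochs):
        order = rng.permutation(len(x_train))
        train_loss, seen = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            if len(idx) < 2:
                continue  # batch norm needs at least two samples
            out = net.forward(x_train[idx], train=True)
            loss, dout = _batch_loss_grad(task, out, t_train[idx], config)
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at stage {stage} epoch {epoch}")
            opt.zero_grad()
            net.backward(dout)
            opt.step()
            train_loss += loss * len(idx)
            seen += len(idx)
        train_loss /= max(seen, 1)
        val_loss, val_metric = _eval_pass(net, task, x_val, t_val, y_val, config)
        if not math.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at stage {stage} epoch {epoch}")
        history.append({"stage": stage, "epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss, "val_metric": val_metric, "lr": lr})
        logger.info("stage %d epoch %d train %.4f val %.4f metric %.4f", stage,
                    epoch, train_loss, val_loss, val_metric)
        monitored = val_loss if config.monitor == "loss" else val_metric
        if monitored < best[0]:
            best = (monitored, _snapshot(net), len(history) - 1)
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                logger.info("early stopping at stage %d epoch %d", stage, epoch)
                break

    _restore(net, best[1])
    if best[2] >= 0:
        history[best[2]]["best"] = True


def calibrate_centroid_head(net: Network, x_val: np.ndarray,
                            y_val: np.ndarray) -> None:
    """Fold a per-axis affine recalibration into the linear output head.

    Squared-error training with limited capacity shrinks coordinate
    predictions toward the workspace mean (classic regression to the
    mean).  Fitting y ~ a * prediction + c per axis on the validation
    split and folding (a, c) into the FC weights removes that bias while
    keeping the head exactly linear.
    """
    outs = []
    for i in range(0, len(x_val), 256):
        outs.append(net.forward(x_val[i:i + 256], train=False))
    pred = np.concatenate(outs)
    for ax in range(pred.shape[1]):
        design = np.vstack([pred[:, ax], np.ones(len(pred))]).T
        (a, c), *_ = np.linalg.lstsq(design, y_val[:, ax], rcond=None)
        net.fc.weight.data[ax] *= np.float32(a)
        if net.fc.bias is not None:
            net.fc.bias.data[ax] = np.float32(a * net.fc.bias.data[ax] + c)
        logger.info("centroid head recalibrated: axis %d scale %.3f offset %.2f",
                    ax, a, c)


def two_stage_train(net: Network, splits: dict[str, DatasetManifest],
                    config: TrainConfig,
                    images: dict[str, np.ndarray] | None = None,
                    ) -> tuple[Network, list[dict]]:
    """Train a model with the two-stage scheme; returns (net, history).

    ``splits`` maps 'train' and 'val' to manifests.  Stage 1 updates only
    the attention module and output head (backbone frozen); stage 2
    fine-tunes everything except blocks 1..ft_depth at the lower stage-2
    rate.  Early stopping monitors validation loss; the best-validation
    weights are restored at the end of each stage.  For the centroid task
    the linear head is recalibrated on the validation split afterwards
    (see :func:`calibrate_centroid_head`).
    """
    task = net.config.task
    net.dropout.p = config.dropout
    x_train, y_train = manifest_arrays(splits["train"], task, net, images)
    x_val, y_val = manifest_arrays(splits["val"], task, net, images)
    t_train = _targets_for(task, y_train, config)
    t_val = _targets_for(task, y_val, config)
    data = (x_train, t_train, x_val, t_val, y_val)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    history: list[dict] = []

    if config.stage1_epochs > 0:
        set_freeze(net, None)
        _run_stage(net, task, 1, config.stage1_lr, config.stage1_epochs, data,
                   config, rng, history)
    if config.stage2_epochs > 0:
        set_freeze(net, config.ft_depth)
        _run_stage(net, task, 2, config.stage2_lr, config.stage2_epochs, data,
                   config, rng, history)
    if task == "centroid" and history:
        calibrate_centroid_head(net, x_val, t_val)
    return net, history
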