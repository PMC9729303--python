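"""Attention-based hierarchical network for capsule tracking.

Three separately trained models share one architecture: a residual
convolutional backbone, a channel-attention module with residual
refinement, global average pooling, dropout and a fully-connected output
head.  Model A classifies the mechanism state (closed / open / lost);
only when the state is closed are Model B (orientation, formulated as a
180-way classification over integer degrees 0-179) and Model C (centroid
regression) invoked — the hierarchical workflow.

Channel attention follows the pooled-statistics design: the feature map
``F`` (N, C, H, W) is reduced by global average pooling and global max
pooling, both pooled vectors pass through a shared two-layer MLP, the
results are summed elementwise and squashed by a sigmoid into a per-channel
gate ``M`` in (0, 1).  The refined map is ``F' = F + F * M`` (residual
refinement), so a zero attention response leaves the features untouched.

Residual blocks use the pre-activation form ``F_l = f_l(F_{l-1}) +
F_{l-1}``: with the inner transform zeroed the block is exactly the
identity, which keeps the residual contract testable by weight surgery.

Backbone variants: ``tiny`` (1-channel input, a few blocks — the desk-scale
backbone trained from random init) and ``resnet50`` (3-channel input,
bottleneck stages; grayscale frames are replicated to 3 channels).
Pretrained weights are an explicit opt-in loaded from a local file; nothing
is ever downloaded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .geometry import PoseLabel, StateLabel, Units, normalize_angle, pose_to_mm

__all__ = [
    "STATE_CLASSES",
    "AttentionConfig",
    "NetworkConfig",
    "ChannelAttention",
    "PreActBlock",
    "Network",
    "TrackingResult",
    "build_model",
    "hierarchical_predict",
    "encode_orientation",
    "decode_orientation",
    "save_checkpoint",
    "load_checkpoint",
]

#: fixed class order of the state head
STATE_CLASSES: tuple[StateLabel, ...] = (StateLabel.CLOSED, StateLabel.OPEN, StateLabel.LOST)

HEAD_SIZES = {"state": 3, "orientation": 180, "centroid": 2}


def encode_orientation(theta: float) -> int:
    """Orientation class index: nearest integer degree, mod 180."""
    return int(round(normalize_angle(theta))) % 180


def decode_orientation(klass: int) -> float:
    """Class ``k`` represents ``k`` degrees."""
    if not 0 <= klass < 180:
        raise ValueError(f"orientation class must be in [0, 180), got {klass}")
    return float(klass)


@dataclass(frozen=True)
class AttentionConfig:
    """Channel-attention hyperparameters.

    ``reduction`` is the MLP bottleneck ratio (hidden width =
    max(1, C // reduction)); ``bias`` toggles MLP biases (off by default so
    zero weights give the clean sigma(0) = 0.5 gate); ``index`` is the
    backbone block after which the module is inserted (None = per-task
    default: the last block for pose tasks, the penultimate for state).
    """

    reduction: int = 16
    bias: bool = False
    index: int | None = None


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture configuration; the checkpoint sidecar serializes this."""

    task: str = "state"
    variant: str = "tiny"
    attention: bool = True
    attention_cfg: AttentionConfig = field(default_factory=AttentionConfig)
    dropout: float = 0.5
    tiny_channels: tuple[int, ...] = (16, 32, 64)
    input_size: int | None = None  # None -> 64 for tiny, 224 for resnet50
    pretrained: bool = False
    pretrained_path: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in HEAD_SIZES:
            raise ValueError(f"unknown task {self.task!r}")
        if self.variant not in ("tiny", "resnet50"):
            raise ValueError(f"unknown backbone variant {self.variant!r}")

    @property
    def head_size(self) -> int:
        return HEAD_SIZES[self.task]

    @property
    def resolved_input_size(self) -> int:
        if self.input_size is not None:
            return self.input_size
        return 64 if self.variant == "tiny" else 224

    @property
    def in_channels(self) -> int:
        return 1 if self.variant == "tiny" else 3

    def to_dict(self) -> dict:
        return {
            "task": self.task, "variant": self.variant, "attention": self.attention,
            "reduction": self.attention_cfg.reduction, "attention_bias": self.attention_cfg.bias,
            "attention_index": self.attention_cfg.index, "dropout": self.dropout,
            "tiny_channels": list(self.tiny_channels), "input_size": self.input_size,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(
            task=d["task"], variant=d["variant"], attention=d["attention"],
            attention_cfg=AttentionConfig(d.get("reduction", 16), d.get("attention_bias", False),
                                          d.get("attention_index")),
            dropout=d.get("dropout", 0.5),
            tiny_channels=tuple(d.get("tiny_channels", (16, 32, 64))),
            input_size=d.get("input_size"), seed=d.get("seed", 0),
        )


class ChannelAttention(nn.Layer):
    """Pooled-statistics channel gate with residual refinement."""

    def __init__(self, channels: int, reduction: int = 16, bias: bool = False,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        hidden = max(1, channels // reduction)
        self.channels, self.hidden = channels, hidden
        self.w0 = nn.Param(nn.he_normal(rng, (hidden, channels), channels))
        self.w1 = nn.Param(nn.he_normal(rng, (channels, hidden), hidden))
        self.b0 = nn.Param(np.zeros(hidden, dtype=np.float32)) if bias else None
        self.b1 = nn.Param(np.zeros(channels, dtype=np.float32)) if bias else None
        self._cache = None

    def params(self) -> list[nn.Param]:
        out = [self.w0, self.w1]
        if self.b0 is not None:
            out += [self.b0, self.b1]
        return out

    def _mlp(self, v: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        h = v @ self.w0.data.T
        if self.b0 is not None:
            h = h + self.b0.data
        hr = np.maximum(h, 0.0)
        a = hr @ self.w1.data.T
        if self.b1 is not None:
            a = a + self.b1.data
        return h, hr, a

    def attention_map(self, f: np.ndarray) -> np.ndarray:
        """Per-channel gate M(F) in (0, 1), shape (N, C); also caches for backward."""
        n, c, h, w = f.shape
        gap = f.mean(axis=(2, 3))
        flat = f.reshape(n, c, h * w)
        argmax = flat.argmax(axis=2)
        gmp = np.take_along_axis(flat, argmax[:, :, None], axis=2)[:, :, 0]
        h_gap, hr_gap, a_gap = self._mlp(gap)
        h_gmp, hr_gmp, a_gmp = self._mlp(gmp)
        m = nn.sigmoid(a_gap + a_gmp).astype(np.float32)
        self._cache = (f, gap, gmp, h_gap, hr_gap, h_gmp, hr_gmp, argmax, m)
        return m

    def forward(self, f: np.ndarray, train: bool) -> np.ndarray:
        m = self.attention_map(f)
        return (f + f * m[:, :, None, None]).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        f, gap, gmp, h_gap, hr_gap, h_gmp, hr_gmp, argmax, m = self._cache
        n, c, hh, ww = f.shape
        mfull = m[:, :, None, None]
        df = dout * (1.0 + mfull)
        dm = (dout * f).sum(axis=(2, 3))
        ds = dm * m * (1.0 - m)

        def mlp_back(ds_, h_, hr_, v_):
            # shared weights: gradients accumulate across both pooled paths
            self.w1.grad += ds_.T @ hr_
            if self.b1 is not None:
                self.b1.grad += ds_.sum(axis=0)
            dhr = ds_ @ self.w1.data
            dh = dhr * (h_ > 0)
            self.w0.grad += dh.T @ v_
            if self.b0 is not None:
                self.b0.grad += dh.sum(axis=0)
            return dh @ self.w0.data

        dgap = mlp_back(ds, h_gap, hr_gap, gap)
        dgmp = mlp_back(ds, h_gmp, hr_gmp, gmp)
        df = df + dgap[:, :, None, None] / (hh * ww)
        dflat = np.zeros((n, c, hh * ww), dtype=np.float32)
        np.put_along_axis(dflat, argmax[:, :, None], dgmp[:, :, None], axis=2)
        return (df + dflat.reshape(n, c, hh, ww)).astype(np.float32)


def refine_features(f: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Residual refinement F' = F + F * M with M broadcast per channel."""
    f = np.asarray(f)
    m = np.asarray(m)
    if m.ndim == 1:
        m = m[None, :]
    if f.ndim != 4 or m.shape[-1] != f.shape[1]:
        raise ValueError(f"cannot broadcast attention map {m.shape} over features {f.shape}")
    return f + f * m[:, :, None, None]


class PreActBlock(nn.Layer):
    """Pre-activation residual block: out = conv(relu(bn(...))) + shortcut."""

    def __init__(self, cin: int, cout: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.bn1 = nn.BatchNorm2d(cin)
        self.relu1 = nn.ReLU()
        self.conv1 = nn.Conv2d(cin, cout, 3, stride=stride, rng=rng)
        self.bn2 = nn.BatchNorm2d(cout)
        self.relu2 = nn.ReLU()
        self.conv2 = nn.Conv2d(cout, cout, 3, stride=1, rng=rng)
        self.projection = (cin != cout or stride != 1)
        self.shortcut = (nn.Conv2d(cin, cout, 1, stride=stride, pad=0, rng=rng)
                         if self.projection else None)

    def params(self) -> list[nn.Param]:
        out = (self.bn1.params() + self.conv1.params() + self.bn2.params()
               + self.conv2.params())
        if self.shortcut is not None:
            out += self.shortcut.params()
        return out

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        a = self.bn1.forward(x, train)
        b = self.relu1.forward(a, train)
        h = self.conv1.forward(b, train)
        h = self.bn2.forward(h, train)
        h = self.relu2.forward(h, train)
        h = self.conv2.forward(h, train)
        sc = self.shortcut.forward(b, train) if self.projection else x
        return h + sc

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dh = self.conv2.backward(dout)
        dh = self.relu2.backward(dh)
        dh = self.bn2.backward(dh)
        db = self.conv1.backward(dh)
        if self.projection:
            db = db + self.shortcut.backward(dout)
        da = self.relu1.backward(db)
        dx = self.bn1.backward(da)
        if not self.projection:
            dx = dx + dout
        return dx


class PreActBottleneck(nn.Layer):
    """Pre-activation bottleneck: 1x1 reduce, 3x3, 1x1 expand + shortcut."""

    def __init__(self, cin: int, cout: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        mid = cout // 4
        self.bn1 = nn.BatchNorm2d(cin)
        self.relu1 = nn.ReLU()
        self.conv1 = nn.Conv2d(cin, mid, 1, pad=0, rng=rng)
        self.bn2 = nn.BatchNorm2d(mid)
        self.relu2 = nn.ReLU()
        self.conv2 = nn.Conv2d(mid, mid, 3, stride=stride, rng=rng)
        self.bn3 = nn.BatchNorm2d(mid)
        self.relu3 = nn.ReLU()
        self.conv3 = nn.Conv2d(mid, cout, 1, pad=0, rng=rng)
        self.projection = (cin != cout or stride != 1)
        self.shortcut = (nn.Conv2d(cin, cout, 1, stride=stride, pad=0, rng=rng)
                         if self.projection else None)

    def params(self) -> list[nn.Param]:
        out = (self.bn1.params() + self.conv1.params() + self.bn2.params()
               + self.conv2.params() + self.bn3.params() + self.conv3.params())
        if self.shortcut is not None:
            out += self.shortcut.params()
        return out

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        a = self.bn1.forward(x, train)
        b = self.relu1.forward(a, train)
        h = self.conv1.forward(b, train)
        h = self.relu2.forward(self.bn2.forward(h, train), train)
        h = self.conv2.forward(h, train)
        h = self.relu3.forward(self.bn3.forward(h, train), train)
        h = self.conv3.forward(h, train)
        sc = self.shortcut.forward(b, train) if self.projection else x
        return h + sc

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dh = self.conv3.backward(dout)
        dh = self.bn3.backward(self.relu3.backward(dh))
        dh = self.conv2.backward(dh)
        dh = self.bn2.backward(self.relu2.backward(dh))
        db = self.conv1.backward(dh)
        if self.projection:
            db = db + self.shortcut.backward(dout)
        dx = self.bn1.backward(self.relu1.backward(db))
        if not self.projection:
            dx = dx + dout
        return dx


class Network:
    """Backbone + attention + GAP + dropout + FC head."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        cin = config.in_channels

        if config.variant == "tiny":
            ch = config.tiny_channels
            self.stem = nn.Sequential(
                nn.Conv2d(cin, ch[0], 3, stride=2, rng=rng),
                nn.BatchNorm2d(ch[0]),
                nn.ReLU(),
            )
            self.blocks: list[nn.Layer] = []
            prev = ch[0]
            for c in ch:  # every block halves the spatial extent
                self.blocks.append(PreActBlock(prev, c, stride=2, rng=rng))
                prev = c
            feat = prev
        else:  # resnet50-style bottom-up: 5 convolutional blocks
            self.stem = nn.Sequential(
                nn.Conv2d(cin, 64, 7, stride=2, pad=3, rng=rng),
                nn.BatchNorm2d(64),
                nn.ReLU(),
            )
            stages = [(64, 256, 3, 1), (256, 512, 4, 2), (512, 1024, 6, 2), (1024, 2048, 3, 2)]
            self.blocks = []
            for cin_s, cout_s, n_units, stride in stages:
                units = [PreActBlock(cin_s, cout_s, stride=stride, rng=rng)]
                units += [PreActBlock(cout_s, cout_s, 1, rng=rng) for _ in range(n_units - 1)]
                self.blocks.append(nn.Sequential(*units))
            feat = 2048

        self.n_blocks = len(self.blocks)
        if config.attention:
            idx = config.attention_cfg.index
            if idx is None:
                idx = self.n_blocks - 1 if config.task == "state" else self.n_blocks
            if not 1 <= idx <= self.n_blocks:
                raise ValueError(f"attention index {idx} out of range 1..{self.n_blocks}")
            self.attention_index = idx
            # channel count at the insertion point
            c_at = self._channels_after_block(idx, feat)
            self.attention: ChannelAttention | None = ChannelAttention(
                c_at, config.attention_cfg.reduction, config.attention_cfg.bias, rng)
        else:
            self.attention = None
            self.attention_index = 0

        self.gap = nn.GlobalAvgPool()
        self.dropout = nn.Dropout(config.dropout, rng=np.random.default_rng(
            np.random.SeedSequence([config.seed, 7]).generate_state(1)[0]))
        self.fc = nn.Linear(feat, config.head_size, rng=rng)

        if config.pretrained:
            if not config.pretrained_path:
                raise ValueError(
                    "pretrained=True requires pretrained_path pointing to a local "
                    "checkpoint; weights are never downloaded")
            load_weights(self, config.pretrained_path)

    def _channels_after_block(self, idx: int, feat: int) -> int:
        if self.config.variant == "tiny":
            return self.config.tiny_channels[idx - 1]
        return [256, 512, 1024, 2048][idx - 1]

    # ----- parameter access -------------------------------------------------
    def backbone_params(self) -> list[nn.Param]:
        out = list(self.stem.params())
        for b in self.blocks:
            out += b.params()
        return out

    def block_params(self, idx: int) -> list[nn.Param]:
        """Parameters of convolutional block ``idx`` (1-based; the stem
        belongs to block 1)."""
        out = list(self.stem.params()) if idx == 1 else []
        return out + self.blocks[idx - 1].params()

    def head_params(self) -> list[nn.Param]:
        out = list(self.fc.params())
        if self.attention is not None:
            out += self.attention.params()
        return out

    def params(self) -> list[nn.Param]:
        return self.backbone_params() + self.head_params()

    def named_params(self) -> dict[str, nn.Param]:
        named: dict[str, nn.Param] = {}

        def walk(prefix: str, layer) -> None:
            if isinstance(layer, nn.Sequential):
                for i, sub in enumerate(layer.layers):
                    walk(f"{prefix}.{i}", sub)
                return
            for attr, val in vars(layer).items():
                if isinstance(val, nn.Param):
                    named[f"{prefix}.{attr}"] = val
                elif isinstance(val, nn.Layer):
                    walk(f"{prefix}.{attr}", val)

        walk("stem", self.stem)
        for i, b in enumerate(self.blocks, 1):
            walk(f"block{i}", b)
        if self.attention is not None:
            walk("attention", self.attention)
        walk("fc", self.fc)
        return named

    def named_buffers(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}

        def walk(prefix: str, layer) -> None:
            if isinstance(layer, nn.Sequential):
                for i, sub in enumerate(layer.layers):
                    walk(f"{prefix}.{i}", sub)
                return
            for name, arr in layer.buffers().items():
                out[f"{prefix}.{name}"] = arr
            for attr, val in vars(layer).items():
                if isinstance(val, nn.Layer):
                    walk(f"{prefix}.{attr}", val)

        walk("stem", self.stem)
        for i, b in enumerate(self.blocks, 1):
            walk(f"block{i}", b)
        if self.attention is not None:
            walk("attention", self.attention)
        walk("fc", self.fc)
        return out

    # ----- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits (classification) or coordinates (regression), (N, head)."""
        h = self.stem.forward(x, train)
        for i, block in enumerate(self.blocks, 1):
            h = block.forward(h, train)
            if self.attention is not None and i == self.attention_index:
                h = self.attention.forward(h, train)
        feats = self.gap.forward(h, train)
        feats = self.dropout.forward(feats, train)
        return self.fc.forward(feats, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.fc.backward(dlogits)
        d = self.dropout.backward(d)
        d = self.gap.backward(d)
        for i in range(self.n_blocks, 0, -1):
            if self.attention is not None and i == self.attention_index:
                d = self.attention.backward(d)
            d = self.blocks[i - 1].backward(d)
        self.stem.backward(d)

    # ----- prediction -------------------------------------------------------
    def preprocess(self, image: np.ndarray) -> np.ndarray:
        """Grayscale (H, W) uint8 -> standardized (C, S, S) float32.

        Resizes to the network input size and normalizes each image to zero
        mean / unit variance, which removes per-frame gain differences
        (imaging contrast varies frame to frame).
        """
        from skimage.transform import resize as sk_resize

        img = np.asarray(image)
        size = self.config.resolved_input_size
        if img.shape != (size, size):
            img = sk_resize(img.astype(float), (size, size), order=1,
                            preserve_range=True, anti_aliasing=True)
        x = img.astype(np.float32)
        x = (x - x.mean()) / max(float(x.std()), 1e-6)
        x = x[None]
        if self.config.in_channels == 3:
            x = np.repeat(x, 3, axis=0)
        return x

    def predict_raw(self, images: np.ndarray) -> np.ndarray:
        """Eval-mode forward on a batch of (H, W) images; chunked."""
        xs = np.stack([self.preprocess(im) for im in images])
        outs = []
        for i in range(0, len(xs), 64):
            outs.append(self.forward(xs[i:i + 64], train=False))
        return np.concatenate(outs, axis=0)

    def predict_single(self, image: np.ndarray) -> np.ndarray:
        """Probabilities (classification) or original-frame coords (regression)."""
        out = self.predict_raw(np.asarray(image)[None])[0]
        if self.config.task in ("state", "orientation"):
            return nn.softmax(out)
        h, w = np.asarray(image).shape
        size = self.config.resolved_input_size
        return np.array([out[0] * w / size, out[1] * h / size])


@dataclass(frozen=True)
class TrackingResult:
    """Outcome of the hierarchical workflow for one frame."""

    state: StateLabel
    confidence: float
    pose_px: PoseLabel | None = None
    pose_mm: PoseLabel | None = None

    @property
    def has_pose(self) -> bool:
        return self.pose_px is not None


def build_model(config: NetworkConfig) -> Network:
    """Construct a network per the configuration (see :class:`NetworkConfig`)."""
    return Network(config)


def hierarchical_predict(image: np.ndarray, state_model, orientation_model,
                         centroid_model, scale_factor: float | None = None,
                         ) -> TrackingResult:
    """Run the hierarchical workflow on one grayscale frame.

    The state model runs first; orientation and centroid models are invoked
    if and only if the detected state is closed.  Models are duck-typed:
    anything with ``predict_single(image)`` returning class probabilities
    (state, orientation) or original-frame pixel coordinates (centroid)
    works, which keeps the workflow testable with stubs.
    """
    probs = np.asarray(state_model.predict_single(image))
    k = int(np.argmax(probs))
    state = STATE_CLASSES[k]
    confidence = float(probs[k])
    if state is not StateLabel.CLOSED:
        return TrackingResult(state, confidence)
    theta = decode_orientation(int(np.argmax(orientation_model.predict_single(image))))
    xy = np.asarray(centroid_model.predict_single(image), dtype=float)
    pose_px = PoseLabel(float(xy[0]), float(xy[1]), theta, Units.PIXEL)
    pose_mm = pose_to_mm(pose_px, scale_factor) if scale_factor else None
    return TrackingResult(state, confidence, pose_px, pose_mm)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(net: Network, path: str | Path) -> None:
    """Write weights (.npz) plus a sidecar JSON describing the architecture."""
    path = Path(path)
    arrays = {f"param/{k}": p.data for k, p in net.named_params().items()}
    arrays.update({f"buffer/{k}": v for k, v in net.named_buffers().items()})
    np.savez(path, **arrays)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(net.config.to_dict(), indent=2))


def load_weights(net: Network, path: str | Path) -> None:
    """Load weights from a .npz checkpoint into an existing network."""
    with np.load(Path(path)) as data:
        named = net.named_params()
        for key in data.files:
            kind, _, name = key.partition("/")
            if kind == "param":
                if name not in named:
                    raise KeyError(f"checkpoint parameter {name!r} not in model")
                if named[name].data.shape != data[key].shape:
                    raise ValueError(f"shape mismatch for {name!r}")
                named[name].data = data[key].astype(np.float32).copy()
        buffers = net.named_buffers()
        for key in data.files:
            kind, _, name = key.partition("/")
            if kind == "buffer" and name in buffers:
                buffers[name][...] = data[key]


def load_checkpoint(path: str | Path) -> Network:
    """Rebuild a network from a checkpoint and its sidecar JSON."""
    path = Path(path)
    cfg = NetworkConfig.from_dict(json.loads(path.with_suffix(".json").read_text()))
    net = Network(cfg)
    load_weights(net, path)
    return net
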