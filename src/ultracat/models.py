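"""VGG-style convolutional backbones and their architectural surgery.

The reference architecture is a 13-conv-layer, 5-block VGG-16-style feature
stack (channel widths 64→512, 2x2 max pooling between blocks, no batch
normalization) followed by adaptive average pooling to a constant 7x7
spatial grid and a fully connected classifier.  Because the adaptive pooling
output never changes size, the classifier survives two kinds of surgery
unchanged in architecture:

* **head replacement** — swapping the K=1000 output layer for a fresh K=1
  detection head while every other parameter stays bit-identical;
* **depth pruning** — removing the deepest convolutional layers one by one
  (down to a single surviving layer), with only the first fully connected
  layer re-instantiated to match the surviving channel width.

Weights are freshly initialized under a seed; externally trained weights of
matching shapes can be injected at construction.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, replace

import numpy as np

from . import _nn
from ._nn import AdaptiveAvgPool2d, Conv2d, Flatten, Linear, MaxPool2d, Param, ReLU
from .errors import WeightMismatchError

__all__ = [
    "BackboneConfig",
    "BackboneModel",
    "DEFAULT_CONFIG",
    "small_preset",
    "make_backbone",
    "replace_head",
    "prune_conv_layers",
    "set_trainable",
    "save_checkpoint",
    "load_checkpoint",
    "parameter_checksum",
]


@dataclass(frozen=True)
class BackboneConfig:
    """Architecture hyperparameters of a backbone.

    Defaults reproduce the VGG-16 feature geometry: 5 blocks of
    (2, 2, 3, 3, 3) convolutions with widths (64, 128, 256, 512, 512),
    adaptive pooling to 7x7, and a (4096, 4096) fully connected classifier.
    ``mean``/``sd`` define the per-channel input standardization applied
    after scaling pixel values to [0, 1]; identity by default, set to the
    conventional ImageNet constants when injecting weights trained there.
    """

    channels: tuple[int, ...] = (64, 128, 256, 512, 512)
    convs_per_block: tuple[int, ...] = (2, 2, 3, 3, 3)
    pool_side: int = 7
    hidden: tuple[int, ...] = (4096, 4096)
    K: int = 1000
    mean: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sd: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.channels) != len(self.convs_per_block):
            raise ValueError("channels and convs_per_block must have equal length")
        if any(c < 1 for c in self.channels) or any(n < 1 for n in self.convs_per_block):
            raise ValueError("channel widths and conv counts must be positive")
        if self.K < 1:
            raise ValueError("output dimension K must be >= 1")

    @property
    def depth(self) -> int:
        """Total number of convolutional layers."""
        return sum(self.convs_per_block)

    def to_dict(self) -> dict:
        return {
            "channels": list(self.channels),
            "convs_per_block": list(self.convs_per_block),
            "pool_side": self.pool_side,
            "hidden": list(self.hidden),
            "K": self.K,
            "mean": list(self.mean),
            "sd": list(self.sd),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BackboneConfig":
        return cls(
            channels=tuple(d["channels"]),
            convs_per_block=tuple(d["convs_per_block"]),
            pool_side=int(d["pool_side"]),
            hidden=tuple(d["hidden"]),
            K=int(d["K"]),
            mean=tuple(d["mean"]),
            sd=tuple(d["sd"]),
        )


DEFAULT_CONFIG = BackboneConfig()


def small_preset(K: int = 1) -> BackboneConfig:
    """Desk-scale preset: 3 blocks of one conv each, widths (8, 16, 32), pool side 4.

    Inputs are standardized around mid-gray (mean 0.5, sd 0.25 per channel):
    without pretrained weights there is no inherited normalization convention,
    and centering the input is what keeps from-scratch optimization of the
    small stack well conditioned.
    """
    return BackboneConfig(
        channels=(8, 16, 32), convs_per_block=(1, 1, 1), pool_side=4, hidden=(64,), K=K,
        mean=(0.5, 0.5, 0.5), sd=(0.25, 0.25, 0.25),
    )


class BackboneModel:
    """A concrete backbone: conv blocks → adaptive pooling → classifier."""

    def __init__(self, config: BackboneConfig, seed: int, weights: dict | None = None):
        self.config = config
        rng = np.random.default_rng(seed)
        self.conv_layers: list[Conv2d] = []
        self.block_sizes: list[int] = list(config.convs_per_block)
        in_ch = 3
        li = 0
        for width, n_convs in zip(config.channels, config.convs_per_block):
            for _ in range(n_convs):
                self.conv_layers.append(Conv2d(in_ch, width, rng, name=f"conv{li}"))
                in_ch = width
                li += 1
        self.classifier: list[Linear] = []
        widths = [in_ch * config.pool_side**2, *config.hidden, config.K]
        for fi, (a, b) in enumerate(zip(widths[:-1], widths[1:])):
            self.classifier.append(Linear(a, b, rng, name=f"fc{fi}"))
        self._rebuild_ops()
        if weights is not None:
            self.load_state_dict(weights)

    # -- structure ---------------------------------------------------------

    def _rebuild_ops(self) -> None:
        ops: list[_nn.Layer] = []
        i = 0
        for bsize in self.block_sizes:
            for _ in range(bsize):
                ops.append(self.conv_layers[i])
                ops.append(ReLU())
                i += 1
            ops.append(MaxPool2d())
        ops.append(AdaptiveAvgPool2d(self.config.pool_side))
        ops.append(Flatten())
        for lin in self.classifier[:-1]:
            ops.append(lin)
            ops.append(ReLU())
        ops.append(self.classifier[-1])
        self._ops = ops

    @property
    def depth(self) -> int:
        return len(self.conv_layers)

    @property
    def n_blocks(self) -> int:
        return len(self.block_sizes)

    @property
    def K(self) -> int:
        return self.classifier[-1].out_features

    def params(self) -> list[Param]:
        out: list[Param] = []
        for op in self._ops:
            out.extend(op.params())
        return out

    def n_parameters(self, trainable_only: bool = False) -> int:
        return sum(
            p.value.size for p in self.params() if p.trainable or not trainable_only
        )

    # -- weights -----------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.value for p in self.params()}

    def load_state_dict(self, weights: dict) -> None:
        own = {p.name: p for p in self.params()}
        bad = [
            name
            for name, arr in weights.items()
            if name in own and own[name].value.shape != np.shape(arr)
        ]
        if bad:
            detail = ", ".join(
                f"{n}: expected {own[n].value.shape}, got {np.shape(weights[n])}" for n in bad
            )
            raise WeightMismatchError(f"shape-incompatible weights for layers: {detail}")
        unknown = sorted(set(weights) - set(own))
        if unknown:
            raise WeightMismatchError(f"weights reference unknown parameters: {unknown}")
        for name, arr in weights.items():
            own[name].value = np.asarray(arr, dtype=np.float32).copy()

    # -- computation -------------------------------------------------------

    def preprocess(self, images: np.ndarray) -> np.ndarray:
        """uint8 NHWC (or HWC) RGB → standardized float32 NCHW."""
        if images.ndim == 3:
            images = images[None]
        x = images.astype(np.float32) / 255.0
        mean = np.asarray(self.config.mean, dtype=np.float32)
        sd = np.asarray(self.config.sd, dtype=np.float32)
        x = (x - mean) / sd
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for op in self._ops:
            x = op.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for op in reversed(self._ops):
            grad = op.backward(grad)

    def scores(self, images: np.ndarray) -> np.ndarray:
        """Raw classifier scores (logits) for uint8 RGB images."""
        return self.forward(self.preprocess(images))

    def pooled_features(self, images: np.ndarray) -> np.ndarray:
        """Post-adaptive-pooling feature maps (N, C, side, side) for uint8 images."""
        x = self.preprocess(images)
        for op in self._ops:
            x = op.forward(x)
            if isinstance(op, AdaptiveAvgPool2d):
                return x
        raise RuntimeError("model has no adaptive pooling stage")

    def feature_side(self, input_side: int) -> int:
        """Spatial side entering the classifier (constant by construction)."""
        return self.config.pool_side


def make_backbone(
    config: BackboneConfig, seed: int = 0, weights: dict | None = None
) -> BackboneModel:
    """Construct a backbone with seed-deterministic initialization.

    ``weights`` optionally injects externally trained parameters (e.g. a
    conversion of published VGG-16 weights); shapes are validated and a
    :class:`~ultracat.errors.WeightMismatchError` lists every offending
    layer.
    """
    return BackboneModel(config, seed, weights)


def replace_head(model: BackboneModel, K_new: int, seed: int = 0) -> BackboneModel:
    """Return a copy whose final classifier layer is re-instantiated with ``K_new`` outputs.

    Every parameter except the final layer is bit-identical to the input
    model's; typical use replaces a K=1000 label head with a K=1 detection
    head before transfer learning.
    """
    if K_new < 1:
        raise ValueError("K_new must be >= 1")
    new = copy.deepcopy(model)
    rng = np.random.default_rng(seed)
    last = new.classifier[-1]
    new.classifier[-1] = Linear(last.in_features, K_new, rng, name=last.W.name.rsplit(".", 1)[0])
    new.config = replace(new.config, K=K_new)
    new._rebuild_ops()
    return new


def prune_conv_layers(model: BackboneModel, n_removed: int, seed: int = 0) -> BackboneModel:
    """Return a copy with the ``n_removed`` deepest convolutional layers removed.

    Emptied blocks lose their pooling stage as well; adaptive pooling keeps
    the classifier's spatial input constant, so only the first fully
    connected layer is re-instantiated (to match the surviving channel
    width).  Surviving convolutional parameters are unchanged.
    ``n_removed = 0`` returns a copy that computes identical outputs.
    """
    if not 0 <= n_removed <= model.depth - 1:
        raise ValueError(
            f"n_removed must lie in [0, {model.depth - 1}], got {n_removed}"
        )
    new = copy.deepcopy(model)
    if n_removed == 0:
        return new
    keep = model.depth - n_removed
    new.conv_layers = new.conv_layers[:keep]
    sizes: list[int] = []
    remaining = keep
    for bsize in model.block_sizes:
        take = min(bsize, remaining)
        if take > 0:
            sizes.append(take)
        remaining -= take
    new.block_sizes = sizes
    surviving_width = new.conv_layers[-1].out_channels
    rng = np.random.default_rng(seed)
    first = new.classifier[0]
    new.classifier[0] = Linear(
        surviving_width * new.config.pool_side**2,
        first.out_features,
        rng,
        name=first.W.name.rsplit(".", 1)[0],
    )
    new.config = replace(
        new.config,
        channels=tuple(model.config.channels[: len(sizes)]),
        convs_per_block=tuple(sizes),
    )
    new._rebuild_ops()
    return new


def set_trainable(model: BackboneModel, policy: str) -> BackboneModel:
    """Set per-parameter trainability in place: ``head_only`` | ``all`` | ``none``.

    ``head_only`` marks exactly the final classifier layer trainable — the
    transfer-learning regime where pre-trained features are frozen.
    """
    if policy not in ("head_only", "all", "none"):
        raise ValueError(f"unknown trainability policy {policy!r}")
    head = {id(p) for p in model.classifier[-1].params()}
    for p in model.params():
        if policy == "all":
            p.trainable = True
        elif policy == "none":
            p.trainable = False
        else:
            p.trainable = id(p) in head
    return model


def save_checkpoint(model: BackboneModel, path) -> None:
    """Serialize weights (npz) with an embedded JSON architecture config."""
    arrays = {k.replace(".", "__"): v for k, v in model.state_dict().items()}
    arrays["__config__"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode("utf-8"), dtype=np.uint8
    )
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> BackboneModel:
    with np.load(path) as data:
        config = BackboneConfig.from_dict(
            json.loads(bytes(data["__config__"]).decode("utf-8"))
        )
        weights = {
            k.replace("__", "."): data[k] for k in data.files if k != "__config__"
        }
    return BackboneModel(config, seed=0, weights=weights)


def parameter_checksum(model: BackboneModel, exclude: tuple[str, ...] = ()) -> str:
    """Hex digest over parameter bytes, for bit-identity assertions."""
    import hashlib

    h = hashlib.sha256()
    for p in sorted(model.params(), key=lambda p: p.name):
        if p.name.rsplit(".", 1)[0] in exclude:
            continue
        h.update(p.name.encode())
        h.update(np.ascontiguousarray(p.value).tobytes())
    return h.hexdigest()
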