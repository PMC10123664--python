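"""The five (re-)training protocols, augmentation policies, and sweeps.

Protocols (weight origin, trainability, augmentation):

* **SLS**  — Supervised Learning from Scratch: random weights, all layers
  trainable, no augmentation.
* **TLC**  — Transfer Learning on Classification layers: pretrained
  backbone, only the final classifier layer trainable, no augmentation.
* **TLA**  — Transfer Learning on All layers: pretrained, all trainable,
  no augmentation.
* **TLDA** — TLC plus a custom augmentation pipeline: random horizontal
  flip (p = 0.5), random vertical flip (p = 0.5), a random rotation (p = 1,
  uniform in ±180°), random grayscale (p = 0.5), applied in that order.
* **TLAA** — TLC plus an auto-augmentation policy: one of a fixed catalogue
  of 16 randomly parameterized affine/photometric operations per call.

Training minimizes sigmoid-linked binary cross-entropy (target = 1,
distractor = 0) with momentum SGD over shuffled mini-batches; defaults are
batch size 8, learning rate 5e-5, momentum 0.99, 25 epochs, threshold 0.5.
Validation accuracy is computed each epoch and the best-epoch weights are
retained.  "Pretrained" weight origins are supplied by the caller — either
injected published weights or, for the synthetic pipeline,
:func:`pretrain_leaf_classifier`, which trains the backbone as a K-leaf
multiclass classifier (a desk-scale analogue of large-database
pretraining).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._nn import SGD, bce_with_logits, softmax_cross_entropy
from .datasets import DatasetSplits, ImageSource
from .errors import CapacityError
from .evaluation import HeadScorer, evaluate, accuracy
from .models import BackboneModel, set_trainable

__all__ = [
    "Protocol",
    "PROTOCOLS",
    "Hyperparams",
    "TrainResult",
    "augment",
    "train",
    "sweep",
    "pretrain_leaf_classifier",
    "save_run_config",
]


@dataclass(frozen=True)
class Protocol:
    name: str
    weight_origin: str  # "random" | "pretrained"
    trainability: str  # "all" | "head_only"
    augmentation: str  # "none" | "custom" | "auto"


PROTOCOLS: dict[str, Protocol] = {
    "SLS": Protocol("SLS", "random", "all", "none"),
    "TLC": Protocol("TLC", "pretrained", "head_only", "none"),
    "TLA": Protocol("TLA", "pretrained", "all", "none"),
    "TLDA": Protocol("TLDA", "pretrained", "head_only", "custom"),
    "TLAA": Protocol("TLAA", "pretrained", "head_only", "auto"),
}


@dataclass(frozen=True)
class Hyperparams:
    batch_size: int = 8
    learning_rate: float = 5e-5
    momentum: float = 0.99
    epochs: int = 25
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")

    def with_(self, **kwargs) -> "Hyperparams":
        return replace(self, **kwargs)


@dataclass
class TrainResult:
    model: BackboneModel
    train_loss: list[float]
    val_accuracy: list[float]
    best_accuracy: float
    best_epoch: int
    config: dict = field(default_factory=dict)

    @property
    def history(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "loss": self.train_loss,
                "val_accuracy": self.val_accuracy,
            }
        )


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def _rotate(image: np.ndarray, angle: float) -> np.ndarray:
    from .transforms import TransformSpec, apply_transform

    return apply_transform(image, TransformSpec(kind="rotation", angle=float(angle)))


def _grayscale(image: np.ndarray) -> np.ndarray:
    from .transforms import TransformSpec, apply_transform

    return apply_transform(image, TransformSpec(kind="grayscale"))


def _affine(image: np.ndarray, matrix: np.ndarray, offset: np.ndarray) -> np.ndarray:
    from scipy.ndimage import affine_transform

    out = np.empty_like(image)
    for c in range(image.shape[2]):
        out[:, :, c] = affine_transform(
            image[:, :, c], matrix, offset=offset, order=1, mode="constant", cval=0
        )
    return out


def _centered_affine(image: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    c = (np.array(image.shape[:2], dtype=float) - 1) / 2.0
    return _affine(image, matrix, c - matrix @ c)


def _blend(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    return np.clip(a.astype(np.float32) * (1 - t) + b.astype(np.float32) * t, 0, 255).astype(
        np.uint8
    )


def _auto_ops() -> list[Callable[[np.ndarray, float, np.random.Generator], np.ndarray]]:
    """The fixed 16-operation auto-augment catalogue.

    Each operation takes (image, magnitude in [0, 1], rng); geometric ops use
    bilinear resampling with black fill.
    """

    def rot(img, m, rng):
        return _rotate(img, rng.choice((-1, 1)) * m * 135.0)

    def shear_x(img, m, rng):
        s = rng.choice((-1, 1)) * m * 0.3
        return _centered_affine(img, np.array([[1.0, 0.0], [s, 1.0]]))

    def shear_y(img, m, rng):
        s = rng.choice((-1, 1)) * m * 0.3
        return _centered_affine(img, np.array([[1.0, s], [0.0, 1.0]]))

    def trans_x(img, m, rng):
        d = rng.choice((-1, 1)) * m * 0.25 * img.shape[1]
        return _affine(img, np.eye(2), np.array([0.0, -d]))

    def trans_y(img, m, rng):
        d = rng.choice((-1, 1)) * m * 0.25 * img.shape[0]
        return _affine(img, np.eye(2), np.array([-d, 0.0]))

    def scale(img, m, rng):
        f = 1.0 + rng.choice((-1, 1)) * m * 0.3
        return _centered_affine(img, np.eye(2) / f)

    def hflip(img, m, rng):
        return np.flip(img, axis=1).copy()

    def vflip(img, m, rng):
        return np.flip(img, axis=0).copy()

    def contrast(img, m, rng):
        f = 1.0 + rng.choice((-1, 1)) * m * 0.8
        mean = img.mean()
        return np.clip((img.astype(np.float32) - mean) * f + mean, 0, 255).astype(np.uint8)

    def brightness(img, m, rng):
        return np.clip(
            img.astype(np.float32) + rng.choice((-1, 1)) * m * 80.0, 0, 255
        ).astype(np.uint8)

    def sharpness(img, m, rng):
        from scipy.ndimage import gaussian_filter

        blurred = gaussian_filter(img.astype(np.float32), sigma=(1.0, 1.0, 0.0))
        return _blend(blurred.astype(np.uint8), img, 1.0 + m)  # t>1 extrapolates: sharpen

    def posterize(img, m, rng):
        bits = max(1, 8 - int(m * 5))
        shift = 8 - bits
        return ((img >> shift) << shift).astype(np.uint8)

    def solarize(img, m, rng):
        threshold = 255 - int(m * 200)
        out = img.copy()
        out[img >= threshold] = 255 - img[img >= threshold]
        return out

    def gray(img, m, rng):
        return _grayscale(img)

    def cutout(img, m, rng):
        side = max(1, int(m * 0.4 * min(img.shape[:2])))
        y = int(rng.integers(0, img.shape[0] - side + 1))
        x = int(rng.integers(0, img.shape[1] - side + 1))
        out = img.copy()
        out[y : y + side, x : x + side] = 0
        return out

    def identity(img, m, rng):
        return img.copy()

    return [
        identity, rot, shear_x, shear_y, trans_x, trans_y, scale, hflip, vflip,
        contrast, brightness, sharpness, posterize, solarize, gray, cutout,
    ]


AUTO_CATALOGUE = _auto_ops()
assert len(AUTO_CATALOGUE) == 16


def custom_draws(rng: np.random.Generator) -> tuple[bool, bool, float, bool]:
    """One draw of the custom policy: (hflip p=.5, vflip p=.5, angle ±180°, grayscale p=.5)."""
    return (
        bool(rng.random() < 0.5),
        bool(rng.random() < 0.5),
        float(rng.uniform(-180.0, 180.0)),
        bool(rng.random() < 0.5),
    )


def augment(image: np.ndarray, policy: str, seed) -> np.ndarray:
    """Apply one augmentation draw to a uint8 RGB image, deterministic under seed.

    ``none`` is the identity; ``custom`` applies horizontal flip (p = 0.5),
    vertical flip (p = 0.5), rotation (always, uniform in ±180°), grayscale
    (p = 0.5) in that order; ``auto`` samples one of the 16 catalogued
    operations with a random magnitude.
    """
    if policy == "none":
        return image.copy()
    rng = np.random.default_rng(seed)
    if policy == "custom":
        hflip, vflip, angle, gray = custom_draws(rng)
        out = image
        if hflip:
            out = np.flip(out, axis=1)
        if vflip:
            out = np.flip(out, axis=0)
        out = _rotate(np.ascontiguousarray(out), angle)
        if gray:
            out = _grayscale(out)
        return np.ascontiguousarray(out)
    if policy == "auto":
        op = AUTO_CATALOGUE[int(rng.integers(len(AUTO_CATALOGUE)))]
        return op(image, float(rng.random()), rng)
    raise ValueError(f"unknown augmentation policy {policy!r}")


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _epoch_image_seed(base_seed: int, epoch: int, image_id: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([base_seed, epoch, zlib.crc32(image_id.encode())])


def train(
    model: BackboneModel,
    splits: DatasetSplits,
    protocol: Protocol,
    hp: Hyperparams | None = None,
) -> TrainResult:
    """(Re-)train a K=1 detection head under one protocol.

    The model is modified in place (trainability set per protocol, weights
    updated, best-epoch weights restored at the end) and returned inside the
    :class:`TrainResult`.  Frozen parameters are untouched bit for bit.
    """
    hp = hp or Hyperparams()
    if model.K != 1:
        raise ValueError(f"training expects a K=1 detection head, got K={model.K}")
    refs = splits.split_refs("train")
    if not refs or not splits.split_refs("val"):
        raise CapacityError("train and val splits must be non-empty")

    set_trainable(model, protocol.trainability)
    opt = SGD(model.params(), lr=hp.learning_rate, momentum=hp.momentum)
    rng = np.random.default_rng(hp.seed)
    scorer = HeadScorer(model)

    losses: list[float] = []
    val_accs: list[float] = []
    best_acc, best_epoch = -1.0, -1
    best_state: dict[str, np.ndarray] = {}

    for epoch in range(hp.epochs):
        order = rng.permutation(len(refs))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), hp.batch_size):
            batch_idx = order[start : start + hp.batch_size]
            images, ys = [], []
            for bi in batch_idx:
                image_id, ref, truth = refs[bi]
                img = splits.source.get(ref.label, ref.index)
                img = augment(img, protocol.augmentation, _epoch_image_seed(hp.seed, epoch, image_id))
                images.append(img)
                ys.append(truth)
            x = model.preprocess(np.stack(images))
            y = np.asarray(ys, dtype=np.float64)
            logits = model.forward(x, train=True)[:, 0]
            loss, dlogits = bce_with_logits(logits, y)
            opt.zero_grad()
            model.backward(dlogits[:, None].astype(np.float32))
            opt.step()
            epoch_loss += loss
            n_batches += 1
        losses.append(epoch_loss / n_batches)
        _, counts = evaluate(scorer, splits, split="val", threshold=hp.threshold)
        acc = accuracy(counts)
        val_accs.append(acc)
        if acc > best_acc:
            best_acc, best_epoch = acc, epoch
            best_state = {
                p.name: p.value.copy() for p in model.params() if p.trainable
            }

    for p in model.params():  # restore best-epoch weights (trainable only; rest never moved)
        if p.name in best_state:
            p.value = best_state[p.name]

    return TrainResult(
        model=model,
        train_loss=losses,
        val_accuracy=val_accs,
        best_accuracy=best_acc,
        best_epoch=best_epoch,
        config={
            "protocol": protocol.name,
            "task_synset": splits.task_synset,
            "hyperparams": {
                "batch_size": hp.batch_size,
                "learning_rate": hp.learning_rate,
                "momentum": hp.momentum,
                "epochs": hp.epochs,
                "threshold": hp.threshold,
                "seed": hp.seed,
            },
        },
    )


def pretrain_leaf_classifier(
    model: BackboneModel,
    source: ImageSource,
    images_per_label: int,
    hp: Hyperparams | None = None,
    augmentation: str = "none",
) -> BackboneModel:
    """Train a K-way leaf classifier — the synthetic analogue of database pretraining.

    ``model`` must output one score per leaf label of ``source``; it is
    trained in place with softmax cross-entropy on ``images_per_label``
    renders per leaf and returned.  The result serves as the "pretrained"
    weight origin for the transfer-learning protocols.  An augmentation
    policy may be applied during pretraining (leaf identity is a
    characteristic spatial scale, so the multiclass task stays well posed
    under flips and rotations).
    """
    hp = hp or Hyperparams()
    labels = source.labels
    if model.K != len(labels):
        raise ValueError(f"model outputs {model.K} classes for {len(labels)} leaf labels")
    pairs = [(label, i) for label in labels for i in range(images_per_label)]
    set_trainable(model, "all")
    opt = SGD(model.params(), lr=hp.learning_rate, momentum=hp.momentum)
    rng = np.random.default_rng(hp.seed)
    index = {l: i for i, l in enumerate(labels)}
    for epoch in range(hp.epochs):
        # step decay stabilizes from-scratch training of the feature stack
        frac = epoch / max(hp.epochs, 1)
        opt.lr = hp.learning_rate * (0.25 if 0.6 <= frac < 0.85 else 0.0625 if frac >= 0.85 else 1.0)
        order = rng.permutation(len(pairs))
        for start in range(0, len(order), hp.batch_size):
            batch = [pairs[i] for i in order[start : start + hp.batch_size]]
            images = [
                augment(
                    source.get(l, i), augmentation,
                    _epoch_image_seed(hp.seed, epoch, f"{l}/{i}"),
                )
                for l, i in batch
            ]
            x = model.preprocess(np.stack(images))
            y = np.array([index[l] for l, _ in batch])
            logits = model.forward(x, train=True)
            _, dlogits = softmax_cross_entropy(logits, y)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
    return model


def sweep(
    model_factory: Callable[[], BackboneModel],
    splits: DatasetSplits,
    protocol: Protocol,
    grid: Mapping[str, Sequence],
    hp_defaults: Hyperparams | None = None,
) -> tuple[Hyperparams, pd.DataFrame]:
    """One-at-a-time hyperparameter sweep (not a full factorial).

    For each parameter in ``grid``, every listed value is trained with the
    other parameters at their defaults; the table reports the best-epoch
    validation accuracy per setting and the returned ``Hyperparams`` carries
    the per-parameter argmax values.
    """
    hp_defaults = hp_defaults or Hyperparams()
    rows = []
    best_values: dict[str, object] = {}
    for param, values in grid.items():
        if len(values) == 0:
            raise ValueError(f"empty value list for parameter {param!r}")
        accs = []
        for value in values:
            hp = hp_defaults.with_(**{param: value})
            result = train(model_factory(), splits, protocol, hp)
            accs.append(result.best_accuracy)
            rows.append({"parameter": param, "value": value, "val_accuracy": result.best_accuracy})
        best_values[param] = values[int(np.argmax(accs))]
    return hp_defaults.with_(**best_values), pd.DataFrame(rows)


def save_run_config(path, **sections) -> None:
    """Write a YAML run-configuration snapshot (protocol, hyperparams, paths, seeds)."""
    import yaml

    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(sections, fh, sort_keys=True)
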