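"""Deterministic image transformations and robustness sweep harnesses.

Transformations: center rotation (−180°..180°, black fill outside the
frame; exact multiples of 90° use lossless grid rotation so cardinal-angle
evaluations are interpolation-free), horizontal/vertical mirror, grayscale
(luminance replicated over channels), and patch shuffle (partition into an
s×s-pixel grid, apply a uniformly random patch permutation — structure
above scale s is destroyed, local statistics survive).

Sweeps score a trained model on the test split under a family of
transformations: accuracy versus rotation angle, and accuracy versus patch
size averaged over shuffle seeds.  ``timed_predict`` additionally reports
wall-clock seconds per prediction; those timings are hardware-dependent and
are reported, never asserted.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .datasets import DatasetSplits
from .evaluation import HeadScorer, accuracy, evaluate

__all__ = [
    "TransformSpec",
    "apply_transform",
    "SweepResult",
    "rotation_sweep",
    "shuffle_sweep",
    "timed_predict",
    "DEFAULT_ANGLES",
    "default_patch_sizes",
]

KINDS = ("rotation", "hflip", "vflip", "grayscale", "patch_shuffle", "identity")

#: default rotation grid; always includes the cardinal angles
DEFAULT_ANGLES = (-180, -135, -90, -45, 0, 45, 90, 135, 180)


def default_patch_sizes(side: int = 256) -> tuple[int, ...]:
    """Patch-size axis {side, side/2, ..., side/32} for the shuffle battery."""
    return tuple(side // f for f in (1, 2, 4, 8, 16, 32))


@dataclass(frozen=True)
class TransformSpec:
    kind: str = "identity"
    angle: float = 0.0
    patch: int | None = None
    seed: int = 0
    interpolation: str = "bilinear"  # or "nearest"
    fill: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind == "rotation" and not -180.0 <= self.angle <= 180.0:
            raise ValueError("rotation angle must lie in [-180, 180]")
        if self.kind == "patch_shuffle" and (self.patch is None or self.patch < 1):
            raise ValueError("patch_shuffle needs a positive patch side")


def _rotate(image: np.ndarray, spec: TransformSpec) -> np.ndarray:
    angle = float(spec.angle) % 360.0
    if angle % 90.0 == 0.0:
        return np.ascontiguousarray(np.rot90(image, k=int(angle // 90), axes=(0, 1)))
    order = 1 if spec.interpolation == "bilinear" else 0
    return ndimage.rotate(
        image,
        angle,
        axes=(1, 0),  # counterclockwise in (row, col) display coordinates
        reshape=False,
        order=order,
        mode="constant",
        cval=spec.fill,
    ).astype(image.dtype)


def _patch_shuffle(image: np.ndarray, spec: TransformSpec) -> np.ndarray:
    side = image.shape[0]
    s = int(spec.patch)
    if image.shape[1] != side or side % s != 0:
        raise ValueError(f"patch side {s} must divide the image side {side}")
    g = side // s
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(g * g)
    patches = (
        image.reshape(g, s, g, s, -1).transpose(0, 2, 1, 3, 4).reshape(g * g, s, s, -1)
    )
    shuffled = patches[perm]
    return np.ascontiguousarray(
        shuffled.reshape(g, g, s, s, -1).transpose(0, 2, 1, 3, 4).reshape(image.shape)
    )


def apply_transform(image: np.ndarray, spec: TransformSpec) -> np.ndarray:
    """Apply one deterministic transformation to a uint8 RGB (H, W, 3) image."""
    if spec.kind == "identity":
        return image.copy()
    if spec.kind == "rotation":
        return _rotate(image, spec)
    if spec.kind == "hflip":
        return np.ascontiguousarray(np.flip(image, axis=1))
    if spec.kind == "vflip":
        return np.ascontiguousarray(np.flip(image, axis=0))
    if spec.kind == "grayscale":
        lum = (
            0.299 * image[:, :, 0].astype(np.float64)
            + 0.587 * image[:, :, 1].astype(np.float64)
            + 0.114 * image[:, :, 2].astype(np.float64)
        )
        lum = np.clip(np.round(lum), 0, 255).astype(np.uint8)
        return np.repeat(lum[:, :, None], 3, axis=2)
    if spec.kind == "patch_shuffle":
        return _patch_shuffle(image, spec)
    raise ValueError(f"unknown transform kind {spec.kind!r}")


@dataclass
class SweepResult:
    """Per-condition accuracies with mean ± sd across replicates."""

    condition_name: str
    conditions: list
    accuracies: np.ndarray = field(repr=False)  # (n_conditions, n_replicates)

    @property
    def mean(self) -> np.ndarray:
        return self.accuracies.mean(axis=1)

    @property
    def sd(self) -> np.ndarray:
        return self.accuracies.std(axis=1)

    @property
    def n(self) -> int:
        return self.accuracies.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.condition_name: self.conditions,
                "accuracy": self.mean,
                "sd": self.sd,
                "n": self.n,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.to_frame().to_json(path, orient="records", indent=2)


def _as_scorers(model_or_scorers) -> list[Callable[[np.ndarray], np.ndarray]]:
    from .models import BackboneModel

    if isinstance(model_or_scorers, BackboneModel):
        return [HeadScorer(model_or_scorers)]
    if callable(model_or_scorers):
        return [model_or_scorers]
    return [
        HeadScorer(m) if isinstance(m, BackboneModel) else m for m in model_or_scorers
    ]


def rotation_sweep(
    model,
    splits: DatasetSplits,
    angles: Sequence[float] = DEFAULT_ANGLES,
    split: str = "test",
    threshold: float = 0.5,
) -> SweepResult:
    """Test-set accuracy as a function of rotation angle.

    ``model`` may be a trained backbone, a scorer, or a list of either
    (replicates for the mean ± sd columns).
    """
    angles = list(angles)
    if not angles:
        raise ValueError("angle list must be non-empty")
    scorers = _as_scorers(model)
    acc = np.empty((len(angles), len(scorers)))
    for ai, angle in enumerate(angles):
        spec = TransformSpec(kind="rotation", angle=angle)
        for si, scorer in enumerate(scorers):
            _, counts = evaluate(
                scorer, splits, split=split, threshold=threshold,
                transform=lambda img, s=spec: apply_transform(img, s),
            )
            acc[ai, si] = accuracy(counts)
    return SweepResult("angle_deg", angles, acc)


def shuffle_sweep(
    model,
    splits: DatasetSplits,
    patch_sizes: Sequence[int] | None = None,
    n_reps: int = 3,
    seed: int = 0,
    split: str = "test",
    threshold: float = 0.5,
) -> SweepResult:
    """Test-set accuracy as a function of shuffled patch size.

    Each replicate uses fresh per-image permutation seeds; full-size patches
    are the identity, so that column reproduces the untransformed accuracy.
    """
    side = next(splits.iter_images(split))[1].shape[0]
    sizes = list(patch_sizes) if patch_sizes is not None else list(default_patch_sizes(side))
    for s in sizes:
        if side % s != 0:
            raise ValueError(f"patch size {s} does not divide the image side {side}")
    scorers = _as_scorers(model)
    if len(scorers) != 1:
        raise ValueError("shuffle_sweep replicates over permutation seeds; pass one scorer")
    scorer = scorers[0]
    acc = np.empty((len(sizes), n_reps))
    for si, s in enumerate(sizes):
        for rep in range(n_reps):
            counter = {"i": 0}

            def tf(img, s=s, rep=rep, counter=counter):
                counter["i"] += 1
                return apply_transform(
                    img,
                    TransformSpec(
                        kind="patch_shuffle", patch=s, seed=seed * 1_000_003 + rep * 9973 + counter["i"]
                    ),
                )

            _, counts = evaluate(scorer, splits, split=split, threshold=threshold, transform=tf)
            acc[si, rep] = accuracy(counts)
    return SweepResult("patch_size", sizes, acc)


def timed_predict(
    model, images: np.ndarray, threshold: float = 0.5
) -> tuple[np.ndarray, float, float]:
    """Per-image wall-clock prediction timing.

    Returns (decisions, mean seconds per image, sd).  Timings depend on the
    host; only qualitative orderings (shallower ⇒ faster) are meaningful.
    """
    if len(images) == 0:
        raise ValueError("empty image batch")
    scorer = _as_scorers(model)[0]
    decisions = np.empty(len(images), dtype=int)
    times = np.empty(len(images))
    for i, img in enumerate(images):
        t0 = time.perf_counter()
        score = scorer(img[None])[0]
        times[i] = time.perf_counter() - t0
        decisions[i] = int(score > threshold)
    return decisions, float(times.mean()), float(times.std())
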