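"""Balanced target/distractor dataset construction from a hyperonym task.

Given an image source, a hierarchy and a task synset, the builder draws
balanced train/validation/test splits: targets are images whose leaf label
is a descendant of the task synset, distractors are images whose label is
not.  Sampling is two-stage (label uniform from the pool, then an unused
image uniform within that label) so that large classes cannot dominate, and
images are disjoint across splits.  The whole construction is a pure
function of (source, graph, synset, config): one seed, one manifest.

Variants: the 'random' control task splits a random label subset into
pseudo-target/pseudo-distractor halves, and the "strict" task additionally
bans descendants of a second synset from the distractor pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Protocol, Sequence

import numpy as np
import pandas as pd

from .errors import CapacityError, TaskUndefinedError
from .hierarchy import SynsetGraph, descendant_labels

__all__ = [
    "ImageSource",
    "BuildConfig",
    "ImageRef",
    "DatasetSplits",
    "build_dataset",
    "build_random_task",
    "build_strict_dataset",
    "write_images",
]

SPLIT_NAMES = ("train", "val", "test")


class ImageSource(Protocol):
    """Anything mapping leaf labels to addressable 256-ish RGB images."""

    @property
    def labels(self) -> tuple[str, ...]: ...

    def count(self, label: str) -> int: ...

    def get(self, label: str, index: int) -> np.ndarray: ...


@dataclass(frozen=True)
class BuildConfig:
    """Split sizes (total images per split), seed, and pool restrictions.

    Default sizes are train 2000, validation 800, test 1200 images; each
    split is an exact half-and-half of targets and distractors, so sizes
    must be even and at least 2.
    """

    train: int = 2000
    val: int = 800
    test: int = 1200
    seed: int = 0
    #: labels never used as targets (e.g. human-depicting classes)
    exclude_target_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name, size in self.sizes.items():
            if size < 2:
                raise ValueError(f"{name} split must hold at least 2 images")
            if size % 2:
                raise ValueError(f"{name} split size {size} is odd; halves must balance")

    @property
    def sizes(self) -> dict[str, int]:
        return {"train": self.train, "val": self.val, "test": self.test}

    def with_(self, **kwargs) -> "BuildConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ImageRef:
    """Address of one image in a source."""

    label: str
    index: int


@dataclass
class DatasetSplits:
    """Balanced target/distractor splits plus their provenance manifest."""

    task_synset: str | None
    seed: int
    source: ImageSource
    targets: dict[str, list[ImageRef]]
    distractors: dict[str, list[ImageRef]]
    target_pool: tuple[str, ...]
    distractor_pool: tuple[str, ...]
    manifest: pd.DataFrame = field(repr=False)

    def split_refs(self, split: str) -> list[tuple[str, ImageRef, int]]:
        """(image_id, ref, truth) triplets for one split; truth 1 = target."""
        out = []
        for cls, refs, truth in (
            ("target", self.targets[split], 1),
            ("distractor", self.distractors[split], 0),
        ):
            for i, ref in enumerate(refs):
                out.append((f"{split}/{cls}/{i:05d}.png", ref, truth))
        return out

    def iter_images(self, split: str) -> Iterator[tuple[str, np.ndarray, int]]:
        for image_id, ref, truth in self.split_refs(split):
            yield image_id, self.source.get(ref.label, ref.index), truth


def _build_manifest(
    splits_targets: dict[str, list[ImageRef]],
    splits_distractors: dict[str, list[ImageRef]],
    task_synset: str | None,
    seed: int,
) -> pd.DataFrame:
    rows = []
    for split in SPLIT_NAMES:
        for cls, refs in (("target", splits_targets[split]), ("distractor", splits_distractors[split])):
            for i, ref in enumerate(refs):
                rows.append(
                    {
                        "path": f"{split}/{cls}/{i:05d}.png",
                        "split": split,
                        "class": cls,
                        "leaf_label": ref.label,
                        "image_index": ref.index,
                        "task_synset": task_synset if task_synset is not None else "random",
                        "seed": seed,
                    }
                )
    return pd.DataFrame(rows)


def _sample_splits(
    source: ImageSource,
    target_pool: Sequence[str],
    distractor_pool: Sequence[str],
    config: BuildConfig,
    task_synset: str | None,
) -> DatasetSplits:
    rng = np.random.default_rng(config.seed)
    # per-label queue of unused image indices in a random order; popping from
    # it realizes uniform-without-replacement draws and guarantees that the
    # three splits are disjoint at the image level
    queues: dict[str, list[int]] = {}
    targets: dict[str, list[ImageRef]] = {s: [] for s in SPLIT_NAMES}
    distractors: dict[str, list[ImageRef]] = {s: [] for s in SPLIT_NAMES}

    def queue(label: str) -> list[int]:
        if label not in queues:
            order = rng.permutation(source.count(label)).tolist()
            queues[label] = order
        return queues[label]

    def draw(pool: Sequence[str], n: int, split: str, cls: str) -> list[ImageRef]:
        refs = []
        for _ in range(n):
            open_labels = [l for l in pool if queue(l)]
            if not open_labels:
                raise CapacityError(
                    f"source exhausted while drawing {cls}s for the {split} split: "
                    f"{n - len(refs)} more image(s) needed from pool {sorted(pool)}"
                )
            label = open_labels[int(rng.integers(len(open_labels)))]
            refs.append(ImageRef(label, queues[label].pop()))
        return refs

    for split in SPLIT_NAMES:
        half = config.sizes[split] // 2
        targets[split] = draw(target_pool, half, split, "target")
        distractors[split] = draw(distractor_pool, half, split, "distractor")

    manifest = _build_manifest(targets, distractors, task_synset, config.seed)
    return DatasetSplits(
        task_synset=task_synset,
        seed=config.seed,
        source=source,
        targets=targets,
        distractors=distractors,
        target_pool=tuple(sorted(target_pool)),
        distractor_pool=tuple(sorted(distractor_pool)),
        manifest=manifest,
    )


def _task_pools(
    graph: SynsetGraph, synset: str, config: BuildConfig
) -> tuple[list[str], list[str]]:
    desc = descendant_labels(graph, synset)
    excluded = set(config.exclude_target_labels)
    target_pool = sorted(l for l in graph.leaf_labels if l in desc and l not in excluded)
    distractor_pool = sorted(l for l in graph.leaf_labels if l not in desc)
    return target_pool, distractor_pool


def build_dataset(
    source: ImageSource, graph: SynsetGraph, synset: str, config: BuildConfig | None = None
) -> DatasetSplits:
    """Build balanced splits for the detection task "does the image contain ``synset``?".

    Targets are drawn from leaves that are descendants of ``synset``,
    distractors from the remaining leaves.  Raises
    :class:`~ultracat.errors.TaskUndefinedError` when either pool is empty
    and :class:`~ultracat.errors.CapacityError` when the source cannot
    supply the configured split sizes without reuse.
    """
    config = config or BuildConfig()
    target_pool, distractor_pool = _task_pools(graph, synset, config)
    if not target_pool:
        raise TaskUndefinedError(f"no leaf label is a descendant of {synset!r}")
    if not distractor_pool:
        raise TaskUndefinedError(f"every leaf label is a descendant of {synset!r}")
    return _sample_splits(source, target_pool, distractor_pool, config, synset)


def build_random_task(
    source: ImageSource,
    graph: SynsetGraph,
    n_labels: int = 500,
    config: BuildConfig | None = None,
) -> DatasetSplits:
    """Build the 'random' control task.

    ``n_labels`` leaves (default 500) are drawn uniformly without
    replacement and split half/half into pseudo-target and pseudo-distractor
    label sets; splits are then built exactly as for a synset task.  On an
    image source where labels are independent of pixels, no classifier can
    beat chance on this task.
    """
    config = config or BuildConfig()
    if n_labels % 2:
        raise ValueError("n_labels must be even to split into two halves")
    if n_labels > graph.n_labels:
        raise CapacityError(
            f"requested {n_labels} labels but the hierarchy has only {graph.n_labels} leaves"
        )
    rng = np.random.default_rng(config.seed)
    chosen = rng.choice(graph.n_labels, size=n_labels, replace=False)
    labels = [graph.leaf_labels[i] for i in chosen]
    half = n_labels // 2
    return _sample_splits(source, sorted(labels[:half]), sorted(labels[half:]), config, None)


def build_strict_dataset(
    source: ImageSource,
    graph: SynsetGraph,
    synset: str,
    excluded: str,
    config: BuildConfig | None = None,
) -> DatasetSplits:
    """Build a "strictly ``synset``" dataset.

    As :func:`build_dataset`, except distractor labels are drawn only from
    leaves that are descendants of *neither* ``synset`` nor ``excluded`` —
    e.g. a strictly-animal task whose distractors are not artifacts either.
    """
    config = config or BuildConfig()
    target_pool, distractor_pool = _task_pools(graph, synset, config)
    banned = descendant_labels(graph, excluded)
    strict_pool = sorted(l for l in distractor_pool if l not in banned)
    if not target_pool:
        raise TaskUndefinedError(f"no leaf label is a descendant of {synset!r}")
    if not strict_pool:
        raise TaskUndefinedError(
            f"no distractor label remains after excluding descendants of {excluded!r}"
        )
    return _sample_splits(source, target_pool, strict_pool, config, synset)


def write_images(splits: DatasetSplits, root) -> Path:
    """Materialize the splits as ``<root>/<split>/<class>/<n>.png`` plus a CSV manifest."""
    from PIL import Image

    root = Path(root)
    for split in SPLIT_NAMES:
        for image_id, image, _truth in splits.iter_images(split):
            path = root / image_id
            path.parent.mkdir(parents=True, exist_ok=True)
            Image.fromarray(image).save(path)
    splits.manifest.to_csv(root / "manifest.csv", index=False)
    return root
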