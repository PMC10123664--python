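"""Accuracy accounting, cross-task bias matrices, and responder agreement.

Accuracy is the plain confusion ratio (TP + TN) / (TP + TN + FP + FN) on a
balanced target/distractor test set, with decisions made by thresholding a
score in [0, 1] at 0.5 (strictly greater → target).  Two scorers are
supported: a K=1 detection head read through a sigmoid, and a look-up-table
scorer that sums a K-way classifier's post-softmax leaf probabilities over
a synset's descendants.

``cross_task_matrix`` evaluates detectors across tasks.  When a model's
trained synset differs from the dataset's task synset, its detection of its
own category is used to predict the *absence* of the foreign category
(decision negated): in natural image collections the two superordinate
categories are anti-correlated within single images, so "no animal
detected" is evidence for "artifact present".  That composition bias — and
its collapse on "strictly" datasets whose distractors carry neither
category — is exactly what the matrix is built to expose.

``agreement`` compares two responders (two models, or a model and pooled
human responses) frame by frame: the fraction of images on which their
*correctness* coincides, with the four-way outcome taxonomy
(both correct / only A / only B / both wrong).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from ._nn import sigmoid, softmax
from .datasets import DatasetSplits
from .errors import AlignmentError, UndefinedMetricError
from .hierarchy import SynsetGraph, descendant_labels
from .lut import lut_probability

__all__ = [
    "ConfusionCounts",
    "accuracy",
    "HeadScorer",
    "LutScorer",
    "evaluate",
    "TaskModel",
    "TaskDataset",
    "cross_task_matrix",
    "agreement",
    "records_to_csv",
    "records_from_csv",
]


@dataclass(frozen=True)
class ConfusionCounts:
    true_positive: int = 0
    true_negative: int = 0
    false_positive: int = 0
    false_negative: int = 0

    @property
    def total(self) -> int:
        return (
            self.true_positive + self.true_negative + self.false_positive + self.false_negative
        )

    @classmethod
    def from_records(cls, records: pd.DataFrame) -> "ConfusionCounts":
        t = records["truth"].to_numpy()
        d = records["decision"].to_numpy()
        return cls(
            true_positive=int(((t == 1) & (d == 1)).sum()),
            true_negative=int(((t == 0) & (d == 0)).sum()),
            false_positive=int(((t == 0) & (d == 1)).sum()),
            false_negative=int(((t == 1) & (d == 0)).sum()),
        )


def accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if counts.total == 0:
        raise UndefinedMetricError("accuracy is undefined on zero evaluated images")
    return (counts.true_positive + counts.true_negative) / counts.total


class HeadScorer:
    """Score images with a K=1 detection head: sigmoid of the raw logit."""

    def __init__(self, model):
        if model.K != 1:
            raise ValueError(f"HeadScorer needs a K=1 model, got K={model.K}")
        self.model = model

    def __call__(self, images: np.ndarray) -> np.ndarray:
        return sigmoid(self.model.scores(images)[:, 0])


class LutScorer:
    """Score images with a K-way classifier via look-up-table aggregation."""

    def __init__(self, model, graph: SynsetGraph, synset: str):
        if model.K != graph.n_labels:
            raise ValueError(
                f"model outputs {model.K} classes but the hierarchy has {graph.n_labels} leaves"
            )
        self.model = model
        self.graph = graph
        self.synset = synset
        members = descendant_labels(graph, synset)
        self._idx = np.array(sorted(graph.leaf_index[l] for l in members), dtype=int)

    def __call__(self, images: np.ndarray) -> np.ndarray:
        probs = softmax(self.model.scores(images), axis=1)
        if self._idx.size == 0:
            return np.zeros(probs.shape[0])
        return probs[:, self._idx].sum(axis=1)

    def single(self, probs: np.ndarray) -> float:
        """LUT score of one explicit probability vector (validated)."""
        return lut_probability(probs, self.synset, self.graph)


def evaluate(
    scorer: Callable[[np.ndarray], np.ndarray],
    splits: DatasetSplits,
    split: str = "test",
    threshold: float = 0.5,
    transform: Callable[[np.ndarray], np.ndarray] | None = None,
    negate: bool = False,
    batch_size: int = 32,
) -> tuple[pd.DataFrame, ConfusionCounts]:
    """Score one split image by image and tally the confusion counts.

    Returns a response-record table (image_id, truth, decision, score) and
    the matching :class:`ConfusionCounts`.  ``transform`` is applied to each
    image before scoring (the robustness batteries pass rotations or patch
    shuffles here); ``negate`` flips decisions, realizing the
    absence-prediction reading used for cross-task cells.
    """
    ids: list[str] = []
    truths: list[int] = []
    images: list[np.ndarray] = []
    for image_id, image, truth in splits.iter_images(split):
        if transform is not None:
            image = transform(image)
        ids.append(image_id)
        truths.append(truth)
        images.append(image)
    if not ids:
        raise UndefinedMetricError(f"split {split!r} holds no images")
    scores = np.concatenate(
        [
            np.asarray(scorer(np.stack(images[i : i + batch_size])))
            for i in range(0, len(images), batch_size)
        ]
    )
    decisions = (scores > threshold).astype(int)
    if negate:
        decisions = 1 - decisions
    records = pd.DataFrame(
        {"image_id": ids, "truth": truths, "decision": decisions, "score": scores}
    )
    return records, ConfusionCounts.from_records(records)


class TaskModel(NamedTuple):
    """A scorer together with the synset it was trained to detect (None = random task)."""

    scorer: Callable[[np.ndarray], np.ndarray]
    synset: str | None


class TaskDataset(NamedTuple):
    """A dataset together with its task synset (None = random task)."""

    splits: DatasetSplits
    synset: str | None


def cross_task_matrix(
    models: Mapping[str, TaskModel],
    datasets: Mapping[str, TaskDataset],
    threshold: float = 0.5,
    split: str = "test",
) -> pd.DataFrame:
    """Full accuracy grid of every model on every dataset.

    Cells where the model's trained synset differs from the dataset's task
    synset are computed with the decision negated (see module docstring).
    """
    table = pd.DataFrame(index=list(models), columns=list(datasets), dtype=float)
    for mname, tm in models.items():
        for dname, td in datasets.items():
            negate = (
                tm.synset is not None
                and td.synset is not None
                and tm.synset != td.synset
            )
            _, counts = evaluate(
                tm.scorer, td.splits, split=split, threshold=threshold, negate=negate
            )
            table.loc[mname, dname] = accuracy(counts)
    return table


def agreement(
    records_a: pd.DataFrame, records_b: pd.DataFrame
) -> tuple[float, dict[str, int]]:
    """Frame-by-frame correspondence of two responders' correct predictions.

    Returns the fraction of shared images on which correctness(A) equals
    correctness(B), plus the outcome taxonomy counts
    ``both_correct`` / ``a_only`` / ``b_only`` / ``both_wrong``.
    """
    a = records_a.set_index("image_id")
    b = records_b.set_index("image_id")
    if set(a.index) != set(b.index):
        diff = sorted(set(a.index) ^ set(b.index))
        raise AlignmentError(f"record sets cover different images: {diff[:20]}")
    b = b.loc[a.index]
    ok_a = (a["truth"] == a["decision"]).to_numpy()
    ok_b = (b["truth"] == b["decision"]).to_numpy()
    taxonomy = {
        "both_correct": int((ok_a & ok_b).sum()),
        "a_only": int((ok_a & ~ok_b).sum()),
        "b_only": int((~ok_a & ok_b).sum()),
        "both_wrong": int((~ok_a & ~ok_b).sum()),
    }
    return float((ok_a == ok_b).mean()), taxonomy


def records_to_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def records_from_csv(path) -> pd.DataFrame:
    """Ingest a responder's records CSV (image_id, truth, decision[, score]).

    Accepts 'target'/'distractor' strings or 0/1 integers in the truth and
    decision columns, so external psychophysics exports load without
    bespoke parsing.
    """
    df = pd.read_csv(path)
    for col in ("truth", "decision"):
        if df[col].dtype == object:
            df[col] = df[col].map({"target": 1, "distractor": 0}).astype(int)
    if "score" not in df:
        df["score"] = df["decision"].astype(float)
    return df[["image_id", "truth", "decision", "score"]]
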