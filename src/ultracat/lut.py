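"""Look-up-table (LUT) scoring: superordinate probability by softmax aggregation.

A K-way leaf classifier already knows about superordinate categories
implicitly: the probability that an image contains *some* kind of 'animal'
is the sum of its post-softmax leaf probabilities over every leaf whose
hyperonym path passes through 'animal'.  This turns a pretrained label
classifier into a detector for any synset without retraining.

The functions here deliberately refuse unnormalized inputs: callers must
apply an explicit softmax (see :func:`ultracat._nn.softmax`) so that raw
logits can never be silently misread as probabilities.
"""

from __future__ import annotations

import numpy as np

from .errors import MissingNodeError
from .hierarchy import SynsetGraph, descendant_labels

__all__ = ["lut_probability", "decide", "validate_probabilities"]

_TOL = 1e-6


def validate_probabilities(probs: np.ndarray, K: int) -> np.ndarray:
    """Check a length-K vector is a probability distribution (sum 1 ± 1e-6)."""
    p = np.asarray(probs, dtype=np.float64)
    if p.shape != (K,):
        raise ValueError(f"expected a length-{K} probability vector, got shape {p.shape}")
    if (p < 0).any():
        raise ValueError("probabilities must be nonnegative")
    total = p.sum()
    if abs(total - 1.0) > _TOL:
        raise ValueError(
            f"probabilities sum to {total:.8f}, not 1; apply an explicit softmax first"
        )
    return p


def lut_probability(probs: np.ndarray, synset: str, graph: SynsetGraph) -> float:
    """Probability that the image contains ``synset``: Σ p[i] over its descendant leaves."""
    p = validate_probabilities(probs, graph.n_labels)
    if synset not in graph:
        raise MissingNodeError(f"synset {synset!r} is not a node of the hierarchy")
    members = descendant_labels(graph, synset)
    idx = [graph.leaf_index[l] for l in members]
    return float(p[idx].sum()) if idx else 0.0


def decide(score: float, threshold: float = 0.5) -> str:
    """'target' iff ``score > threshold`` (strictly); boundary scores are distractors."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score {score} outside [0, 1]")
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold {threshold} outside (0, 1)")
    return "target" if score > threshold else "distractor"
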