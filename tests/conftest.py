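"""Shared fixtures: tiny hierarchies, fake image sources, random DAGs."""

from __future__ import annotations

import numpy as np
import pytest

from ultracat.hierarchy import SynsetGraph, hyperonym_paths

EDGES_5 = [
    ("shepherd", "dog"),
    ("dog", "animal"),
    ("animal", "root"),
    ("hammer", "artifact"),
    ("artifact", "root"),
]


@pytest.fixture
def shepherd_graph() -> SynsetGraph:
    """Two-leaf graph: a shepherd is a dog is an animal; a hammer is an artifact."""
    return SynsetGraph.from_edges(EDGES_5, ["shepherd", "hammer"])


@pytest.fixture
def diamond_graph() -> SynsetGraph:
    """Multi-parent leaf: a → {b, c} → root."""
    return SynsetGraph.from_edges(
        [("a", "b"), ("a", "c"), ("b", "root"), ("c", "root")], ["a"]
    )


def random_dag(seed: int, n_nodes: int = 30, p_edge: float = 0.15) -> SynsetGraph:
    """Random DAG over topologically ordered nodes; sources become the leaves."""
    rng = np.random.default_rng(seed)
    names = [f"n{i}" for i in range(n_nodes)]
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                edges.append((names[i], names[j]))
    # connect stragglers so every node is in the edge set
    in_graph = {a for e in edges for a in e}
    for i, name in enumerate(names[:-1]):
        if name not in in_graph:
            edges.append((name, names[rng.integers(i + 1, n_nodes)]))
    if names[-1] not in {a for e in edges for a in e}:
        edges.append((names[-2], names[-1]))
    g_nodes = {a for e in edges for a in e}
    has_parent = {child for child, _ in edges}
    has_child = {parent for _, parent in edges}
    leaves = sorted(g_nodes - has_child)  # no hyponyms: usable as image labels
    if not leaves:
        leaves = [sorted(g_nodes)[0]]
    return SynsetGraph.from_edges(edges, leaves)


def brute_force_descendants(graph: SynsetGraph, synset: str) -> set[str]:
    """Oracle: leaves whose exhaustively enumerated hyperonym paths contain synset."""
    out = set()
    for leaf in graph.leaf_labels:
        for path in hyperonym_paths(graph, leaf):
            if synset in path:
                out.add(leaf)
                break
    return out


class FakeSource:
    """In-memory image source with per-label constant-brightness images.

    Targets can be made trivially separable from distractors by assigning
    bright values to some labels and dark values to others.
    """

    def __init__(self, counts: dict[str, int], values: dict[str, int] | None = None, side: int = 32):
        self._counts = dict(counts)
        self._values = values or {}
        self.side = side

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self._counts)

    def count(self, label: str) -> int:
        return self._counts[label]

    def get(self, label: str, index: int) -> np.ndarray:
        value = self._values.get(label, 128)
        img = np.full((self.side, self.side, 3), value, dtype=np.uint8)
        img[0, 0, 0] = index % 256  # make addresses distinguishable
        return img
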