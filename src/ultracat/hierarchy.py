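"""Hyperonym hierarchies over synsets.

A *synset* is a node in a semantic graph; a directed edge points from a
hyponym to one of its hypernyms ("a dog is a kind of animal").  A designated
ordered subset of nodes are the *leaf labels*: the image classes.  The chain
of increasingly general synsets from a leaf up to a root is a *hyperonym
path*; a leaf counts as a descendant of a synset when any of its hyperonym
paths passes through that synset.  Those descendant sets drive both dataset
construction (targets vs. distractors) and look-up-table scoring.

The graph is a DAG, not a tree: a synset may have several hypernyms, in which
case a leaf has several hyperonym paths.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .errors import HierarchyFormatError, MissingNodeError

__all__ = [
    "SynsetGraph",
    "load_hierarchy",
    "load_leaf_labels",
    "hyperonym_paths",
    "descendant_labels",
]


@dataclass(frozen=True)
class SynsetGraph:
    """A validated hyperonym DAG with an ordered set of leaf image labels.

    Attributes
    ----------
    graph:
        ``networkx.DiGraph`` with hyponym→hypernym edges.
    leaf_labels:
        Ordered leaf names; position fixes the class index 0..K−1 used by
        every length-K probability vector downstream.
    """

    graph: nx.DiGraph
    leaf_labels: tuple[str, ...]
    leaf_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise HierarchyFormatError(f"hyperonym relation is cyclic: {cycle}")
        for leaf in self.leaf_labels:
            if leaf not in self.graph:
                raise MissingNodeError(f"leaf label {leaf!r} is not a node of the hierarchy")
        if len(set(self.leaf_labels)) != len(self.leaf_labels):
            raise HierarchyFormatError("leaf labels are not unique")
        object.__setattr__(
            self, "leaf_index", {name: i for i, name in enumerate(self.leaf_labels)}
        )

    @property
    def n_labels(self) -> int:
        """K, the number of leaf image labels."""
        return len(self.leaf_labels)

    @property
    def roots(self) -> set[str]:
        """Nodes with no hypernym."""
        return {n for n in self.graph if self.graph.out_degree(n) == 0}

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], leaf_labels: Sequence[str]
    ) -> "SynsetGraph":
        g = nx.DiGraph()
        g.add_edges_from(edges)
        return cls(graph=g, leaf_labels=tuple(leaf_labels))


def _read_lines(source) -> list[str]:
    if hasattr(source, "read"):
        return source.read().splitlines()
    if isinstance(source, (str, os.PathLike)):
        text = str(source)
        if "\n" not in text and os.path.exists(text):
            with open(text, "r", encoding="utf-8") as fh:
                return fh.read().splitlines()
        return text.splitlines()
    return [str(line) for line in source]


def load_hierarchy(edge_list, leaf_labels) -> SynsetGraph:
    """Parse a hyponym/hypernym edge list into a validated :class:`SynsetGraph`.

    Parameters
    ----------
    edge_list:
        Path, file-like object, or literal text.  Each non-comment line holds
        two whitespace-separated names, ``<hyponym> <hypernym>``; ``#`` starts
        a comment.  An iterable of ``(hyponym, hypernym)`` pairs also works.
    leaf_labels:
        Ordered leaf names: a path, file-like object, text (one name per
        line), or a sequence of names.  Order fixes the class indices.

    Raises
    ------
    HierarchyFormatError
        On malformed lines or a cyclic edge relation.
    MissingNodeError
        If a leaf name does not appear among the edge list's nodes.
    """
    edges: list[tuple[str, str]] = []
    if not hasattr(edge_list, "read") and not isinstance(edge_list, (str, os.PathLike)):
        seq = list(edge_list)
        if seq and isinstance(seq[0], tuple):
            edges = [(str(a), str(b)) for a, b in seq]
    if not edges:
        for lineno, raw in enumerate(_read_lines(edge_list), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise HierarchyFormatError(
                    f"line {lineno}: expected '<hyponym> <hypernym>', got {raw!r}"
                )
            edges.append((parts[0], parts[1]))
    leaves = load_leaf_labels(leaf_labels)
    return SynsetGraph.from_edges(edges, leaves)


def load_leaf_labels(source) -> tuple[str, ...]:
    """Read an ordered leaf-label list (one name per line, '#' comments)."""
    if not hasattr(source, "read") and not isinstance(source, (str, os.PathLike)):
        return tuple(str(s) for s in source)
    names = []
    for raw in _read_lines(source):
        name = raw.split("#", 1)[0].strip()
        if name:
            names.append(name)
    return tuple(names)


def hyperonym_paths(graph: SynsetGraph, label: str) -> set[tuple[str, ...]]:
    """Enumerate every maximal leaf-to-root walk starting at ``label``.

    Each path follows hyponym→hypernym edges from the leaf to a node with no
    hypernym.  A leaf under a multi-parent synset yields one path per branch.
    """
    if label not in graph.leaf_index:
        raise ValueError(f"{label!r} is not a leaf label of this hierarchy")
    g = graph.graph
    out: set[tuple[str, ...]] = set()

    def walk(node: str, prefix: tuple[str, ...]) -> None:
        parents = list(g.successors(node))
        if not parents:
            out.add(prefix)
            return
        for p in parents:
            walk(p, prefix + (p,))

    walk(label, (label,))
    return out


def descendant_labels(graph: SynsetGraph, synset: str) -> set[str]:
    """Leaf labels having some hyperonym path through ``synset``.

    The complement within ``graph.leaf_labels`` is the distractor label pool
    for a detection task on ``synset``.
    """
    if synset not in graph.graph:
        raise MissingNodeError(f"synset {synset!r} is not a node of the hierarchy")
    below = nx.ancestors(graph.graph, synset) | {synset}
    return {leaf for leaf in graph.leaf_labels if leaf in below}
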