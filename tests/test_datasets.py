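"""Balanced target/distractor split construction and its manifest invariants."""

import numpy as np
import pandas as pd
import pytest

from ultracat.datasets import (
    BuildConfig,
    build_dataset,
    build_random_task,
    build_strict_dataset,
    write_images,
)
from ultracat.errors import CapacityError, MissingNodeError, TaskUndefinedError
from ultracat.hierarchy import SynsetGraph, descendant_labels
from ultracat.synthetic import SyntheticSpec, generate_hierarchy, make_source

from conftest import FakeSource


@pytest.fixture
def lazy_world():
    """Lazy synthetic source big enough for default split sizes (never rendered)."""
    spec = SyntheticSpec(side=64, n_animal=4, n_artifact=4, n_neutral=2)
    source = make_source(spec, seed=0, images_per_label=600)
    return source, source.graph


class TestBuildDataset:
    def test_default_sizes_and_balance(self, lazy_world):
        source, graph = lazy_world
        splits = build_dataset(source, graph, "animal", BuildConfig(seed=1))
        m = splits.manifest
        assert m.groupby("split").size().to_dict() == {"train": 2000, "val": 800, "test": 1200}
        by_class = m.groupby(["split", "class"]).size()
        assert by_class.loc[("train", "target")] == 1000
        assert by_class.loc[("val", "distractor")] == 400
        assert by_class.loc[("test", "target")] == 600

    def test_targets_are_descendants_distractors_are_not(self, lazy_world):
        source, graph = lazy_world
        splits = build_dataset(source, graph, "animal", BuildConfig(40, 16, 24, seed=2))
        members = descendant_labels(graph, "animal")
        m = splits.manifest
        assert set(m.loc[m["class"] == "target", "leaf_label"]) <= members
        assert not (set(m.loc[m["class"] == "distractor", "leaf_label"]) & members)

    def test_splits_are_image_disjoint(self, lazy_world):
        source, graph = lazy_world
        splits = build_dataset(source, graph, "animal", BuildConfig(40, 16, 24, seed=3))
        addresses = list(zip(splits.manifest["leaf_label"], splits.manifest["image_index"]))
        assert len(addresses) == len(set(addresses))

    def test_single_target_leaf(self, shepherd_graph):
        source = FakeSource({"shepherd": 10, "hammer": 10})
        splits = build_dataset(source, shepherd_graph, "animal", BuildConfig(4, 2, 2, seed=0))
        m = splits.manifest
        targets = m[m["class"] == "target"]
        assert len(targets) == 4
        assert set(targets["leaf_label"]) == {"shepherd"}

    def test_seeded_determinism(self, lazy_world):
        source, graph = lazy_world
        cfg = BuildConfig(40, 16, 24, seed=11)
        m1 = build_dataset(source, graph, "animal", cfg).manifest
        m2 = build_dataset(source, graph, "animal", cfg).manifest
        pd.testing.assert_frame_equal(m1, m2)
        m3 = build_dataset(source, graph, "animal", cfg.with_(seed=12)).manifest
        assert not m1.equals(m3)
        assert m3.groupby("split").size().to_dict() == m1.groupby("split").size().to_dict()

    def test_capacity_error_reports_shortfall(self, shepherd_graph):
        source = FakeSource({"shepherd": 3, "hammer": 3})
        with pytest.raises(CapacityError, match="train"):
            build_dataset(source, shepherd_graph, "animal", BuildConfig(10, 2, 2, seed=0))

    def test_empty_pool_is_task_undefinable(self, shepherd_graph):
        source = FakeSource({"shepherd": 10, "hammer": 10})
        with pytest.raises(TaskUndefinedError):
            build_dataset(source, shepherd_graph, "root", BuildConfig(4, 2, 2, seed=0))

    def test_human_exclusion_list_removes_target_labels(self, lazy_world):
        source, graph = lazy_world
        cfg = BuildConfig(40, 16, 24, seed=5, exclude_target_labels=("animal_000",))
        splits = build_dataset(source, graph, "animal", cfg)
        assert "animal_000" not in set(
            splits.manifest.loc[splits.manifest["class"] == "target", "leaf_label"]
        )

    def test_odd_split_size_rejected(self):
        with pytest.raises(ValueError):
            BuildConfig(train=7)


class TestRandomTask:
    def test_forced_half_split(self):
        g = generate_hierarchy(SyntheticSpec(n_animal=4, n_artifact=4, n_neutral=0))
        source = FakeSource({l: 10 for l in g.leaf_labels})
        splits = build_random_task(source, g, n_labels=4, config=BuildConfig(8, 4, 4, seed=0))
        assert len(splits.target_pool) == 2
        assert len(splits.distractor_pool) == 2
        assert not (set(splits.target_pool) & set(splits.distractor_pool))

    def test_default_samples_500_labels(self):
        g = generate_hierarchy(SyntheticSpec(n_animal=500, n_artifact=500, n_neutral=0))
        source = FakeSource({l: 4 for l in g.leaf_labels})
        splits = build_random_task(source, g, config=BuildConfig(8, 4, 4, seed=1))
        assert len(splits.target_pool) == 250
        assert len(splits.distractor_pool) == 250

    def test_too_many_labels_is_capacity_error(self, shepherd_graph):
        source = FakeSource({"shepherd": 10, "hammer": 10})
        with pytest.raises(CapacityError):
            build_random_task(source, shepherd_graph, n_labels=4, config=BuildConfig(4, 2, 2))


class TestStrictDataset:
    @pytest.fixture
    def three_branch(self):
        edges = [("dog", "animal"), ("hammer", "artifact"), ("cloud", "sky"),
                 ("animal", "root"), ("artifact", "root"), ("sky", "root")]
        g = SynsetGraph.from_edges(edges, ["dog", "hammer", "cloud"])
        return g, FakeSource({"dog": 20, "hammer": 20, "cloud": 20})

    def test_strict_distractors_avoid_both_synsets(self, three_branch):
        g, source = three_branch
        splits = build_strict_dataset(source, g, "animal", "artifact", BuildConfig(8, 4, 4, seed=0))
        assert set(splits.distractor_pool) == {"cloud"}
        assert set(splits.target_pool) == {"dog"}

    def test_strict_pool_is_subset_of_plain_pool(self, three_branch):
        g, source = three_branch
        cfg = BuildConfig(8, 4, 4, seed=0)
        plain = build_dataset(source, g, "animal", cfg)
        strict = build_strict_dataset(source, g, "animal", "artifact", cfg)
        assert set(strict.distractor_pool) < set(plain.distractor_pool)

    def test_missing_excluded_node(self, three_branch):
        g, source = three_branch
        with pytest.raises(MissingNodeError):
            build_strict_dataset(source, g, "animal", "nonexistent", BuildConfig(8, 4, 4))

    def test_empty_strict_pool(self, shepherd_graph):
        source = FakeSource({"shepherd": 10, "hammer": 10})
        with pytest.raises(TaskUndefinedError):
            build_strict_dataset(source, shepherd_graph, "animal", "artifact", BuildConfig(4, 2, 2))


def test_write_images_layout(tmp_path, shepherd_graph):
    source = FakeSource({"shepherd": 10, "hammer": 10}, side=16)
    splits = build_dataset(source, shepherd_graph, "animal", BuildConfig(4, 2, 2, seed=0))
    root = write_images(splits, tmp_path / "ds")
    assert (root / "manifest.csv").exists()
    assert (root / "train" / "target" / "00000.png").exists()
    manifest = pd.read_csv(root / "manifest.csv")
    assert len(manifest) == 8
    assert set(manifest["class"]) == {"target", "distractor"}
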