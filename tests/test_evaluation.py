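"""Confusion accounting, scorers, cross-task grids, responder agreement."""

import numpy as np
import pandas as pd
import pytest

from ultracat._nn import softmax
from ultracat.datasets import BuildConfig, build_dataset
from ultracat.errors import AlignmentError, UndefinedMetricError
from ultracat.evaluation import (
    ConfusionCounts,
    HeadScorer,
    LutScorer,
    TaskDataset,
    TaskModel,
    accuracy,
    agreement,
    cross_task_matrix,
    evaluate,
    records_from_csv,
)
from ultracat.hierarchy import SynsetGraph
from ultracat.lut import decide, lut_probability
from ultracat.models import make_backbone, small_preset
from ultracat.synthetic import SyntheticSpec, make_source

from conftest import FakeSource


class TestAccuracy:
    def test_direct_arithmetic(self):
        assert accuracy(ConfusionCounts(3, 2, 1, 0)) == pytest.approx(5 / 6)
        assert accuracy(ConfusionCounts(0, 0, 5, 5)) == 0.0

    def test_empty_evaluation_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            accuracy(ConfusionCounts())

    def test_equals_per_record_recount(self):
        """Confusion-ratio accuracy equals the mean correctness indicator."""
        rng = np.random.default_rng(0)
        records = pd.DataFrame(
            {
                "image_id": [f"i{i}" for i in range(500)],
                "truth": rng.integers(0, 2, 500),
                "decision": rng.integers(0, 2, 500),
                "score": rng.random(500),
            }
        )
        counts = ConfusionCounts.from_records(records)
        assert counts.total == 500
        recount = (records["truth"] == records["decision"]).mean()
        assert accuracy(counts) == pytest.approx(recount)

    def test_symmetric_under_class_relabeling(self):
        a = ConfusionCounts(true_positive=7, true_negative=2, false_positive=3, false_negative=1)
        b = ConfusionCounts(true_positive=2, true_negative=7, false_positive=1, false_negative=3)
        assert accuracy(a) == accuracy(b)


@pytest.fixture
def separable_task(shepherd_graph):
    """Targets are bright, distractors dark: brightness is a perfect score."""
    source = FakeSource({"shepherd": 20, "hammer": 20}, values={"shepherd": 250, "hammer": 10})
    return build_dataset(source, shepherd_graph, "animal", BuildConfig(8, 4, 8, seed=0))


def brightness_scorer(images):
    return images.reshape(len(images), -1).mean(axis=1) / 255.0


class TestEvaluate:
    def test_perfect_scorer(self, separable_task):
        records, counts = evaluate(brightness_scorer, separable_task, split="test")
        assert accuracy(counts) == 1.0
        assert counts.false_positive == counts.false_negative == 0
        assert len(records) == 8

    def test_constant_scorer_on_balanced_set_is_chance(self, separable_task):
        records, counts = evaluate(lambda im: np.full(len(im), 0.5), separable_task, split="test")
        assert accuracy(counts) == 0.5  # boundary score → all distractor decisions
        assert (records["decision"] == 0).all()

    def test_negation_flips_decisions(self, separable_task):
        records, counts = evaluate(brightness_scorer, separable_task, split="test", negate=True)
        assert accuracy(counts) == 0.0

    def test_counts_sum_to_evaluated_images(self, separable_task):
        for split in ("train", "val", "test"):
            _, counts = evaluate(brightness_scorer, separable_task, split=split)
            assert counts.total == len(separable_task.split_refs(split))

    def test_lut_mode_composes_module_oracles(self):
        """Evaluate-with-LutScorer equals per-image softmax → lut → decide."""
        spec = SyntheticSpec(side=64, n_animal=2, n_artifact=2, n_neutral=1)
        source = make_source(spec, seed=3, images_per_label=8)
        graph = source.graph
        task = build_dataset(source, graph, "animal", BuildConfig(8, 4, 8, seed=1))
        model = make_backbone(small_preset(K=graph.n_labels), seed=4)
        scorer = LutScorer(model, graph, "animal")
        records, _ = evaluate(scorer, task, split="test")
        for image_id, image, _truth in task.iter_images("test"):
            probs = softmax(model.scores(image[None]), axis=1)[0]
            expected = lut_probability(probs, "animal", graph)
            row = records.loc[records["image_id"] == image_id].iloc[0]
            assert row["score"] == pytest.approx(expected, abs=1e-6)
            assert row["decision"] == (1 if decide(expected) == "target" else 0)

    def test_head_scorer_requires_single_output(self):
        model = make_backbone(small_preset(K=3), seed=0)
        with pytest.raises(ValueError):
            HeadScorer(model)


class TestCrossTaskMatrix:
    def test_single_cell_equals_evaluate(self, separable_task):
        from ultracat.evaluation import accuracy as acc

        _, counts = evaluate(brightness_scorer, separable_task, split="test")
        table = cross_task_matrix(
            {"m": TaskModel(brightness_scorer, "animal")},
            {"d": TaskDataset(separable_task, "animal")},
        )
        assert table.shape == (1, 1)
        assert table.loc["m", "d"] == pytest.approx(acc(counts))

    def test_foreign_synset_cell_uses_negated_decision(self, separable_task):
        """A detector transferred across tasks predicts the foreign category's absence."""
        direct = cross_task_matrix(
            {"m": TaskModel(brightness_scorer, "animal")},
            {"d": TaskDataset(separable_task, "animal")},
        ).loc["m", "d"]
        crossed = cross_task_matrix(
            {"m": TaskModel(brightness_scorer, "artifact")},
            {"d": TaskDataset(separable_task, "animal")},
        ).loc["m", "d"]
        assert direct == pytest.approx(1.0)
        assert crossed == pytest.approx(0.0)  # same scorer, complemented reading

    def test_random_task_rows_stay_direct(self, separable_task):
        table = cross_task_matrix(
            {"rnd": TaskModel(brightness_scorer, None)},
            {"d": TaskDataset(separable_task, "animal")},
        )
        assert table.loc["rnd", "d"] == pytest.approx(1.0)


class TestAgreement:
    @staticmethod
    def records(correct_mask):
        n = len(correct_mask)
        truth = np.zeros(n, dtype=int)
        decision = np.where(correct_mask, 0, 1)
        return pd.DataFrame(
            {"image_id": [f"i{k}" for k in range(n)], "truth": truth,
             "decision": decision, "score": decision.astype(float)}
        )

    def test_self_agreement_is_one(self):
        r = self.records(np.ones(10, dtype=bool))
        frac, taxonomy = agreement(r, r)
        assert frac == 1.0
        assert taxonomy == {"both_correct": 10, "a_only": 0, "b_only": 0, "both_wrong": 0}

    def test_perfect_vs_always_wrong(self):
        a = self.records(np.ones(10, dtype=bool))
        b = self.records(np.zeros(10, dtype=bool))
        frac, taxonomy = agreement(a, b)
        assert frac == 0.0
        assert taxonomy["a_only"] == 10

    def test_disjoint_error_sets_give_2p_minus_1(self):
        """Two responders at accuracy p with disjoint errors agree on 2p−1 of frames."""
        n, p = 100, 0.7
        wrong = int(round(n * (1 - p)))
        mask_a = np.ones(n, dtype=bool)
        mask_a[:wrong] = False
        mask_b = np.ones(n, dtype=bool)
        mask_b[wrong : 2 * wrong] = False
        frac, taxonomy = agreement(self.records(mask_a), self.records(mask_b))
        assert frac == pytest.approx(2 * p - 1)
        assert taxonomy["both_wrong"] == 0

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a = self.records(rng.random(50) < 0.8)
        b = self.records(rng.random(50) < 0.6)
        assert agreement(a, b)[0] == agreement(b, a)[0]

    def test_identifier_mismatch_is_alignment_error(self):
        a = self.records(np.ones(5, dtype=bool))
        b = self.records(np.ones(6, dtype=bool))
        with pytest.raises(AlignmentError, match="i5"):
            agreement(a, b)


def test_records_csv_accepts_string_classes(tmp_path):
    path = tmp_path / "human.csv"
    path.write_text(
        "image_id,truth,decision\nimg0,target,target\nimg1,distractor,target\n"
    )
    records = records_from_csv(path)
    assert records["truth"].tolist() == [1, 0]
    assert records["decision"].tolist() == [1, 1]
    assert len(records.columns) == 4
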