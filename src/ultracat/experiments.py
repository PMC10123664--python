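"""Standard desk-scale experiment recipe.

One place defines the study conditions used by the packaged analyses: the
synthetic world (a 64-px rendering of the default texture statistics, two
superordinate branches of four leaves plus two neutral leaves), the
pretraining stage that stands in for large-database training, and the
transfer trainings at the canonical hyperparameters (batch 8, learning
rate 5e-5, momentum 0.99, 25 epochs).

Pretraining renders its own corpus (a different master seed than the task
images, so no task image is ever seen during pretraining) and runs 30
epochs of momentum SGD at 2e-3 with step decay — enough for the small
backbone's features to support linear branch separation.

Every function takes one integer seed and derives all sub-seeds from it.
"""

from __future__ import annotations

from .datasets import BuildConfig, DatasetSplits
from .models import BackboneModel, make_backbone, replace_head, small_preset
from .synthetic import SyntheticSpec, SyntheticImageSource, make_source
from .training import PROTOCOLS, Hyperparams, TrainResult, pretrain_leaf_classifier, train

__all__ = [
    "desk_spec",
    "desk_sources",
    "desk_config",
    "pretrained_base",
    "transfer_model",
    "desk_hyperparams",
]

#: image side used in the desk-scale experiments (divisible by 32)
DESK_SIDE = 64
#: split sizes for the desk-scale experiments
DESK_SIZES = (200, 80, 120)
#: images rendered per leaf in the pretraining corpus
PRETRAIN_IMAGES_PER_LABEL = 60
PRETRAIN_HP = dict(epochs=30, learning_rate=2e-3, momentum=0.9)


def desk_spec(**overrides) -> SyntheticSpec:
    """The desk-scale synthetic world: 4 animal + 4 artifact + 2 neutral leaves at 64 px."""
    params = dict(side=DESK_SIDE, n_animal=4, n_artifact=4, n_neutral=2)
    params.update(overrides)
    return SyntheticSpec(**params)


def desk_sources(
    seed: int, spec: SyntheticSpec | None = None, images_per_label: int = 80
) -> tuple[SyntheticImageSource, SyntheticImageSource]:
    """(pretraining corpus, task image source) with disjoint master seeds."""
    spec = spec or desk_spec()
    pre = make_source(spec, seed=seed * 1000 + 1, images_per_label=PRETRAIN_IMAGES_PER_LABEL)
    task = make_source(spec, seed=seed * 1000 + 2, images_per_label=images_per_label)
    return pre, task


def desk_config(seed: int) -> BuildConfig:
    train_n, val_n, test_n = DESK_SIZES
    return BuildConfig(train=train_n, val=val_n, test=test_n, seed=seed * 1000 + 3)


def desk_hyperparams(seed: int, **overrides) -> Hyperparams:
    """Canonical transfer hyperparameters with a derived seed."""
    return Hyperparams(seed=seed * 1000 + 6).with_(**overrides)


def pretrained_base(seed: int, source: SyntheticImageSource) -> BackboneModel:
    """Pretrain the small backbone as a K-leaf classifier on the given corpus."""
    model = make_backbone(small_preset(K=len(source.labels)), seed=seed * 1000 + 4)
    hp = Hyperparams(seed=seed * 1000 + 5, **PRETRAIN_HP)
    return pretrain_leaf_classifier(
        model, source, images_per_label=source.images_per_label, hp=hp
    )


def transfer_model(
    base: BackboneModel,
    splits: DatasetSplits,
    protocol_name: str,
    seed: int,
    hp: Hyperparams | None = None,
) -> tuple[BackboneModel, TrainResult]:
    """Replace the head with a K=1 detector and train it under one protocol."""
    model = replace_head(base, 1, seed=seed * 1000 + 7)
    result = train(model, splits, PROTOCOLS[protocol_name], hp or desk_hyperparams(seed))
    return model, result
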