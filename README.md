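# ultracat

Tools for modelling **ultrafast image categorization** — the psychophysical
go/no-go task in which an observer reports, after a ~20 ms flash, whether an
image contains an instance of a superordinate category such as *animal* or
*artifact*. The package lets you build the complete modelling pipeline used
to compare convolutional networks with human rapid-categorization behaviour:

- **Semantic hierarchy** (`ultracat.hierarchy`) — a hyperonym DAG over
  synsets ("a German Shepherd is a dog, a dog is an animal") with leaf image
  labels; answers "is label X a kind of synset S?" through hyperonym-path
  enumeration and descendant queries.
- **Dataset builder** (`ultracat.datasets`) — balanced target/distractor
  train/val/test splits (defaults 2000/800/1200 images) for any synset task,
  the 500-label random control task, and "strictly-S" variants whose
  distractors also avoid a second synset.
- **Synthetic world** (`ultracat.synthetic`) — a procedural image generator
  with an animal-like branch (curved, orientation-isotropic texture), an
  artifact-like branch (oriented gratings), neutral clutter, nuisance
  variation, a tunable anti-correlation between the two category cues within
  one image, and a no-signal mode — so every experiment runs with no
  download.
- **Backbones** (`ultracat.models`) — VGG-16-style stacks (13 conv layers in
  5 blocks, 64→512 channels, adaptive pooling to 7×7, no batch norm) on a
  compact NumPy CNN engine, with head replacement, layer freezing, and
  deep-end pruning (down to a single conv layer).
- **Training protocols** (`ultracat.training`) — the five strategies
  SLS / TLC / TLA / TLDA / TLAA (scratch vs. transfer; frozen vs. full;
  none / custom / auto augmentation), binary cross-entropy with logits,
  momentum SGD (defaults: batch 8, lr 5·10⁻⁵, momentum 0.99, 25 epochs), and
  a one-at-a-time hyperparameter sweep harness.
- **LUT scoring** (`ultracat.lut`) — superordinate detection from a K-way
  classifier without retraining: P(synset) = Σ softmax probabilities over the
  synset's descendant leaves, thresholded at 0.5 (strictly greater → target).
- **Robustness batteries** (`ultracat.transforms`) — rotation (−180°…180°,
  lossless at cardinal angles), flips, grayscale, patch shuffling, with sweep
  harnesses and timing.
- **Evaluation** (`ultracat.evaluation`) — confusion-count accuracy
  (TP+TN)/(TP+TN+FP+FN), cross-task bias matrices, and frame-by-frame
  responder agreement (model vs. model, or model vs. human records CSV).

## Worked example

Pretrain a small backbone on the synthetic leaf-classification task, transfer
it to "is there an animal in this image?", and probe its rotation robustness:

```python
from ultracat import experiments
from ultracat.datasets import build_dataset
from ultracat.evaluation import HeadScorer, accuracy, evaluate
from ultracat.transforms import rotation_sweep

seed = 1
pre_source, source = experiments.desk_sources(seed)
animal = build_dataset(source, source.graph, "animal", experiments.desk_config(seed))

base = experiments.pretrained_base(seed, pre_source)       # K-leaf classifier
tlc, result = experiments.transfer_model(base, animal, "TLC", seed)

_, counts = evaluate(HeadScorer(tlc), animal, split="test")
print(f"TLC test accuracy: {accuracy(counts):.3f}")
sweep = rotation_sweep(tlc, animal, [-180, -90, 0, 90, 180])
print(dict(zip(sweep.conditions, sweep.mean.round(3))))
```

Output:

```
TLC test accuracy: 0.950
{-180: 0.975, -90: 0.608, 0: 0.95, 90: 0.633, 180: 0.975}
```

The frozen-backbone transfer detector separates the categories almost
perfectly on upright images, keeps that accuracy at ±180° (where the
near-vertical artifact cue is unchanged), and collapses toward chance at ±90°
(where it becomes horizontal) — the cardinal-angle signature of a detector
trained without rotation augmentation. Re-training with the TLDA policy
flattens the curve.

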