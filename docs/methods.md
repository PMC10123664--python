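# Methods

## The task and the modelling question

Ultrafast image categorization asks an observer to report, from a briefly
flashed image, whether it contains an instance of a superordinate category
(canonically *animal*). Human performance is fast, accurate (~80 % correct
on natural photographs) and strikingly robust to geometric transformations
such as rotation or grayscale conversion, and the physiological time course
constrains the computation to be essentially feed-forward. The package
models this regime with convolutional detectors and asks four questions:
how much accuracy transfer learning buys over training from scratch; whether
augmentation during re-training reproduces the human-like robustness;
how few convolutional layers suffice (depth pruning, patch shuffling); and
how dataset composition induces cross-task biases between the *animal* and
*artifact* detectors.

## Hierarchy-driven dataset construction

Tasks are defined against a hyperonym DAG: a leaf image label is a
*descendant* of a synset when any of its leaf-to-root hyperonym paths passes
through that synset. A detection dataset for synset S draws targets from
descendants of S and distractors from the rest, balanced exactly within
each of the train/validation/test splits (defaults 2000/800/1200 images).
Multi-parent synsets are allowed; descendant membership uses *any*-path
semantics with set deduplication. Three further choices are deliberate:

- **Image-level disjointness across splits.** Each (label, image) address is
  consumed at most once per dataset; leakage between train and test would
  silently inflate every accuracy claim downstream.
- **Two-stage sampling** — label uniform from the pool, then an unused image
  uniform within that label — so labels with many images cannot dominate a
  split.
- **Determinism.** The manifest is a pure function of
  (source, graph, synset, config); the same seed reproduces it byte for byte.

The *random* control task draws 500 leaf labels (or any even number) without
replacement and splits them into pseudo-target/pseudo-distractor halves; the
"strictly S" variants additionally ban descendants of a second synset from
the distractor pool. An optional exclusion list keeps designated labels
(e.g. human-depicting classes) out of the target pool.

## The synthetic world

The generator emulates the statistical structure the analyses need, not
photorealism. A toy hierarchy (root → {animal, artifact, neutral} → leaves)
feeds a procedural renderer:

- **Animal-like leaves**: a handful of soft annuli — curved, orientation-
  isotropic energy at a characteristic radius. Each leaf has its own radius
  factor (leaf identity).
- **Artifact-like leaves**: a Gabor-like grating patch — rectilinear,
  orientation-anisotropic energy, near-vertical by default (±5° jitter), with
  a per-leaf characteristic wavelength. Because the orientation is fixed,
  the cue is rotation-*sensitive*; setting `rotation_invariant_cues` draws
  the orientation uniformly instead, removing that sensitivity.
- **Neutral leaves**: background clutter only.

Clutter (smoothed Gaussian noise, sd 0.10), object position (±12 % of the
side), scale (0.85–1.2), and a per-image color tint are class-independent
nuisances. Cues are achromatic, so color never separates the classes and
grayscale conversion is harmless — mirroring the corresponding behavioural
finding.

Two parameters define dataset-composition structure. With probability
`cross_category_exclusion` (default 0.9) an image carries only its own
branch's cue; otherwise the opposite branch's cue is superimposed at 0.6 of
the primary amplitude (an intruding category is a minor scene element, and
full-amplitude superposition would make such images genuinely ambiguous).
This anti-correlation is what the cross-task bias battery detects, and 0.9
rather than 1.0 keeps cross-task accuracies high but imperfect. With
`signal=False` every leaf renders pure clutter: labels become independent of
pixels, which is the no-signal regime of the random control.

Default cue contrast (0.55 against the [0, 1] intensity range) was chosen so
that the categories are comfortably separable by low-level oriented-energy
statistics: a logistic probe on gradient-orientation histograms reaches
≥ 0.9, and transfer-trained detectors reach ~0.95 — the operating point at
which re-trained networks perform on the real task. A 3-point contrast dial
(accuracy increases monotonically with contrast) and a rotation dial (probe
accuracy at 90° drops only when cues are orientation-locked) are tested
properties of the generator, not incidental behaviour.

What the generator does **not** emulate: object shape and semantics, scene
context, occlusion, within-class photographic variability, and the
high-order statistics of natural images. Passing tests therefore certify
the pipeline's mechanics and the direction of each effect, not
photograph-level accuracy values.

## Backbones and the CNN engine

The reference architecture follows the VGG-16 feature geometry: 13
convolutional layers (3×3, stride 1, ReLU) in 5 blocks of (2, 2, 3, 3, 3)
with widths (64, 128, 256, 512, 512), 2×2 max pooling between blocks, no
batch normalization, adaptive average pooling to a constant 7×7 grid, and a
(4096, 4096) fully connected classifier. Because the adaptive pooling
output is size-invariant, the classifier's architecture survives both any
input resolution ≥ 32 px and any amount of convolutional pruning.

The engine underneath is a compact NumPy implementation (`ultracat._nn`):
im2col-style 3×3 convolution, analytic backprop (verified against central
differences in the test suite), momentum SGD (v ← μv + g, w ← w − ηv), and
numerically stable BCE-with-logits / softmax cross-entropy. Float32
throughout. Inputs are scaled to [0, 1] and standardized per channel;
the default config uses identity standardization (set the conventional
constants when injecting externally trained weights), while the desk-scale
preset standardizes around mid-gray (mean 0.5, sd 0.25) because centering is
what keeps from-scratch optimization of a small stack well conditioned.

**Pruning** removes individual layers from the deep end, not whole blocks:
twelve depth factors can only arise from 13 layers minus 1…12. A block's
pooling stage disappears when the block empties. The first fully connected
layer is re-instantiated whenever layers are removed — its input width must
match the surviving channel width, and pruned networks are re-trained
afterwards anyway. **Head replacement** re-instantiates only the final
classifier layer (K=1000 → K=1); every other parameter is bit-identical,
which the tests assert by checksum.

## Training protocols

Five strategies, written as (weight origin, trainability, augmentation):
SLS = (random, all, none); TLC = (pretrained, head-only, none);
TLA = (pretrained, all, none); TLDA = (pretrained, head-only, custom);
TLAA = (pretrained, head-only, auto). TLDA/TLAA inherit TLC's freezing —
augmentation is tested as an addition to head-only transfer.

The loss is sigmoid-linked binary cross-entropy on target = 1 /
distractor = 0; the optimizer is momentum SGD with defaults batch 8,
learning rate 5·10⁻⁵, momentum 0.99, 25 epochs, decision threshold 0.5
(strictly greater → target; a boundary score is a distractor). There is no
early stopping; the best-epoch weights by validation accuracy are retained.
Mini-batch order and per-image augmentation draws derive deterministically
from the training seed. Frozen parameters are never touched — the optimizer
skips them, so bit-identity holds trivially and is still asserted.

The **custom** augmentation applies, in order: horizontal flip (p = 0.5),
vertical flip (p = 0.5), rotation (always; the angle range is unspecified in
common practice, and we use uniform ±180° to match the evaluation sweep),
grayscale (p = 0.5). The **auto** policy draws one of a fixed catalogue of
16 operations per call (identity, rotation, two shears, two translations,
scale, two flips, contrast, brightness, sharpness, posterize, solarize,
grayscale, cutout) with a random magnitude; the catalogue is the package's
documented contract and is seed-deterministic.

The hyperparameter sweep is one-at-a-time, not factorial: each parameter is
varied over its range with the others at defaults, and the per-setting
best-epoch validation accuracy is tabulated with the per-parameter argmax.

**Pretraining.** "Pretrained" weight origins are supplied by the caller.
With no external weights in scope, the synthetic pipeline realizes
pretraining by training the small backbone as a K-leaf classifier (softmax
cross-entropy) on its own rendered corpus — a desk-scale analogue of
large-database pretraining. The pretraining corpus uses a different master
seed than the task images, so no task image is seen during pretraining.
Because this stage stands in for a converged large-scale training run, it
uses its own optimization recipe (30 epochs at 2·10⁻³, momentum 0.9, with a
two-step learning-rate decay at 60 % and 85 % of training) rather than the
transfer-phase defaults; without the decay, from-scratch feature quality
varies substantially across seeds.

## LUT scoring

A K-way leaf classifier detects a superordinate category without
retraining: P(S) is the sum of post-softmax leaf probabilities over S's
descendants, compared to the same 0.5 threshold. The scorer refuses
unnormalized vectors (tolerance 10⁻⁶ on the sum) so logits can never be
silently misread as probabilities. Descendant sets of disjoint synsets give
subadditive scores, with equality when they partition the leaves.

## Robustness batteries

Rotation is about the image center, frame preserved, out-of-frame regions
filled with black (the fill value is a free choice; black matches the zero
of the standardized input). Exact multiples of 90° use lossless grid
rotation so cardinal-angle evaluations are interpolation-free — those angles
are where detectors trained on upright images peak — and other angles use
bilinear resampling (nearest-neighbour available for bit-exactness checks).
Patch shuffling partitions the image into an s×s-pixel grid and applies a
uniform random permutation ("reassembled from permuted patches"): structure
above scale s is destroyed, the multiset of patch contents — hence the pixel
histogram — is conserved. Default patch sizes on 256-px images are
{256, 128, 64, 32, 16, 8}. Prediction timing is wall-clock per image and is
reported only; it is hardware-dependent and only the qualitative
shallower-is-faster ordering is meaningful.

## Evaluation and the cross-task matrix

Accuracy is (TP+TN)/(TP+TN+FP+FN) over a balanced test split. The
cross-task matrix evaluates every named model on every named dataset. When
a model's trained synset differs from the dataset's task synset, the
model's decision is negated: in the image population the two superordinate
categories are anti-correlated within single images, so "my category is
absent" is the detector's prediction of the foreign category's presence.
This is the reading under which an animal detector transfers above chance
to the artifact task — and under which that transfer collapses on the
strictly-artifact dataset, whose distractors carry neither category, which
is precisely the composition bias the matrix exposes. Cells on the model's
own task (including its "strictly" variant) and all random-task cells use
the direct decision.

Responder agreement is the fraction of shared frames on which two
responders' *correctness* coincides (not response identity), with the
four-way taxonomy both-correct / A-only / B-only / both-wrong. For two
responders with accuracy p and disjoint error sets this is 2p − 1, a
closed form the tests exercise. Human responses load from a plain records
CSV (image id, truth, decision), accepting either 0/1 or
target/distractor coding.

## Desk-scale study conditions

The packaged experiments (`ultracat.experiments`, used by the test suite
and `scripts/acceptance.py`) run on a 64-px rendering of the default
synthetic world with 4 animal, 4 artifact and 2 neutral leaves;
200/80/120-image splits; a 600-image pretraining corpus (60 per leaf); and
the canonical transfer hyperparameters. These sizes keep a full pipeline
run — pretraining, two transfer trainings, a control training, two rotation
sweeps, a shuffle sweep, and the bias battery — in the minutes range on one
CPU core while leaving every effect direction detectable with wide margins.
The reference 256-px geometry and 2000/800/1200 splits are exercised
structurally (construction, manifests, shapes) rather than through full
training runs.

## Known limitations

- The NumPy engine is single-threaded BLAS-bound and has no GPU path; it is
  sized for the desk-scale backbone, not for training the full 13-layer
  reference network to convergence.
- No dropout in the classifier; at desk scale the head-only protocols do
  not overfit, and the from-scratch SLS protocol's overfitting is itself
  part of the phenomenon under study.
- The auto-augmentation catalogue approximates a learned policy with fixed
  uniform-magnitude operations.
- The cross-task negation rule is a modelling choice about how a
  single-category detector is read out on a foreign task; the direct
  (non-negated) reading would place anti-correlated transfer below chance.
- Agreement is fraction-identical-correctness, one of several plausible
  correspondence measures; it is labelled as such wherever reported.
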