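# Methods

## Problem and model

The Clock Drawing Test (CDT) asks a subject to draw a clock face showing
11:10; the drawing is rated on the Shulman 0–5 scale (5 = normal, 4 = minor
visuospatial deficits, 3 = incorrect time representation, lower = more
severe abnormality). Automatic scoring is a *fine-grained* image
classification problem: a 4 differs from a 5 only in subtle local details.

`clockapi` implements a pairwise contrastive training scheme for this task.
A CNN backbone embeds each image into a d-dimensional vector. During
training, images are consumed in pairs; an attentive pairwise interaction
block computes

- a mutual vector `x_m = MLP([x_1; x_2])` (two affine maps, ReLU and
  dropout between them, `2d → h → d` with `h = d` by default),
- gate vectors `g_i = σ(x_m ⊙ x_i)`,
- four attentive features by residual attention,
  `x_i^self = x_i + x_i ⊙ g_i`, `x_1^other = x_1 + x_1 ⊙ g_2` (and
  symmetrically for image 2),
- four probability vectors from a single shared softmax classifier
  `p_i^j = softmax(W x_i^j + b)`.

The training objective is `L = L_CE + λ·L_RK`, where `L_CE` is the
cross-entropy summed over the four predictions and `L_RK` the score-ranking
hinge `Σ_i max(0, p_i^other(c_i) − p_i^self(c_i) + ε)`, which asks the
self-gated view of the true class to beat the other-gated view by at least
the margin ε. Defaults: λ = 1, ε = 0.005. At inference the interaction
block is dropped entirely: a single image is embedded and classified
directly, i.e. the conventional pipeline with contrastively trained
weights.

Both loss terms are defined per pair; over a batch of pairs we take the
mean (the alternative, summing, rescales the gradient with the number of
mined pairs and would entangle the learning rate with batch composition).

## Pair mining

The training set is randomly partitioned, stratified by class, into
batches of `per_class` images per class (default 20, i.e. batch 60 for
three classes). Within a batch, every image serves as an anchor and is
paired with

- the most *dissimilar* same-class image (intra-class pair), and
- the most *similar* image of each adjacent class present (inter-class
  pair): a score-4 anchor yields three pairs, scores 3 and 5 two each.

Similarity is the Euclidean distance between backbone embeddings
(`embedding` strategy), between raw pixel vectors (`raw`), or pairing is
uniform at random ignoring scores (`random`). Inter-class pairs never join
scores 3 and 5 under the distance-based strategies; under `random`,
non-adjacent pairings can occur by construction. Distance ties break
toward the smallest image id so mining is reproducible. Embeddings for
mining are recomputed with the current backbone in evaluation mode
whenever backbone parameters may have moved, and cached otherwise. A
trailing partial batch is kept only if every class in it has at least two
members; otherwise pair mining is ill-defined and the batch is dropped
with a warning.

Each anchor iterates over the full batch, and the same unordered pair may
appear twice with the roles swapped; this matches the per-anchor
construction of the mining rule.

## Training schedules

Two schedules are provided on top of a *finetuned* backbone (supervised
single-image training of backbone + temporary linear head, default 40
epochs; the head is then discarded):

- **frozen** — the backbone is fixed; only the interaction MLP and shared
  classifier learn (default 100 epochs, Adam, lr 5e-5, batch 60);
- **gradual** — the interaction block and classifier train alone for
  `frozen_epochs` (default 10) epochs, then all components train jointly.

Model selection keeps the checkpoint with the best validation accuracy
measured through the single-image inference path — the only sensible use
of the 25 % validation split, and it evaluates exactly the path that is
deployed.

Freezing is enforced at two levels: frozen parameters are skipped by the
optimizer *and* excluded from graph construction, so a frozen backbone is
bitwise unchanged by training (checksum-verified in the tests).

## Backbone

A backbone is any CNN with its classification head removed; the embedding
is the global average pool of the last convolutional feature map — the
standard cut point, and the form the interaction block requires (equal
length vectors). The bundled `tinycnn` needs no downloaded weights: a 2×
average pool (256 → 128 px) followed by four stride-2 3×3 convolution
blocks (16, 32, 64, d channels; d defaults to 64) and global average
pooling over the final 8×8 map. The light initial pooling halves the
resolution for CPU affordability while preserving the few-pixel cues that
separate score 4 from score 5 (an earlier 4× pooling variant lost them
and could not fit the training set on some seeds); the registry accepts
externally supplied feature extractors for larger architectures.

Finetuning defaults to lr 1e-3: `tinycnn` trains from random
initialization, where the 1e-4 regime customary for finetuning pretrained
networks is too timid to leave the chance plateau in 40 epochs.

## Synthetic clock drawings

The generator fabricates the three retained classes with graded,
documented deficits:

| class | number jitter (px) | hand-angle error (deg) | omitted numbers | stroke noise (px) |
|-------|--------------------|------------------------|-----------------|--------------------|
| 5     | 0                  | 0                      | 0               | 0                  |
| 4     | 6                  | 8                      | 0               | 0.6                |
| 3     | 10                 | 60                     | 2               | 1.2                |

The rendered hand-angle error is drawn as `±uniform(0.5, 1.0) ×
magnitude`, so the score-3 magnitude of 60° always produces a drawn time
that is wrong by at least 30°, while score-4 hands are off by at most 8° —
a minor deficit. All classes share small seed-driven "handwriting"
variability (circle radius, centre, digit size, hand length) independent
of the deficits, so distinct seeds give distinct images in every class and
score-4/5 drawings differ only subtly (their mean embedding distance is
smaller than the 3-vs-5 distance under any fixed backbone — the
fine-grained structure the method targets). Digits are seven-segment
stroke glyphs (no font dependency); the two digits of 10/11/12 are tied by
a connecting stroke so each number is a single ink component, which makes
omissions countable by connected-component labelling.

What the generator does *not* emulate: real handwriting stroke dynamics,
scanner artefacts, paper texture, clinical annotation marks, and the full
heterogeneity of abnormal clocks (perseveration, spatial neglect,
micrographia). Passing tests on this data demonstrate that the training
machinery behaves as specified, not that the scorer reaches clinical
accuracy on scanned drawings.

## Desk-scale reference experiment

`clockapi.experiments.desk_run` wires the pipeline end to end at a size a
single CPU core handles in a few minutes: 150 synthetic images (50 per
class), a 50/25/25 stratified split, 40 finetuning epochs (lr 3e-3,
batch 15), a classifier warm-start, 300 frozen-backbone pairwise epochs
(lr 3e-3), and a conventional comparator (identical finetuned starting
weights, plain cross-entropy on single images, same optimizer budget).

The warm-start deserves a note. Pairwise training only ever shows the
shared classifier gate-scaled attentive features `(1 + g) ⊙ x` with
`g ∈ (0,1)`, while inference applies the same classifier to plain
embeddings `x`. With a large pretrained backbone the two distributions
are close enough that this mismatch is harmless; with a small
from-scratch backbone and few classifier dimensions, training can satisfy
the pairwise losses through input-dependent gate patterns without ever
making `W x` itself discriminative, and the deployed path then
underperforms. Fitting `W, b` briefly on the raw embeddings (full-batch
Adam, 200 steps) before pairwise training anchors the classifier to the
inference-time distribution; pairwise training proceeds normally from
there. The learning rates are larger than the 5e-5 default because
nothing here is pretrained, and the run is sized to overfit its 75
training images (training accuracy ≥ 0.95) to demonstrate end-to-end
correctness of every gradient path.

## Augmentation

Brightness (additive, ±0.2), contrast (deviations from mid-gray scaled by
[0.8, 1.2]), shift (±10 % of side) and isotropic scale ([0.9, 1.1]), all
drawn uniformly per image; never a rotation or reflection, which would
change the time a clock reads. Borders exposed by shift/zoom-out are
filled with white, the paper background. Augmentation is applied online,
per epoch, to the training split only, and is off by default in the
desk-scale runs (the synthetic generator already provides per-image
variability, and augmentation forces per-epoch re-embedding, which
dominates runtime when the backbone is frozen).

## Score-CAM

Saliency maps are gradient-free: each channel of the last convolutional
feature map is bilinearly upsampled to input size, min-max normalized,
and used to mask the standardized input (all-zero baseline); the masked
inputs are forwarded through the deployed pipeline (backbone →
classifier) and the target-class logits collected. A softmax over these
logits weighs the upsampled maps; the map is the ReLU of the weighted sum,
min-max normalized to [0, 1]. The inspected layer defaults to the last
convolution block; masking happens after standardization because that is
the input distribution the model was trained on.

## Numerical choices

- Logarithms inside the losses are clamped at 1e-12 (gradient zero on the
  floor); irrelevant at operating scale, prevents −∞ on degenerate
  one-hot predictions.
- Sigmoid is evaluated in the numerically stable split form; softmax
  subtracts the row maximum.
- All gradients are produced by a small reverse-mode autodiff core written
  for this package and validated against central finite differences
  (element-wise ops, matmul, softmax, convolution, pooling).
- Network parameters are float32; gradient-check tests run in float64.
- He-normal initialization throughout; Adam with β = (0.9, 0.999),
  eps = 1e-8.
- The mutual MLP uses plain concatenation, so it is order-dependent; an
  optional `symmetric` mode averages both concatenation orders, and the
  swap-equivariance property is asserted only for that mode.

## Known limitations

- Only `tinycnn` ships with the package; VGG/ResNet/DenseNet backbones
  require an external feature-extractor plug-in and pretrained weights.
- The binary score-4-vs-5 task is supported through configuration
  (`classes=(4, 5)`, `num_classes=2`) but the bundled experiments exercise
  the three-class task.
- Cross-strategy statistical comparisons (ANOVA, paired t-tests) are out
  of scope; `repeated_runs` exposes the per-run metric table needed to
  perform them externally.
- Synthetic-data results do not transfer to claims about scanned clinical
  drawings; see the generator's non-goals above.
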