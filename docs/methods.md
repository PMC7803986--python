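# Methods

## Model

The segmentation network is a fully-convolutional encoder–decoder.  With
depth *d* and base filter count *f*, the encoder has *d* blocks of two 3×3
same-padding convolutions (leaky ReLU, slope 0.01) followed by 2×2 max
pooling, doubling filters per level; a two-convolution bottleneck at
*f·2^d* channels is the deepest encoder activation and the feature tap for
class prototypes; the decoder mirrors the encoder with nearest-neighbour ×2
up-sampling plus a 2×2 "up-convolution", skip concatenation and two 3×3
convolutions, halving filters per level.  A 1×1 convolution maps the top
decoder features to C per-pixel class scores, normalised by softmax.  At
the full-scale configuration (256×256 input, f = 32, d = 5) this counts 28
convolutional layers with an 8×8×1024 bottleneck; d = 4 reproduces the
classic 23-convolution architecture.

Same-padding is used throughout so predictions are input-sized (no
crop-and-copy).  Leaky rather than plain rectification is a deliberate
choice for curriculum training: a coarse stage with few classes can turn
feature channels off, and a strictly-zero rectifier would make them
unrecoverable by gradient in later stages.

Everything (forward, backward, Adam) is plain numpy in float32, so training
is deterministic given the seeds.  Backward passes are verified against
float64 numerical differentiation in the test suite.

Initialisation is seeded He-normal.  Zero initialisation of all weights is
not usable for training — every unit in a layer would receive identical
gradients and the symmetry never breaks — so the package uses the standard
scheme wherever a network is built from scratch.

## Loss, metrics, optimisation

The loss is per-pixel categorical cross-entropy: the truth-weighted log of
the softmax prediction, reduced to a *mean* over pixels so reported values
are comparable across patch sizes (a uniform prediction over c channels
scores ln c).  Accuracy is the fraction of pixels whose argmax channel
equals the true label.  The optimizer is Adam with its published defaults
(lr 10⁻³, β₁ 0.9, β₂ 0.999, ε 10⁻⁸) as `TrainingConfig` defaults; the
scaled-down experiments pass lr 3·10⁻³ explicitly because they run a few
hundred optimizer steps in total (roughly two orders of magnitude fewer
than a full-scale training) and the default rate leaves both training arms
deep inside their initial transient; 10⁻² was observed to diverge.

## Curriculum construction

Class prototypes are one row per class: bottleneck volumes of k = 3 sampled
patches per class are reduced per channel by global average pooling (1024
features at full scale) and averaged.  Raw depth-wise serialisation is
available behind the `feature_origin` tag; the global-average default is
what makes "1024 variables per class" exact.  For wide backbone features a
depth-wise reduction first rearranges the (H′, W′, D) volume into an
(H′·W′ × D) matrix, projects the D columns onto the top 50 principal axes
fitted on that same matrix, and serialises row-major (so (32, 32, 4096)
gives 51 200 instead of 4 194 304 features).  Whether to cluster raw
prototypes or their PCA scores is configurable; the default clusters PCA
scores.

Agglomerative clustering defaults to Ward linkage with Euclidean distance
(stable, balanced groups for curriculum use); single/complete/average with
other metrics are accepted.  Cuts are taken just below each of the k
greatest *distinct* link heights, with tied links severed together; a
partition into n clusters becomes a stage with C = n + 1 labels (background
is never clustered and is fixed at label 0 in every stage), and an identity
stage over the full class set is appended.  Because tied heights can make a
cut much finer than k + 1 clusters, explicit per-stage target cluster
counts are also supported (the coarsest cut reaching the count is used).

## Sequential training

One network is carried through the stages.  At each stage the classifier
head is replaced at the new width C and masks are remapped through the
stage's table; training stops early once validation accuracy reaches the
90% target, else at the stage's epoch budget.  The full-scale schedule is
C = 3, 4, 5, 17, 66 with budgets 10, 10, 10, 10, 20 (60 epochs);
the desk-scale schedule is the two-stage analogue
(families + background, then all classes + background) with the final
stage receiving the larger budget.

A replacement head is drawn from its seed but scaled by 0.01: a
full-magnitude draw on top of trained (large-magnitude) features produces
confidently wrong initial predictions whose gradients, under a freshly
reset Adam, measurably damage the carried encoder before the head aligns.
`run_stl` additionally offers `head_init="inherit"`, which warm-starts each
fine-stage channel from its parent cluster's head channel (plus seeded
jitter to break the sibling tie), so a stage begins *at* the coarse
solution.  The scaled-down experiments use this mode: with ~27 optimizer
steps per epoch a fresh head cannot re-align within the first epoch,
whereas a full-scale epoch (361 steps) can, and the warm start restores the
stage hand-off behaviour that the method relies on.

## Synthetic fixture

The generator emulates tray photographs structurally, not photometrically:
a gray background, one superelliptical food-like region per bounding box,
one class per region.  Classes are organised into families: family base
colours sit on a chroma circle of radius σ_b (`family_color_spread`,
default 60 eight-bit units) in the constant-luminance plane of RGB, and
each class adds a Gaussian offset with σ_w (`class_color_spread`, default
6), so within-family distances are an order of magnitude smaller than
between-family distances (σ_b = 10 σ_w) and the designed hierarchy is
recoverable from colour statistics alone.  Band-limited texture (low-
resolution noise up-sampled at the configured spatial scales) and iid pixel
noise are added per blob.  Blobs are placed one per jittered grid cell, so
they never overlap and packing is feasible by construction; class
assignment cycles through seeded permutations, making class frequencies
uniform to within one count and guaranteeing coverage.

What the fixture does *not* emulate: real food texture statistics,
illumination and shadow, occlusion and touching regions, annotation noise,
class imbalance, and intra-class variability beyond colour/texture jitter.
Tests passing on this fixture validate the pipeline's mechanics and the
curriculum machinery, not full-scale food-recognition accuracy.

## The scaled-down study

`stlseg.experiments.run_study` pairs, per seed, a sequential run (budgets
[2, 6], head warm start, early-advance at 90% validation accuracy) against
a conventional run at the matched total budget (8 epochs) on the default
3×3-family fixture: 20 training trays (160 patch–mask pairs after flips,
128/32 train/validation) and 18 test trays (36 patches), base-8 depth-3
network on 64×64 patches, batch 6.  Reported per seed: family-recovery
adjusted Rand index, final test loss/accuracy of both arms, the final
stage's first-epoch training accuracy against the conventional first-epoch
accuracy (the "better start" comparison), epochs actually consumed, and
definiteness summaries at the strict 0.75 hit-ratio threshold.

Problem sizes were chosen so the whole multi-seed study runs in a few
minutes on one CPU.

## Known limitations

* At desk scale the curriculum's accuracy benefit is not reproduced: the
  coarse stage commits the tiny network's 8-channel head representation to
  family-level distinctions, and the fine stage then stalls near the
  family-solution level (family-level accuracy above 0.95 while sibling
  classes remain near chance).  Control experiments locate the effect in
  the coarse *labels*, not the restart mechanics: pretraining on the fine
  task itself and restarting (head swap + fresh optimizer) transfers
  positively.  Consequently, at matched short budgets the two arms are
  statistically even (the sequential arm is the more consistent one, the
  conventional arm occasionally escapes its transient early and wins), and
  at long budgets the conventional arm is ahead.  The robust desk-scale
  signatures of the method are the better start of the final stage and the
  early-epoch advantage, not final-accuracy parity; reproducing the
  full-scale accuracy gain appears to require capacity and per-stage step
  counts far beyond a desk-scale run.
* Hit ratios measure only target-class recall within single-class patches;
  background precision is deliberately excluded.
* The numpy network is CPU-bound; full-scale configurations build and run
  forward passes but are not practical to train.
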