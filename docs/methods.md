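# Methods

This note records the scientific and numerical choices behind the
package: what the model and pipeline compute, where the design was
genuinely open and what was decided, and what the synthetic phantoms do
and do not establish.

## Architecture

The classifier is a lightweight CNN for single-view grayscale bone
radiographs. Grayscale input is replicated to three channels so the
preprocessing contract matches ImageNet-style models, and normalised
with the ImageNet statistics (μ = [0.485, 0.456, 0.406],
σ = [0.229, 0.224, 0.225]).

The layer graph is declarative (`ArchConfig`): a two-conv stem at full
resolution (3×3, 32 then 64 filters), two residual depthwise-separable
blocks (64→128 and 128→256, stride 2 each), a 1×1 refinement block, a
multi-scale aggregation module (parallel 1×1/3×3/5×5 branches, 256→128
each, concatenated to 384 and fused back to 256 by a 1×1 conv), global
average pooling, and a 256→512→K fully connected head with dropout
p = 0.3. Softmax is applied only at prediction time; the loss consumes
logits for numerical stability.

Several micro-architectural details are not fixed by the block-level
description above; the package resolves them as follows and treats them
as part of its own design:

* **Ordering inside a separable block**: depthwise conv → BN → ReLU →
  pointwise conv → BN, add the shortcut, final ReLU — the same
  conv→BN→ReLU idiom as the stem.
* **Shortcut across a channel/stride change**: a projection (1×1 conv
  with the block's stride, plus BN). An identity shortcut across
  64→128 with stride 2 is impossible, so a projection is the only
  faithful reading of "residual shortcut" there.
* **Stride placement**: on the depthwise convolution, keeping the 1×1
  pointwise at the reduced resolution (the standard separable-block
  choice and the cheaper one).
* **The 1×1 refinement block** carries no residual: it is a plain
  conv→BN→ReLU.
* **Biases**: convolutions followed by BatchNorm have no bias (the BN
  affine makes it redundant); fully connected layers keep biases.

With the defaults this yields exactly 1,553,769 trainable parameters.
Parameter-count figures of both "1.52 M" and "1.9 M" circulate for
networks described at this block level; the closed-form count for the
graph as specified lands at ≈1.55 M depending only on the
shortcut/normalisation choices above, so the profiler reports the exact
number and the package asserts only the ≤1.9 M budget plus a
1.45–1.65 M sanity band around the hand-derived sum.

## Implementation of the network

No GPU tensor framework is a dependency: layers, backward passes, the
Adam optimiser and the softmax cross-entropy are implemented directly
in NumPy (`bonecnn.nn`, float32, im2col + BLAS matmul for
convolutions). This keeps the package self-contained and makes the
arithmetic fully inspectable. Correctness is pinned by central
finite-difference gradient checks (run in float64) for every layer type
and for the assembled network, and by bitwise-determinism tests for
evaluation-mode forward passes.

## Complexity profiling

Parameters and multiply–accumulates are computed closed-form from the
config: a standard convolution contributes k²·C_in·C_out parameters and
that times H_out·W_out MACs; a depthwise convolution k²·C and
k²·C·H_out·W_out; BatchNorm 2C parameters and no MACs (foldable affine
at inference); a fully connected layer n_in·n_out(+bias) parameters and
n_in·n_out MACs. Two independent routes must agree exactly: the
analytic schedule walk, and a measurement pass that runs the real
network and reads each convolution's recorded output shape
(`count_macs` raises on any disagreement). FLOPs are reported under
both conventions (MACs and 2×MACs) because usage in the literature is
split. The closed-form total at 224×224 is ≈5.50 GMAC — dominated by
the full-resolution 64-channel stem (≈0.93 GMAC for its second conv
alone) and the 5×5 aggregation branch at 56×56 (≈2.57 GMAC) — so a
0.48 GFLOPs figure cannot be produced by this graph at this input size;
the profile says so in its notes rather than asserting it.

## Data handling

Manifests (CSV: path, class_index, class_name, split, origin,
source_image, seed) are the single source of truth. Splitting is
image-level (the benchmark this pipeline targets has no patient IDs)
and stratified at 70/20/10: per class, records are shuffled with the
split seed and cut by floor allocation plus largest-remainder
correction, guaranteeing every subset is within one image of n·f. Note
that no single rounding rule reproduces every row of a hand-made split
table exactly (different classes can round in different directions), so
the package asserts the ±1 stratification property, not cell-exact
agreement with any published per-class table. K-fold planning deals
shuffled records to folds cyclically with a cursor that continues
across classes, so per-class and overall fold sizes both differ by at
most one.

Augmentation happens strictly after splitting and only on the train
partition; augmented records are structurally forbidden (a validated
invariant of `ImageRecord`) from carrying any other split, so
validation and test sets contain original images only.

## Augmentation family

Per augmented copy, all five transforms are drawn from a seeded stream
and applied in a fixed order: CLAHE → rotation (uniform in ±12°) →
horizontal flip (p = 0.5) → translation (uniform per axis, bounded
strictly below 5% of each dimension) → gamma correction (exponent
uniform in [0.8, 1.2], a "slight" perturbation range chosen to preserve
mineralisation patterns; configurable). Contrast equalisation precedes
the geometric ops so tile histograms are computed on uninterpolated
intensities; geometric borders use edge replication to avoid black
wedges a network could exploit as class signal. Class balancing
distributes target − current copies as evenly as possible over a
class's training images (multiplicities differ by at most one, the
remainder assigned by a seeded draw).

CLAHE is implemented directly (per-tile histograms at 256 levels,
clipping at clip_limit × tile_pixels/256 with uniform redistribution of
the excess, per-tile mappings cdf/n, bilinear interpolation between
tile centres). The defining degenerate case — one tile, no clipping
equals global histogram equalisation at the same quantisation — is an
oracle test against a brute-force per-pixel CDF.

Resizing is plain bilinear to the square target, i.e. anisotropic for
non-square inputs; an aspect-preserving pad-then-resize is available
behind a flag but off by default, matching the standard ImageNet-style
preprocessing the three-channel contract implies.

## Training procedure

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) at base rate 1e-4, batch size 8,
categorical cross-entropy on logits, at most 60 epochs. The schedule is
cosine annealing with warm restarts,
η = η_min + ½(η_base − η_min)(1 + cos(π·t/T)); the restart period
(T₀ = 10 epochs), period multiplier (2) and floor (η_min = 0) are
package defaults — the shape of the schedule is specified, its period
is not, and these are common values. The learning rate is held constant
within an epoch (the schedule is stepped per epoch).

Early stopping watches validation loss with patience 8; any decrease
resets the counter, and the weights of the minimum-validation-loss
epoch are what training returns (and checkpoints, as .npz plus a JSON
sidecar recording the architecture config). Epoch-level training
metrics are running averages over the minibatches as the weights move;
validation metrics come from a clean evaluation-mode pass. Mixed
precision exists as a config flag for API completeness but is a no-op
in this NumPy implementation, which is CPU float32 throughout.

Diagnostics: the overfit gap is final validation loss minus final
training loss; epoch-to-plateau is the first epoch after which the
running-minimum validation loss never again improves by ε = 1e-3.

## Evaluation

Hard predictions are the argmax of softmax probabilities, ties broken
toward the lowest class index for deterministic reports. Precision,
recall and F1 are per class from the confusion matrix, with zero
denominators yielding 0 plus a warning; macro averages are unweighted,
weighted averages use supports. AUC is the Mann–Whitney rank statistic
(ties credited half) per class one-vs-rest; the macro average excludes
classes with no positives or no negatives (with a warning), and the
micro variant pools the (score, indicator) pairs of all classes before
ranking — a construction chosen and documented here because "micro AUC"
is not uniquely defined in the literature. The rank route is tested
against exhaustive pair counting on all small inputs and against an
independent library implementation.

Cross-validation reports the arithmetic mean and sample standard
deviation (ddof = 1) of each metric across folds. The
accuracy-vs-complexity composite is
w·(acc/acc_ref) + (1−w)·(params_ref/params), clipped to [0, 1], with
w = 0.5 by default; published "normalised scores" for model families of
this kind are typically not reverse-engineerable to a unique formula,
so the package's score is explicit and recorded wherever reported, and
no attempt is made to match any externally printed score values.

## Phantom generator

The generator emulates the structure of a long-bone radiograph — soft
tissue, bright cortical stripes, darker medulla with faint trabecular
texture — and stamps one class-keyed lesion motif (lytic disc with
sclerotic rim, moth-eaten lucencies, ground-glass patch, exostosis,
sunburst spicules, onion-skin laminations, expansile thinned cortex,
punctate calcifications, horizontal striations), followed by Gaussian
blur (σ = 1 px) and additive Gaussian noise (σ = 0.03). Lesion contrast
defaults to 0.35 against a 0.55 medulla; the trabecular texture
amplitude (0.04) is kept well below half the lesion contrast so lesion
structure dominates. Classes 1 and 2 are intentionally confusable
(small lucencies vs ground-glass texture) to exercise confusion-matrix
reporting. Motif parameters depend only on (class, seed, image index),
never on generation order.

What the phantoms establish: that the full pipeline is correct,
deterministic, and able to learn — a linear probe on raw pixels beats
chance, the network overfits 32 images to 100% training accuracy within
200 gradient steps, and a short end-to-end run (20 images/class at
64 px, 10 epochs) clears three times the chance rate on its held-out
split. What they do not establish: anything about clinical radiographs.
Real radiographs have anatomy, projection geometry, detector and
exposure variability that the phantoms make no attempt to model, so
passing tests here say nothing about diagnostic performance.

## Problem sizes used in tests

The routine suite trains at 32–64 px with tens of images — the sizes at
which the package's own capacity and determinism claims are stated.
Cross-validation is exercised at k = 5 on a 90-image phantom set with
single-epoch folds: enough to pin the fold-accounting and aggregation
contracts, which do not depend on the per-fold model being converged.
Full-scale training (224 px, thousands of images, 60 epochs) uses
exactly the same code paths and is what the CLI defaults describe, but
reproducing published accuracy on the real nine-class radiograph
benchmark requires the external dataset and training-scale compute, and
is out of scope for the test suite.

## Known limitations

* The NumPy network is single-threaded CPU code; it is meant for
  correctness and desk-scale experiments, not production training
  throughput.
* CLAHE quantises to 256 levels regardless of source bit depth.
* The cross-validation driver re-trains from scratch per fold with
  seed offset by fold index; fold results are therefore not variance
  estimates of a single initialisation.
* `mixed_precision` is accepted but inert (see above).
* Manifest CSV reconstruction of class names requires every class to
  appear in at least one record; empty classes survive a round trip
  only by position.
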