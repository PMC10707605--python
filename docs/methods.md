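# Methods

## Model

The clustering model is a convolutional autoencoder with a softmax
classifier head between encoder and decoder.

**Encoder.** Stacked stride-2 convolutions (kernel 4, padding 1), each
followed by a leaky rectifier (slope 0.1) and, in the full-size
profile, a refining stride-1 3×3 convolution; channel widths grow
through the plan (15, 45, 128). The final feature map is flattened and
projected linearly to the upper latent space of dimension D (default
196). Inputs larger than the encoder's working side can be downscaled
first (`input_rescale`); 128-pixel patches are downscaled to 64 so one
architecture depth serves both published patch sizes. The downscale is
a 2×2 block mean for integer factors (identical to bilinear averaging
at factor 2) and bilinear interpolation otherwise.

**Classifier.** A dense stack D → 128 → 64 → K with leaky rectifiers
and a final softmax, so each patch gets a distribution over the K
clusters (the lower latent space / soft assignment).

**Decoder.** The concatenation [upper, lower] (width D + K) is
projected to the deepest feature map and upsampled by stride-2
transposed convolutions (kernel 4, padding 1) mirroring the encoder,
ending in a sigmoid so reconstructions live in (0, 1) like the
normalized inputs.

The published layer inventory gives hidden sizes (15, 45, 128, 196,
n_c), kernels {1, 3, 4}, strides {1, 2} and paddings {0, 1} but not the
exact per-layer arrangement; the arrangement above is consistent with
that inventory and is fully config-driven (`ModelConfig`), so
alternative stacks can be swapped in without code changes.

## Objective

With soft assignments P = {p_θ(y|x_i)} for a mini-batch:

* conditional entropy `H(Y|X) = (1/N) Σ_i h(p_θ(y|x_i))`;
* marginal entropy `H(Y) = h((1/N) Σ_i p_θ(y|x_i))`, estimated per
  mini-batch;
* `h(p) = −Σ p log p` in nats, with 0·log 0 = 0 and an ε = 1e-12 floor
  inside logarithms;
* reconstruction `L_recon` = mean squared error over all elements of
  the batch against the (possibly downscaled) input;
* affine consistency `L_AF` = mean over the batch of
  `D_KL(P_row ‖ Q_row)`, where P are the assignments of the originals
  (the reference) and Q those of their affine-transformed copies;
* total `L = L_recon − (λ_ME·H(Y) − λ_CE·H(Y|X)) + λ_AF·L_AF` with
  defaults λ_ME = 0.1, λ_CE = 0.03, λ_AF = 0.03.

With λ_ME = λ_CE = λ the objective is exactly "regularizer − λ·I(X;Y)",
the regularized-information-maximization form; the split weights
generalize it and the split form is authoritative here.

Maximizing H(Y) forbids the degenerate solution that puts every patch
in one cluster; minimizing H(Y|X) pushes each patch to a confident
assignment; the KL term makes assignments invariant to mild geometric
perturbation; reconstruction keeps the latent space informative about
the input.

## Augmentation

One affine copy per sample per batch: rotation, translation and
scaling sampled uniformly from angle ∈ [−30°, 30°], per-axis shift ∈
[−10%, 10%] of the side, scale ∈ [0.9, 1.1] (ranges are config-exposed;
the magnitudes are chosen mild enough to preserve class identity, since
no published ranges exist). All channels of a patch share one
transform, preserving stain co-registration. Interpolation is bilinear
with reflected borders; the batched warp kernel is verified against
scipy.ndimage's affine transform to interpolation precision. The copy
is produced at the encoder's working resolution (after the optional
downscale): the consistency penalty compares classifier outputs, which
only ever see the downscaled input, and warping at working resolution
is both equivalent in effect and substantially cheaper. Only shear is
excluded (the transform family is rotation/translation/scale).

## Training

Adadelta (ρ = 0.95, ε = 1e-6) over whole-dataset per-epoch shuffles;
a trailing short batch is dropped to keep the per-batch marginal-entropy
estimate stable. Parameters use fan-in-scaled uniform initialization
from a seeded generator; the seed fixes initialization, shuffling and
the augmentation stream, so runs are bit-reproducible. A non-finite
loss aborts with a diagnostic of all components. Per epoch the history
records the mean reconstruction, H(Y), H(Y|X), affine KL, total and
mutual information.

Two profiles ship:

* **full-scale profile** — full architecture, 4000 epochs (128² patches) or
  3000 (64²), batch 100, learning rate 0.003, sweep K ∈ 8…18. At 150
  batches per epoch this is roughly half a million optimizer steps; it
  is the published configuration and is not intended for a single-CPU
  desk run.
* **desk profile** — reduced architecture (working side 16 after
  downscaling 32² inputs, channel plan (16, 32), D = 32, one conv per
  stage), 600 patches, 300 epochs, batch 25, learning rate 5.0, sweep
  K ∈ {3, 4, 5}. The smaller batch and larger step size compensate for
  the ~300× smaller step budget: the softmax head starts near the
  uniform distribution, which is a stationary point of both entropy
  terms, and escaping it within 300 epochs requires enough sufficiently
  large optimizer steps. With batch 100 and small steps the mutual
  information stays pinned at 0 for the whole desk budget; with batch
  25 and step size 5.0 the head reliably escapes and the three
  benchmark seeds all reach ARI 1.0 on the 4-class recovery task.

## Synthetic data

The generator emulates the structure of co-registered multi-stain
patches: each latent class is a texture field (stripe frequency and
orientation plus Gaussian blobs) and one field realization per patch is
rendered through `n_stains` stain-specific color transfers
(light backgrounds, stain-like foregrounds), giving 3×n_stains channels
that share one geometry. Class color offsets are pairwise-orthonormal
directions in the 3·n_stains-dimensional color space scaled linearly by
`separation`, so inter-class distance is controlled and symmetric
rather than left to chance; texture parameters are modulated by the
bounded factor separation/(1+separation). At separation 0 all classes
are statistically indistinguishable; class distinguishability (e.g.
silhouette on per-channel pixel means) grows monotonically with
separation. Labels are assigned round-robin then shuffled, matching the
balanced-cluster regime the marginal-entropy term rewards. Gaussian
pixel noise (`noise_sd`, default 0.05) is added before clipping to
[0, 1]. Defaults (4 classes, 600 patches, 32², 5 stains, separation 3,
noise 0.05) are the desk benchmark conditions.

What the generator does *not* emulate: histologically realistic nuclei
or stroma, stain-deconvolution physics, spatial correlation between
neighboring patches, slide-level artifacts (folds, blur, pen marks) and
class imbalance. Passing the recovery benchmark therefore shows the
pipeline's machinery is correct and that information maximization
recovers well-separated balanced classes; it does not certify
performance on clinical slides.

A synthetic whole-slide image places one generated tile per entry of a
known class map; re-cutting it with the sequential tiler recovers the
tiles pixel-exactly, which is the basis of the end-to-end cluster-map
test.

## Cluster-count selection

Each candidate K is trained separately; its clustering is scored in
the model's own upper-latent space (D-dimensional embeddings, argmax
labels) by the six indices. Design notes:

* Euclidean distance and arithmetic-mean centroids everywhere; every
  index raises on K < 2, an empty cluster, or a degenerate geometry
  (coincident centroids, zero within-cluster scatter) rather than
  returning an infinity.
* Xie-Beni is the crisp form by default — the published score
  magnitudes (tens to hundreds) are consistent with the crisp, not the
  normalized fuzzy, variant; the fuzzy form with squared memberships is
  available when soft assignments are supplied.
* Hartigan is the log-of-ratio form ln(SSB/SSW), matching the published
  description and the presence of a negative score in the published
  grid; the incremental rule-of-thumb variant is not implemented.
* Dunn follows the standard definition, which is unbounded above (a
  two-cluster line already gives 9); descriptions bounding it by 1
  refer to a different normalization.
* Per-column ties go to the smallest cluster count and are flagged;
  the vote histogram always sums to the number of columns.
* For very large N an optional recorded-seed subsample bounds the
  O(N²) pair computations (off by default).

All six implementations agree with naive all-pairs/all-points reference
implementations to 1e-9 relative tolerance on randomized instances, and
the selection logic reproduces every per-index choice and the 14-cluster
vote on the published index grid shipped with the package.

## Problem sizes

The shipped experiments are sized for a single CPU: recovery and
model-selection use 600 patches of 32², the reduced model and 300
epochs per run (about 1.5 minutes each); the acceptance script runs one
seed's sweep over K ∈ {3, 4, 5}, and the test suite repeats the sweep
for three seeds. The published full-scale configuration (15000 patches,
128²/64², thousands of epochs) is expressible with the same code via
the full-scale profile but is a cluster-scale computation; its published
index grid is included as data so the selection logic can be exercised
against the full-scale outcome.

## Numerical choices

float32 forward/backward passes (float64 in the metric-only paths);
ε = 1e-12 log flooring; softmax computed with max subtraction;
argmax ties resolved toward the lowest cluster index; gradient
correctness of every autodiff primitive verified against central finite
differences; the numba convolution kernels verified against a pure
NumPy reference implementation.

## Known limitations

Training on a CPU autodiff engine is orders of magnitude slower than a
GPU framework, so full-scale runs are impractical here; index
computation is O(N²) in memory/time without subsampling; UMAP is an
external routine treated as a black box (its layout is for inspection,
not measurement); the desk profile's recovery guarantees apply to the
synthetic benchmark regime, not to clinical data.
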