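# Methods

This note records the scientific and numerical choices behind `foliar`: the
models implemented, the parameters that matter, what the synthetic
generators do and do not emulate, and the places where the published
description of this pipeline family is ambiguous and a concrete reading had
to be chosen.

## Haze-model restoration

The observed image is modeled as `I(X) = J(X) t(X) + L (1 − t(X))` with
scene radiance `J`, global atmospheric light `L` and per-pixel transmission
`t`. The dark-channel prior — haze-free outdoor patches contain a pixel
whose channel minimum is near zero — yields the estimates

* dark channel: minimum filter (window `patch` = 15, odd) over the
  per-pixel channel minimum;
* atmospheric light: mean color of the brightest 0.1 % of dark-channel
  pixels (at least one pixel);
* transmission: `T = 1 − ω · dark(I / L)` with haze retention ω = 0.95
  (retaining 5 % haze is the standard perceptual choice; ω = 1 makes the
  estimator exact on scenes with a zero dark channel);
* recovery: `J = (I − L) / max(T, t₀) + L`, floor t₀ = 0.1, clipped to
  [0, 1].

**Static-offset variant.** The recovery is sometimes written with a fixed
scalar offset a = 0.2 in place of `L`. That form does not invert the haze
model: substituting the forward model gives a residual error
`(L − a)(1 − t) / t`, which for white atmospheric light exceeds the haze
distortion itself at every `t` in [0.3, 0.9]. We therefore default to the
atmospheric-light offset (which our inversion tests verify) and expose the
static form as `recover_radiance(..., offset=a)` and
`HazeConfig(static_recovery=True)` for fidelity with that written variant.

**What a green inversion test establishes.** The dehazing tests use a
synthetic scene whose dark channel is identically zero (fully saturated
colors) with a white highlight large enough to contain one full
dark-channel window. Real leaf photographs violate both assumptions to
some degree (no sky region; leaf/soil channel minima around 0.15–0.3), so
restoration on real images carries a bias proportional to the scene's true
dark channel. This is a property of the dark-channel prior, not of the
implementation.

## Bi-histogram equalization (BiHE)

Luminance is Rec. 601 (`0.299 R + 0.587 G + 0.114 B`); chrominance is
preserved by scaling RGB with the per-pixel luminance ratio, since
equalizing channels independently would shift hue. The 256-bin luminance
histogram is smoothed with a Gaussian of σ = 3 bins; local maxima (plateau
ties resolved to the leftmost bin; peaks closer than 8 bins merged keeping
the higher) define the modes, and the axis is cut at the minimum bin
between consecutive maxima. Each sub-histogram is equalized independently
onto its own input span — a proportional dynamic-range allocation, chosen
so that a uniform single-mode histogram maps near-identically — and the
output mean luminance is rescaled to the input mean (preserved to within
0.02 even after clipping, which the tests assert). A constant image has no
partition and is returned unchanged. Enhancement is not idempotent and is
not claimed to be.

## Architecture accounting

Both builders follow their published block structure exactly: BRwSA has a
32-wide stride-2 stem, four groups of parallel bottleneck paths
(5/5/5/3 paths with widths 32→128→32, 128→256→64, 256→512→128,
512→512→256; ReLU + batch-norm after the first two convolutions of each
path), identity skips into the addition nodes, stride-2 transition
convolutions of depth 64/128/256, and a tail of conv-512/ReLU, 3×3 stride-2
max-pool, conv-1024, global average pool, flatten, self-attention, and the
classifier head. IBRwSA mirrors this with five-path inverted bottlenecks
(expand 64/128/256/512, channel-wise 3×3 grouped convolution, squeeze
32/64/128/256) and a conv-512/ReLU/batch-norm tail.

**Layer convention.** Every node — including input, ReLU, batch-norm,
addition, flatten, attention, softmax and the classification output —
counts as one layer. Under this convention the builders enumerate exactly
149 and 161 layers, which requires two asymmetries that the published
enumerations themselves carry: the BRwSA 1024-deep tail convolution has no
ReLU, and IBRwSA terminates at its softmax with no separate
classification-output node.

**Learnable counting.** Convolution `k²·c_in·c_out/groups + c_out`
(channel-wise grouped convolution: `k²·c + c`), fully-connected
`in·out + out`, batch-norm `2·c` (scale and shift; running statistics are
not learnables), attention as below. The text-pinned backbones then carry
22,384,516 (BRwSA) and 3,387,365 (IBRwSA) parameters.

**Attention sizing.** The attention layer is single-head scaled
dot-product over the pooled feature vector (width c = 1024 or 512) with a
full-width value projection. The two reference totals, 23.6 M and 3.9 M,
require the attention layers to contribute ≈ 1.18 M and ≈ 0.53 M
parameters — i.e. ≈ 1.16 c² and ≈ 1.96 c². No parameterization that scales
homogeneously with c can produce both coefficients, so the sizing is
per-model: BRwSA projects queries and keys to c/16 = 64 key channels
(the SAGAN-style key reduction) giving
2·(64·1024 + 64) + 1024² + 1024 = 1,180,800 and a total of 23,565,316
(→ 23.6 M); IBRwSA shares one full-width query-key matrix giving
2·(512² + 512) = 525,312 and a total of 3,912,677 (→ 3.9 M). Regression
tests pin all four totals.

Because the pooled representation is a single token, the attention weight
is identically one and the layer's output equals its value projection; the
query/key projections are genuine learnables of the layer but receive no
gradient. The feature tap point is this layer's output (N×1024 / N×512).

**Runtime.** Graphs execute on a numpy backend (same-padding convolutions
via grouped matrix products over sliding windows, `floor((H+2p−k)/s)+1`
output sizes). Initialization is He-normal, with layers feeding a k-way
addition attenuated by 1/k so that the summed parallel-path variance stays
comparable to the identity skip — without this the four stacked five-path
blocks multiply the activation variance and full-precision training
diverges immediately. Reduced-scale builders (same topology, scaled widths,
smaller input) exist so the training path is testable on CPU in seconds;
the full-size builders remain the reference for all counts.

## Training, extraction, fusion

Splits are stratified per class with `floor` rounding (10 → 6/1/3,
100 → 60/10/30); the alternative 70:30 protocol is available through
`TrainConfig.split`. Training is plain SGD with classical momentum
(defaults lr 2e-4, momentum 0.702, batch 64, 100 epochs, constant
schedule); determinism is a contract of the seed on a fixed backend.
Divergence (non-finite loss) raises an error carrying the epoch.
`tune_hyperparameters` can search a small discrete grid with the HLO
machinery, reflecting that these defaults were themselves reported as the
product of such a search; the search space is not published, so only the
found values are defaults. Feature fusion is column concatenation with
provenance tags preserved.

## Improved binary HLO

Each of n = 10 individuals is a bit-mask over the m feature columns.
Per generation, every bit of a candidate is drawn by rate
(pr = 0.1 random exploration, pi = 0.85 individual-learning threshold): an
IL bit copies from a uniformly chosen member of that individual's IKD
(size g = 3), an SL bit from a uniformly chosen member of the global SKD
(size h = 3); databases are kept sorted by cost, bounded, and
bit-deduplicated. An individual whose personal best has not improved for
10 generations relearns: its IKD is cleared and re-seeded with a fresh
evaluated random solution (the SKD is untouched, so the global best trace
is non-increasing by construction — asserted on every run).

The wrapper cost is `0.82 · (1 − acc) + 0.02 · (selected/m)` where `acc`
is a k = 10 nearest-neighbor accuracy (Euclidean, on columns z-scored by
training-part statistics) on a 30 % holdout drawn once per run, so the
fitness landscape is fixed within a run. An all-zero mask is assigned the
worst error (cost 0.82) rather than resampled, keeping the fitness total.

**Bayesian refinement.** The "improved" final-selection step is only cited
in the source literature, never specified; our concrete reading places a
per-bit Beta(1, 1) posterior over inclusion, updated with the SKD members
weighted by rank (best member weight h, worst weight 1), thresholds the
posterior mean at 0.5, and falls back to the best SKD member whenever the
thresholded mask scores worse. With `iterations = 0` the refinement is
skipped and the best initial SKD member is returned.

**Leakage.** The reference flow selects features on test-partition
features; `select_features` operates on whatever matrix it is given, and
the documented recommendation is to pass training-partition features
(`HloConfig.leakage_safe` marks that intent in configs).

**Signal-recovery check.** On the 40-column fixture (5 informative, 10
redundant copies, 25 noise), "recovering" an informative signal means
selecting the informative column *or any of its redundant copies*: the
copies correlate ≥ 0.99 with their sources, so they are statistically
interchangeable, and the feature-count penalty makes retaining all 15
near-duplicates the wrong optimum rather than the target. Mean coverage
over 5 seeds is asserted ≥ 0.8 (observed 1.0).

## Shallow classifiers and metrics

The published layouts are followed as printed — SWNN [10], MN2 [25],
N3 [100], BiN2 [100, 100], TiN2 [100, 100, 100] — although the source text
is internally inconsistent about the wide network's width ("wide" yet ten
neurons) and about the bi-/tri-layered layouts; the layouts are
constructor arguments for users who prefer another reading. Training is
full-batch L-BFGS (max 1000 iterations, tol 1e-6, seeded). Cross-validation
is stratified k-fold (default 10), with `folds = N` falling back to
leave-one-out; out-of-fold predictions are pooled into a single confusion
matrix. Metrics are macro averages of per-class TPR (diag/row sum), PPV
(diag/column sum), F1, and FPR (off-diagonal column mass / negatives);
zero-denominator classes contribute 0 with a warning. AUC for K > 2 is
one-vs-rest macro over pooled softmax scores (the single reported AUC in
this family of results is not given a definition; this is the standard
multiclass choice). Wall-clock time is logged but is explicitly not an
acceptance quantity.

## Synthetic fixtures

`make_leaf_images` renders a textured soil background, a jittered
elliptical leaf, and class-specific disease blobs (count, radius, hue per
class) blended at `disease_contrast` (default 0.3; 0.1 is genuinely
low-contrast); classes differ only in blob statistics so the class signal
is the disease region. Optional forward haze uses the haze model with
`L = (1,1,1)`. It does not emulate leaf venation, specular highlights,
camera noise or pose/scale variation — green pipeline tests establish
mechanism correctness, not field performance.

`make_feature_matrix` defaults: n = 300 samples, 3 classes, per-column
class separation of 1.0 noise SD (weak individual features, so a wrapper
has measurable pressure to retain the whole informative set), redundant
copy-noise SD 0.1 (copies correlate ≥ 0.9 with sources). These defaults
were fixed before any acceptance measurement.

`make_dehaze_scene` is described under haze-model restoration above.

## Pipeline

Stage seeds derive from `sha256(master_seed:stage_name) mod 2³¹`, so any
stage can be re-run independently and the whole run is reproducible (the
selection mask file hashes identically across reruns). The default order
splits before augmenting and augments the training partition only;
`augment_before_split` restores the reference ordering at the cost of
leaking generated variants of test images into training. Each stage
records one artifact with its SHA-256 and wall time in `manifest.json`; a
stage failure aborts with the stage name, keeping completed artifacts.

## Known limitations

* The numpy backend is CPU-only and float64; full-size training is out of
  desk scope by design (forward passes are seconds, training uses the
  reduced builders).
* Attention is degenerate (single token) at the tap point; richer spatial
  attention would require tapping before global pooling, which the
  reference feature widths rule out.
* The transmission map has no guided-filter refinement, so dehazed edges
  can halo on scenes with depth discontinuities.
* Augmentation quality is bounded by a small autoencoder; it balances
  class counts and perturbs appearance but does not synthesize novel
  disease morphology.
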