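# Methods

This note records the models, the defaults and the design decisions behind
`dermpipe`, and what the synthetic benchmarks do and do not demonstrate.

## Block-scrambling cipher

The cipher operates on `Bx x By` pixel blocks (default 16 x 16, the standard
setting for codec-friendly image scrambling) in row-major order:

1. **K1** permutes the block order (a uniform random permutation).
2. **K2** applies one of the 8 dihedral symmetries of the square per block.
   "Invert and rotate" is read as the full dihedral group — 4 rotations x
   optional horizontal flip — with a fixed index table: index `k` means
   rotate counter-clockwise `k mod 4` quarter turns, then flip horizontally
   if `k >= 4`. Rotations invert as `(4 - k) mod 4`; the reflections are
   involutions.
3. **K3** holds one bit per block; where it is 1 every pixel is complemented,
   `p' = p XOR (2^L - 1)`. The bit is Bernoulli(0.5). The XOR is
   self-inverse. K1–K3 are shared across the three colour components.
4. **K4** permutes the colour channels per block by one of the 3! = 6
   permutations of (R, G, B), enumerated lexicographically with index 0 the
   identity.

Decryption applies the exact inverses in reverse order (K4⁻¹, K3, K2⁻¹,
K1⁻¹). The K2/K3/K4 streams are indexed by the block's position *after* the
K1 permutation; this convention is part of the format contract.

**Key derivation.** The source scheme assumes the four streams exist but does
not say how they arise from a single private key, so this implementation
fixes a contract: one PCG64 generator seeded with the integer master seed
emits K1, K2, K3, K4 in that order. Determinism of the generator and the
stream order are what make the seed a key.

**Non-divisible dimensions** are a hard error by default; with `pad=True`
the image is reflect-padded bottom/right and the pad amounts recorded so
decryption crops back exactly. **Serialization** defaults to PNG, which is
lossless and therefore preserves exact decryption; JPEG is supported but
flagged lossy (a decode smoke test is the only claim made for it — no
quantitative compression-efficiency criterion is defined). The step order
at encryption follows the listed steps 1→4; whether the channel shuffle
precedes the negative–positive step in the original design is not decidable
from its description, so the listed order is fixed here and inverted
consistently.

No cryptographic hardness is claimed: the cipher's purpose is reversible
obfuscation compatible with standard codecs, not provable security.

## Feature extraction

Three reduced-scale backbone families produce features at 64 x 64 input
(bilinear resize, channels scaled to [0, 1]):

- *MobileNetV2-style*: 3x3 stride-2 stem, then inverted residual blocks
  (1x1 expand → 3x3 depthwise → 1x1 project) with a shortcut addition when
  the stride is 1 and channel counts match.
- *Inception-style*: stem + max-pool, then blocks running 1x1 / 3x3 / 5x5
  and pooled-1x1 branches in parallel, concatenated channel-wise.
- *AlexNet-style*: a 7x7 stride-2 first layer (the wide-receptive-field idea
  at this input scale), then 5x5 and 3x3 stages — the canonical
  5-convolution design. (Descriptions of this family sometimes state eight
  fully connected layers *and* five convolutional layers; the canonical
  5-conv + FC shape is implemented and the discrepancy simply noted.)

All activations are ReLU. The feature vector is the global-average-pooled
output of the final convolutional stage (the penultimate representation —
where the "features" are tapped is otherwise a free choice). Fusion is
concatenation in declared order followed by optional per-feature z-scoring
with statistics fitted on training data only; this is the simplest faithful
reading of "fusion" and leaves feature weighting to the classifier.

Weights are He-initialized from a seed and the networks are used as fixed
random-projection extractors; random convolutional features preserve the
colour/shape statistics that separate the synthetic classes, and the
`set_weights` interface accepts externally trained parameters when transfer
from pretrained models is available. Gradient training of the backbones is
out of scope for this package. The pipeline extracts features from
*decrypted* images (the round trip is exact, and this is asserted at run
time by comparing against plaintext features); running on ciphertext is
possible through the same API but is an experiment, not the default.

## Conditional VAE

Encoder and decoder are two-hidden-layer ReLU MLPs (default width 64) with
inverted dropout (default 0.5). The class enters both networks as a one-hot
concatenation. The encoder outputs `mu` and `log sigma^2` (clipped to ±12 so
`exp` stays finite early in training); `z = mu + sigma * eps` with a single
standard-normal sample per step. The loss is

    reconstruction + KL,   KL = 0.5 * sum(mu^2 + sigma^2 - 1 - ln sigma^2)

with the unit-variance Gaussian decoder giving reconstruction
`0.5 ||x - xhat||^2` (a Bernoulli/cross-entropy decoder is available for
[0, 1] inputs). Training uses Adam at the configured learning rate
(default 0.01, 50 epochs, batch size 5 — the benchmark settings) with
hand-written backpropagation; everything is seeded.

**Decision rule.** A generative CVAE does not come with a classifier, so one
is fixed: evaluate the trained objective for every candidate class with the
noise pinned to 0 and return the argmin (conditional-likelihood
classification; exact ties break to the lowest class index). This uses
exactly the objective that was trained, with no extra parameters. Note that
with strongly class-separated inputs the encoder may learn to ignore the
class input entirely (the KL term rewards that); the class signal then lives
in the decoder, which is what the decision rule exploits.

The latent dimension must be strictly smaller than the input dimension.
Architecture width, latent dim, dropout, batch size and learning rate are
the HO-tunable hyperparameters.

## Hippopotamus optimizer

Minimizes `f` over a box `[L_j, U_j]^N` with population `M`, iterations
`T_max`. Per iteration:

- **Phase 1 (social).** For the first `ceil(M/2)` members: the male proposal
  `x + rand .* (leader - C1 * x)` and then a female/calf proposal with three
  branches keyed on the decay `T = exp(-t / T_max)` (which stays in
  `(e^-1, 1]`, so the exploratory first branch is active early; the printed
  form of this decay is typographically ambiguous and this reading is the
  implemented, configurable one) and a fair coin: toward
  `leader - C2 * RG_m`, away from the leader, or a uniform restart. `RG_m`
  is the per-dimension mean of a uniformly chosen random subset of the
  population (subset size uniform on 1..M). The random multiplier `v` is one
  of five documented scenarios chosen uniformly per update. Both proposals
  are applied to the same first half in sequence, greedily — the split of
  male vs female/calf indices is ambiguous in the source description and
  this is the fixed choice.
- **Phase 2 (defense).** For the second half: predator `P ~ U(box)`,
  distance `Dist = |P - x|` elementwise, scalar factor
  `b / (c - d cos(2 pi g))` with per-update uniform draws `b in [2,4]`,
  `c in [1,1.5]`, `d in [2,3]`, `g in [-1,1]` (these symbols are undefined
  in the source; the ranges are package defaults, configurable). The
  proposal is `levy .* P + factor / Dist` when the predator is fitter, else
  `levy .* P + factor / (2 Dist + rand)`; a zero distance is guarded by a
  1e-12 epsilon. The Levy step uses the Mantegna stable-ratio construction
  with exponent 1.5.
- **Phase 3 (escape).** For all members: local bounds `L_j / t`, `U_j / t`
  (shrinking as 1/iteration) and proposal
  `x + rand .* (L_loc + alpha .* (U_loc - L_loc))` with `alpha` one of
  {2 rand - 1, rand, randn}.

Every proposal is clamped to the box before evaluation and accepted only on
*strict* improvement (ties reject), so the best-so-far trajectory is
non-increasing by construction. A single seeded generator drives everything:
runs are exactly reproducible, and `n_evals` counts every fitness call so
baselines (random search) can be budget-matched.

For hyperparameter tuning the box is (log10 lr in [-3,-1], latent dim in
[2,15], batch size in [2,16], dropout in [0,0.6]); integer dimensions are
rounded at evaluation. The objective is minus validation macro precision on
a 20% validation carve-out of the training data (the source defines no
validation protocol, so one is fixed here). The default configuration's
point is always evaluated alongside the search, so tuning can never return
something worse than the default on the same data — a cheap guarantee the
search itself does not provide. The tuning budget defaults to M=8, 10
iterations (desk scale) with a reduced epoch count per evaluation.

## Metrics

Per-class metrics come from one-vs-rest binarization of the K x K confusion
matrix. Per-class *accuracy* is the binarized accuracy — with 9 classes it
sits near 1 for any reasonable classifier, which matches the reporting
convention of the multiclass tables this layout mirrors. MCC is the binary
one-vs-rest coefficient per class (the multiclass R_K statistic is not
used). Macro averages are unweighted arithmetic means; printed reports are
percentages rounded half-up to 2 decimals, with full precision retained
internally. Every metric whose denominator is zero is defined as 0.

## Synthetic data

Class `k` has a deterministic parametric appearance (lesion hue around the
colour wheel, eccentricity, radius, sinusoidal border wobble, texture noise)
equal to a shared base plus a class offset scaled by `separability`; each
image then draws per-image jitter. At separability 0 all classes share one
distribution (exchangeable — any classifier's expected accuracy is 1/K); at
1 the offsets are maximal. Default separability 0.8 — distinct but
overlapping classes, so metrics are informative rather than saturated.
Default counts mirror the emulated archive's 9-class imbalance
(114, 376, 95, 438, 357, 462, 77, 181, 139) scaled by 0.1 (≈225 images),
which keeps imbalance-sensitive metrics like MCC exercised at desk scale;
default image size 64 x 64. Splits are stratified per class (whether the
original evaluation stratified is unstated; stratification is this package's
choice), exact partitions, seed-reproducible.

The generator exercises the pipeline's machinery — cipher exactness, feature
discriminability, classifier training, imbalance-aware metrics — but is not
photorealistic dermoscopy: texture, vascular patterns and imaging artifacts
are absent, so passing benchmarks here say nothing about clinical accuracy
on real dermoscopy archives, and the original 99%-range benchmark numbers
(which require the real archive, pretrained backbones and training-scale
compute) are deliberately not reproduced.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen up front: 32–64 px
images, ≈100–225 images per pipeline run, feature dimension 60, CVAE width
32–64, optimizer budgets of 10–30 members x 10–100 iterations. The
acceptance script's end-to-end run uses the full default configuration
(count factor 0.1, 64 px, 50 epochs). Tolerances: cipher checks are exact
integer equality; KL and metric formula checks are exact to floating point;
stochastic checks (bit frequency, random-search wins, holdout accuracy) use
explicit bounds stated with each test. Log-variances are clipped at ±12;
variance guards reject non-positive `sigma^2`; the defense phase guards zero
predator distance with 1e-12.

## Known limitations

- Backbones are random-feature extractors; no gradient training of the
  convolutional stacks is provided.
- The cipher is obfuscation with exact inversion, not analyzed cryptography.
- The defense-phase scalars b, c, d, g and the Levy construction are
  documented package defaults, not values fixed by the source description.
- Synthetic images are parametric blobs; results do not transfer to real
  dermoscopy without retraining and real data.
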