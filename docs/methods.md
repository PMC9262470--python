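# Methods

`orascreen` classifies small sets of two-class oral-lesion photographs
(cancer vs noncancer) with a four-stage pipeline: Gabor-bank
preprocessing, fixed-length texture features, a deep belief network
(DBN) classifier, and swarm-based hyperparameter tuning.  This note
records the models, the defaults and why they were chosen, the numerical
conventions, and what the synthetic benchmark does and does not show.

## Gabor preprocessing

A Gabor filter is a complex sinusoid modulated by a Gaussian envelope.
With image coordinates (a, b) (a = column offset, b = row offset, origin
at the kernel centre, top-left image origin, row-major storage) and
rotated coordinates a′ = a cos θ + b sin θ, b′ = −a sin θ + b cos θ:

    G(a, b) = exp(−(a′² + γ² b′²) / (2σ²)) · exp(i(2π a′ / δ + ψ))

Parameters, with defaults used by the standard bank:

| symbol | meaning | default |
|---|---|---|
| δ | sinusoid wavelength (pixels/cycle) | 4 and 8 |
| θ | orientation, [0, π) suffices by symmetry | 8 steps over [0, π) |
| ψ | phase offset (radians) | 0 |
| σ | Gaussian envelope SD (pixels) | derived from bw |
| γ | aspect ratio (envelope ellipticity) | 0.5 |
| bw | half-response spatial-frequency bandwidth (octaves) | 1 |

σ follows from the bandwidth via σ = (δ/π)·√(ln 2 / 2)·(2^bw + 1)/(2^bw − 1),
so bw = 1 gives σ ≈ 0.56 δ.  Kernel side length defaults to the smallest
odd integer covering ±3σ/max(γ, 1).

Filtering is plain spatial correlation (never FFT) with reflect padding;
the output per filter is the magnitude √(real² + imag²) of the complex
response, which is invariant to the phase of the underlying texture.
The preprocessing image is the per-pixel maximum of the bank's magnitude
responses, min-max rescaled to [0, 1]: the strongest oriented bandpass
channel survives at each pixel while unoriented broad-band noise is
attenuated.  Colour images are collapsed to luminance
(0.299 R + 0.587 G + 0.114 B) before filtering.  These conventions
(correlation rather than convolution, reflect padding, magnitude
response, max combination) are each fixed so that runs are
bit-reproducible; none is forced by the model itself.

## Feature extraction

The default extractor is deliberately training-free and offline.  The
resized image (bilinear; by default the pipeline extracts at the native
synthetic resolution of 128×128 to avoid upscaling interpolation, while
the spec of an extractor defaults to 224×224 to mirror CNN input
geometry) is filtered by the 16-filter bank; each magnitude response is
pooled on a 4×4 grid of cells with three statistics per cell — mean,
standard deviation, and energy (mean square).  That yields
16 filters × 16 cells × 3 = 768 raw values which a seeded Gaussian
random projection (unit-variance entries, regenerated identically from
the seed on every call) maps to `output_dim` = 128 features.  The raw
statistics are a pure function of the image bytes, so equal inputs give
bitwise-equal features.

An optional adapter can instead run a pretrained mobile-class CNN
(global-average-pooling the last feature map and truncating/padding to
`output_dim`), but it requires an optional deep-learning runtime with
downloaded weights; when absent it raises a loud "adapter unavailable"
error rather than silently degrading.  No network is ever trained here.

## DBN classifier

Visible units v ∈ {0,1}^m and hidden units h ∈ {0,1}^n of a restricted
Boltzmann machine carry the energy

    E(v, h) = −Σᵢⱼ ωᵢⱼ vᵢ hⱼ − Σᵢ aᵢ vᵢ − Σⱼ bⱼ hⱼ,
    p(v, h) = e^{−E} / R,

and the bipartite structure factorises both conditionals into logistic
units, p(hⱼ = 1 | v) = σ(Σᵢ ωᵢⱼ vᵢ + bⱼ) with σ(x) = 1/(1 + e^{−x}).
Training is contrastive divergence CD-k (k = 1 default): the positive
statistic ⟨v h⟩ uses data-driven hidden probabilities; the negative
phase runs k alternating Gibbs steps with hidden states sampled and
visible reconstructions mean-field, taking the final statistics from
probabilities (a standard variance-reduction choice); parameters move by
(α/β)(⟨·⟩_data − ⟨·⟩_model) with learning rate α and batch size β.

Real-valued features are min-max scaled to [0, 1] upstream and used
directly as visible probabilities.  This is the simplest convention
consistent with the binary energy model; it discards the tail behaviour
a Gaussian-visible RBM would capture and is a documented limitation.

The DBN stacks RBMs greedily (layer k + 1 trains on layer k's hidden
probabilities), appends a C-way softmax layer, and fine-tunes the whole
stack by plain mini-batch gradient descent on cross-entropy (no
momentum, no weight decay, no persistent CD).  Prediction is a
deterministic mean-field forward pass; ties in the argmax resolve to the
lexicographically smaller class label.

Defaults: two hidden layers (64, 32), α = 0.3, β = 16, 50 pretraining
and 50 fine-tuning epochs, weights initialised Gaussian(0, 0.01²) with
zero biases from the run seed.  The relatively strong learning rate and
long pretraining are load-bearing: with 0.01-scale initial weights and
plain SGD, a two-hidden-layer sigmoid stack whose RBMs are only weakly
pretrained keeps near-constant activations (≈0.5) and backpropagation
alone recovers the class signal too slowly at desk scale.  Fifty CD
epochs at α = 0.3 give the hidden layers enough structure for
fine-tuning to converge on the benchmark fixtures; both numbers are
overridable and are part of the tuning search space.

Exact enumeration of the 2^(m+n) joint states backs the small-model
verification (joint, marginal, log-likelihood); it refuses models with
m + n > 20.

## Grasshopper tuning (EGOA)

The grasshopper optimization algorithm moves N candidates under pairwise
social forces s(y) = f·e^{−y/l} − e^{−y} (intensity f = 0.5, length
scale l = 1.5): repulsion at short range, attraction at long range, zero
at the comfort distance y* = 3 ln 2 ≈ 2.08.  The per-iteration update
sums, over all other grasshoppers, c·((u_d − l_d)/2)·s(·) along the unit
inter-agent direction, then adds the best-known position; gravity and
wind-drift terms of the general swarm model are omitted in the working
update.  The comfort coefficient c(t) = c_max − t(c_max − c_min)/t_max
shrinks linearly from 1.0 to 10⁻⁵.

Because s(·) saturates to ~0 within a few length units, raw pairwise
distances over wide search boxes would freeze the swarm; per-dimension
distances are therefore remapped linearly into [1, 4] before applying
s, keeping every pair inside the force's active range.  Positions are
clamped componentwise to the bounds after every update.

The enhancement is opposition-based learning (OBL): the opposite of x in
box [l, u] is x̄ = u + l − x, and the fitter of {x, x̄} is kept (ties
keep x).  OBL is applied at initialisation — sample N uniform positions,
add their N opposites, keep the best N — and once per iteration to the
global best, bounding the extra fitness evaluations by t_max.  Total
evaluations per run are exactly 2N + t_max + N·t_max.  Non-finite
fitness values cause that candidate to be resampled uniformly.

For DBN tuning the 5-dimensional search box is

    [log₁₀ α ∈ (−4, −1); h₁ ∈ [16, 256]; h₂ ∈ [8, 128];
     pretraining epochs ∈ [5, 50]; β ∈ [8, 64]]

with the integer dimensions kept continuous during search and rounded
half-away-from-zero only at decode time.  Fitness is 1 − validation
accuracy on a seeded stratified 80/20 split of the training portion;
test rows are never visible to the tuner.  Defaults N = 8, t_max = 10
(106 DBN fits per split) keep a full run in the order of a minute on one
CPU; they are deliberately a desk-scale budget, not a converged search.

## Evaluation conventions

Binary confusion matrices use rows = true class, columns = predicted,
class order (cancer, noncancer).  All metrics are percentages; per class
k, precision = 100·TPₖ/(TPₖ + FPₖ), recall = 100·TPₖ/(TPₖ + FNₖ),
F = harmonic mean, and the accuracy column repeats the overall accuracy
on every class row.  The "Average" row is the unweighted (macro) mean of
the per-class columns computed from unrounded values; rounding is
half-up to two decimals and happens only at display time.  (Averaging
already-rounded cells would differ in the second decimal — e.g.
(92.3077 + 100)/2 = 96.15, while (92.31 + 100)/2 would display 96.16.)
Zero denominators report 0 with an explicit flag rather than raising.
ROC and precision-recall curves sweep descending unique scores of the
cancer class (scikit-learn backend, no intermediate-point dropping).

## Synthetic data

The texture generator emulates what matters to an oriented-filter
pipeline at the scale of a small clinical photograph collection: 87
"cancer" and 44 "noncancer" images (≈2:1 imbalance) of 128×128 pixels.
Each image is an oriented sinusoidal grating — class A at wavelength 4
and 30°, class B at wavelength 8 and 120°, with ±5% wavelength and ±5°
orientation jitter and a uniform random phase per image — overlaid with
dark soft-edged elliptical blobs (6 per class-A image, 2 per class-B,
standing in for lesion-like structure) plus Gaussian pixel noise
(SD 0.05), clipped to [0, 1].  Everything is a pure function of the
seed.

What this does *not* emulate: photographic illumination and colour
variation, anatomical context, specular highlights, intra-class lesion
heterogeneity, or label noise.  Class identity is carried by global
texture frequency/orientation, which the Gabor features are built to
detect, so the pipeline's ≈90%+ synthetic accuracy demonstrates that the
chain of stages is implemented coherently — it is *not* evidence of
clinical-grade performance on real photographs.

The feature-cluster generator bypasses the image stages: two isotropic
unit-variance Gaussian clusters at Mahalanobis separation s along a
fixed axis, min-max scaled per dimension.  s = 6 gives a 3-sigma margin
per side (Bayes error < 1%) for classifier contracts; s = 0 gives
chance-level data for negative controls.

## Pipeline hygiene and reproducibility

For each train/test ratio (default sweep 90:10, 80:20, 70:30, 60:40)
the split is stratified: per-class test counts are round(class size ×
test fraction), nudged ±1 on the largest rounding residuals to hit the
global total.  The min-max scaler is fitted on training rows only; test
features falling outside [0, 1] are clipped and the clip count logged.
Hyperparameter tuning sees only training rows (inner stratified 80/20
validation split) — holdout test data influence nothing before final
evaluation, and tuning runs independently per split ratio.  One master
seed derives each stage's seed by a fixed offset, so a re-run of the
same configuration is bitwise identical.

## Known limitations

- Bernoulli visible units on min-max-scaled features; no
  Gaussian-visible RBM variant.
- Plain SGD everywhere (no momentum/weight decay), so training depends
  on the learning-rate and epoch defaults discussed above.
- The default feature extractor is a fixed texture summary, not a
  learned representation; images whose class signal is not textural
  will not separate.
- The tuning budget defaults are small by design; a larger swarm or
  iteration count may find better configurations at proportional cost.
- Binary classification only; the evaluation module does not generalise
  to more than two classes.
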