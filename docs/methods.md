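# Methods

`auscult` classifies short auscultation recordings into eleven cardiorespiratory
classes — six lung conditions (BA, BO, COPD, H, P, URTI) and five heart conditions
(AS, MR, MS, MVP, N) — with a hybrid model: a fixed-size bispectrum image of the
signal, a compact CNN that reduces the image to a 64-dimensional embedding, and a
best-discrepancy forest (BDF) voting over those embeddings. This note records the
model, its assumptions, the parameters that matter, and the choices made where the
design was genuinely open.

## Signal conditioning

Auscultation content of interest lives in roughly 25–400 Hz. Every recording,
regardless of its native rate (4–44.1 kHz) and duration, is reduced to a
`CleanSignal`: 2500 samples at 1 kHz with amplitudes strictly inside (−1, 1).

* **Bandpass.** 2nd-order Butterworth, 25–400 Hz, applied at the *native* rate and
  *before* resampling (content between 400 and 500 Hz can therefore never alias
  into the band). The filter runs forward–backward (`sosfiltfilt`), i.e. zero
  phase; the squared magnitude response this implies is what the tests assert
  against. The mean is removed first — nearly redundant given the 25 Hz edge, but
  it stabilizes the third-order cumulant estimator downstream.
* **Resampling.** Polyphase rational resampling to 1 kHz; duration is preserved to
  within one output sample.
* **Truncation.** The first 2500 samples (2.5 s) are kept. Shorter records are
  zero-padded at the end rather than rejected: the short heart records are valid
  data and padding is neutral for the cumulant estimate.
* **Normalization.** Division by the peak magnitude with a combined relative
  (1e−6) and absolute (1e−12) epsilon. The absolute term keeps the all-zero signal
  at zero; the relative term keeps the peak strictly below 1.0 *at any input
  scale and after a float32 serialization round-trip* — a purely absolute epsilon
  underflows against large peaks and the contract silently breaks. Normalization
  is scale-invariant: `normalize(c·x) = normalize(x)` for any `c > 0` up to the
  epsilon.

At inference on long recordings the pipeline classifies the first 2.5 s window by
default; vote-averaging over consecutive windows is exposed as a flag
(`predict --windowed`) but is not part of the training protocol.

## Class balancing (per-class VAE)

The combined corpus is heavily imbalanced (COPD 793 records vs BO 13). One small
dense VAE per minority class is trained on that class's CleanSignals and sampled
from the N(0, I) latent prior to top the class up to its target: every heart class
+600 and every minority lung class +630, majority class untouched (1917 → 8067).

Architecture: encoder 2500 → 256 → 64 (ReLU) with 32-dimensional μ and log σ²
heads; mirrored decoder with tanh output so samples land in (−1, 1) (they are
re-normalized afterwards anyway). Objective: summed squared reconstruction error
plus the analytic KL divergence −½ Σ(1 + log σ² − μ² − σ²), with the
reparameterization z = μ + σ⊙ε. Training: Adam 1e−3, 200 epochs, batch 32, fixed
seed. These hyperparameters are the package's own choice — the smallest dense
model that reconstructs band-limited 2.5 s signals well — as is the decision to
train *per-class* VAEs rather than one conditional VAE: balancing is inherently a
per-class operation and per-class models cannot leak cross-class structure.

Augmentation operates on time-domain CleanSignals *before* imaging, so synthetic
records pass through exactly the same imaging path as real ones.

## Bispectrum imaging

The bispectrum B(f1, f2) — the 2-D Fourier transform of the third-order cumulant
sequence — vanishes for Gaussian processes and concentrates at frequency pairs
with quadratic phase coupling, which makes it a good fixed-size representation for
murmurs and adventitious sounds. Estimation is indirect:

1. Biased cumulant estimate C(τ1, τ2) = (1/N) Σₙ x(n)x(n+τ1)x(n+τ2) over lags
   |τ| ≤ L.
2. Separable 2-D Hann lag window (variance reduction; the estimator is otherwise
   quite noisy at L comparable to N).
3. Zero-padding of the (2L+1)×(2L+1) support onto a 256×256 grid and a 2-D FFT.

Choices where the design was open, all fixed once and documented here:

* **L = 127**, the largest lag for which the 255-point support still fits the
  256-point FFT grid without truncation.
* **Single-segment estimation** over the whole 2500-sample record; a
  segment-averaged variant (`segments > 1`) exists for lower-variance estimates,
  and is what the QPC test oracle uses (phase randomization only cancels *across*
  segments).
* **Origin convention:** pixel (0, 0) is (f1, f2) = (0, 0), frequencies increase
  along rows/columns to the 500 Hz Nyquist (FFT order, no shift).
* **Log compression** `log(1+|B|)` before min–max scaling to [0, 1]: bispectral
  peaks span orders of magnitude and would otherwise saturate single pixels.
* The **full 256×256 plane** is kept — no principal-domain cropping — and the
  all-zero signal maps to the all-zero image (guarded min–max).

Float32 arrays are the training representation; 8-bit PNGs are exported for
inspection only (quantization error ≤ 1/255).

## CNN feature extractor

The network is deliberately tiny (embedded-deployment constraint):

| layer | configuration | output | params |
|---|---|---|---|
| conv1 | 24 @ 5×5, stride 4×2, ReLU | 64×128×24 | 624 |
| conv2 | 48 @ 5×5, stride 1×1, ReLU | 64×128×48 | 28,848 |
| maxpool | 4×2, stride 4×2 | 16×64×48 | — |
| conv3 | 16 @ 3×3, stride 1×1, ReLU | 16×64×16 | 6,928 |
| dense | 64, ReLU | 64 | 1,048,640 |
| head | softmax 11 | 11 | 715 |

The three conv layers hold exactly 36,400 parameters; the dense layers add about a
million more, and `param_counts()` reports both figures rather than folding them
together. Open details resolved here: SAME padding for convs / VALID for pooling
(keeps stride-divisible shapes; parameter counts are padding-independent), strides
read as (rows, columns), ReLU on conv2 (uniform with the other convs). The softmax
head exists only for CNN training and the pure-CNN ablation; the hybrid classifier
consumes the 64-unit dense activations.

Training: Adam (1e−3), categorical cross-entropy, 100 epochs and mini-batch 128 by
default. Gradients for a 128-batch are accumulated over 16-image chunks, which is
mathematically identical to a single 128-image step and bounds peak memory.

The layers are implemented directly on numpy: convolutions run as im2col plus one
BLAS GEMM per pass with a numba scatter-add for the backward col2im, everything in
float32 with persistent per-layer scratch buffers. Feature extraction is
deterministic and independent of batch composition; training is bit-reproducible
for a fixed seed on a given BLAS.

## Best-discrepancy forest

Ordinary bagging draws each tree's training multiset uniformly with replacement,
so per-bag class proportions fluctuate ~1/√N. The BDF instead draws **systematic**
bags: sort the dataset by class then source id, pick a uniform random start
u ∈ [0, N), and take index

    ordering[ floor(u + j·θN) mod N ],   j = 0 … n−1,   θ = (√5−1)/2.

The golden-ratio Weyl step is equidistributed, so every bag's class distribution
closely mirrors the dataset's (the tests bound the max deviation by 0.05 over 500
bags and verify the variance is no larger than random bagging's), while duplicates
keep the "with replacement" character. The exact published construction is not
reproduced in the source text; the Weyl sequence is the canonical low-discrepancy
choice satisfying every stated property. Plain random bagging remains available
(`bagging="random"`) for ablations.

Trees are standard CART (Gini, grown to purity, `mtry = ⌈√64⌉ = 8` random
candidate features per split — the conventional default, not stated in the source)
via scikit-learn. Bag size defaults to n = N (`bag_fraction = 1.0`); the general
bagging definition has n < N, and the fraction is exposed for that reading.
Prediction is a plurality vote; ties break to the smallest index in the fixed
class order, making prediction fully deterministic.

## Evaluation

Confusion matrices are oriented **rows = predicted, columns = true** — the only
orientation under which the published worked-example matrix reproduces its printed
sensitivity/precision pair, so it is fixed and asserted in tests. Macro one-vs-rest
metrics (accuracy, precision, sensitivity, specificity, F1) are unweighted means of
per-class binary rates, in percent, rounded to two decimals half-even; 0/0 rates
(class absent and never predicted) count as 1. Protocols: stratified 80/20 hold-out
(train size ⌊0.8N⌋) and stratified 10-fold CV with unweighted averaging of fold
reports. Stratification prevents empty-class folds at small N; `--no-stratify`
gives the literal unstratified reading.

## Surrogate data generator

The generator exists so the pipeline is testable end-to-end with no external
corpus. It aims for **spectral separability between classes, not clinical
realism** — passing tests demonstrate that the pipeline can learn and preserve
class-discriminative spectral structure, *not* that it diagnoses real patients.
Real auscultation data differ in ways the surrogates deliberately ignore: sensor
and ambient noise, inter-patient variability, overlapping pathologies, imperfect
annotations, and murmur morphology far richer than band-limited noise bursts.

Heart surrogates (8 kHz, matching the real heart corpus): S1/S2 Gaussian tone
bursts (~38/52 Hz) at a jittered ~1.2 Hz cycle; murmurs are band-filtered noise in
class-specific bands and windows (AS mid-systolic 150–400 Hz, MR holosystolic
100–300 Hz, MS diastolic 25–120 Hz, MVP a 300 Hz click plus late murmur; N none).
Lung surrogates (4/10/44.1 kHz cycled, matching the real lung corpus's rates):
breath-cycle-modulated 60–250 Hz noise plus crackles (P dense fine ~320 Hz, BO
sparse coarse ~120 Hz, BA clustered ~210 Hz) or wheezes (COPD sustained expiratory
~190 Hz, URTI intermittent ~360 Hz); H plain. All content sits inside 20–450 Hz so
it survives the bandpass. Default durations are 3–6 s (heart) and 10–15 s (lung):
the pipeline consumes only the first 2.5 s after resampling, so longer records add
runtime without touching the method. Everything is deterministic given the seed;
WAVs are written as 16-bit PCM to exercise the same reader as real data.

## Problem sizes and numerical choices

* The desk-scale end-to-end experiment (the package's own validation and the
  default of `run_experiment`) uses 100 surrogate records per class, 25 CNN
  epochs, and 100 trees on a stratified 80/20 hold-out — small enough to run on a
  single CPU core while exercising every stage at full image resolution.
* Reported headline-scale settings (100 epochs, 500 trees, the full balanced
  corpus) remain the defaults of the CLI `train` command.
* Seed fan-out: one global seed expands to per-stage seeds via named
  `SeedSequence` spawn keys (`synth`, `augment`, `split`, `cnn`, `bdf`), so any
  stage can be re-run independently.
* Degenerate inputs: all-zero signals propagate to all-zero images; min–max
  scaling guards division by zero; the zero-vote tie in the forest resolves to the
  first class in the vocabulary.

## Known limitations

* The numpy CNN is single-threaded and CPU-bound; training wall-time scales
  linearly with images × epochs (~30 ms per image step at 256×256).
* The VAE measures reconstruction in the time domain; it preserves spectral
  envelopes well but not fine phase structure. That is sufficient for balancing
  bispectrum-image classes (phase offsets largely cancel in the magnitude
  bispectrum) but the samples are not realistic audio.
* Surrogate separability is by construction; no claim about real-data accuracy is
  made or tested here.
* No respiratory-cycle segmentation, noise suppression, or source separation is
  performed; recordings enter the pipeline whole.
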