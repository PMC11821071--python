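# Methods

## Signal model and scope

An observed ambulatory ECG is modeled as `x̃(n) = α(n)·x(n) + β(n)` with a
multiplicative component α (amplitude modulation from respiration and
electrode orientation) and an additive component β (baseline wander, EMG
noise, electrode-motion transients).  This package addresses the additive
component only, which accounts for the bulk of ambulatory artifacts; the
corruption engine is therefore purely additive and `noisy − clean`
reconstructs the injected noise exactly (a tested invariant).

The unit of processing is a 512-sample, 360 Hz, zero-mean segment in mV.
No amplitude normalization is applied to clean segments: the model must
cope with natural inter-subject amplitude variation.

## Architecture

Encoder block: gated self-ONN (order q, kernel 9) → instance norm →
LeakyReLU(0.3) → max-pool(2) → channel attention.  Decoder block: gated
transpose convolution (stride 2, order 1) → instance norm → LeakyReLU →
channel attention.  Four residual gates mask decoder feature maps with
sigmoid functions of point convolutions of the decoder output and the
matching encoder skip; the skip content reaches the decoder only through
the mask.  Feature-map trace for a 512×1 input:
encoder 256×16 → 128×32 → 64×64 → 32×64 → 16×1;
decoder 32×64 → 64×64 → 128×32 → 256×16 → 512×1.

Design choices made where the design was genuinely open:

* **Order-0 term of the polynomial kernel.**  The constant term of the
  MacLaurin expansion is folded into a single per-output-channel bias
  shared across orders.  This is standard self-ONN practice, and it is the
  only convention under which the parameter totals close: going from q=1
  to q=2 adds exactly one kernel bank (121,248 weights) and no biases.
* **Channel schedule.**  The schedule (16, 32, 64, 64, 1) is the unique
  natural choice reproducing both printed parameter totals; it is the
  default of `ModelConfig` and overridable.
* **Gate order.**  Both the input and the gate path of a gated self-ONN
  use order q.  The per-order increment 121,248 = Σ over 5 blocks of
  2 paths × 9 × C_in × C_out confirms this reading.
* **Attention.**  One shared kernel-3 convolution with bias over the
  channel axis serves both pooled descriptors; 10 blocks × 4 parameters
  = 40.  Attention is present in all blocks, including the degenerate
  1-channel bottleneck and output blocks.
* **Residual gates.**  Full C→C point convolutions with biases (no
  bottleneck): 2·(C²+C) per gate, 19,296 in total.
* **Transpose-conv padding.**  The full transpose-convolution output
  (length 2L+7 for kernel 9, stride 2) is cropped symmetrically to exactly
  2L samples, surplus to the right edge, so the U-Net halving/doubling
  bookkeeping is exact.  Internally the operation is evaluated as
  zero-stuffing followed by a stride-1 correlation with the flipped
  kernel — algebraically identical (tested against the direct scatter
  definition) and much faster on CPU.
* **Dropout.**  0.001·q on the gated self-ONN gate path, 0.001 elsewhere;
  active only during training and only where the channel count exceeds 1.
* **Instance norm ε** = 1e-3 (configurable; does not affect parameter
  counts).  Weight init is seeded fan-in-uniform; the exact scheme is not
  prescribed by the architecture and is recorded in the checkpoint seed.
* **Final block.**  The last decoder block keeps the full block structure
  with no extra output activation; required for the parameter accounting.

## Compute core

No deep-learning framework is a dependency.  `fgdae._autodiff` implements
a tape-based reverse-mode autodiff on numpy arrays with custom conv /
transpose-conv / max-pool operations expressed as batched BLAS matmuls on
shifted views (no im2col buffer).  Every primitive and the assembled
network are verified against central-difference numerical gradients
(worst-case ~1e-8 absolute on float64).  Tensors preserve their input
floating dtype: training runs in float32 for CPU throughput; oracle tests
run in float64.

## Losses

* `J_recon` = SSD + λ·MAD per segment, λ = 50; batch mean.
* `J_grad` = max |Δx − Δx̂| over the first differences, unscaled; batch
  mean.
* `J_morph` = λ_morph·(1 − minᵢ corr(xᵢ, x̂ᵢ)), λ_morph = 10, minimum over
  the current batch (a per-epoch minimum is not computable in streamed
  training).  The Pearson correlation is exact whenever both standard
  deviations exceed `corr_eps` (1e-8); below that the segment is treated
  as zero-variance and contributes correlation 0 (worst-case-safe).  This
  threshold guard, rather than an additive ε in the denominator, keeps the
  term's range extremes exact: identical pairs give 0, an anti-correlated
  pair gives 2.
* `J_reg` = λ_reg·Σ|θ| over all trainable parameters of the five encoder
  blocks (kernels, biases, norm affine, attention), λ_reg = 0.01; a
  parameter mask is provided for narrower readings.
* Batch aggregation: means for `J_recon`/`J_grad`, minimum for `J_morph`,
  batch-independent `J_reg`.

## Benchmark construction

Records are resampled to 360 Hz (polyphase), segmented with window 512 /
overlap 256 (trailing partials dropped), and mean-subtracted per segment
(clean side only; the noisy segment is clean + noise and may have nonzero
mean).  Noise splits: each two-channel artifact record is halved; version
nv1 trains on channel 1 first half and tests on channel 2 second half, nv2
swaps the channels — train and test noise never share a channel or a half.
RMN recipes draw the combination (uniform over 8), the scale `a ~ U[0.2,2]`
(independent) and one contiguous random-offset slice per active artifact
type.  When several artifact types combine, their **sum** is rescaled as
one so that the noise peak equals `a` times the clean peak (the corruption
has a single additive term).  Both ECG channels are treated as independent
single-channel signals.  The canonical 14-subject test split is honored
verbatim; the validation split is a seeded random 20 % of training pairs.

The printed full-benchmark pair totals depend on record-specific lengths
and exclusions of the source database and cannot be recomputed without the
PhysioNet download; the per-record arithmetic (15 min at 250 Hz → 324,000
samples → 1264 windows per channel) is tested instead.

A minimal WFDB reader (.hea + .dat, formats 16 and 212, gain/baseline
applied) ships with the package; fixtures write and re-read tiny records
programmatically.

## Synthetic data

The generator exists so every component is exercisable offline; it
emulates the statistical structure the corruption scheme assumes, not
real electrophysiology:

* **ECG** — five Gaussian bumps per beat (P −0.22, Q −0.045, R 0,
  S +0.045, T +0.30 of the RR interval; amplitudes 0.15/−0.10/1.00/−0.25/
  0.35 mV by default) with Gaussian per-beat heart-rate jitter.  Each
  synthetic "subject" draws its own rate (55–95 bpm), jitter and R/T
  amplitudes.
* **BW** — five random-phase sinusoids below 0.7 Hz plus a low-passed
  random walk (≥95 % of power below 0.7 Hz by construction; 0.7 Hz
  mirrors the classical baseline-wander filter cutoff of 0.67 Hz).
* **MA** — 5–50 Hz band-limited noise (standard surface-EMG band) under a
  smoothed random burst envelope.
* **EM** — Poisson-placed step discontinuities (~8/min) plus smoothed
  large spikes and mild background noise; guarantees first-difference
  outliers, the signature of electrode motion.

What passing tests on synthetic data do **not** show: robustness to real
pathological morphologies (arrhythmia, conduction abnormalities), real
electrode-motion statistics, or multiplicative modulation.  They do show
that the architecture, losses, optimization and evaluation interact
correctly and that the model learns to remove additive mixed noise.

## Training and evaluation

Adam (β₁ 0.9, β₂ 0.999, ε 1e-8), lr₀ 1e-3, batch 64.  The plateau
schedule halves the rate when the running-best validation loss fails to
improve by ≥0.05 (absolute, as specified) for 2 consecutive epochs,
re-arming after each reduction, floored at 1e-10; early stopping after 10
consecutive epochs without a new best; the best-validation weights are
restored.  "Iterations" are interpreted as epochs; the LR rule is
epoch-based (the standard reading for validation-loss plateau schedules).

Metrics: SSD, MAD, PRD (mean-centered denominator), cosine similarity,
RMSE, MAE, SNR.  Degenerate cases: perfect reconstruction reports the
documented 300 dB SNR cap; PRD of a constant reference is an error (real
ECG segments are never constant); cosine similarity with a zero-norm
vector is 0.  Stratified reports use left-closed amplitude bins
([0.2,0.6), [0.6,1.0), [1.0,1.5), [1.5,2.0]) and the eight combination
rows; every pair carries a drawn scale, so stratum counts sum to the
total.  Method comparisons use the two-sided Wilcoxon signed-rank test
(zero differences discarded; all-zero differences define p = 1), α = 0.05.

## Scaled-down training check

The acceptance-level training check runs the q=1 model for 20 epochs on a
synthetic benchmark of 2,560 generated pairs (2,048 train / 512 validation
after the 20 % split) with 256 held-out test pairs, seed 7, on CPU.  The
SNR-improvement and cosine-similarity comparisons are evaluated on the
noise-present test pairs (combinations 2–8): a clean-input pair has
unbounded input SNR, so including it under the 300 dB cap would measure
the cap rather than the denoising; clean-input behaviour is visible in the
noise-type-stratified report instead.  These problem sizes are the
package's standard small-scale regression setting; the full benchmark uses
~91k training pairs and the complete early-stopping schedule.

## Classical baselines

Zero-phase high-pass filters at 0.67 Hz, 360 Hz: a 4th-order Butterworth
applied forward-backward (padding extended to ten filter time constants so
edge transients — and with them any forward/backward asymmetry — decay
below ~1e-10), and a 1001-tap symmetric FIR built as the complement of a
unity-DC Hamming-window lowpass (`δ − h_lp`), applied by centered
convolution with reflect padding.  The complement construction makes the
tap sum exactly zero, so a constant input is nulled to machine precision;
the tap count is this package's own choice (long enough for a ~1.2 Hz
transition yet usable on single 512-sample segments).  These filters
address baseline wander only — by construction they cannot remove in-band
muscle or electrode-motion artifacts, which is what motivates the learned
model.

## Known limitations

* CPU-only; a full-benchmark training run at ~91k pairs is feasible but
  slow (no GPU path).
* The synthetic ECG is a morphological stand-in; results on it do not
  transfer quantitatively to patient data.
* Only the additive artifact component is modeled.
* The FIR baseline's exact published tap design is not reproduced; the
  implementation matches its cutoff and zero-phase contract.
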