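# Methods

This note records the modeling and numerical choices behind `pcgnet`, in the
order the data flows through the package.

## Signal standardization

Every recording is brought to a fixed analysis length (default 1.4 s, i.e.
`round(fs × 1.4)` samples) before feature extraction: longer recordings keep
their **initial** portion, shorter ones are zero-padded at the end. Keeping
the beginning is a deterministic choice — heart-sound recordings have no
privileged alignment, and any 1.4 s window of a quasi-periodic signal carries
the same class information; the cut point is configurable through
`standardize_length`. The operation is idempotent. Resampling uses a
polyphase filter (`scipy.signal.resample_poly`) at the exact rational rate
ratio.

Dataset splitting operates strictly on whole recordings, never on segments,
so no recording contributes to both train and test. Holdout splits are
stratified by class; balanced k-fold assigns an equal per-class quota to each
fold (and requires class sizes divisible by k), random k-fold partitions the
shuffled manifest without class constraints. All randomness flows from the
plan's seed.

## MFCC configuration

Defaults: 0.2 s frames (1600 samples at 8 kHz, 400 at 2 kHz), 50% overlap,
Hamming window, 2048-point FFT (shorter windows are zero-padded to the FFT
length), 32 triangular unit-peak mel filters spanning 0 to fs/2 on the
standard mel scale m = 2595·log10(1 + f/700), natural log with a floor of
1e-10 on the filterbank energies (so silent frames produce finite, constant
columns), orthonormal type-II DCT, 17 retained coefficients.

Choices worth flagging:

* **Energy coefficient.** "17 static coefficients including the energy
  coefficient" is implemented as retaining DCT coefficient 0 (which is the
  mean log filterbank energy up to scale) rather than appending a separately
  computed frame log-energy row. This keeps the feature map exactly
  n_static × frames, matching the classifier's 17×13 input contract. A
  consequence used by the tests: scaling the waveform by a > 0 shifts only
  row 0 (by a constant per frame), leaving all shape coefficients unchanged.
* **Pre-emphasis** defaults to 0.97, the speech-processing convention; it is
  configurable and its exact value is not critical for band-limited heart
  sounds.
* **Deltas.** Delta and delta–delta rows (for the dimensionality study that
  motivates preferring the 17 static coefficients) use the standard symmetric
  regression window, default half-width 2, with edge frames replicated.
  A d-row static map becomes 3d rows (13 → 39).

## The WCNN and its training

The network is built from an explicit `ArchitectureSpec`, and three
quantities are derived *analytically* from that spec — forward shapes
(valid convolutions, floor division on stride), parameter count
((K_h·K_w·C_in + 1)·C_out per conv, (in + 1)·out per dense) and forward
FLOPs (2·K_h·K_w·C_in·H_out·W_out·C_out and 2·in·out). Batch normalization,
dropout, flatten and the KWC layer contribute zero to both counts
(normalization parameters are conventionally excluded as negligible; the
instantiated network's trainable-parameter count equals the analytic count
under the same exclusion, and the tests fuzz this identity over random
architectures). A consequence of the stride-2 third convolution: an even
input height and the next odd one yield identical parameter counts, since
the trailing row is floored away.

Conv blocks order activation before normalization (Conv → ReLU → BN);
the alternative order is available via `bn_before_relu` and changes neither
count. Dropout (rate 0.3, configurable — the rate is an artifact default)
sits after the third conv block and after the hidden dense layer. The KWC
layer sits after the conv stack, recomputes its weights from the current
activations on every forward pass, and backpropagates through both the
weight and the map (product rule); it is positively homogeneous of degree 2,
which the tests assert numerically.

Training uses Adam (framework-default β₁ = 0.9, β₂ = 0.999), initial
learning rate 1e-3 with a staircase decay of 0.95 every 10,000 iterations,
batch size 16, categorical cross-entropy on a softmax output — or, for
two-class problems, optionally binary cross-entropy on a single sigmoid
logit. Initialization is He-normal and fully seed-deterministic; two runs
with the same `random_state` produce bit-identical histories. A non-finite
loss raises `TrainingDivergedError` with the epoch, iteration and learning
rate. The engine is pure numpy (im2col-style convolution via strided views);
at these model sizes (312k parameters, 2×2 kernels) a CPU epoch over ~900
feature maps takes on the order of a second.

Binary problems treat the pathological class as the positive class for
precision/recall/f1; multiclass metrics are one-vs-rest with macro averaging
by default (macro is the convention that reproduces the published fold-level
recall and f1 from the benchmark's confusion matrices; weighted averaging is
available). Cohen's kappa comes from observed vs expected agreement on the
confusion matrix. AUC-ROC sweeps every distinct score threshold (ties
grouped) and integrates by trapezoids — equal to the Mann–Whitney
concordance fraction, which the tests verify by exhaustive pair counting.
Average precision is the step-wise precision-recall sum; mAP is the
unweighted per-class mean. Per-class ratios with zero denominators are
reported as 0 with a `RuntimeWarning` instead of raising, so a degenerate
fold cannot crash a cross-validation sweep. Hard labels from probabilities
use argmax (equivalently a 0.5 threshold in the binary case).

## Grad-CAM

Heatmaps are taken at the last convolution layer by default (any conv layer
can be selected): per-channel weights are the global average of the
target-class logit's gradient with respect to the layer activation; the
weighted channel sum is rectified, bilinearly upsampled from the conv grid
(7×5 by default) to the input geometry (17×13), and min-max normalized to
[0, 1]. An identically zero map (e.g. an untrained model on zero input) is
returned flagged rather than raising. `attention_profile` averages heatmaps
over samples and frames to one score per MFCC dimension — the quantity used
to judge which coefficient rows the model attends to. Because the conv grid
has 7 rows against 17 input rows, localization is accurate to roughly one
row; the planted-feature test therefore checks recall over seeded
repetitions rather than exact argmax identity.

## Band energy ratio

BER = (energy in 20–700 Hz) / (energy below 20 Hz plus above 700 Hz),
computed on the squared magnitude of the full-length DFT after resampling to
2000 Hz. Band edges are inclusive; the DC bin is excluded from the
denominator (a constant offset is neither heart sound nor meaningful noise
energy). A signal whose out-of-band energy is numerically negligible
(< 1e-12 of the total) is flagged with an unbounded ratio instead of raising;
an all-zero signal raises. No averaging or windowing is applied by default
(the metric is a plain spectral sum; a taper can be passed in). The
three-way decomposition (`band_decompose`) reconstructs the 20–700 Hz
component and its complement by zero-phase spectral masking at the native
rate, so the parts sum exactly to the raw signal.

## Synthetic generator

The generator emulates only what the pipeline consumes:

* **Timing.** Heart rate is drawn from 60–100 bpm (resting adult range),
  duration from 1.2–4 s (matching the five-class corpus the workflow
  targets). S1 is placed near each cycle start and S2 at 35% of the cycle;
  both are Gaussian-windowed tones (S1 in 30–100 Hz, S2 in 50–150 Hz, S2 at
  0.6 relative amplitude).
* **Murmurs** are band-limited noise under class-distinct envelopes:
  mid-systolic diamond at 200–450 Hz (aortic stenosis), holosystolic flat at
  100–250 Hz (mitral regurgitation), diastolic decaying rumble at 100–220 Hz
  (mitral stenosis), mid-systolic click (300–600 Hz) plus late-systolic ramp
  at 150–350 Hz (mitral valve prolapse), none for normal. Amplitude defaults
  to 0.35 of S1; at amplitude 0 every class degenerates to the normal
  waveform under the same seed. The binary mode draws one pathological
  template per abnormal recording and supports the 4:1 normal:abnormal
  imbalance.
* **Noise.** Drift at 1–18 Hz and hiss at 720–950 Hz. The hiss band is
  deliberately kept below 1000 Hz so that it survives resampling to the
  2000 Hz BER analysis rate — otherwise the generator's energy ledger and
  the measured BER would disagree by construction. The noise scale solves
  the exact quadratic (including the signal-noise cross spectrum) so the
  ledger's in-band/out-of-band ratio equals the requested target to
  numerical precision; the measured BER then recovers the target to within
  a few percent (the residual is the resampling filter's passband edge).
  Requesting a target at or above the clean signal's ratio is an error
  (noise can only lower it); a sampling rate with no room above 700 Hz
  falls back to drift-only injection, flagged in the ground truth.
* **Ledger.** Per-recording ground truth records event times, murmur windows
  and a spectral (Parseval) energy split of the final waveform — in-band,
  out-of-band, DC — which sums exactly to the time-domain energy.
  Defining the ledger spectrally (rather than summing per-component
  time-domain energies) is what makes the Parseval identity hold exactly;
  additive component energies would differ by cross terms.

What the generator does **not** emulate: real murmur morphology, ECG
alignment, respiratory modulation, sensor transfer functions, or inter-class
acoustic overlap. Classes are separable by construction, so passing
end-to-end tests demonstrates that the pipeline learns and evaluates
correctly — not that the model would reach the same accuracy on clinical
recordings.

## Test problem sizes

The end-to-end separability check trains the default model on the
generator's full five-class study condition (200 recordings per class, fixed
seed, stratified 90/10 holdout) for 18 epochs — convergence on the clean
synthetic set occurs well before that, so the longer published schedule adds
nothing here. The KWC ablation check uses 5 seeded repetitions at a reduced
size (40 recordings per class, 6 epochs) under heavy noise (target BER
0.05), comparing macro-f1 of the full model against the KWC-removed variant;
at these sizes both variants are near ceiling on several seeds, so the check
is directional (full ≥ ablated in a majority of runs), matching its intent.

## Known limitations

* The numpy training engine is single-threaded apart from BLAS matmuls; it
  is sized for the 312k-parameter WCNN, not for large architectures.
* Replicating the published headline accuracies requires the two public
  clinical corpora (five-class GitHub PCG at 8 kHz; PhysioNet/CinC 2016 at
  2 kHz), which are not downloaded or bundled; the workflow accepts them as
  ordinary WAV manifests once obtained.
* The published fold-level precision for the first balanced fold (98.05)
  is not exactly the macro precision recomputable from its confusion matrix
  (≈98.10); the averaging behind that single printed value is unclear, so
  precision is checked structurally but not against that digit.
* BER is descriptive: the package does not reject or down-weight recordings
  by quality.
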