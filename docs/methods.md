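# Methods

`ecgfusion` re-creates, at desk scale and on synthetic data, a hybrid
two-branch pipeline for classifying single-lead ECGs that are only
available as plot images: one branch works on handcrafted beat features,
the other on an audio-style Mel-spectrogram rendering of the same trace,
and the two class-probability vectors are combined by weighted
aggregation. This note records the models, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical conventions a reader would need to reproduce or extend the
results.

## Synthetic ECG model

Each heartbeat is a sum of five Gaussian kernels — P, Q, R, S, T — with
per-wave amplitude (mV), width (the Gaussian sigma, seconds) and center
offset relative to the R peak (seconds). Beats repeat at the period
implied by the heart rate; optional additive white noise (`noise_sd`,
mV) and a 0.33 Hz sinusoidal baseline wander complete the record. The
generator returns exact fiducials (R-peak indices, RR intervals, and
half-open P/QRS/T sample windows), which is the point: every downstream
stage can be scored against ground truth.

Two presets encode the study's class contrast. The negative class is a
textbook beat (R amplitude 1.0 mV, QRS sigmas 10–12 ms). The positive
class widens Q/R/S by 1.6x and raises R to 1.5 mV (Q and S by 1.4x) — a
ventricular-hypertrophy-like signature in which the QRS complex is both
broader and taller. Default study conditions: 75 ± 5 bpm, 250 Hz,
10 s records, `noise_sd = 0.05`, wander amplitude 0.02, 100 records per
class.

What the generator does *not* emulate: realistic PQRST morphology
variation, arrhythmias, electrode artifacts, multi-lead layouts, or the printed
grid of clinical ECG paper (an optional light grid can be drawn). Passing tests therefore demonstrate that the pipeline's
machinery is correct and that it can learn and explain a controlled
QRS-morphology contrast — not that it would diagnose real patients.

## Plot rendering and digitization

Records are rasterized dark-on-light: the trace's amplitude range maps
affinely onto the vertical plotting region (maximum at the top), samples
map left-to-right onto columns, and the stroke joins adjacent columns
vertically at a configurable thickness. The default canvas is
256 × 1280 px with a 10 px margin; at 10 s per record this yields ~126
columns/s, enough for a 10–20 ms QRS stroke to survive rasterization
(at 768 px the digitization round-trip correlation drops from ~0.97 to
~0.92 because R spikes alias into single columns).

Digitization follows grayscale → Gaussian blur → adaptive threshold →
largest 8-connected component → column-wise read-out. The adaptive rule
marks a pixel as foreground when its blurred intensity lies more than
`adaptive_offset` below the local block mean (31 px block). Defaults are
a light blur (kernel 3, sigma 0.6) and offset 30: a heavier blur or a
more permissive offset keeps a halo several pixels wide around the
stroke, which biases the column-mean amplitude read-out. Columns without
foreground are filled by linear interpolation. Pixels never carry a
time calibration; callers must pass columns-per-second explicitly.

## Audio conversion and spectrograms

Traces are centered and scaled to [-1, 1]. Two normalization modes
exist because the natural reading of "subtract the mean, divide by the
maximum absolute value" does not actually guarantee that range when the
signal has a large offset: `verbatim` divides by max|x| as written,
`strict` (default) divides by max|x − mean| so the advertised range
holds. Resampling is FFT band-limited with output length
round(L·target/source); audio is written as 16-bit PCM mono WAV at
8 kHz, the conventional rate for heart-sound work.

A digitized ECG is band-limited to half its column rate (~63 Hz here).
Fed directly into a 22.05 kHz Mel analysis, all of its content lands in
the bottom two of 128 Mel bands and the spectrogram is a single active
row — unusable for classification or for localizing anything. The
pipeline therefore sonifies at 8x playback speed (the standard trick
for sub-audio biosignals), which lifts the ECG band to ~4–500 Hz where
the Mel filterbank resolves it and QRS spikes appear as broadband
vertical striations. The spectrogram stage itself is fixed at the
standard audio configuration: 22,050 Hz, FFT 1024, hop 512, periodic
Hann window, 128 unit-peak triangular Mel filters with centers equally
spaced on M(f) = 2595·log10(1 + f/700) between 0 and the Nyquist
frequency. Power is converted to dB against the per-spectrogram maximum
with a −80 dB floor, min–max scaled, bilinearly resized to 224 × 224 and
replicated to three channels; dB conversion happens before resizing.

## Beat features (branch 1 input)

R peaks come from a Pan–Tompkins-style detector: 20 ms moving-average
lowpass, first difference, squaring, 150 ms moving-window integration,
candidate peaks at least 200 ms apart, an adaptive acceptance threshold
at half the running mean of accepted integrated peaks, and a slope-based
T-wave veto for candidates within 360 ms of the previous beat. The
reported index is the raw-trace maximum inside the detection window.
The lowpass matters: at `noise_sd = 0.05` the first difference of raw
noise rivals the R slope and both the threshold margin and the T-veto
degrade without it (precision ~0.90 instead of 1.00).

Per beat the extractor reads the P amplitude (maximum in R−200..−80 ms),
the QRS peak-to-peak value and QRS maximum (R ± 60 ms); windows clipped
by record edges shrink rather than error. The record's lists — RR
intervals, P values, QRS values, QRS peak indices, QRS maxima — are
packed column-wise into a zero-padded N × 5 matrix, N being the longest
list.

## Classifiers

Both networks are written on a small reverse-mode autodiff engine
(float64, pure numpy) so that the defining equations appear literally in
code, gradients are exact (verified against central differences), and
runs are bit-reproducible on one CPU.

**Branch 1** pads feature matrices to 16 rows, standardizes per column,
and treats them as a 5-channel sequence. Three pre-activation residual
blocks — out = x + W2ᵀ ReLU(BN(W1ᵀ ReLU(BN(x)))) with kernel-2
convolutions — at widths 32, 64, 128 (1-lift convolutions between
blocks; max pooling after the first two blocks only) feed a
bidirectional tanh RNN encoder and a second BiRNN decoder whose linear
read-out of [h_fwd, h_bwd] is averaged over time and soft-maxed.
Training: He-normal init, decoupled-weight-decay Adam at lr 1e−4 and
decay 0.01, batch 32, cross-entropy, early stopping on a stratified 15%
validation split, 25 epochs.

**Branch 2** is a compact spectrogram classifier with the same input
contract as a large pretrained audio-spectrogram transformer (224×224×3
in [0,1]), which can be plugged in instead via `external_model`. The
image is channel-averaged and average-pooled anisotropically to 28 × 112
(frequency 8x, time 2x): beats are ~0.8 s apart, and coarser time bins
could not localize a QRS at all. Rows are standardized per frequency
band — energies differ by orders of magnitude across bands, and within-
row time structure is what Grad-CAM localization depends on. Two 3×3
convolutions (8 then 16 channels, ReLU, 2x max pooling) are read out by
a time-averaged linear head. Training mirrors a fine-tuning protocol:
phase 1 updates the head only, phase 2 everything, AdamW at lr 2e−5,
decay 0.01, batch 16, up to 50 epochs, SpecAugment-style masking on
training batches, early stopping and best-checkpoint restoration across
both phases.

Two defaults earn a justification. The classifier heads are
zero-initialized so training starts at the uniform softmax: at these
small learning rates, He-initialized heads begin with large confidently
wrong logits and spend most of the epoch budget undoing them. And the
default augmentation is mild (one time + one frequency mask, 8 cells):
mask fills at the image mean are roughly 40x larger than the synthetic
class contrast, and aggressive masking removes the signal faster than it
regularizes.

SMOTE balances classes before branch-1 fitting (synthetic minority
points drawn uniformly on segments to one of the k = 5 nearest minority
neighbours; originals preserved). The study design is balanced, so this
is a no-op there, but in cross-validation it is restricted to training
folds to prevent leakage. The ensemble is p = w1·p1 + w2·p2 with
default (0.5, 0.5) and an optional accuracy grid search; argmax ties
resolve toward the positive class.

## Explainability

Grad-CAM weights each channel of the last convolutional activation by
the spatial mean of the class-score gradient, sums, rectifies, upsamples
bilinearly to the input grid and min–max normalizes. Region metrics
follow the two-number protocol: Region Attention Accuracy (RAA) is the
percentage of samples whose most-activated connected region (cells
≥ 0.5) touches any expected zone; QRS overlap is the fraction of
activated area inside the QRS zone. Expected zones come from the
generator's ground-truth windows — mapped trace-sample → audio-sample →
STFT frame → image column, spanning all frequency rows — so on synthetic
data the metrics measure ground-truth agreement, not expert agreement.
Significance of the mean QRS overlap is assessed against a null that
circularly shifts each QRS mask along the time axis (200 permutations).

A known limitation, established experimentally and worth stating
plainly: the QRS-localization property is unstable across training
seeds (at seeds 0/1/2 the 50-sample permutation test gives p ≈
0.72/0.03/0.005). Three mechanisms interact. First, amplitude
normalization divides by the R peak, so the positive class's taller R
rescales its P/T/baseline *down* — planting genuine class evidence in
non-QRS regions. Second, the QRS spectral signature itself is
sign-ambiguous: a wider QRS has more mid-band but less high-band energy.
Third, a two-logit softmax head determines only the difference of the
class scores, so which class's rectified map inherits the QRS-positive
evidence is an initialization accident. The metrics and the test are
kept faithful to the protocol rather than adjusted to mask this.

## Evaluation

Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy
(TP+TN)/total, F1 from precision and recall; all carried at full
precision with display rounding chosen per report (integer, one- and
two-decimal percent presets all appear in the literature). AUC is
trapezoidal over thresholds with tied scores collapsed, which equals the
positive–negative pair concordance estimator exactly (property-tested
against brute-force enumeration). Splitting is stratified 80/20 with
per-class rounding; cross-validation is stratified 5-fold with per-fold
metrics and mean ± sample-sd reporting, all fitting (SMOTE included)
confined to training folds.

## Problem sizes and numerical conventions

The shipped study uses 100 records per class; the full run (both
subsystems at their stated epoch budgets plus reduced-epoch 5-fold
cross-validation — 10 epochs for branch 1 folds, 20 for branch 2 folds)
completes in a few minutes on one CPU. Degenerate inputs follow explicit
conventions rather than erroring where a value is representable: a
constant trace renders as a mid-plot line and normalizes to zeros (with
a warning), an all-zero spectrogram sits at the dB floor, a featureless
record packs to a 1 × 5 zero matrix, a constant Grad-CAM map returns
zeros. Component ties in the digitizer break toward the smallest
row-major pixel index; ensemble argmax ties break toward the positive
class. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; there is no global RNG state.
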