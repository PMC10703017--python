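# Methods

## Problem and model

Given multichannel resting-state EEG recordings x_i with binary labels
y_i (1 = PD-like, 0 = control-like), the package learns a classifier F
minimizing the mean categorical cross-entropy over the training set.
Recordings are band-pass filtered, segmented, artifact-rejected,
transformed to time-frequency feature sequences, and classified by a
recurrent network; per-segment scores are fused into one prediction per
subject.

### Gabor transform

The analysis kernel is a Gaussian-windowed complex exponential
g(u, f) = exp(−u²/2σ_t²)·exp(j2πfu). We compute

    X(t, f) = (1/fs) · Σ_τ x(τ) · conj(g(τ − t, f)),

a Riemann-sum discretization of the continuous windowed transform with
the kernel truncated at ±`truncation`·σ_t (default 6) and zero-padded
edges. Written with the modulation inside the window, the integrand is
exp(−(τ−t)²/2σ_t²)·exp(−j2πf(τ−t)); an alternative formulation that
modulates by exp(−j2πfτ) while the kernel itself also carries a
modulation would double-shift the spectrum and localize a pure tone at
half its frequency, so the windowed-inner-product form above — the one
for which a tone's magnitude peaks at the tone frequency, which the test
suite asserts — is the implemented definition. |X| is invariant to the
residual phase convention.

Defaults: σ_t = 0.1 s (≈1.6 Hz frequency SD, a balanced time-frequency
trade-off for the 1–45 Hz band), analysis frequencies 1–45 Hz at 1 Hz
steps, and `n_steps = 178` evenly spaced analysis instants per segment —
the classifier presets' published input length. Feature sequences
concatenate per-channel log-magnitudes (floor 1e−8; magnitudes span
decades and the log keeps gradients usable).

### Recurrent networks from the gate equations

`pdeeg.cells` implements the LSTM cell exactly as the gate equations
read: i, f, o are sigmoids of affine maps of [h_{t−1}, x_t]; the
candidate cell state is the tanh of the same form; c_t = f⊙c_{t−1} +
i⊙ĉ_t; h_t = o⊙tanh(c_t). The bidirectional composition runs an
independent cell over the reversed sequence and concatenates per step;
its non-sequence output is [h_f(T), h_b(1)], the final step of each
direction — the only convention consistent with the published
(None, 256) shape of the wide bidirectional block.

The densely linked stack gives layer l the concatenation of all
preceding layers' outputs [d⁰, …, d^{l−1}] (d⁰ ≡ x) and emits
d^l = [h^l, x_t]. Concatenation, not element-wise addition, is the
linking operation — skip-concatenation preserves gradients without
requiring width-matched residuals. (One printed recurrence skips d¹ in
its ellipsis; we read it as all preceding layers, which is the only
reading under which the stated widths compose.)

These pure-NumPy functions are the reference semantics. The trainable
network (`pdeeg.network`) re-implements the same arithmetic on a small
reverse-mode autodiff engine (`pdeeg.autodiff`) and is held to agree
with the reference to 1e−12 in the test suite; no external deep-learning
framework is involved anywhere.

### Architecture presets and parameter counting

Three named presets reproduce the published layer tables
layer-for-layer. The counting rules are: dense = units·(in+1);
lstm = 4·(units·(in+units)+units); bilstm twice that; batch
normalization = 4·features — scale, shift, and the two running-moment
vectors. Counting the (untrained) running moments is the only convention
that matches the printed 1,024 and 256; training updates only scale and
shift. Two printed numbers do not follow from the printed shapes: the
first LSTM count 668,928 implies an input feature width of 2548 (stated
nowhere; the preset adopts it so the count reproduces), and the 99 for a
32→2 dense head (which is 66 by any counting rule) is reproduced by
nothing and reported as 66.

The published tables also declare a per-step feature dimension of 1,
which cannot carry a multi-frequency spectrogram; feature width is
therefore a preset parameter (`input_width`), and the published tables
are reproduced verbatim at width 1 for counting and inspection.

### Loss and fusion

The loss is standard categorical cross-entropy with log-sum-exp
stabilization: mean over rows of −Σ_i y_i(φ_i − log Σ_k exp φ_k). The
multi-scale sliding-window fusion averages, for each window width p, the
per-window mean scores over all T−p+1 windows, then averages over
widths — a normalization under which constant score sequences are fixed
points. The raw printed double sum with divisor (T−p)·p is available
behind `FusionConfig(literal=True)` for comparison; it is not a fixed
point on constant inputs, which is why the corrected reading is the
default. Fusion widths {1, 3, 5} convert a subject's per-segment
positive-class scores into one subject-level score, thresholded at 0.5.

### Training

Adam (lr 0.001), batch 64, up to 20 epochs, dropout 0.4 — the best
column of the published hyperparameter sweep; the optimizer itself is
unnamed there and Adam is the field default. Early stopping monitors
validation loss with patience 5 and restores the best epoch's weights.
Initialization is Glorot-uniform with zero biases except the forget-gate
bias at 1 (the standard stability convention). All randomness descends
from a single integer seed; runs are bit-reproducible.

## Evaluation protocol

* **80-10-10 split**: stratified by class, |val| = |test| = ⌊0.1·n⌋,
  remainder to train (31 subjects → 25/3/3).
* **Six-fold cross-validation**: stratified fold assignment at the
  *subject* level by default, so no individual contributes segments to
  both a training and a test fold. Whether the published protocol folded
  subjects or segments is unstated; subject-level is the leakage-safe
  reading and segment-level is available behind `level="segment"` for
  comparison. The split evaluation and the cross-validation are
  independent modes, not composed.
* **Metrics**: accuracy, precision, recall/sensitivity, specificity, F1
  (harmonic mean of precision and recall), each also reported per class
  with the class roles swapped; ratios with zero denominators are
  reported as 0 and flagged rather than raised. AUC uses the
  rank-statistic (Mann–Whitney) formulation with ties counted half.
* **Leakage guard**: normalization and feature-standardization
  statistics come from training folds only; held-out subjects' features
  are read only after the fold's model has finished training (the test
  suite audits the access order through the dataset accessor).

## Synthetic cohort generator

Each subject's signal is a sum of per-band filtered Gaussian noise
(4th-order Butterworth band-pass of white noise — EEG-like spectra, not
tones), broadband Gaussian noise (5 µV), a mains sinusoid (50 Hz, 2 µV
by default), and blink-like transients: one-sided exponential bumps
(τ = 75 ms, ≈0.3 s support) at 10/min, amplitude 5–10× the analytic
background SD, full-strength on the first quarter of channels
("frontal") and 0.15× elsewhere. `artifact_truth` records each bump's
0.15 s high-amplitude core, so rejection rules can be scored against
ground truth. Default band powers are alpha-dominant
(δ 1.0, θ 0.7, α 1.5, β 0.8, γ 0.3 relative variance; band RMS =
5 µV·√power).

The class effect is a band-power ratio — by default elevated beta in the
PD-like class. This is a controllable stand-in chosen for testability,
**not** a claim about PD electrophysiology; nothing in the underlying
clinical literature pins down a single spectral discriminant, and the
package makes no such claim.

Per-subject, per-channel gains U(1±spread) (default spread 0.1) emulate
electrode-impedance variability and give every subject a stable
multichannel amplitude fingerprint. The fingerprint is deliberately
multichannel rather than a single scalar: a scalar gain is a
one-dimensional signature whose values collide across classes in small
cohorts, which would make the subject-identity leakage that segment-level
cross-validation suffers from — a real and well-documented failure mode —
undetectable in the demonstration below.

What the generator does **not** emulate: volume conduction and
inter-channel correlation, non-stationarity over minutes, realistic
artifact taxonomies (muscle, electrode pops), and any physiologically
grounded PD signature. Passing tests therefore demonstrate that the
pipeline recovers a known spectral class effect under honest
cross-validation — not that it diagnoses PD.

## Experiment scales

Desk-scale study conditions (chosen once; all seeds flow from the
experiment seed):

* **Class-effect recovery**: 15 PD-like + 16 control-like subjects
  (the published cohort's class sizes), 8 channels at 128 Hz, 60 s per
  subject, 2 s non-overlapping segments, amplitude rejection at 5 robust
  SDs, Gabor features on a 4–40 Hz grid (4 Hz steps) at 32 time steps,
  classified with the two-block bidirectional preset scaled to 16 units;
  six-fold subject-level CV with beta ratio 3, plus a permuted-label
  null. The γ band is dropped at this sampling rate (its upper edge
  exceeds Nyquist).
* **Leakage demonstration**: 6+6 subjects, 40 s each, zero class effect,
  gain spread 0.5, three folds at both CV levels, trained to convergence
  (60 epochs, no early-stopping budget) because the leaked
  subject-identity signal is precisely what a memorizing fit picks up.

## Numerical choices and degenerate inputs

* Filters: 4th-order Butterworth SOS applied forward-backward
  (zero phase); IIR notch with Q = 30 at a configurable 50/60 Hz.
* Segmentation: 0-based sample indices, half-open [start, end)
  intervals; a window longer than the recording yields zero segments
  with a warning, not an exception.
* Normalization: zero-variance channels floored at machine epsilon and
  logged; `train_only` statistics are returned for reuse on held-out
  data.
* ICA-based scrubbing (optional): FastICA decomposition with components
  whose time courses have excess kurtosis above 5 zeroed before
  amplitude thresholding — a surrogate for the manual artifact curation
  real datasets receive; the kurtosis rule targets spiky blink/muscle
  components and is scored against generator ground truth.
* EDF writing quantizes to 16 bits over each channel's printed physical
  range; the writer re-parses its own printed header fields so the
  round-trip error is bounded by quantization alone. HDF5 is the
  lossless mirror and carries `artifact_truth`.
* Cross-entropy uses log-sum-exp; gates use the numerically stable
  split-sign sigmoid.

## Known limitations

* The trainable network runs on a minimal autodiff engine: single CPU,
  no GPU path; wall-clock scales linearly in sequence length and fold
  count.
* The generator's class effect and subject fingerprints are simplified
  (see above); results on synthetic cohorts bound what the pipeline can
  do, not what any clinical model achieves.
* Real-data reproduction of published headline figures requires the
  external cohort those figures were computed on and a fold-unit
  disclosure that does not exist; the package deliberately reports
  synthetic-cohort substitutes instead.
* Segment-level cross-validation is provided only to demonstrate its
  failure mode; it should not be used for reporting.
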