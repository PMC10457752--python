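# Methods

## Signal model

An EBI channel is treated as `Z(t) = Z0 + dZ(t)`: a static tissue
impedance plus a small cardiac-pulsatile component, and likewise
`rPPG(t) = rPPG0 + drPPG(t)` for the optical channel. The package never
models complex (phase) impedance; all series are magnitude-style.

`Z0` is estimated as the **median** of the raw channel — robust to the
asymmetric pulse shape, which biases a mean upward. `dZ(t)` is the
Savitzky–Golay-smoothed channel minus that baseline; smoothing uses 100
side points (window 201) with polynomial order 3, a common default that
preserves peak shape. The per-beat amplitude is max−min of `dZ(t)` within
each beat-centered span (bounded by midpoints between consecutive
systolic peaks); `dZ(t)_mean ± σ` are the mean and SD of those per-beat
amplitudes, i.e. σ measures across-beat dispersion within a recording
(the plausible alternative — dispersion across repeated recordings — is
obtained by aggregating the per-recording table). The denominator of the
sensitivity `100·dZ_mean/Z` is the maximum of the **raw** (unsmoothed)
channel.

## Synthetic generator

The generator replaces non-public single-subject recordings. Each
recording is built as baseline + slow drift + respiratory-modulated pulse
train + white noise, per channel, with ground-truth systolic-peak indices
recorded.

- **Pulse template.** One cardiac period is a superposition of smooth
  Gaussian bumps: a systolic peak at the segment midpoint and a dicrotic
  complex (notch dip followed by a reflected-wave bump) after it. The
  complex is scaled as a unit by `notch_amp_frac`: with no notch the
  reflected wave merges into the systolic decay, as in an overdamped
  pulse, so `notch_amp_frac = 0` guarantees a single local maximum. The
  complex is additionally capped analytically so the systolic peak is
  always the strict global maximum, for any admissible fractions; the
  peak-to-trough range equals the programmed amplitude exactly.
- **Beat schedule.** Per-beat periods are drawn normally around
  `fs·60/HR` with an SD mapped from the beats-per-minute jitter; beats
  whose template would cross the end of the recording are dropped.
- **Respiration.** Sinusoidal amplitude modulation (default 15
  breaths/min), applied as a scalar factor per beat evaluated at the peak
  time, so per-beat amplitudes follow the respiratory envelope exactly.
  Depth defaults to 0.15 for the brachial and carotid sites, where
  respiratory influence is prominent, and 0.05 elsewhere.
- **Excitation frequencies.** The four EBI channels share one pulse train
  scaled by a per-frequency factor (0.85/1.0/1.15/1.25 for
  50/100/500/1000 kHz) with independent noise — the minimal testable
  model of frequency dependence; no tissue-spectroscopy realism is
  attempted.
- **Defaults.** Per-site pulse amplitudes use the measured scale
  (dZ 0.029–11.123 Ω, drPPG 0.068–0.413 V); baselines are set so the
  sensitivity lands near the reported figures (carotid ≈ 0.86%, posterior
  tibial ≈ 0.27%, others below). Heart rate 65 ± 2 bpm, duration 60 s
  (no canonical duration exists; 60 s yields ~60 periods per recording,
  enough for stable folds). EBI noise SD is 6% of the pulse amplitude
  (EBI needs filtering in practice) against 1% for the optically clean
  rPPG channel; drift is 15% of amplitude at 0.05 Hz.
- **Null mode** gives every class the brachial morphology and amplitudes,
  making sites indistinguishable by construction — the negative control.

What the generator does **not** emulate: motion artifacts, electrode
contact changes, frequency-dependent morphology shape changes, inter-beat
morphology drift, or subject-to-subject variability. Passing tests
therefore demonstrate that the pipeline recovers what its assumptions
encode, not clinical performance on real skin-surface recordings.

## Segmentation

Peaks are detected on the band-passed (Butterworth order 2, 0.5–50 Hz,
zero-phase forward–backward so peak times are not lag-shifted),
normalized signal by local-maximum search with a refractory distance
(default 0.4 s ⇔ 150 bpm) and a prominence threshold (30% of the signal
range). The filtered signal's own maximum defines the window center.
Windows are 1495 samples: the classifier's average-pooling factor of 5
and its published stage lengths force an input of 5 × 299; for even
lengths the peak sits at the left-of-center sample `len//2`. Windows
crossing the recording bounds are dropped silently.

## Classifier

Nine layers; unpadded convolutions (299−4+1 = 296, 74−20+1 = 55) and
pool sizes 4 and 11 — the unique integer choices reproducing the stage
lengths with stride = size. Hidden activations are ReLU; the output layer
is softmax with cross-entropy. Totals: 20 + 810 + 3264 + 325 = 4419
trainable parameters, none non-trainable.

The implementation is pure NumPy (im2col-style convolution, explicit
backward passes, Adam). Training defaults — Adam at 1e-3, 30 epochs,
batch 32 — are exposed in `TrainingConfig`; weight initialization is
He-normal. Correctness of the backward pass is established by a
finite-difference gradient check in the test suite, and the initial
average-pooling is verified to be part of the model (pooled input through
the truncated stack equals raw input through the full stack).

Cross-validation is stratified at the **period** level (periods are
treated as separate samples). Because overlapping windows from one
recording then appear in both train and test folds, a recording-level
split mode (`split_level="recording"`) is provided; the null-generator
control bounds the practical effect of this leakage — with class
information removed, period-level CV still scores at chance.

## Metrics and aggregation

The per-period probability is trace/total of the confusion matrix
(per-class: diagonal over row sum). Majority-vote accuracy resolves ties
by higher mean prediction score, then lowest class index — a documented
deterministic convention. With 15 recordings the accuracy granularity is
1/15. "Median of runs" is applied to confusion-matrix **cells**, metrics
recomputed from the median matrix; `of_metrics=True` medians the metrics
instead. All randomness — generator, fold assignment, initialization,
dropout, shuffling — derives from one master seed via SHA-256, so a rerun
reproduces every report byte for byte.

## Problem sizes

The full study conditions are 5 classes × 3 × 60 s recordings
(~190 windows per class), 5-fold CV, 10-run medians. The test suite and
examples use these conditions for the class-recovery and null controls
and smaller sizes (12–30 s, 1–3 runs, fewer epochs) where the property
under test — determinism, bookkeeping, qualitative channel ordering — is
scale-free; each test states its sizes inline.

## Known limitations

- Single synthetic "subject": no inter-subject morphology variation, so
  absolute classification figures are not comparable to human data.
- The frequency channels differ only in gain and noise; morphology shape
  differences across excitation frequencies are not modelled.
- Peak detection assumes an upright systolic peak after band-passing;
  inverted or severely clipped waveforms are out of scope.
- Derivative-based fiducial points (dZ/dt nomenclature) beyond the
  systolic peak are not implemented.
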