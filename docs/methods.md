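# Methods

## Signal model and preprocessing

A recording is a single-channel neck-PPG trace, 140 s at 75 Hz, tagged
with a scenario (control, slow breathing, breath hold, or one of eight
artifact subtypes) and accompanied by ground-truth interval annotations
`[onset, offset)` in seconds; unannotated time is implicitly `normal`.
Each recording is normalized independently by z-scoring. The method for
normalization is a design choice (the protocol being emulated states
only that recordings were normalized independently): z-scoring makes
amplitude-derived features comparable across subjects and sensors and
keeps the zero-crossing rate meaningful around zero.

## Pulse segmentation

Systolic peaks are local maxima of a 0.5–8 Hz zero-phase (Butterworth
order 2, forward-backward) band-passed copy of the signal, gated by a
minimum separation of 60/max_rate s (default max_rate = 180 bpm) and a
prominence threshold of 0.5× the filtered signal's standard deviation.
Onsets are minima of the *raw* signal between consecutive peaks; the
offset of pulse i is the onset of pulse i+1, and the final offset is the
last raw-signal local minimum after the last peak. Pulses truncated by
the recording edge are dropped rather than extrapolated. The detector
itself is this package's choice — simple, deterministic and auditable —
validated against generator beat times (count within ±1 beat-equivalent
tolerance; median peak error ≤ 2 samples on clean synthetic signals).

## The 51 features

Windows of length W ∈ {4,5,6,7,8,10} s slide by 2 s. Per window:

* **F1–F8** are means over in-window pulses of amplitude (onset→peak),
  width (onset→offset, s), peak-height difference, peak distance (s) and
  trough difference between consecutive pulses, rise time (s), and
  value-distribution skewness/kurtosis of the pulse segment.
* **F9–F16 (Change)** are means of absolute consecutive differences of
  each per-pulse series; absolute values are used so sign cancellation
  cannot mask instability.
* **F17–F24 (Std)** are sample (n−1) standard deviations of each series.
* **F25** is the zero-crossing rate (sign changes per second; zeros
  inherit the previous sign).
* **F26–F29** come from the biased, lag-0-normalized autocorrelation of
  the mean-removed window, searched for local maxima from lag 0.25 s
  (guarding the trivial lag-0 peak; 0.25 s corresponds to a 240 bpm
  ceiling) up to min(4 s, W/2).
* **F30–F41** derive from a spectrogram of 10 s Hamming-tapered
  modified-periodogram frames hopped by 1 s (90% overlap), stored in
  dB/Hz with a −120 dB floor. The window PSD is the mean over frames
  whose centers fall in the window, converted back to linear power for
  all arithmetic — dB is presentation/storage only. Spectral entropy is
  Shannon entropy (natural log) of the band-restricted normalized PSD
  divided by log(#bins), so values lie in [0,1]. Spectral kurtosis is
  the per-bin normalized fourth moment of the real STFT part over
  in-window frames (falling back to frames merely overlapping the
  window when fewer than four centers are inside), band-averaged.
  Relative powers divide band sums by the total; average band powers are
  band means. Band edges are inclusive with a 1e-9 Hz tolerance because
  the printed band limits coincide exactly with the 0.1 Hz bin grid.
* **F42–F51** use the upper envelope: a cubic spline (not-a-knot)
  through local maxima at least 50 samples (0.667 s) apart, constant
  beyond the outer knots, degrading to a flagged constant when fewer
  than two maxima exist. Envelope statistics, ApEn, trapezoidal area of
  the absolute envelope, and mean periodogram powers of the mean-removed
  envelope in 0–0.15, 0.2–0.5, 0–0.5 and 0.5–1 Hz.

Approximate entropy follows the standard Pincus definition — Chebyshev
distance, self-matches included, ApEn = Φ_m − Φ_{m+1} — with m = 2 and
r = 0.2·std(x). The std-scaled radius is scale-consistent after
z-scoring; a constant input returns 0 by convention.

Windows with fewer than two detected pulses give NaN for pulse-based
features and are dropped (with a log entry) at table assembly.

## Labelling, balancing and tasks

A window is positive when its corrupt fraction — continuous overlap of
positive-class annotation with the half-open window span, divided by
W — reaches Thd. For the artifacts task the positive class is any
artifact subtype and the negative class is all clean PPG (normal, slow
breathing and apnea). The apnea task lives in the clean-PPG universe:
windows overlapping any artifact are excluded outright, and the feature
table is restricted to breath-hold recordings, whose normal-breathing
gaps supply the negatives (the thirds partition below operates on
exactly those recordings). Tables are balanced by seeded uniform
downsampling of the majority class; no synthetic oversampling.

The experiment driver additionally caps each class at `max_per_class`
windows (default 1000) per table. This bounds the cost of the LOSO grid
search on large synthetic cohorts; it is a problem-size choice of this
package, applied before partitioning, and does not change the generator
conditions.

## Model and selection pipeline

The classifier is a soft-margin SVM, minimize ½‖w‖² + C·Σξᵢ subject to
yᵢ(w·φ(xᵢ)+b) ≥ 1−ξᵢ, ξᵢ ≥ 0, with Gaussian kernel
K(x,x′) = exp(−γ‖x−x′‖²), γ = 1/(2σ²). Features are z-scored with
training-fold statistics before the kernel (stored in the model, so test
data always uses training statistics). The solver is scikit-learn's SVC
with an iteration cap of 2·10⁵; near-degenerate grid corners (γ = 2⁻¹⁵
gives an almost constant kernel) otherwise dominate runtime while never
being selected.

Per outer repetition, on the training side only:

1. chi-square ranking of all 51 features — each feature is discretized
   into 10 equal-frequency bins (equal-frequency avoids empty cells on
   skewed features; the discretization is a design choice) and tested
   for independence against the label; ascending p-value, ties broken by
   feature index; constant features get p = 1;
2. grid search over the task's printed C/γ grid at the top-30 feature
   set, scored by LOSO fold-mean accuracy (artifacts) or pooled F1
   (apnea — F1 is ill-defined on tiny per-subject folds); ties prefer
   smaller C, then smaller γ (smoother models);
3. forward sequential selection: candidates ranked 31–51 are offered in
   rank order at the chosen (C, γ); a candidate is accepted while the
   relative decrease in LOSO misclassification error (1 − accuracy on
   concatenated LOSO predictions) is at least 1e-6, and the search stops
   at the first failure;
4. final refit on all training data with the selected subset.

Fixing hyperparameters during selection (tuning before selecting) is a
documented ordering choice; the alternative order is not specified by
the pipeline being reproduced.

## Partitions

*Artifacts*: leave-30%-of-subjects-out — round(0.30·n) subjects form the
test side, all their recordings travelling with them. *Apnea*: each
subject's breath-hold recording is split into three contiguous
equal-duration segments; windows straddling a segment border are dropped
from both sides; repetition r tests segment r mod 3. "Even" segments are
interpreted by duration (window counts are logged); a segment missing a
class fails that repetition with a named error. Failed repetitions are
recorded, not hidden; more than 20% failures aborts the combination.
All randomness flows from one experiment seed through per-(W, Thd,
repetition) derived seeds.

## Metrics and model selection

ACC, SE, SP, precision and F1 are computed from confusion counts in
percent; undefined ratios (zero denominators) become NaN, are excluded
from aggregation and counted in the log rather than imputed. Summaries
report both per-repetition ratio means and mean confusion counts — the
two aggregations differ in the second decimal and both are emitted. The
best artifacts model is the (W, Thd) maximizing mean ACC; the best apnea
model maximizes mean F1.

## Synthetic cohort generator

The generator emulates the acquisition protocol: per subject one
control, one slow-breathing and one breath-hold recording plus ten
artifact recordings cycling eight subtypes, each 140 s at 75 Hz.
Subject identity (heart rate 55–90 bpm, respiratory rate 0.15–0.35 Hz,
pulse morphology, amplitude) is drawn once per subject, creating the
between-subject variance LOSO is meant to respect. Signals are pulse
templates (half-cosine upstroke, decaying downstroke, dicrotic bump)
placed at lognormally jittered beat intervals (CV 3%), with per-beat
amplitude modulated by (1 + 0.3·sin(2π·f_resp·t)), slow baseline wander
and white sensor noise (σ = 0.02). Breath-hold episodes (three per
recording, 20–30 s, one anchored inside each recording third with ≥4 s
margins so every partition segment contains both classes) collapse the
modulation depth to 0.02 and shrink interval jitter; slow-breathing
episodes halve f_resp; artifact recordings superimpose subtype-specific
corruption (band-limited noise bursts, step/ramp excursions, or
large low-frequency oscillations) on fixed alternating 20 s bursts at
+6 dB over the local pulse power.

This is a discriminative test harness, not a hemodynamic model: it is
built so that the catalogued features separate the classes. Passing
end-to-end tests therefore demonstrates that the pipeline recovers
separable classes under realistic cohort structure — not that the
classifiers reach any particular accuracy on human neck-PPG, where
morphology, artifact physics and inter-subject variation are far richer.
Synthetic accuracies (mid-90s on the default cohort) accordingly sit
above the mid/high-80s reported for comparable human experiments.

## Problem sizes and numerical choices

Default experiment sizes: 12-subject cohorts, classes capped at 1000
windows per table, 5 repetitions per (W, Thd) in the shipped end-to-end
checks (the driver accepts 30). Spectrogram floor −120 dB; band-edge
tolerance 1e-9 Hz; SVM iteration cap 2·10⁵; forward-selection tolerance
1e-6 (relative); seeds below 2³¹ derived via `numpy.random.SeedSequence`
spawn keys.

## Known limitations

* Artifact subtype waveforms are schematic stand-ins; no claim of
  morphological fidelity per subtype.
* The pulse detector is not validated on arrhythmic or very low-SNR
  signals; heavy artifacts may yield windows with too few pulses, which
  are dropped rather than classified.
* EDF/WFDB ingestion, SpO2 channels, signal reconstruction of corrupted
  segments and multi-class artifact labelling are out of scope.
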