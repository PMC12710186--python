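# Methods

This note records the modelling and numerical choices behind
`betaburst`: what the synthetic generator emulates, the exact
conventions of each pipeline stage, where the design was genuinely open
and why it was settled the way it was, and what the passing tests do and
do not establish about real recordings.

## Synthetic LFP generator

The generator produces the statistical structure the pipeline exploits,
not a biophysical STN model.

**Carrier and bursts.**  A beta carrier `cos φ(t)` at the requested peak
frequency (default 18 Hz) is amplitude-modulated by a profile that is 1
at baseline and rises to `burst_amplitude_gain` (default 3) during
bursts, via half-cosine ramps of 80 ms full width whose half-amplitude
points define the ground-truth onset/offset.  Burst durations are
gamma-distributed with mean 0.5 s and CV 1/3 (shape 9), inside the range
reported for pathological OFF-medication bursts.  Together with the
default rate of 30 bursts/min this puts burst occupancy at ≈25% of
samples, which is what makes the 75th-percentile envelope threshold land
in the gap between the baseline and burst amplitude modes — each
suprathreshold run then corresponds to one programmed burst, and the
detected count tracks the programmed count closely.

**Event process.**  Onset-to-onset intervals follow a renewal process:
previous duration + a 500 ms dead time (guaranteeing clean pre-burst
windows for labeling) + a gamma-distributed wait whose mean is chosen so
that the realized onset rate equals `burst_rate`.  A thinned Poisson
process was considered and rejected because dead-time thinning deflates
the realized rate well below the nominal one.

**Pre-burst dip.**  When `dip_depth > 0`, the amplitude is multiplied by
a raised-cosine notch of `dip_width` (default 100 ms) centered
`dip_latency` (default 90 ms) before each onset, and the carrier phase
is reset to 0 at the notch center.  The phase reset reflects the
interpretation of the dip as a coordinated phase reset of oscillatory
populations preceding burst initiation, and gives the classifier a
causal waveform feature in addition to the amplitude notch.  Dips that
would overlap the previous burst are skipped with a warning.

**Noise.**  Spectrally shaped Gaussian noise with a 1/f^a spectrum
(default a = 1), scaled so that baseline beta power over noise power
*within the beta ± 3 Hz band* equals `snr` dB (default 15).  An in-band
definition is used because broadband SNR would make the effective
difficulty depend on the (irrelevant) out-of-band spectrum.

**Determinism.**  One `numpy` generator seeded per call drives events,
durations, noise and channel noise; identical seeds give bit-identical
recordings.

**What is not emulated:** nonstationarity (drifting beta peak, state
changes), artifacts and line noise, multi-oscillator interactions,
amplitude-dependent waveform asymmetries, and recording-specific
referencing.  Passing tests therefore demonstrate the *pipeline's*
correctness and the learnability of a dip-like biomarker under
controlled conditions, not clinical performance.

## Preprocessing conventions

* **Power spectrum**: Hamming-windowed STFT, 1 s windows, 50% overlap,
  squared magnitudes averaged over windows, reported on the integer
  1–100 Hz grid.
* **Beta channel**: the channel whose spectrum has the largest *local
  maximum* inside 13–30 Hz on that grid.  Ties break toward lower
  frequency, then toward the lexicographically smaller channel label
  (deterministic and permutation-invariant).  A hemisphere with no
  in-band local maximum yields `None`, a distinguishable outcome the
  caller must handle by exclusion.
* **Band-pass**: `scipy.signal.butter(6, [peak-3, peak+3])` applied with
  `sosfilt` — forward-only, so output at time t depends only on inputs
  ≤ t.  "6th order" refers to the design order passed to the filter
  design routine.  The causal chain has a group delay of roughly 200 ms
  at a 6 Hz bandwidth; everything downstream (envelope, bursts, windows,
  dip latencies) lives consistently in this filtered time base, exactly
  as it would in a real-time device.
* **Downsampling**: integer-factor `scipy.signal.decimate` (2400→600 Hz
  for the high-rate regime); non-integer ratios are rejected rather than
  resampled, to avoid silent resampling dialects.
* **Envelope**: absolute value, peaks of the rectified signal located
  with `find_peaks`, linear interpolation between peaks evaluated at
  every sample, edges held at the nearest peak value.  The envelope is
  ≥ 0 everywhere and equals the rectified signal at peak locations.
  Because rectified peaks occur every half carrier cycle (~28 ms at
  18 Hz), envelope-derived event times carry a quantization/lag of
  roughly a quarter cycle; this is why recovered dip latencies read
  ~10 ms longer than the injected value (see "Dip recovery" below).
* **Burst threshold**: the stated percentile (default 75) of the
  envelope over a *reference* portion.  The pipeline passes the training
  portion of the recording as reference so validation/test data never
  shape the threshold; a per-session threshold is available by omitting
  the reference.  Membership is *strictly above* the threshold, making
  the constant-envelope case well-defined (zero bursts).  No minimum
  burst duration is imposed by default (bursts are predicted regardless
  of duration); a configurable minimum exists.
* **Vigilance**: each 10-min window of 2-min bradykinesia scores is
  labeled `sleep` when ≥3 of its 5 samples exceed 80 (≥6 min of
  immobility), `awake` otherwise, `unknown` when samples are missing.

Sample indexing is 0-based; burst intervals and windows are half-open
`[onset, offset)` in samples; reported times are seconds (or ms where
stated).

## Window labeling

Fixed scheme (lead `t`): one Class 1 window per usable burst ending
exactly `t` ms before onset; Class 0 windows tiled at 50 ms stride,
ending at least the guard gap (250 ms; a 150 ms variant is available via
configuration) before the next onset and not touching any burst interval
under closed-interval overlap; Class 0 is then randomly subsampled
(seeded, recorded in metadata) to the Class 1 count.  Bursts too close
to the recording start are skipped, never zero-padded.

Sliding scheme (stride 30 ms at 600 Hz): grid windows ending inside a
burst are Class Burst and excluded from all model data (bursts are
detectable by thresholding; nothing is gained by classifying them).
Each burst contributes 12 Class 1 windows ending 30–85 ms before onset
on a 5 ms grid — a 30–90 ms inclusive grid has 13 points, so one
endpoint must go, and the 90 ms end is dropped to keep the windows
closest to onset.  Grid windows ending within (0, 90] ms of the next
onset are excluded: ends in (0, 30) have no defined label, and ends in
[30, 90] would duplicate the dense Class 1 band at a coarser stride.
All remaining windows are Class 0; no balancing is applied in this
scheme.

Splits are contiguous in time (or whole sessions/days); windows
straddling a partition boundary are dropped, so no window spans two
partitions.

## Prediction network

A compact 1-D CNN written directly in numpy (no deep-learning framework
is required): three blocks of convolution (kernel 13 samples ≈ 22 ms,
'same' padding) → batch normalization → ReLU → max-pool 2 → dropout 0.3,
with 8/16/32 filters, followed by a position-aware flatten + dense
sigmoid head.  Global average pooling was tried first and rejected: it
discards *where* the dip sits relative to the window end, which is
precisely what separates a predictive window (trough and phase reset
near the end) from a non-predictive window that clips the dip's leading
flank; the flatten head raised test sensitivity at a fixed alarm rate
from ~0.71 to ~0.89 under otherwise identical conditions.  The head is
zero-initialized so an untrained network outputs probability exactly 0.5
and the initial balanced loss is ln 2.

Inputs are beta-filtered windows standardized by the training-set
mean/SD (stored with the model).  Training minimizes binary
cross-entropy with inverse-frequency class weights (weighting preserves
the temporal statistics of Class 0 better than oversampling), using Adam
at a constant 1e-3 (a cosine schedule is available but measured worse
here), batch 64, up to 30 epochs with early stopping on validation
AUC-PR (patience 10) and best-epoch restoration.  All randomness
(initialization, shuffling, dropout) flows from the seeded model
generator, so fixed seeds reproduce training exactly.  A non-finite loss
aborts with diagnostics rather than continuing silently.

**Threshold calibration** uses validation data only: the default
criterion maximizes sensitivity subject to a validation false-alarm
ceiling of 5 FP/min — the tolerable alarm rate for proactive
stimulation — with best-F1 available as an alternative.  The sweep is
evaluated at every distinct score; the returned cutoff is the midpoint
of the realizing score gap, so separable classes get the midpoint of the
separating interval.  Degenerate (all-equal) scores fall back to 0.5
with a warning.

## Evaluation bookkeeping

Ratio metrics are window-level, matching the classifier's unit of
analysis; undefined ratios (zero denominators) are reported as NaN with
a flag, never silently 0.  SPC = TN/(TN+FP), the standard complement of
the false-positive rate.  Consecutive positive Class 0 windows each
count as one FP (no merging).  FP/min divides the FP count by the
duration of the analyzed test span.  AUC-ROC and AUC-PR delegate to
scikit-learn (trapezoidal ROC is the pairwise-concordance value with
half credit for ties; average precision is the interpolation-free step
sum); the tests verify both against independent hand-written oracles.
PT-PBO is per burst: among a burst's predictive windows, the earliest
positive decision defines the prediction time, and bursts with no
positive window count toward FN, not PT-PBO.

**Envelope by outcome.**  For TP and FN the latest predictive window per
burst is selected and time-locked to (detected) burst onset; that
window's own decision assigns the group.  Only bursts sharing the modal
end offset enter the average so all traces align on one grid; FP windows
are averaged on their window-relative axis.  Means come with SEM across
segments and the time of the trace minimum.

**Dip recovery and contrast.**  The dip-bearing reference run recovers
the envelope minimum ~100 ms before *detected* onset for a 90 ms
injected latency; the ~10 ms excess is the quarter-cycle lag of the
peak-interpolated envelope plus threshold-crossing jitter, and is a
property of the causal measurement chain, not of the dip.  The contrast
statistic compares the trace minimum (searched at times ≤ −70 ms, before
the detection-jitter-smeared burst on-ramp) against the pre-dip baseline
level (trace mean at times ≤ −160 ms); a minimum deeper than 2 SEM below
that baseline marks a genuine dip.  Comparing against the whole-window
mean instead would let the terminal amplitude rise pose as contrast and
would flag dip-free data.

## Surrogate control

`make_surrogate` performs per-channel phase randomization: the rFFT
amplitude spectrum is kept exactly (DC and Nyquist bins untouched) and
phases are drawn uniformly.  This is a generic surrogate construction
chosen here as a stand-in for the original study's (unavailable)
surrogate recipe, and is documented as such.  The control carries the
*original* recording's burst annotation over to the surrogate signal:
labels are then independent of the signal by construction and the
trained model's test AUC-PR equals Class 1 prevalence.  Re-annotating
the surrogate instead would leave a residual envelope-autocorrelation
predictability (windows shortly before any threshold crossing have
elevated envelopes) that has nothing to do with pre-burst structure.

## Template baseline

The dip template is the pointwise mean beta envelope of training Class 1
trials from the fixed scheme with the window terminating at onset
(0 ms lead).  Trials are scored by Pearson correlation with the
template; the correlation cutoff is calibrated on validation trials by
best F1 (the selection criterion was not prescribed; alternatives are
exposed).  The baseline is calibrated and evaluated on *fixed-scheme*
trials: applied to sliding-scheme windows the onset-locked template
carries no signal at all, because its dominant component — the terminal
amplitude rise into onset — is absent from windows that end 30–85 ms
early.  Mann–Whitney U compares Class 0 vs Class 1 correlations
(two-sided; exact enumeration for groups ≤ 20 without ties, tie-corrected
normal approximation otherwise; fully tied data reports p = 1 with a
flag).

## Problem sizes

The reference study conditions used throughout the tests and the
acceptance script are 600 s of 600 Hz single-channel data (≈300 bursts,
≈20,000 sliding windows, 70/15/15 split); unit-level training tests use
240–300 s simulations, and the seven-lead fixed-window audit trains on
the balanced per-lead sets (≈420 training trials each).  These sizes
give stable metrics while keeping a full run in minutes on one CPU.

## Known limitations

* All performance figures are on synthetic data; none of the original
  study's patient-data numbers are reproduced or asserted.
* The network architecture is a reconstruction, not a replica of the
  original (unpublished) design.
* The fixed 30–90 ms predictive band and the sharp label boundary at
  90 ms create irreducible ambiguity for windows ending just beyond it;
  detection-time jitter (±~10 ms) blurs labels further.  Both effects
  cap attainable window-level sensitivity below 1 even on clean data.
* Validation-based threshold calibration inherits the Poisson noise of
  small validation FP counts; operating-point FP/min on test data can
  deviate from the validation ceiling in either direction.
* The vigilance classifier implements the stated wearable-score rule
  only; it performs no signal-based sleep staging.
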