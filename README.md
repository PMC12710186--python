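# betaburst

Prediction of subthalamic beta-burst onset from local field potentials.

## The problem

In Parkinson's disease, the subthalamic nucleus (STN) shows transient
episodes of exaggerated beta-band (13–30 Hz) oscillatory synchrony —
*beta bursts* — whose prolonged occurrence tracks motor impairment.
Adaptive deep brain stimulation (aDBS) today reacts to bursts after they
have started: stimulation is triggered once the beta amplitude envelope
crosses a threshold, which means every burst is treated late.  If burst
onset could be *predicted* from the immediately preceding signal,
stimulation could be delivered proactively.

`betaburst` implements that prediction pipeline end to end, together
with a synthetic LFP generator that makes every stage testable without
patient recordings:

1. **synthesis** — seeded STN-like LFP with ground-truth burst timings,
   a programmable pre-burst amplitude dip with carrier phase reset, and
   1/f background noise (`simulate_recording`), plus phase-randomized
   surrogates (`make_surrogate`);
2. **preprocessing** — STFT power spectra (1 s Hamming windows, 50%
   overlap, 1–100 Hz), beta-channel selection by the largest in-band
   spectral peak, causal 6th-order Butterworth band-pass of ±3 Hz around
   the patient-specific beta peak, rectified peak-interpolated amplitude
   envelope, and burst annotation at the envelope's 75th percentile;
3. **window labeling** — fixed-lead and sliding (real-time-mimicking)
   schemes with Class 0 / Class 1 / Class Burst bookkeeping, seeded
   class balancing, and leakage-free train/validation/test splits;
4. **prediction** — a compact 1-D convolutional network (self-contained
   numpy implementation: im2col convolution, batch normalization,
   max-pooling, dropout, Adam, manual backpropagation) mapping a
   beta-filtered window to the probability of imminent burst onset, with
   the sigmoid threshold calibrated on validation data;
5. **evaluation** — confusion counts, ACC/PRC/SEN/SPC, AUC-ROC/AUC-PR,
   FP/min, prediction time prior to burst onset (PT-PBO), threshold
   sweeps, and the mean-envelope-by-outcome analysis that exposes the
   pre-burst beta dip;
6. **baseline** — a dip-template Pearson-correlation classifier with a
   Mann–Whitney comparison of Class 0 vs Class 1 correlations.

## The statistics in brief

A burst is a maximal run of envelope samples strictly above the
threshold `q75(env)`.  In the sliding scheme a 200 ms window ending
`t` ms before the next onset is *predictive* (Class 1) for
`t ∈ [30, 85]` (12 windows per burst on a 5 ms grid), *Class Burst*
(excluded) if it ends inside a burst, and non-predictive (Class 0)
otherwise.  With decisions `d = 1[score ≥ θ]`:

    ACC = (TP + TN) / (TP + TN + FP + FN)     PRC = TP / (TP + FP)
    SEN = TP / (TP + FN)                      SPC = TN / (TN + FP)
    FP/min = FP / minutes of analyzed data

PT-PBO is the mean over predicted bursts of (onset − end of the earliest
positive predictive window).  AUC-PR (average precision) is the headline
threshold-free metric because Class 1 windows are rare.

## Worked example

`examples/train_and_evaluate.py` runs a shortened (5 min) simulation
through the whole sliding-scheme pipeline:

```
trained on 6285 windows, tested on 1350
sigmoid threshold (validation-calibrated): 0.838
test sensitivity:  0.91
test precision:    0.98
test AUC-PR:       1.00 (Class 1 prevalence 0.20)
false alarms:      5.24/min
PT-PBO:            81 ms before burst onset
```

91% of predictive windows are caught, the threshold-free ranking is
near-perfect against a 20% prevalence, and the earliest correct alarm
fires on average 81 ms before burst onset — prediction, not detection.
The other scripts in `examples/` demonstrate burst annotation
(`simulate_and_annotate.py`), the labeling schemes (`label_windows.py`),
the pre-burst dip and the template baseline (`dip_analysis.py`), the
phase-randomized negative control (`surrogate_control.py`), and
sleep/awake labeling from wearable bradykinesia scores
(`vigilance_state.py`).

A thin CLI mirrors the stages (`betaburst simulate | preprocess | label |
train | predict | evaluate | dip-baseline | run-all`); `run-all` writes a
fully reproducible run directory (config, burst table, window manifest,
checkpoint, metrics, threshold sweep, envelope averages, provenance log)
from a single YAML configuration.

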