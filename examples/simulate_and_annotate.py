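"""Generate a synthetic STN LFP recording and annotate its beta bursts.

A 3-channel, 2-minute recording is synthesized with an 18 Hz beta
carrier whose amplitude rises during bursts (30/min) and dips ~90 ms
before each burst onset.  The pipeline then recovers the beta channel
from the power spectra, band-pass filters it causally, builds the
rectified-peak-interpolated amplitude envelope, and marks bursts where
the envelope exceeds its 75th percentile.
"""

import numpy as np

import betaburst as bb

params = bb.SimulationParams(duration=120.0, n_channels=3, seed=7)
recording, truth = bb.simulate_recording(params)
print(f"simulated {recording.n_channels} channels, "
      f"{recording.duration:.0f} s at {recording.sampling_rate:.0f} Hz; "
      f"{truth.n_bursts} ground-truth bursts")

pre = bb.preprocess_recording(recording)
sel = pre.selection
print(f"beta channel: {sel.channel_label} "
      f"(spectral peak at {sel.beta_peak_frequency:.0f} Hz)")

stats = bb.burst_statistics(pre.bursts, recording.duration)
print(f"detected {stats['count']} bursts "
      f"({stats['rate_per_min']:.1f}/min, "
      f"mean duration {stats['mean_duration_s'] * 1000:.0f} ms) "
      f"vs {truth.n_bursts} programmed")
print(f"envelope threshold (75th percentile): {pre.bursts.threshold:.2f}; "
      f"{np.mean(pre.envelope.envelope > pre.bursts.threshold):.0%} of "
      "samples lie above it")
# The detected count should match the programmed one closely: the
# threshold separates the bimodal envelope distribution, so each
# suprathreshold run corresponds to one programmed burst.
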