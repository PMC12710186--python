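"""Label beta-filtered windows under the fixed and sliding schemes.

Fixed scheme: one predictive (Class 1) window per burst ending a fixed
lead time before onset, balanced against randomly subsampled
non-predictive (Class 0) windows.  Sliding scheme: windows tiled at a
30 ms stride, with 12 densely sampled predictive windows per burst
(ends 30-85 ms pre-onset) and windows ending inside bursts excluded
(Class Burst) - bursts themselves are detectable by thresholding, so the
classifier only ever sees pre-onset data.
"""

import betaburst as bb

recording, _ = bb.simulate_recording(bb.SimulationParams(duration=120.0, seed=7))
pre = bb.preprocess_recording(recording)

fixed = bb.make_fixed_window_dataset(
    pre.filtered, pre.bursts, bb.WindowConfig(lead_time=60.0)
)
counts = fixed.class_counts()
print(f"fixed scheme (60 ms lead): {counts[bb.CLASS1]} Class 1, "
      f"{counts[bb.CLASS0]} Class 0 (balanced)")

sliding = bb.make_sliding_window_dataset(pre.filtered, pre.bursts,
                                         bb.WindowConfig())
counts = sliding.class_counts()
print(f"sliding scheme: {counts[bb.CLASS0]} Class 0, "
      f"{counts[bb.CLASS1]} Class 1, "
      f"{counts[bb.CLASS_BURST]} Class Burst (excluded from the model)")

offs = sliding.end_offsets_ms[sliding.labels == bb.CLASS1]
print(f"Class 1 window ends span {offs.min():.0f} to {offs.max():.0f} ms "
      "relative to burst onset - the predictive band the network is "
      "asked to recognize")

train, val, test = bb.split_dataset(sliding, bb.SplitSpec((0.7, 0.15, 0.15)))
print(f"time-contiguous split: {len(train)}/{len(val)}/{len(test)} windows "
      "(no window straddles a partition boundary)")
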