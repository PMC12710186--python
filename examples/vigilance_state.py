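"""Sleep/awake labeling from wearable bradykinesia scores.

Wrist-worn movement monitors report a bradykinesia score every 2
minutes.  Sustained immobility (score > 80 for at least 6 of each 10
minutes, i.e. 3 of 5 samples) marks sleep; otherwise the window is
awake; windows with missing samples are unknown.
"""

import numpy as np

import betaburst as bb

rng = np.random.default_rng(0)
awake = rng.uniform(20, 75, size=15)            # three active windows
sleep = rng.uniform(82, 120, size=10)           # two immobile windows
broken = np.array([90.0, np.nan, 95.0, 88.0, 91.0])  # dropout -> unknown
scores = np.concatenate([awake, sleep, broken])

labels = bb.classify_vigilance_state(scores)
for w, label in enumerate(labels):
    chunk = scores[5 * w : 5 * w + 5]
    print(f"window {w} (minutes {10 * w}-{10 * w + 10}): {label:8s} "
          f"scores={np.round(chunk, 0)}")
print("burst-prediction models can then be trained separately on sleep "
      "and awake data, or on both combined")
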