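"""The pre-burst beta dip: envelope averages and the template baseline.

Averages the beta amplitude envelope of the windows behind TP/FN/FP
predictions (time-locked to burst onset for TP/FN) to reveal the
stereotyped amplitude dip preceding bursts, then compares the simple
dip-template correlation classifier against the CNN.
"""

import betaburst as bb

config = bb.RunConfig(
    simulation=bb.SimulationParams(duration=300.0, seed=7),
    model=bb.ModelConfig(max_epochs=15, patience=15),
)
result = bb.run_synthetic_pipeline(config)

tp = result.envelope_groups["TP"]
contrast, sem = tp.dip_contrast(tmax_ms=-70.0, baseline_tmax_ms=-160.0)
print(f"TP mean envelope (n={tp.n} bursts): minimum at {tp.t_min_ms:.0f} ms "
      f"relative to detected onset")
print(f"dip depth below pre-dip baseline: {contrast:.3f} "
      f"({contrast / sem:.1f} x SEM) - the injected dip sits 90 ms before "
      "onset, recovered with the causal pipeline's small detection lag")

bl = result.baseline
u, p = result.mann_whitney
print(f"template baseline (fixed scheme, 0 ms lead): "
      f"AUC-PR {bl.metrics.AUC_PR:.2f} at correlation threshold "
      f"{bl.threshold:.2f}")
print(f"Mann-Whitney U={u:.0f}, p={p:.2g}: Class 1 correlations clearly "
      "exceed Class 0")
print(f"CNN AUC-PR {result.metrics.AUC_PR:.2f} vs template "
      f"{bl.metrics.AUC_PR:.2f}: the template detects the dip but the "
      "network exploits it better")
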