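"""Correcting the power bias by renormalization with ground-truth noise.

Runs the correction experiment on a small grid: the renormalized AEC
recovers the simulated coupling even where the raw estimate is off by ~60%.
At this reduced scale (8 repetitions of 2-minute pairs) the residual pooled
error is a few percent of Monte-Carlo noise; the study-scale run in
scripts/acceptance.py resolves sub-percent accuracy.
"""
from envren import SimulationConfig, grid_configs, run_correction_experiment

base = SimulationConfig(fs=500.0, duration_s=120.0, n_repetitions=8, seed=11)
configs = grid_configs(base, [(1.4, 1.4)], [0.2, 0.4, 0.6, 0.8])
table, summary = run_correction_experiment(configs)

cell_means = table.groupby("aec0")[["aec", "aec_ren"]].mean()
print("true AEC0   raw AEC   renormalized")
for aec0, row in cell_means.iterrows():
    print(f"   {aec0:.1f}      {row.aec:6.3f}      {row.aec_ren:6.3f}")
err = summary.correction_error_pct.iloc[0]
print(f"\npooled correction error vs realized coupling: {err:.2f}%")
print("(raw estimates sit on a line of slope ~0.4; renormalized ones on the "
      "identity)")
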