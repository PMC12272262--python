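# envren — power-bias-corrected amplitude envelope correlation

Functional connectivity between narrow-band electrophysiological signals
(MEG/EEG source time courses, LFPs) is commonly estimated as the **amplitude
envelope correlation (AEC)**: the Pearson correlation of the (squared)
Hilbert envelopes of two band-filtered signals. AEC suffers from the
**power bias** — background noise attenuates the estimate nonlinearly in the
signal-to-noise ratio, so noisy frequency bands show spuriously weak
connectivity, which can fake spectral specificity of brain networks.

`envren` implements a correction of this bias by **renormalization**. With
measured signals `x = x0 + eps_x`, `y = y0 + eps_y` (connectivity processes
plus background noise), the corrected estimate is

    AEC_ren = [ AEC − cov(Aεx², Aεy²)/(σ_Ax² σ_Ay²)
                    − (L(x,y) + L(x,Hy))/(σ_Ax² σ_Ay²) ]
              / [ √(1 − SNRx_ampl⁻²) · √(1 − SNRy_ampl⁻²) ],

where `SNR_ampl = σ_Ax² / √(σ_Aεx²² + 2⟨Ax²⟩⟨Aεx²⟩ − 2⟨Aεx²⟩²)` is an
amplitude-specific SNR, and `L(x,y) = 8[cov(x,y)cov(εx,εy) − cov(εx,εy)²]`
removes residual linear-synchronization effects. The denominator equals the
per-signal envelope attenuation exactly for signal-independent
circular-gaussian noise, so the true coupling is recovered whatever its
strength.

The noise moments come from either of two noise models:

- **non-bursting brain activity**: a per-node, per-band two-state gaussian
  HMM on the envelope separates transient high-amplitude bursts (which carry
  amplitude coupling) from sustained low-amplitude oscillations (which do
  not); noise statistics are computed over coincident non-bursting periods;
- **measurement noise**: a separate noise recording (empty-room analogue)
  processed with the same filterbank.

The package also provides the synthetic-pair simulator that validates the
correction (controlled envelope coupling `AEC0`, noise coupling, per-signal
SNR), zero-lag leakage orthogonalization, the PBM effect-size measure, a
(deliberately inadequate) linear-regression correction baseline, and
spectral-similarity tests with effective spectral degrees of freedom.

## Worked example

```python
from envren import SimulationConfig, grid_configs, run_bias_experiment

base = SimulationConfig(band_low_hz=8, band_high_hz=12, fs=500.0,
                        duration_s=120.0, n_repetitions=8, seed=7)
table, summary = run_bias_experiment(
    grid_configs(base, [(1.4, 1.4), (3.5, 5.0)], [0.5]))
print(summary[["snr_x", "snr_y", "mean_aec", "pbm_pct"]])
```

prints (8 repetitions of 2-minute 8–12 Hz pairs, true coupling 0.5):

```
   snr_x  snr_y  mean_aec    pbm_pct
0    1.4    1.4  0.189...  62.2...
1    3.5    5.0  0.465...   6.9...
```

i.e. at amplitude SNR 1.4 the raw AEC (0.19) underestimates the true
coupling (0.5) by ~60%, while above SNR 3 the bias is below 10%. Running the
correction experiment on the same cells
(`run_correction_experiment`, see `examples/02_renormalization.py`) shows
the renormalized estimates back on the identity line:

```
true AEC0   raw AEC   renormalized
   0.2       0.085       0.190
   0.4       0.155       0.397
   0.6       0.242       0.598
   0.8       0.308       0.757
```

The `examples/` directory holds one short script per capability: the power
bias (`01`), its correction (`02`), the burst/non-burst HMM noise model end
to end (`03`), and spectral-similarity testing (`04`).

A thin CLI wraps the library for shell use:

```bash
envren fixtures --scenario burst_gated --seed 0 --out-dir demo/
envren renorm --in demo/burst_gated.h5 --bands 4:22:6 --bandwidth 2 --out spectra.csv
```

## Scope

Sensor-level preprocessing (artifact removal, source reconstruction,
forward modelling) and phase-based connectivity are out of scope; inputs are
clean multichannel time series (delimited text or HDF5). See
`docs/methods.md` for the model, conventions, design choices and
limitations.
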