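"""Generator contracts: band-limited noise, envelope coupling, SNR scaling."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import periodogram

from envren.errors import InvalidBandError
from envren.simulate import (
    SimulationConfig,
    amplitude_snr_to_variance_ratio,
    assemble_pair,
    couple_envelopes,
    envelope_mixing_gain,
    gen_band_limited_gaussian,
    grid_configs,
    run_bias_experiment,
)
from envren._utils import analytic_signal, pearson


class TestBandLimitedGaussian:
    def test_variance_concentrated_in_band(self):
        x = gen_band_limited_gaussian(8, 12, 500, 60, seed=1)
        assert len(x) == 30000
        assert abs(x.mean()) < 1e-12
        f, pxx = periodogram(x, fs=500)
        in_band = pxx[(f >= 7) & (f <= 13)].sum() / pxx.sum()
        assert in_band > 0.9

    def test_deterministic_given_seed(self):
        a = gen_band_limited_gaussian(8, 12, 250, 10, seed=7)
        b = gen_band_limited_gaussian(8, 12, 250, 10, seed=7)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("low,high,fs,dur,err", [
        (8, 12, 250, 0, ValueError),        # zero-length duration
        (100, 140, 250, 10, InvalidBandError),  # band beyond Nyquist
        (12, 8, 250, 10, InvalidBandError),     # inverted band
    ])
    def test_invalid_inputs(self, low, high, fs, dur, err):
        with pytest.raises(err):
            gen_band_limited_gaussian(low, high, fs, dur, seed=0)


class TestEnvelopeMixingGain:
    def test_printed_value(self):
        assert envelope_mixing_gain(0.6, 1.0, 1.0) == pytest.approx(0.75)

    def test_zero_coupling(self):
        assert envelope_mixing_gain(0.0, 2.0, 3.0) == 0.0

    def test_scales_with_sigma_ratio(self):
        assert envelope_mixing_gain(0.6, 2.0, 1.0) == pytest.approx(1.5)

    @pytest.mark.parametrize("aec0", [1.0, 1.5])
    def test_divergence_at_unity(self, aec0):
        with pytest.raises(ValueError):
            envelope_mixing_gain(aec0, 1.0, 1.0)

    def test_degenerate_envelope(self):
        with pytest.raises(ValueError):
            envelope_mixing_gain(0.5, 1.0, 0.0)

    @settings(derandomize=True, max_examples=60)
    @given(aec0=st.floats(0.0, 0.99),
           sig_a=st.floats(1e-3, 1e3),
           sig_b=st.floats(1e-3, 1e3))
    def test_gain_satisfies_defining_identity(self, aec0, sig_a, sig_b):
        # k is defined so that corr(a, b + k a) = AEC0 for independent a, b
        # with stds sig_a, sig_b: k sig_a / sqrt(sig_b^2 + k^2 sig_a^2) = AEC0
        k = envelope_mixing_gain(aec0, sig_b, sig_a)
        corr = k * sig_a / np.hypot(sig_b, k * sig_a)
        assert corr == pytest.approx(aec0, abs=1e-9)


class TestCoupleEnvelopes:
    def test_mixing_identity_iid(self, rng):
        # the closed-form identity corr = c/sqrt(1+c^2) = AEC0 holds for any
        # independent inputs; check it on iid squared envelopes at large N
        n = 200_000
        a2 = rng.exponential(2.0, n)
        b2 = rng.exponential(2.0, n)
        for aec0 in (0.2, 0.5, 0.8):
            k = envelope_mixing_gain(aec0, b2.std(), a2.std())
            assert pearson(a2, b2 + k * a2) == pytest.approx(
                aec0, abs=2 / np.sqrt(n))

    def test_coupling_of_band_limited_signals(self):
        x0 = gen_band_limited_gaussian(8, 12, 500, 200, seed=11)
        y0 = gen_band_limited_gaussian(8, 12, 500, 200, seed=12)
        yc = couple_envelopes(x0, y0, 0.5)
        ax2 = np.abs(analytic_signal(x0)) ** 2
        ay2 = np.abs(analytic_signal(yc)) ** 2
        # ~1200 effective envelope samples at 4 Hz bandwidth, 200 s
        assert pearson(ax2, ay2) == pytest.approx(0.5, abs=0.06)

    def test_zero_coupling_is_identity(self):
        y0 = gen_band_limited_gaussian(8, 12, 250, 10, seed=3)
        x0 = gen_band_limited_gaussian(8, 12, 250, 10, seed=4)
        np.testing.assert_array_equal(couple_envelopes(x0, y0, 0.0), y0)

    def test_phase_preserved(self):
        x0 = gen_band_limited_gaussian(8, 12, 250, 20, seed=5)
        y0 = gen_band_limited_gaussian(8, 12, 250, 20, seed=6)
        yc = couple_envelopes(x0, y0, 0.5)
        ph0 = np.angle(analytic_signal(y0))
        phc = np.angle(analytic_signal(yc))
        # phases agree except for numerical edge effects of re-analysis
        assert np.median(np.abs(np.angle(np.exp(1j * (phc - ph0))))) < 0.05

    def test_identical_inputs_flagged(self):
        x0 = gen_band_limited_gaussian(8, 12, 250, 10, seed=3)
        with pytest.warns(UserWarning, match="independent"):
            couple_envelopes(x0, x0, 0.5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            couple_envelopes(np.zeros(10), np.zeros(11), 0.3)


class TestAssemblePair:
    def test_measured_signal_is_sum_of_processes(self):
        cfg = SimulationConfig(fs=250, duration_s=20, aec0=0.4,
                               snr_x=2.0, snr_y=3.0, seed=1)
        pair = assemble_pair(cfg)
        np.testing.assert_allclose(pair.x, pair.x0 + pair.eps_x)
        np.testing.assert_allclose(pair.y, pair.y0 + pair.eps_y)

    def test_process_snr_convention_exact(self):
        cfg = SimulationConfig(fs=250, duration_s=20, snr_x=2.0, snr_y=5.0,
                               snr_convention="process", seed=1)
        pair = assemble_pair(cfg)
        assert pair.x0.std() / pair.eps_x.std() == pytest.approx(2.0)
        assert pair.y0.std() / pair.eps_y.std() == pytest.approx(5.0)

    def test_amplitude_snr_convention_variance_ratio(self):
        cfg = SimulationConfig(fs=250, duration_s=20, snr_x=1.4, snr_y=3.0,
                               snr_convention="amplitude", seed=2)
        pair = assemble_pair(cfg)
        rho = amplitude_snr_to_variance_ratio(1.4)
        assert pair.eps_x.var() / pair.x0.var() == pytest.approx(rho, rel=1e-6)
        # closed form: rho = sqrt(s^2/(s^2-1)) - 1
        assert rho == pytest.approx(np.sqrt(1.96 / 0.96) - 1)

    def test_noise_free_limit(self):
        cfg = SimulationConfig(fs=250, duration_s=20, aec0=0.3, seed=1)
        pair = assemble_pair(cfg)
        np.testing.assert_array_equal(pair.x, pair.x0)
        np.testing.assert_array_equal(pair.eps_x, np.zeros_like(pair.x))

    def test_bit_identical_rerun(self):
        cfg = SimulationConfig(fs=250, duration_s=20, aec0=0.5, snr_x=2.0,
                               snr_y=2.0, seed=42)
        p1, p2 = assemble_pair(cfg), assemble_pair(cfg)
        for attr in ("x", "y", "x0", "y0", "eps_x", "eps_y"):
            np.testing.assert_array_equal(getattr(p1, attr), getattr(p2, attr))

    def test_uncoupled_noise_envelopes(self):
        cfg = SimulationConfig(fs=500, duration_s=100, aec_noise=0.0,
                               snr_x=2.0, snr_y=2.0, seed=3)
        pair = assemble_pair(cfg)
        ax2 = np.abs(analytic_signal(pair.eps_x)) ** 2
        ay2 = np.abs(analytic_signal(pair.eps_y)) ** 2
        assert abs(pearson(ax2, ay2)) < 0.1

    @pytest.mark.parametrize("kwargs", [
        dict(aec0=1.0), dict(aec0=-0.1), dict(snr_x=0.0),
        dict(snr_x=0.8, snr_convention="amplitude"),
        dict(n_repetitions=0), dict(band_low_hz=0.0),
        dict(band_low_hz=100.0, band_high_hz=130.0),
    ])
    def test_config_validation(self, kwargs):
        with pytest.raises((ValueError, InvalidBandError)):
            SimulationConfig(fs=250, duration_s=10, **kwargs)


@pytest.fixture(scope="module")
def small_grid_summary():
    base = SimulationConfig(fs=250, duration_s=60, n_repetitions=3, seed=9)
    configs = grid_configs(base, [(2.0, 2.0), (20.0, 20.0)],
                           [0.0, 0.4, 0.8])
    _, summary = run_bias_experiment(configs)
    return summary


class TestBiasExperiment:
    def test_high_snr_slope_near_unity(self, small_grid_summary):
        s = small_grid_summary
        slope = s[s.snr_x == 20.0].slope.iloc[0]
        assert slope == pytest.approx(1.0, abs=0.08)

    def test_slope_monotone_in_snr(self, small_grid_summary):
        s = small_grid_summary
        assert (s[s.snr_x == 2.0].slope.iloc[0]
                < s[s.snr_x == 20.0].slope.iloc[0])

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            run_bias_experiment([])

    def test_experiment_reproducible(self):
        base = SimulationConfig(fs=250, duration_s=30, n_repetitions=2, seed=5)
        cfgs = grid_configs(base, [(2.0, 2.0)], [0.5])
        t1, _ = run_bias_experiment(cfgs)
        t2, _ = run_bias_experiment(cfgs)
        assert t1.equals(t2)
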