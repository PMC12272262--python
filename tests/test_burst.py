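"""HMM burst segmentation, Viterbi oracle, non-bursting noise statistics."""
import itertools

import numpy as np
import pytest
from scipy.stats import norm

from envren._utils import analytic_signal
from envren.burst import (
    StateSegmentation,
    TwoStateHmm,
    coincident_nonburst_mask,
    fit_two_state_hmm,
    measurement_noise_statistics,
    nonburst_noise_statistics,
    viterbi,
)
from envren.errors import (
    DegenerateFitError,
    InsufficientDataError,
    LayoutMismatchError,
)
from envren.renorm import noise_pair_moments_from_processes
from envren.spectral import MultichannelRecording


def two_level_envelope(rng, fs=100.0, dur=60.0, means=(1.0, 3.0),
                       dwell_s=1.0, jitter=0.3):
    """Alternating low/high amplitude regimes with gaussian jitter."""
    n = int(fs * dur)
    period = int(2 * dwell_s * fs)
    states = ((np.arange(n) % period) >= period // 2).astype(int)
    env = np.where(states == 0, means[0], means[1]) + jitter * rng.standard_normal(n)
    return np.abs(env), states


class TestFit:
    def test_recovers_two_level_means(self, rng):
        env, _ = two_level_envelope(rng)
        hmm = fit_two_state_hmm(env, seed=1)
        assert hmm.means[0] == pytest.approx(1.0, rel=0.1)
        assert hmm.means[1] == pytest.approx(3.0, rel=0.1)
        assert hmm.nonbursting_state == 0

    def test_loglik_trace_non_decreasing(self, rng):
        env, _ = two_level_envelope(rng)
        hmm = fit_two_state_hmm(env, seed=2)
        diffs = np.diff(hmm.loglik_trace)
        assert np.all(diffs >= -1e-6 * np.abs(hmm.loglik_trace[:-1]))

    def test_constant_envelope_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_two_state_hmm(np.ones(5000), seed=0)

    def test_single_regime_collapses(self, rng):
        # pure noise around one level: the two states are indistinguishable
        env = np.abs(2.0 + 0.001 * rng.standard_normal(5000))
        with pytest.raises(DegenerateFitError):
            fit_two_state_hmm(env, seed=0)

    def test_deterministic_given_seed(self, rng):
        env, _ = two_level_envelope(rng)
        h1 = fit_two_state_hmm(env, seed=3)
        h2 = fit_two_state_hmm(env, seed=3)
        np.testing.assert_array_equal(h1.means, h2.means)
        np.testing.assert_array_equal(h1.transition, h2.transition)

    def test_too_short_envelope(self):
        with pytest.raises(InsufficientDataError):
            fit_two_state_hmm(np.abs(np.random.default_rng(0).normal(1, 1, 50)))


def _brute_force_viterbi(obs, hmm):
    """Exhaustive argmax over all state paths (oracle for small T)."""
    best_path, best_lp = None, -np.inf
    for path in itertools.product((0, 1), repeat=len(obs)):
        lp = np.log(hmm.initial[path[0]])
        lp += norm.logpdf(obs[0], hmm.means[path[0]], hmm.stds[path[0]])
        for t in range(1, len(obs)):
            lp += np.log(hmm.transition[path[t - 1], path[t]])
            lp += norm.logpdf(obs[t], hmm.means[path[t]], hmm.stds[path[t]])
        if lp > best_lp:
            best_lp, best_path = lp, path
    return np.array(best_path)


class TestViterbi:
    @pytest.mark.parametrize("trial", range(20))
    def test_matches_exhaustive_enumeration(self, trial):
        rng = np.random.default_rng(100 + trial)
        means = np.sort(rng.uniform(0.5, 3.0, 2))
        hmm = TwoStateHmm(
            means=means, stds=rng.uniform(0.2, 1.0, 2),
            transition=rng.dirichlet((2, 2), size=2),
            initial=rng.dirichlet((2, 2)),
            loglik_trace=np.array([0.0]))
        obs = rng.uniform(0.0, 4.0, 6)
        seg = viterbi(obs, hmm)
        np.testing.assert_array_equal(seg.labels, _brute_force_viterbi(obs, hmm))

    def test_separated_emissions_nearest_mean(self):
        hmm = TwoStateHmm(means=np.array([1.0, 10.0]),
                          stds=np.array([0.1, 0.1]),
                          transition=np.full((2, 2), 0.5),
                          initial=np.array([0.5, 0.5]),
                          loglik_trace=np.array([0.0]))
        obs = np.array([1.1, 9.8, 0.9, 10.2, 1.0])
        seg = viterbi(obs, hmm)
        np.testing.assert_array_equal(seg.labels,
                                      (np.abs(obs - 1.0) > np.abs(obs - 10.0)))

    def test_decodes_two_level_signal(self, rng):
        env, states = two_level_envelope(rng)
        hmm = fit_two_state_hmm(env, seed=4)
        seg = viterbi(env, hmm)
        assert np.mean(seg.labels == states) > 0.95
        assert seg.mask_nonburst.sum() == np.sum(seg.labels == 0)


class TestCoincidentMask:
    def _seg(self, mask):
        labels = np.where(mask, 0, 1)
        return StateSegmentation(labels=labels, nonbursting_state=0)

    def test_identical_masks(self, rng):
        m = rng.random(1000) < 0.4
        out = coincident_nonburst_mask(self._seg(m), self._seg(m))
        np.testing.assert_array_equal(out, m)

    def test_disjoint_masks_error(self):
        m = np.arange(100) < 50
        with pytest.raises(InsufficientDataError):
            coincident_nonburst_mask(self._seg(m), self._seg(~m))

    def test_independent_masks_product_rate(self, rng):
        p, q, n = 0.6, 0.5, 40000
        mx, my = rng.random(n) < p, rng.random(n) < q
        out = coincident_nonburst_mask(self._seg(mx), self._seg(my))
        assert out.mean() == pytest.approx(p * q, abs=0.02)

    def test_minimum_retained_enforced(self, rng):
        m = rng.random(1000) < 0.05
        with pytest.raises(InsufficientDataError):
            coincident_nonburst_mask(self._seg(m), self._seg(m),
                                     min_samples=900)


class TestNoiseStatistics:
    def test_full_mask_equals_whole_signal(self, rng):
        zx = analytic_signal(rng.standard_normal(4000))
        zy = analytic_signal(rng.standard_normal(4000))
        full = nonburst_noise_statistics(zx, zy, np.ones(4000, bool))
        whole = noise_pair_moments_from_processes(zx, zy)
        assert full.mean_sq_env_x == whole.mean_sq_env_x
        assert full.cov_sq_env == whole.cov_sq_env
        assert full.n_samples == 4000

    def test_measurement_noise_independent_channels(self, rng):
        rec = MultichannelRecording(rng.standard_normal((int(60 * 250), 3)),
                                    250.0)
        stats = measurement_noise_statistics(rec, [10.0, 20.0], 4.0)
        for b in range(2):
            c = stats.cov_sq_env[b]
            offdiag = c[~np.eye(3, dtype=bool)]
            # normalized by the diagonal, cross terms are near zero
            assert np.all(np.abs(offdiag) < 0.1 * np.min(np.diag(c)))
        pair = stats.pair(10.0, "ch0", "ch2")
        assert pair.mean_sq_env_x > 0 and pair.n_samples > 0

    def test_layout_mismatch(self, rng):
        rec = MultichannelRecording(rng.standard_normal((1000, 2)), 250.0,
                                    ["a", "b"])
        other = MultichannelRecording(rng.standard_normal((1000, 2)), 250.0,
                                      ["a", "c"])
        with pytest.raises(LayoutMismatchError):
            measurement_noise_statistics(rec, [10.0], 4.0, reference=other)
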