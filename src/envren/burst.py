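"""Burst / non-burst segmentation and the cerebral background-noise model.

Resting-state narrow-band activity alternates between transient
high-amplitude oscillatory bursts and sustained low-amplitude oscillations.
Amplitude coupling is carried by coincident bursts, so the non-bursting
periods provide a biologically informed estimate of the background-noise
statistics the renormalization needs.  Each node's Hilbert envelope is
modelled with a two-state gaussian hidden Markov model, fitted per node and
per narrow band; the state with the lower emission mean is the non-bursting
state, decoded with Viterbi.  All noise moments are then computed over
samples where *both* signals of a pair are simultaneously non-bursting.

The EM fit is delegated to hmmlearn's GaussianHMM (restarts, seeding, state
ordering and collapse detection are handled here); the model collapses -- and
is reported as degenerate rather than used -- when the two state means are
indistinguishable, which happens for signals without bursting dynamics.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from hmmlearn.hmm import GaussianHMM

from ._utils import derive_rng
from .errors import DegenerateFitError, InsufficientDataError
from .renorm import NoisePairMoments, noise_pair_moments_from_processes
from .spectral import BandAnalytic, MultichannelRecording
from .renorm import NoiseStatistics, noise_statistics_from_bands

#: states whose means differ by less than this fraction of the envelope std
#: are considered collapsed.
STATE_COLLAPSE_RTOL = 0.05

#: default number of EM restarts (1-D two-state EM is multimodal but cheap).
DEFAULT_RESTARTS = 5

#: minimum samples for an HMM fit.
MIN_FIT_SAMPLES = 100


@dataclass
class TwoStateHmm:
    """Fitted two-state gaussian HMM on an envelope signal.

    State 0 is always the low-mean (non-bursting) state; state 1 the
    high-mean (bursting) state.  ``loglik_trace`` is the per-iteration EM
    log-likelihood of the winning restart (non-decreasing).
    """

    means: np.ndarray
    stds: np.ndarray
    transition: np.ndarray
    initial: np.ndarray
    loglik_trace: np.ndarray

    @property
    def nonbursting_state(self) -> int:
        return int(np.argmin(self.means))


@dataclass
class StateSegmentation:
    """Per-sample state labels with the non-bursting state identified."""

    labels: np.ndarray
    nonbursting_state: int

    @property
    def mask_nonburst(self) -> np.ndarray:
        return self.labels == self.nonbursting_state


def _order_states(model: GaussianHMM) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    means = model.means_.ravel()
    stds = np.sqrt(model.covars_.ravel())
    order = np.argsort(means)
    perm = np.empty_like(order)
    perm[order] = np.arange(2)
    return (means[order], stds[order],
            model.transmat_[np.ix_(order, order)], model.startprob_[order])


def fit_two_state_hmm(envelope: np.ndarray, seed: int = 0, tol: float = 1e-2,
                      max_iter: int = 200,
                      n_restarts: int = DEFAULT_RESTARTS) -> TwoStateHmm:
    """Fit a two-state gaussian HMM to a 1-D envelope by EM (Baum-Welch).

    Runs ``n_restarts`` EM fits from seeds derived from ``seed`` and keeps
    the best by final log-likelihood; deterministic given ``seed``.

    Raises
    ------
    DegenerateFitError
        If the winning fit's state means are closer than
        ``STATE_COLLAPSE_RTOL`` times the envelope std (no burst/non-burst
        structure to separate).
    InsufficientDataError
        If the envelope is shorter than ``MIN_FIT_SAMPLES``.
    """
    env = np.asarray(envelope, dtype=float).ravel()
    if env.size < MIN_FIT_SAMPLES:
        raise InsufficientDataError(
            f"envelope has {env.size} samples; need >= {MIN_FIT_SAMPLES}")
    sd = env.std()
    if sd == 0:
        raise DegenerateFitError("constant envelope: nothing to segment")
    obs = env[:, None]
    best: GaussianHMM | None = None
    best_ll = -np.inf
    # hmmlearn logs spurious "not converging" messages for sub-tol EM
    # oscillations at float precision; silence them during the restarts
    hmm_logger = logging.getLogger("hmmlearn.base")
    old_level = hmm_logger.level
    hmm_logger.setLevel(logging.ERROR)
    for r in range(n_restarts):
        rs = derive_rng(seed, r).integers(2 ** 31 - 1)
        model = GaussianHMM(n_components=2, covariance_type="diag",
                            n_iter=max_iter, tol=tol,
                            random_state=int(rs))
        model.fit(obs)
        ll = model.monitor_.history[-1]
        if ll > best_ll:
            best, best_ll = model, ll
    hmm_logger.setLevel(old_level)
    means, stds, trans, init = _order_states(best)
    if abs(means[1] - means[0]) < STATE_COLLAPSE_RTOL * sd:
        raise DegenerateFitError(
            f"state means {means} separated by less than "
            f"{STATE_COLLAPSE_RTOL} envelope std: degenerate fit")
    trace = np.asarray(list(best.monitor_.history), dtype=float)
    return TwoStateHmm(means=means, stds=stds, transition=trans,
                       initial=init, loglik_trace=trace)


def viterbi(envelope: np.ndarray, hmm: TwoStateHmm) -> StateSegmentation:
    """Maximum-probability state path of an envelope under a fitted HMM.

    Ties between paths are broken deterministically towards the lower state
    index (argmax convention).  The non-bursting state is the low-mean state
    (index 0 after ordering).
    """
    env = np.asarray(envelope, dtype=float).ravel()
    model = GaussianHMM(n_components=2, covariance_type="diag", init_params="")
    model.startprob_ = hmm.initial
    model.transmat_ = hmm.transition
    model.means_ = hmm.means[:, None]
    model.covars_ = (hmm.stds ** 2)[:, None]
    _, labels = model.decode(env[:, None], algorithm="viterbi")
    return StateSegmentation(labels=labels.astype(int),
                             nonbursting_state=hmm.nonbursting_state)


def coincident_nonburst_mask(seg_x: StateSegmentation,
                             seg_y: StateSegmentation,
                             min_samples: int = 1) -> np.ndarray:
    """Samples where both signals are simultaneously non-bursting.

    Raises :class:`InsufficientDataError` if fewer than ``min_samples``
    samples are retained (callers typically require 10 seconds' worth).
    """
    mx = seg_x.mask_nonburst
    my = seg_y.mask_nonburst
    if mx.shape != my.shape:
        raise ValueError("segmentations must have equal length")
    mask = mx & my
    if int(mask.sum()) < max(int(min_samples), 1):
        raise InsufficientDataError(
            f"only {int(mask.sum())} coincident non-bursting samples "
            f"retained; need >= {min_samples}")
    return mask


def nonburst_noise_statistics(x_analytic: np.ndarray, y_analytic: np.ndarray,
                              mask: np.ndarray) -> NoisePairMoments:
    """Noise moments of a pair from coincident non-bursting periods.

    The signals themselves, restricted to the coincident non-bursting mask,
    estimate the background-noise processes: all squared-envelope and
    cross moments are temporal averages over the masked samples only.
    """
    if int(np.sum(mask)) < 2:
        raise InsufficientDataError("mask retains fewer than 2 samples")
    return noise_pair_moments_from_processes(np.asarray(x_analytic),
                                             np.asarray(y_analytic),
                                             mask=np.asarray(mask, bool))


def measurement_noise_statistics(noise_rec: MultichannelRecording,
                                 centers_hz, bandwidth_hz: float = 1.0,
                                 reference: MultichannelRecording | None = None,
                                 ) -> NoiseStatistics:
    """Noise statistics from a separate noise recording (no masking).

    The empty-room analogue: the noise recording is decomposed with the same
    filterbank as the subject data and all moments are taken over the full
    recording.  If ``reference`` is given, channel layout and sampling rate
    must match it.
    """
    from .errors import LayoutMismatchError
    from .spectral import decompose
    if reference is not None:
        if (list(noise_rec.channel_labels) != list(reference.channel_labels)
                or noise_rec.fs != reference.fs):
            raise LayoutMismatchError(
                "noise recording must share channel layout and sampling "
                "rate with the subject recording")
    bands = decompose(noise_rec, centers_hz, bandwidth_hz)
    return noise_statistics_from_bands(bands)


def segment_band(band: BandAnalytic, seed: int = 0) -> list[StateSegmentation]:
    """Fit + decode every channel of one band; one segmentation per channel."""
    segs = []
    for c in range(band.analytic.shape[1]):
        env = np.abs(band.analytic[:, c])
        hmm = fit_two_state_hmm(env, seed=seed + c)
        segs.append(viterbi(env, hmm))
    return segs
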