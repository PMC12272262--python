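"""Power-bias correction of amplitude envelope correlation by renormalization.

Narrow-band functional connectivity estimated as the Pearson correlation of
(squared) Hilbert envelopes is biased towards zero by background noise: with
measured signals x = x0 + eps_x, y = y0 + eps_y, the estimated AEC is an
attenuated version of the coupling carried by the connectivity processes
(x0, y0).  For circular-gaussian, signal-independent noise the attenuation
factorizes, and the true coupling can be recovered as the renormalized
estimate

    AEC_ren = [ AEC - cov(Ae_x^2, Ae_y^2) / (s_Ax2 * s_Ay2)
                    - (L(x, y) + L(x, Hy)) / (s_Ax2 * s_Ay2) ]
              / [ sqrt(1 - SNR_x_ampl^-2) * sqrt(1 - SNR_y_ampl^-2) ],

with s_A2 = std of the squared envelope, the amplitude-specific SNR

    SNR_x_ampl = std(Ax^2) / sqrt( std(Ae_x^2)^2
                                   + 2 <Ax^2><Ae_x^2> - 2 <Ae_x^2>^2 ),

and the linear-synchronization term
L(x, y) = 8 [ cov(x, y) cov(eps_x, eps_y) - cov(eps_x, eps_y)^2 ].

The denominator corrects the power bias proper (per signal,
sqrt(1 - SNR_ampl^-2) equals std(A0^2)/std(Ax^2) exactly); the first
numerator correction removes spurious noise amplitude correlation and the
second the residual effect of zero-lag (linear) synchronization.  All terms
are plain temporal moments, so they can be estimated either from a separate
noise recording or from non-bursting signal periods (see ``envren.burst``).

The procedure is ill-conditioned when SNR_ampl approaches 1 (noise as
variable as the signal): such estimates are flagged, never silently returned.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from ._utils import cov0, pearson
from .errors import DegenerateEnvelopeError, IllConditionedError

#: SNR_ampl must exceed 1 + ILL_CONDITION_TOL for a renormalized estimate.
ILL_CONDITION_TOL = 1e-6


# ---------------------------------------------------------------------------
# elementary operations

def snr_plain(sigma_x: float, sigma_eps: float) -> float:
    """Plain SNR = sigma_x / sigma_eps; infinity marker for zero noise."""
    if sigma_eps < 0 or sigma_x < 0:
        raise ValueError("standard deviations must be non-negative")
    if sigma_eps == 0:
        return math.inf
    return sigma_x / sigma_eps


def snr_ampl(std_sq_env: float, mean_sq_env: float,
             noise_std_sq_env: float, noise_mean_sq_env: float) -> float:
    """Amplitude-specific SNR from squared-envelope moments.

    Returns ``inf`` in the noise-free limit (all noise moments zero); raises
    :class:`IllConditionedError` when the radicand is non-positive, which is
    the regime where low- and high-amplitude periods cannot be discriminated.
    """
    radicand = (noise_std_sq_env ** 2
                + 2.0 * mean_sq_env * noise_mean_sq_env
                - 2.0 * noise_mean_sq_env ** 2)
    if noise_std_sq_env == 0.0 and noise_mean_sq_env == 0.0:
        return math.inf
    if radicand <= 0.0:
        raise IllConditionedError(
            f"amplitude-SNR radicand non-positive ({radicand:.3g}); "
            "noise moments exceed what the signal moments allow")
    return std_sq_env / math.sqrt(radicand)


def lin_sync_L(cov_xy: float, cov_eps: float) -> float:
    """Linear-synchronization term L = 8 [cov(x,y) cov(ex,ey) - cov(ex,ey)^2]."""
    return 8.0 * (cov_xy * cov_eps - cov_eps ** 2)


def slope_model(snr: float) -> float:
    """Model attenuation slope sqrt(1 - 2 SNR^-2) of the AEC-vs-AEC0 line.

    Undefined at or below SNR = sqrt(2), where the modelled pair attenuation
    hits zero.
    """
    if snr <= math.sqrt(2.0):
        raise ValueError(f"slope model undefined for SNR <= sqrt(2), got {snr}")
    return math.sqrt(1.0 - 2.0 / snr ** 2)


# ---------------------------------------------------------------------------
# pairwise moment containers

@dataclass
class SignalPairMoments:
    """Squared-envelope and cross moments of a measured signal pair."""

    aec: float
    mean_sq_env_x: float
    mean_sq_env_y: float
    std_sq_env_x: float
    std_sq_env_y: float
    cov_signal: float
    cov_signal_hilbert: float
    n_samples: int


@dataclass
class NoisePairMoments:
    """Moments of the background-noise processes of a signal pair."""

    mean_sq_env_x: float
    mean_sq_env_y: float
    std_sq_env_x: float
    std_sq_env_y: float
    cov_sq_env: float
    cov_noise: float
    cov_noise_hilbert: float
    n_samples: int

    @classmethod
    def zero(cls) -> "NoisePairMoments":
        """Noise-free moments (renormalization reduces to the identity)."""
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0)


def signal_pair_moments(zx: np.ndarray, zy: np.ndarray,
                        aec: float | None = None) -> SignalPairMoments:
    """Moments of a measured pair from its analytic signals."""
    ax2 = np.abs(zx) ** 2
    ay2 = np.abs(zy) ** 2
    if aec is None:
        aec = aec_squared_envelopes(ax2, ay2)
    return SignalPairMoments(
        aec=aec,
        mean_sq_env_x=float(ax2.mean()), mean_sq_env_y=float(ay2.mean()),
        std_sq_env_x=float(ax2.std()), std_sq_env_y=float(ay2.std()),
        cov_signal=cov0(zx.real, zy.real),
        cov_signal_hilbert=cov0(zx.real, zy.imag),
        n_samples=len(ax2))


def noise_pair_moments_from_processes(zex: np.ndarray, zey: np.ndarray,
                                      mask: np.ndarray | None = None,
                                      ) -> NoisePairMoments:
    """Noise moments from (possibly masked) analytic noise processes."""
    if mask is not None:
        zex, zey = zex[mask], zey[mask]
    aex2 = np.abs(zex) ** 2
    aey2 = np.abs(zey) ** 2
    return NoisePairMoments(
        mean_sq_env_x=float(aex2.mean()), mean_sq_env_y=float(aey2.mean()),
        std_sq_env_x=float(aex2.std()), std_sq_env_y=float(aey2.std()),
        cov_sq_env=cov0(aex2, aey2),
        cov_noise=cov0(zex.real, zey.real),
        cov_noise_hilbert=cov0(zex.real, zey.imag),
        n_samples=len(aex2))


def aec_squared_envelopes(ax2: np.ndarray, ay2: np.ndarray) -> float:
    """Pearson correlation of squared envelopes (raw AEC).

    Raises :class:`DegenerateEnvelopeError` for an envelope of
    (numerically) zero variance, e.g. a pure tone.
    """
    from .spectral import DEGENERATE_ENV_RTOL
    for name, a2 in (("x", ax2), ("y", ay2)):
        if a2.std() <= DEGENERATE_ENV_RTOL * a2.mean():
            raise DegenerateEnvelopeError(
                f"envelope of {name} has no variance (pure-tone-like signal)")
    return pearson(ax2, ay2)


@dataclass
class RenormResult:
    """Renormalized AEC with its conditioning diagnostics."""

    value: float
    conditioned: bool
    denominator: float
    snr_ampl_x: float
    snr_ampl_y: float


def aec_renormalized(signal: SignalPairMoments, noise: NoisePairMoments,
                     tol: float = ILL_CONDITION_TOL,
                     on_ill: Literal["raise", "flag"] = "raise",
                     ) -> RenormResult:
    """Renormalized (power-bias-corrected) AEC of one pair and direction.

    With all noise moments zero this is exactly the identity
    (``value == signal.aec``).  When either amplitude-specific SNR is at or
    below ``1 + tol``, the correction is ill-conditioned: it raises by
    default, or flags (NaN value, ``conditioned=False``) with
    ``on_ill="flag"`` so that callers can report missing cells explicitly.
    """
    try:
        sx = snr_ampl(signal.std_sq_env_x, signal.mean_sq_env_x,
                      noise.std_sq_env_x, noise.mean_sq_env_x)
        sy = snr_ampl(signal.std_sq_env_y, signal.mean_sq_env_y,
                      noise.std_sq_env_y, noise.mean_sq_env_y)
    except IllConditionedError:
        if on_ill == "raise":
            raise
        return RenormResult(math.nan, False, math.nan, math.nan, math.nan)
    if sx <= 1.0 + tol or sy <= 1.0 + tol:
        if on_ill == "raise":
            raise IllConditionedError(
                f"amplitude-specific SNR too low (x: {sx:.4g}, y: {sy:.4g}); "
                "renormalization denominator vanishes")
        return RenormResult(math.nan, False, 0.0, sx, sy)
    denom = math.sqrt(1.0 - sx ** -2) * math.sqrt(1.0 - sy ** -2)
    norm = signal.std_sq_env_x * signal.std_sq_env_y
    noise_corr = noise.cov_sq_env / norm
    lin_corr = (lin_sync_L(signal.cov_signal, noise.cov_noise)
                + lin_sync_L(signal.cov_signal_hilbert,
                             noise.cov_noise_hilbert)) / norm
    value = (signal.aec - noise_corr - lin_corr) / denom
    return RenormResult(value, True, denom, sx, sy)


# ---------------------------------------------------------------------------
# whole-connectome noise statistics

@dataclass
class NoiseStatistics:
    """Background-noise moments for every channel and pair, per band.

    Array layout: ``mean_sq_env``/``std_sq_env`` are (bands, channels);
    the covariance stacks are (bands, channels, channels), with
    ``cov_noise_hilbert[b, i, j] = cov(eps_i, H eps_j)`` (antisymmetric in
    (i, j) up to sampling noise).
    """

    centers_hz: np.ndarray
    channel_labels: list[str]
    mean_sq_env: np.ndarray
    std_sq_env: np.ndarray
    cov_sq_env: np.ndarray
    cov_noise: np.ndarray
    cov_noise_hilbert: np.ndarray
    n_samples: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def band_index(self, center_hz: float) -> int:
        idx = np.flatnonzero(np.isclose(self.centers_hz, center_hz))
        if idx.size == 0:
            raise KeyError(f"no noise statistics for band {center_hz} Hz")
        return int(idx[0])

    def pair(self, center_hz: float, label_x: str, label_y: str) -> NoisePairMoments:
        b = self.band_index(center_hz)
        i = self.channel_labels.index(label_x)
        j = self.channel_labels.index(label_y)
        return NoisePairMoments(
            mean_sq_env_x=float(self.mean_sq_env[b, i]),
            mean_sq_env_y=float(self.mean_sq_env[b, j]),
            std_sq_env_x=float(self.std_sq_env[b, i]),
            std_sq_env_y=float(self.std_sq_env[b, j]),
            cov_sq_env=float(self.cov_sq_env[b, i, j]),
            cov_noise=float(self.cov_noise[b, i, j]),
            cov_noise_hilbert=float(self.cov_noise_hilbert[b, i, j]),
            n_samples=int(self.n_samples[b]))


def noise_statistics_from_bands(bands: Sequence["BandAnalytic"],  # noqa: F821
                                ) -> NoiseStatistics:
    """Full-recording noise statistics from decomposed bands (no masking).

    This is the measurement-noise route: the bands come from a separate
    noise recording processed with the same filterbank as the subject data.
    """
    centers = np.array([b.center_hz for b in bands], dtype=float)
    labels = list(bands[0].channel_labels)
    nb, nc = len(bands), len(labels)
    mean_sq = np.zeros((nb, nc))
    std_sq = np.zeros((nb, nc))
    cov_sq = np.zeros((nb, nc, nc))
    cov_n = np.zeros((nb, nc, nc))
    cov_h = np.zeros((nb, nc, nc))
    n_samp = np.zeros(nb, dtype=int)
    for b, band in enumerate(bands):
        z = band.analytic
        a2 = np.abs(z) ** 2
        mean_sq[b] = a2.mean(axis=0)
        std_sq[b] = a2.std(axis=0)
        cov_sq[b] = np.cov(a2.T, ddof=0)
        cov_n[b] = np.cov(z.real.T, ddof=0)
        re = z.real - z.real.mean(axis=0)
        im = z.imag - z.imag.mean(axis=0)
        cov_h[b] = re.T @ im / z.shape[0]
        n_samp[b] = z.shape[0]
    return NoiseStatistics(centers, labels, mean_sq, std_sq, cov_sq,
                           cov_n, cov_h, n_samp)


# ---------------------------------------------------------------------------
# effect size and the regression comparison arm

def pbm(aec_spectrum: np.ndarray, reference_spectrum: np.ndarray,
        method: Literal["rms", "mean_relative"] = "rms") -> float:
    """Power bias measure: percent deviation between two spectra.

    Default aggregation is the RMS of the per-band differences relative to
    the RMS of the reference, over the full spectral range supplied; the
    alternative averages per-band relative differences.
    """
    aec = np.asarray(aec_spectrum, dtype=float)
    ref = np.asarray(reference_spectrum, dtype=float)
    if aec.shape != ref.shape:
        raise ValueError("spectra must have equal length")
    keep = np.isfinite(aec) & np.isfinite(ref)
    aec, ref = aec[keep], ref[keep]
    if aec.size == 0 or not np.any(ref != 0):
        raise ValueError("reference spectrum is empty or identically zero")
    if method == "rms":
        return 100.0 * float(np.sqrt(np.mean((aec - ref) ** 2))
                             / np.sqrt(np.mean(ref ** 2)))
    if method == "mean_relative":
        nz = ref != 0
        return 100.0 * float(np.mean(np.abs(aec[nz] - ref[nz]) / np.abs(ref[nz])))
    raise ValueError(f"unknown PBM method {method!r}")


def regression_correction_baseline(aec_spectra: np.ndarray,
                                   power_spectra: np.ndarray) -> np.ndarray:
    """Linear-regression power-bias correction (comparison arm only).

    Regresses each AEC spectrum on the corresponding power spectrum across
    frequencies and returns intercept + residuals.  This removes any affine
    power-AEC relationship but, being linear in power, cannot capture the
    SNR nonlinearity of the true bias; it is provided to reproduce the
    failure mode of regression-based correction.
    """
    aec = np.atleast_2d(np.asarray(aec_spectra, dtype=float))
    pw = np.atleast_2d(np.asarray(power_spectra, dtype=float))
    if aec.shape != pw.shape:
        raise ValueError("AEC and power spectra must share the frequency axis")
    if aec.shape[1] < 2:
        raise ValueError("regression needs at least two frequency bins")
    out = np.empty_like(aec)
    for i in range(aec.shape[0]):
        x, y = pw[i], aec[i]
        if np.ptp(x) == 0:
            raise np.linalg.LinAlgError(
                "power spectrum is constant across frequencies; "
                "regression design is rank-deficient")
        design = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        out[i] = coef[0] + (y - design @ coef)
    return out if np.asarray(aec_spectra).ndim > 1 else out[0]
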