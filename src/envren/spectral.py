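"""Narrow-band decomposition, Hilbert envelopes and leakage orthogonalization.

The connectivity pipeline works on narrow-band analytic signals: a recording
is decomposed with a zero-phase band-pass filterbank (1-Hz-wide bands by
default, mirroring the 1, 2, ..., 45 Hz grid commonly used for spectrally
resolved envelope connectivity), each band is turned into its analytic signal
whose modulus is the Hilbert envelope, and spurious zero-lag mixing between
two signals ("spatial leakage" in source-projected MEG/EEG) is removed by
pairwise orthogonalization before envelopes are correlated.

Conventions: all frequencies in Hz, times in seconds, 0-based samples,
half-open sample windows.  Band edges are full widths: a band with center c
and bandwidth b spans [c - b/2, c + b/2].
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt

from ._utils import analytic_signal, cov0
from .errors import DegenerateEnvelopeError, InvalidBandError

#: seconds trimmed at each end after filtering, per Hz of bandwidth:
#: ceil(EDGE_TRIM_BANDWIDTH_SECONDS / bandwidth) seconds.
EDGE_TRIM_BANDWIDTH_SECONDS = 3.0

#: relative envelope-variance threshold below which an envelope is treated
#: as degenerate (e.g. a pure tone, whose envelope is constant).
DEGENERATE_ENV_RTOL = 1e-3

DEFAULT_FILTER_ORDER = 4


@dataclass
class MultichannelRecording:
    """Real-valued multichannel time series.

    Attributes
    ----------
    data : (n_samples, n_channels) float array
    fs : sampling rate in Hz
    channel_labels : unique channel names
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (samples x channels)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.data.shape[1])]
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label {label!r}") from None


@dataclass
class BandAnalytic:
    """Analytic signals and Hilbert envelopes of one narrow band.

    ``analytic`` is complex (samples x channels); ``envelope`` is its modulus.
    """

    center_hz: float
    bandwidth_hz: float
    fs: float
    analytic: np.ndarray
    channel_labels: list[str] = field(default_factory=list)

    @property
    def envelope(self) -> np.ndarray:
        return np.abs(self.analytic)

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label {label!r}") from None


def design_bandpass(low_hz: float, high_hz: float, fs: float,
                    order: int = DEFAULT_FILTER_ORDER) -> np.ndarray:
    """Butterworth band-pass in second-order sections (stable for 1-Hz bands)."""
    if not (0.0 < low_hz < high_hz < fs / 2.0):
        raise InvalidBandError(
            f"band [{low_hz}, {high_hz}] Hz outside (0, {fs / 2}) Hz")
    return butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")


def edge_trim_samples(bandwidth_hz: float, fs: float) -> int:
    """Samples dropped at each end after filtering: ceil(3/bandwidth) seconds."""
    return int(np.ceil(EDGE_TRIM_BANDWIDTH_SECONDS / bandwidth_hz) * fs)


def bandpass(rec: MultichannelRecording, low_hz: float, high_hz: float,
             order: int = DEFAULT_FILTER_ORDER,
             trim: bool = True) -> MultichannelRecording:
    """Zero-phase band-pass of a recording, with edge transients trimmed."""
    sos = design_bandpass(low_hz, high_hz, rec.fs, order)
    ntrim = edge_trim_samples(high_hz - low_hz, rec.fs) if trim else 0
    if rec.n_samples <= 2 * ntrim:
        raise InvalidBandError(
            f"recording too short ({rec.n_samples} samples) for the "
            f"{high_hz - low_hz} Hz band's edge trim of {ntrim} samples/end")
    out = sosfiltfilt(sos, rec.data, axis=0)
    if ntrim:
        out = out[ntrim:-ntrim]
    return MultichannelRecording(out - out.mean(axis=0), rec.fs,
                                 list(rec.channel_labels))


def filterbank(rec: MultichannelRecording, centers_hz: Sequence[float],
               bandwidth_hz: float = 1.0,
               order: int = DEFAULT_FILTER_ORDER) -> list[MultichannelRecording]:
    """Decompose a recording into narrow bands centered on ``centers_hz``.

    Each output is the zero-phase band-pass [c - b/2, c + b/2] with the edge
    transient (ceil(3/bandwidth) seconds per end) removed.  Bands outside the
    Nyquist range raise, listing the offending centers.
    """
    centers = np.asarray(list(centers_hz), dtype=float)
    if centers.size == 0:
        raise InvalidBandError("no band centers given")
    half = bandwidth_hz / 2.0
    bad = centers[(centers - half <= 0) | (centers + half >= rec.fs / 2.0)]
    if bad.size:
        raise InvalidBandError(
            f"band centers outside (0, Nyquist): {bad.tolist()}")
    return [bandpass(rec, c - half, c + half, order) for c in centers]


def analytic_and_envelope(band_rec: MultichannelRecording, center_hz: float,
                          bandwidth_hz: float) -> BandAnalytic:
    """Analytic signal (complex Hilbert transform) of a band-filtered recording.

    The real part of ``analytic`` equals the input; ``envelope`` is the
    modulus, i.e. the instantaneous oscillation amplitude.
    """
    z = analytic_signal(band_rec.data, axis=0)
    return BandAnalytic(center_hz=center_hz, bandwidth_hz=bandwidth_hz,
                        fs=band_rec.fs, analytic=z,
                        channel_labels=list(band_rec.channel_labels))


def decompose(rec: MultichannelRecording, centers_hz: Sequence[float],
              bandwidth_hz: float = 1.0,
              order: int = DEFAULT_FILTER_ORDER) -> list[BandAnalytic]:
    """Filterbank + analytic signal in one step."""
    bands = filterbank(rec, centers_hz, bandwidth_hz, order)
    return [analytic_and_envelope(b, c, bandwidth_hz)
            for b, c in zip(bands, centers_hz)]


def orthogonalize_pair(x_analytic: np.ndarray,
                       y_analytic: np.ndarray) -> np.ndarray:
    """Remove the zero-lag component of y along x (leakage correction).

    Regresses the real part of ``y`` on the real part of ``x`` and re-derives
    the analytic signal of the residual, so that cov(Re x, Re y_orth) = 0.
    This is the symmetric pairwise stand-in for geometric leakage correction:
    downstream estimates average the two orthogonalization directions.

    Raises
    ------
    DegenerateEnvelopeError
        If x is (numerically) zero, or if y is collinear with x (total
        leakage), in which case no connectivity estimate is defined.
    """
    x = np.real(np.asarray(x_analytic))
    y = np.real(np.asarray(y_analytic))
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    vx = cov0(x, x)
    if vx == 0:
        raise DegenerateEnvelopeError("cannot orthogonalize against a zero signal")
    beta = cov0(x, y) / vx
    resid = y - beta * x
    vy = cov0(y, y)
    if vy == 0 or cov0(resid, resid) < (DEGENERATE_ENV_RTOL ** 2) * vy:
        raise DegenerateEnvelopeError(
            "orthogonalization left no residual signal (y collinear with x)")
    return analytic_signal(resid)
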