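"""Spectrally resolved amplitude envelope correlation (AEC).

AEC is the Pearson correlation between the Hilbert envelopes of two
narrow-band signals; by default the squared envelopes are correlated, which
is the level at which the power-bias renormalization is exact (the plain
envelope variant is available).  Pairs are orthogonalized at zero lag before
correlating to suppress spatial leakage, and the estimate is symmetrized by
averaging the two orthogonalization directions.

Degenerate bands (zero-variance envelopes, total leakage) yield NaN markers
with a logged warning, never silent zeros, so flat spectra cannot be faked
by failures.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._utils import pearson
from .errors import DegenerateEnvelopeError
from .renorm import aec_squared_envelopes
from .spectral import (
    BandAnalytic,
    MultichannelRecording,
    decompose,
    orthogonalize_pair,
)

logger = logging.getLogger(__name__)

Variant = Literal["raw", "non_bursting", "renormalized"]
EnvelopeKind = Literal["power", "amplitude"]


@dataclass
class ConnectivitySpectrum:
    """Per-frequency AEC for one channel pair."""

    pair: tuple[str, str]
    centers_hz: np.ndarray
    aec: np.ndarray
    variant: Variant = "raw"

    def rms(self) -> float:
        """Root-mean-square AEC across (finite) bands: the spectrum norm."""
        vals = self.aec[np.isfinite(self.aec)]
        if vals.size == 0:
            return np.nan
        return float(np.sqrt(np.mean(vals ** 2)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pair_a": self.pair[0], "pair_b": self.pair[1],
            "center_hz": self.centers_hz, "variant": self.variant,
            "aec": self.aec})


def aec(envelope_x: np.ndarray, envelope_y: np.ndarray,
        envelope_kind: EnvelopeKind = "power",
        mask: np.ndarray | None = None) -> float:
    """Pearson correlation of two envelopes (squared by default).

    ``mask`` restricts the correlation to selected samples (used for
    non-bursting AEC).  Raises for zero-variance envelopes.
    """
    ex = np.asarray(envelope_x, dtype=float)
    ey = np.asarray(envelope_y, dtype=float)
    if ex.shape != ey.shape:
        raise ValueError("envelopes must have equal length")
    if mask is not None:
        ex, ey = ex[mask], ey[mask]
    if envelope_kind == "power":
        return aec_squared_envelopes(ex ** 2, ey ** 2)
    from .spectral import DEGENERATE_ENV_RTOL
    for name, e in (("x", ex), ("y", ey)):
        if e.std() <= DEGENERATE_ENV_RTOL * e.mean():
            raise DegenerateEnvelopeError(
                f"envelope of {name} has no variance")
    return pearson(ex, ey)


def aec_symmetrized(x_analytic: np.ndarray, y_analytic: np.ndarray,
                    envelope_kind: EnvelopeKind = "power",
                    mask: np.ndarray | None = None) -> float:
    """Leakage-corrected AEC, averaged over both orthogonalization directions.

    Computes AEC(x, y orthogonalized to x) and AEC(y, x orthogonalized to y)
    and returns their mean, which is symmetric under argument swap by
    construction.
    """
    zx = np.asarray(x_analytic)
    zy = np.asarray(y_analytic)
    a_xy = aec(np.abs(zx), np.abs(orthogonalize_pair(zx, zy)),
               envelope_kind, mask)
    a_yx = aec(np.abs(zy), np.abs(orthogonalize_pair(zy, zx)),
               envelope_kind, mask)
    return 0.5 * (a_xy + a_yx)


def _band_pair_aec(band: BandAnalytic, i: int, j: int,
                   envelope_kind: EnvelopeKind,
                   orthogonalize: bool) -> float:
    zx = band.analytic[:, i]
    zy = band.analytic[:, j]
    try:
        if orthogonalize:
            return aec_symmetrized(zx, zy, envelope_kind)
        return aec(np.abs(zx), np.abs(zy), envelope_kind)
    except DegenerateEnvelopeError as exc:
        logger.warning("band %.3g Hz, pair (%s, %s): %s; marked missing",
                       band.center_hz, band.channel_labels[i],
                       band.channel_labels[j], exc)
        return np.nan


def connectivity_spectrum(rec: MultichannelRecording, pair: tuple[str, str],
                          centers_hz: Sequence[float], bandwidth_hz: float = 1.0,
                          envelope_kind: EnvelopeKind = "power",
                          orthogonalize: bool = True) -> ConnectivitySpectrum:
    """Symmetrized AEC of one channel pair across a filterbank."""
    i = rec.channel_index(pair[0])
    j = rec.channel_index(pair[1])
    bands = decompose(rec, centers_hz, bandwidth_hz)
    vals = np.array([_band_pair_aec(b, i, j, envelope_kind, orthogonalize)
                     for b in bands])
    return ConnectivitySpectrum(pair=tuple(pair),
                                centers_hz=np.asarray(centers_hz, float),
                                aec=vals, variant="raw")


def connectome_spectra(rec: MultichannelRecording,
                       centers_hz: Sequence[float], bandwidth_hz: float = 1.0,
                       envelope_kind: EnvelopeKind = "power",
                       orthogonalize: bool = True) -> list[ConnectivitySpectrum]:
    """AEC spectra of every unordered channel pair (diagonal excluded)."""
    if rec.n_channels < 2:
        raise ValueError("a connectome needs at least 2 channels")
    bands = decompose(rec, centers_hz, bandwidth_hz)
    out = []
    for i in range(rec.n_channels):
        for j in range(i + 1, rec.n_channels):
            vals = np.array([_band_pair_aec(b, i, j, envelope_kind,
                                            orthogonalize) for b in bands])
            out.append(ConnectivitySpectrum(
                pair=(rec.channel_labels[i], rec.channel_labels[j]),
                centers_hz=np.asarray(centers_hz, float),
                aec=vals, variant="raw"))
    return out


def spectra_to_frame(spectra: Sequence[ConnectivitySpectrum]) -> pd.DataFrame:
    """Tidy table (pair_a, pair_b, center_hz, variant, aec) of many spectra."""
    return pd.concat([s.to_frame() for s in spectra], ignore_index=True)
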