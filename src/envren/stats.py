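"""Spectral-similarity statistics with effective spectral degrees of freedom.

Power and connectivity spectra are smooth across neighbouring 1-Hz bands, so
a Pearson correlation between two spectra has far fewer independent samples
than frequency bins.  The one-sided correlation test used here places the
Fisher-transformed correlation R under a gaussian null with variance
1/(n - 3), where n is the *effective* number of spectral degrees of freedom
estimated from the cross-frequency covariance of individual (per-subject or
per-repetition) spectra via the eigenvalue participation ratio
(sum lambda)^2 / sum lambda^2.  Family-wise error is controlled by
Bonferroni over the number of independent units (rho nodes, or
rho(rho-1)/2 connections), supplied by the caller.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class SpectralTestResult:
    """One-sided spectral-similarity test outcome."""

    r: float
    n_eff: float
    z: float
    p: float
    m_comparisons: int = 1
    significant: bool = False


def effective_spectral_df(individual_spectra: np.ndarray) -> float:
    """Effective number of independent frequency bins of a set of spectra.

    ``individual_spectra`` is (n_observations, n_frequencies): one spectrum
    per subject or repetition (after averaging the two spectra entering the
    correlation).  Returns the eigenvalue participation ratio
    (tr C)^2 / tr(C^2) of the cross-frequency correlation matrix C, which is
    n_frequencies for independent bins and 1 for perfectly redundant ones.

    With few observations the naive sample participation ratio is strongly
    biased low (sample eigenvalues spread), which would make the downstream
    correlation test far too conservative; tr(C^2) is therefore replaced by
    its unbiased gaussian estimate
    nu^2/((nu-1)(nu+2)) * [tr(S^2) - (tr S)^2/nu], nu = n_observations - 1
    (Srivastava-type moment debiasing), and the result is clipped to
    [1, n_frequencies].
    """
    spectra = np.atleast_2d(np.asarray(individual_spectra, dtype=float))
    n_obs, n_freq = spectra.shape
    if n_obs < 3 or n_freq < 2:
        raise ValueError("need >= 3 individual spectra and >= 2 frequency bins")
    sd = spectra.std(axis=0, ddof=1)
    if np.all(sd == 0):
        raise ValueError("cross-frequency covariance has rank 0")
    keep = sd > 0
    z = (spectra[:, keep] - spectra[:, keep].mean(axis=0)) / sd[keep]
    nu = n_obs - 1
    s = z.T @ z / nu  # sample correlation matrix of the spectra
    t1 = float(np.trace(s))
    t2 = float(np.sum(s * s))  # tr(S^2) for symmetric S
    t2_unbiased = nu ** 2 / ((nu - 1) * (nu + 2)) * (t2 - t1 ** 2 / nu)
    if t2_unbiased <= 0:
        return float(np.sum(keep))
    return float(np.clip(t1 ** 2 / t2_unbiased, 1.0, np.sum(keep)))


def participation_ratio(cov: np.ndarray) -> float:
    """(sum lambda)^2 / sum lambda^2 of a covariance/correlation matrix."""
    lam = np.clip(np.linalg.eigvalsh(np.asarray(cov, dtype=float)), 0.0, None)
    return float(lam.sum() ** 2 / np.sum(lam ** 2))


def fisher_one_sided_test(r: float, n_eff: float,
                          m_comparisons: int = 1,
                          alpha: float = 0.05) -> SpectralTestResult:
    """One-sided Pearson correlation test with effective df.

    p is the upper-tail gaussian probability of z * sqrt(n_eff - 3) with
    z = atanh(r); ``significant`` applies the Bonferroni-corrected threshold
    alpha / m_comparisons.
    """
    if not -1.0 < r < 1.0:
        raise ValueError(f"|r| must be < 1, got {r}")
    if n_eff <= 3:
        raise ValueError(f"n_eff must exceed 3, got {n_eff}")
    z = math.atanh(r)
    p = float(sps.norm.sf(z * math.sqrt(n_eff - 3.0)))
    return SpectralTestResult(r=float(r), n_eff=float(n_eff), z=z, p=p,
                              m_comparisons=int(m_comparisons),
                              significant=p < alpha / m_comparisons)


def bonferroni_m(n_independent_units: int,
                 level: Literal["node", "connection"] = "connection") -> int:
    """Number of Bonferroni comparisons: rho nodes or rho(rho-1)/2 connections."""
    rho = int(n_independent_units)
    if rho < 1:
        raise ValueError("need at least one independent unit")
    return rho if level == "node" else rho * (rho - 1) // 2


def familywise_correct(p_values: Sequence[float], n_independent_units: int,
                       level: Literal["node", "connection"] = "connection",
                       alpha: float = 0.05) -> np.ndarray:
    """Bonferroni significance decisions at family-wise level ``alpha``."""
    m = max(bonferroni_m(n_independent_units, level), 1)
    return np.asarray(p_values, dtype=float) < alpha / m


def spectral_similarity_test(spectrum_a: np.ndarray, spectrum_b: np.ndarray,
                             individual_spectra: np.ndarray,
                             m_comparisons: int = 1,
                             alpha: float = 0.05) -> SpectralTestResult:
    """Test whether two spectra are positively correlated across frequency.

    ``individual_spectra`` are the per-subject (or per-repetition) spectra
    of the averaged quantity, used only to estimate the effective spectral
    degrees of freedom.
    """
    a = np.asarray(spectrum_a, dtype=float)
    b = np.asarray(spectrum_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("spectra must share the frequency axis")
    r = float(np.corrcoef(a, b)[0, 1])
    n_eff = effective_spectral_df(individual_spectra)
    return fisher_one_sided_test(r, n_eff, m_comparisons, alpha)
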