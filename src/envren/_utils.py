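"""Internal numerical helpers."""
from __future__ import annotations

import numpy as np
from scipy.fft import next_fast_len
from scipy.signal import hilbert


def analytic_signal(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """FFT-based analytic signal, computed on a padded fast length.

    Padding to the next fast FFT length and truncating back keeps the
    transform O(n log n) for awkward lengths (e.g. 300 000 samples).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[axis]
    if n == 0:
        raise ValueError("empty signal")
    z = hilbert(x, N=next_fast_len(n), axis=axis)
    return np.take(z, np.arange(n), axis=axis)


def derive_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Deterministic child generator for (master_seed, operation key)."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *map(int, key)]))


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two 1-D arrays (population moments)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ad = a - a.mean()
    bd = b - b.mean()
    denom = np.sqrt((ad @ ad) * (bd @ bd))
    if denom == 0:
        return np.nan
    return float((ad @ bd) / denom)


def cov0(a: np.ndarray, b: np.ndarray) -> float:
    """Population (ddof=0) covariance of two 1-D arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.mean((a - a.mean()) * (b - b.mean())))
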