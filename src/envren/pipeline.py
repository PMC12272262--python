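"""End-to-end connectivity pipeline and deterministic demo fixtures.

The pipeline chains the package: narrow-band decomposition -> Hilbert
envelopes -> zero-lag orthogonalization -> raw AEC -> per-node burst
segmentation -> coincident non-bursting noise statistics -> renormalized
AEC, with an optional measurement-noise variant when a separate noise
recording is supplied.

Fixture scenarios generate small synthetic recordings with known ground
truth (written as HDF5 + a YAML manifest when a directory is given), for
tests and demos.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from ._utils import derive_rng
from .aec import aec
from .burst import (
    coincident_nonburst_mask,
    fit_two_state_hmm,
    nonburst_noise_statistics,
    viterbi,
)
from .errors import (
    DegenerateEnvelopeError,
    DegenerateFitError,
    EnvrenError,
    LayoutMismatchError,
)
from .renorm import aec_renormalized, signal_pair_moments
from .simulate import SimulationConfig, assemble_pair, gen_band_limited_gaussian
from .spectral import MultichannelRecording, decompose, orthogonalize_pair

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# fixtures

def _scenario_fig1_cell(master_seed: int, fs: float = 1000.0,
                        duration_s: float = 60.0) -> tuple[MultichannelRecording, dict]:
    cfg = SimulationConfig(fs=fs, duration_s=duration_s, aec0=0.5,
                           snr_x=2.0, snr_y=2.0, seed=master_seed)
    pair = assemble_pair(cfg, derive_rng(master_seed, 0))
    rec = MultichannelRecording(np.column_stack([pair.x, pair.y]), fs,
                                ["x", "y"])
    manifest = {"scenario": "fig1_cell", "master_seed": master_seed,
                "aec0": cfg.aec0, "snr_x": cfg.snr_x, "snr_y": cfg.snr_y,
                "snr_convention": cfg.snr_convention,
                "band_hz": [cfg.band_low_hz, cfg.band_high_hz],
                "fs": fs, "duration_s": duration_s,
                "noise_var_x": float(pair.eps_x.var()),
                "noise_var_y": float(pair.eps_y.var())}
    return rec, manifest


def _markov_gate(rng: np.random.Generator, n: int, fs: float,
                 dwell_on_s: float, dwell_off_s: float) -> np.ndarray:
    """Two-state Markov burst gate with given mean dwell times."""
    p_off_on = 1.0 / (dwell_off_s * fs)
    p_on_off = 1.0 / (dwell_on_s * fs)
    u = rng.random(n)
    gate = np.empty(n, dtype=bool)
    state = False
    for t in range(n):
        state = (u[t] < p_off_on) if not state else (u[t] >= p_on_off)
        gate[t] = state
    return gate


def _scenario_burst_gated(master_seed: int, fs: float = 250.0,
                          duration_s: float = 120.0,
                          burst_gain: float = 4.0,
                          band: tuple[float, float] = (9.0, 11.0),
                          ) -> tuple[MultichannelRecording, dict]:
    """Two channels whose coupling exists only inside shared bursts.

    Each channel is a sustained low-amplitude alpha background plus a
    high-amplitude alpha burst process switched on and off by a common
    (smoothed) Markov gate, plus independent broadband sensor-like noise:
    envelopes co-fluctuate only through burst co-occurrence, so
    non-bursting AEC is ~0 while raw AEC is alpha-peaked.  The gate is
    smoothed with a 0.4-s Hann window so that switching edges do not leak
    gate-locked energy into distant frequency bands.
    """
    rng = derive_rng(master_seed, 1)
    n = int(round(fs * duration_s))
    gate = _markov_gate(rng, n, fs, dwell_on_s=0.5, dwell_off_s=0.5)
    win = np.hanning(max(int(0.4 * fs), 3))
    smooth_gate = np.convolve(gate.astype(float), win / win.sum(), mode="same")
    data = []
    for _ in range(2):
        bg = gen_band_limited_gaussian(band[0], band[1], fs, duration_s, rng)
        burst = gen_band_limited_gaussian(band[0], band[1], fs, duration_s, rng)
        broadband = 0.5 * bg.std() * rng.standard_normal(n)
        data.append(bg + burst_gain * smooth_gate * burst + broadband)
    rec = MultichannelRecording(np.column_stack(data), fs, ["left", "right"])
    manifest = {"scenario": "burst_gated", "master_seed": master_seed,
                "fs": fs, "duration_s": duration_s, "band_hz": list(band),
                "burst_gain": burst_gain, "burst_fraction": float(gate.mean()),
                "coupling": "burst co-occurrence only"}
    return rec, manifest


def _scenario_uncoupled(master_seed: int, fs: float = 250.0,
                        duration_s: float = 60.0, n_channels: int = 3,
                        ) -> tuple[MultichannelRecording, dict]:
    rng = derive_rng(master_seed, 2)
    data = np.column_stack([
        gen_band_limited_gaussian(8.0, 12.0, fs, duration_s, rng)
        for _ in range(n_channels)])
    rec = MultichannelRecording(data, fs,
                                [f"node{i}" for i in range(n_channels)])
    manifest = {"scenario": "uncoupled", "master_seed": master_seed,
                "fs": fs, "duration_s": duration_s, "aec0": 0.0}
    return rec, manifest


_SCENARIOS = {
    "fig1_cell": _scenario_fig1_cell,
    "burst_gated": _scenario_burst_gated,
    "uncoupled": _scenario_uncoupled,
}


def fixture_generator(scenario_name: str, master_seed: int,
                      out_dir: str | Path | None = None,
                      **overrides) -> tuple[MultichannelRecording, dict]:
    """Generate a named synthetic scenario (deterministic per seed).

    With ``out_dir`` set, writes ``<scenario>.h5`` (the recording) and
    ``<scenario>_manifest.yaml`` (the ground truth) into the directory.
    """
    try:
        builder = _SCENARIOS[scenario_name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {scenario_name!r}; available: "
            f"{sorted(_SCENARIOS)}") from None
    rec, manifest = builder(master_seed, **overrides)
    if out_dir is not None:
        from .io import write_recording_hdf5
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_recording_hdf5(rec, out / f"{scenario_name}.h5")
        with open(out / f"{scenario_name}_manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh)
    return rec, manifest


# ---------------------------------------------------------------------------
# end-to-end pipeline

def _directional_renorm(zx: np.ndarray, zy: np.ndarray,
                        mask: np.ndarray | None,
                        noise_pair) -> float:
    sig = signal_pair_moments(zx, zy)
    if noise_pair is None:
        noise_pair = nonburst_noise_statistics(zx, zy, mask)
    res = aec_renormalized(sig, noise_pair, on_ill="flag")
    return res.value


def end_to_end_pipeline(rec: MultichannelRecording,
                        noise_rec: MultichannelRecording | None = None,
                        centers_hz: Sequence[float] = tuple(range(1, 46)),
                        bandwidth_hz: float = 1.0,
                        pairs: Sequence[tuple[str, str]] | None = None,
                        seed: int = 0,
                        min_noise_seconds: float = 10.0,
                        orthogonalize: bool = True) -> pd.DataFrame:
    """Raw, non-bursting and renormalized AEC spectra for channel pairs.

    Returns a tidy frame (pair_a, pair_b, center_hz, variant, value) with
    variants ``raw``, ``non_bursting``, ``renormalized`` and -- when a noise
    recording is given -- ``renormalized_measurement``.  Bands where an
    estimate is undefined (degenerate envelope, collapsed HMM, too few
    coincident non-bursting samples, ill-conditioned renormalization) carry
    NaN and a log line, never silent zeros.
    """
    if pairs is None:
        pairs = [(a, b) for k, a in enumerate(rec.channel_labels)
                 for b in rec.channel_labels[k + 1:]]
    bands = decompose(rec, centers_hz, bandwidth_hz)
    noise_bands = None
    if noise_rec is not None:
        if (list(noise_rec.channel_labels) != list(rec.channel_labels)
                or noise_rec.fs != rec.fs):
            raise LayoutMismatchError(
                "noise recording must share channel layout and sampling "
                "rate with the subject recording")
        noise_bands = decompose(noise_rec, centers_hz, bandwidth_hz)
    min_samples = int(min_noise_seconds * rec.fs)

    rows = []

    def add(pair, c, variant, value):
        rows.append({"pair_a": pair[0], "pair_b": pair[1], "center_hz": c,
                     "variant": variant, "value": value})

    for band, noise_band in zip(bands, noise_bands or [None] * len(bands)):
        c = band.center_hz
        # per-channel segmentations, computed lazily per band
        segs: dict[int, object] = {}

        def segmentation(idx):
            if idx not in segs:
                env = np.abs(band.analytic[:, idx])
                hmm = fit_two_state_hmm(env, seed=seed + idx)
                segs[idx] = viterbi(env, hmm)
            return segs[idx]

        for pair in pairs:
            i, j = band.channel_index(pair[0]), band.channel_index(pair[1])
            zx, zy = band.analytic[:, i], band.analytic[:, j]
            try:
                if orthogonalize:
                    zy_x = orthogonalize_pair(zx, zy)
                    zx_y = orthogonalize_pair(zy, zx)
                else:
                    zy_x, zx_y = zy, zx
                raw = 0.5 * (aec(np.abs(zx), np.abs(zy_x))
                             + aec(np.abs(zy), np.abs(zx_y)))
            except DegenerateEnvelopeError as exc:
                logger.warning("band %.3g Hz %s: %s", c, pair, exc)
                for v in ("raw", "non_bursting", "renormalized"):
                    add(pair, c, v, np.nan)
                if noise_rec is not None:
                    add(pair, c, "renormalized_measurement", np.nan)
                continue
            add(pair, c, "raw", raw)
            try:
                seg_x = segmentation(i)
                seg_y = segmentation(j)
                mask = coincident_nonburst_mask(seg_x, seg_y, min_samples)
                nb = 0.5 * (aec(np.abs(zx), np.abs(zy_x), mask=mask)
                            + aec(np.abs(zy), np.abs(zx_y), mask=mask))
                add(pair, c, "non_bursting", nb)
                ren = 0.5 * (_directional_renorm(zx, zy_x, mask, None)
                             + _directional_renorm(zy, zx_y, mask, None))
                add(pair, c, "renormalized", ren)
            except (EnvrenError, DegenerateFitError) as exc:
                logger.warning("band %.3g Hz %s (HMM noise model): %s",
                               c, pair, exc)
                add(pair, c, "non_bursting", np.nan)
                add(pair, c, "renormalized", np.nan)
            if noise_rec is not None:
                try:
                    zni = noise_band.analytic[:, i]
                    znj = noise_band.analytic[:, j]
                    if orthogonalize:
                        znj_i = orthogonalize_pair(zni, znj)
                        zni_j = orthogonalize_pair(znj, zni)
                    else:
                        znj_i, zni_j = znj, zni
                    from .renorm import noise_pair_moments_from_processes
                    ren_m = 0.5 * (
                        _directional_renorm(
                            zx, zy_x, None,
                            noise_pair_moments_from_processes(zni, znj_i))
                        + _directional_renorm(
                            zy, zx_y, None,
                            noise_pair_moments_from_processes(znj, zni_j)))
                    add(pair, c, "renormalized_measurement", ren_m)
                except EnvrenError as exc:
                    logger.warning("band %.3g Hz %s (measurement noise): %s",
                                   c, pair, exc)
                    add(pair, c, "renormalized_measurement", np.nan)
    return pd.DataFrame(rows)
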