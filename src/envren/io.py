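"""Readers and writers for recordings, envelopes, noise statistics, spectra.

Formats: delimited text (samples x channels, header row of labels) and HDF5
(one dataset per recording with ``fs`` as attribute; one group per band for
envelopes).  Spectra and experiment tables are tidy CSV.  All numeric HDF5
storage is float64, and text IO uses 17 significant digits with round-trip
float parsing, so write/read round trips are lossless.
"""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .renorm import NoiseStatistics
from .spectral import BandAnalytic, MultichannelRecording


# ---------------------------------------------------------------------------
# recordings

def read_recording_text(path: str | Path, fs: float,
                        delimiter: str = ",") -> MultichannelRecording:
    """Delimited text with a header row of channel labels; fs supplied."""
    df = pd.read_csv(path, delimiter=delimiter, float_precision="round_trip")
    return MultichannelRecording(df.to_numpy(dtype=float), fs,
                                 [str(c) for c in df.columns])


def write_recording_text(rec: MultichannelRecording, path: str | Path,
                         delimiter: str = ",") -> None:
    # 17 significant digits round-trips any float64 exactly
    np.savetxt(path, rec.data, fmt="%.17g", delimiter=delimiter,
               header=delimiter.join(rec.channel_labels), comments="")


def read_recording_hdf5(path: str | Path,
                        name: str = "recording") -> MultichannelRecording:
    with h5py.File(path, "r") as f:
        ds = f[name]
        labels = [s.decode() if isinstance(s, bytes) else str(s)
                  for s in ds.attrs["channel_labels"]]
        return MultichannelRecording(ds[()], float(ds.attrs["fs"]), labels)


def write_recording_hdf5(rec: MultichannelRecording, path: str | Path,
                         name: str = "recording") -> None:
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        ds = f.create_dataset(name, data=rec.data.astype(np.float64))
        ds.attrs["fs"] = rec.fs
        ds.attrs["channel_labels"] = [str(c) for c in rec.channel_labels]


# ---------------------------------------------------------------------------
# band envelopes

def write_envelopes_hdf5(bands: Sequence[BandAnalytic],
                         path: str | Path) -> None:
    """One group per band: real/imag analytic parts plus metadata."""
    with h5py.File(path, "a") as f:
        for band in bands:
            gname = f"band_{band.center_hz:g}Hz"
            if gname in f:
                del f[gname]
            g = f.create_group(gname)
            g.create_dataset("analytic_real", data=band.analytic.real)
            g.create_dataset("analytic_imag", data=band.analytic.imag)
            g.attrs["center_hz"] = band.center_hz
            g.attrs["bandwidth_hz"] = band.bandwidth_hz
            g.attrs["fs"] = band.fs
            g.attrs["channel_labels"] = [str(c) for c in band.channel_labels]


def read_envelopes_hdf5(path: str | Path) -> list[BandAnalytic]:
    bands = []
    with h5py.File(path, "r") as f:
        for gname in sorted(f, key=lambda s: float(f[s].attrs["center_hz"])):
            g = f[gname]
            labels = [s.decode() if isinstance(s, bytes) else str(s)
                      for s in g.attrs["channel_labels"]]
            z = g["analytic_real"][()] + 1j * g["analytic_imag"][()]
            bands.append(BandAnalytic(
                center_hz=float(g.attrs["center_hz"]),
                bandwidth_hz=float(g.attrs["bandwidth_hz"]),
                fs=float(g.attrs["fs"]), analytic=z, channel_labels=labels))
    return bands


# ---------------------------------------------------------------------------
# noise statistics

def write_noise_statistics_hdf5(stats: NoiseStatistics,
                                path: str | Path) -> None:
    with h5py.File(path, "a") as f:
        if "noise_statistics" in f:
            del f["noise_statistics"]
        g = f.create_group("noise_statistics")
        g.create_dataset("centers_hz", data=stats.centers_hz)
        g.attrs["channel_labels"] = [str(c) for c in stats.channel_labels]
        for key in ("mean_sq_env", "std_sq_env", "cov_sq_env",
                    "cov_noise", "cov_noise_hilbert", "n_samples"):
            g.create_dataset(key, data=getattr(stats, key))


def read_noise_statistics_hdf5(path: str | Path) -> NoiseStatistics:
    with h5py.File(path, "r") as f:
        g = f["noise_statistics"]
        labels = [s.decode() if isinstance(s, bytes) else str(s)
                  for s in g.attrs["channel_labels"]]
        return NoiseStatistics(
            centers_hz=g["centers_hz"][()], channel_labels=labels,
            mean_sq_env=g["mean_sq_env"][()], std_sq_env=g["std_sq_env"][()],
            cov_sq_env=g["cov_sq_env"][()], cov_noise=g["cov_noise"][()],
            cov_noise_hilbert=g["cov_noise_hilbert"][()],
            n_samples=g["n_samples"][()])


# ---------------------------------------------------------------------------
# segmentations and spectra tables

def write_segmentation_hdf5(labels: np.ndarray, nonbursting_state: int,
                            path: str | Path, name: str = "segmentation",
                            hmm_params: dict | None = None) -> None:
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        g = f.create_group(name)
        g.create_dataset("labels", data=np.asarray(labels, dtype=np.int8))
        g.attrs["nonbursting_state"] = int(nonbursting_state)
        for key, val in (hmm_params or {}).items():
            g.attrs[key] = val


def write_spectra_csv(frame: pd.DataFrame, path: str | Path,
                      header_meta: dict | None = None) -> None:
    """Tidy spectra/experiment CSV with provenance echoed as '#' comments."""
    with open(path, "w") as fh:
        for key, val in (header_meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        frame.to_csv(fh, index=False)


def read_spectra_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")
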