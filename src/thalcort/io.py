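"""Readers and writers for the package's tabular interchange formats.

Recordings travel as wide delimited text (one column per channel, one row
per sample) or EDF (via :mod:`mne`, if installed); spectra, band energies
and topologies are plain CSV.  Simulation configs round-trip through a
``key = value`` text format.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .eeg import Recording
from .experiment import SimulationConfig
from .network import NetworkTopology
from .spectral import PowerSpectrum

__all__ = [
    "read_recording",
    "write_recording",
    "write_spectrum",
    "read_spectrum",
    "write_band_energy",
    "write_edge_table",
    "read_config",
    "write_config",
]


def read_recording(path: str | Path, fs: float | None = None, **metadata) -> Recording:
    """Load a recording from EDF or delimited text.

    Text dialects (.csv/.tsv/.txt) are wide tables with channel names in the
    header; an optional ``time`` column (seconds) supplies the sampling rate,
    otherwise ``fs`` must be given.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # volts -> microvolts
        return Recording(data=data, fs=float(raw.info["sfreq"]),
                         channels=list(raw.ch_names), metadata=metadata)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if "time" in df.columns:
        t = df.pop("time").to_numpy()
        fs = 1.0 / float(np.median(np.diff(t)))
    if fs is None:
        raise ValueError("sampling rate unknown: pass fs= or include a time column")
    return Recording(data=df.to_numpy().T, fs=float(fs), channels=list(df.columns),
                     metadata=metadata)


def write_recording(recording: Recording, path: str | Path, time_column: bool = True) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.DataFrame(recording.data.T, columns=recording.channels)
    if time_column:
        df.insert(0, "time", np.arange(recording.n_samples) / recording.fs)
    df.to_csv(path, sep=sep, index=False)


def write_spectrum(spectrum: PowerSpectrum, path: str | Path) -> None:
    pd.DataFrame({"freq_hz": spectrum.freqs, "power": spectrum.power}).to_csv(path, index=False)


def read_spectrum(path: str | Path) -> PowerSpectrum:
    df = pd.read_csv(path)
    return PowerSpectrum(freqs=df["freq_hz"].to_numpy(), power=df["power"].to_numpy())


def write_band_energy(band_energy: dict[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"band": list(band_energy), "mse": list(band_energy.values())}
    ).to_csv(path, index=False)


def write_edge_table(topology: NetworkTopology, path: str | Path) -> None:
    topology.edge_table().to_csv(path, index=False)


_CONFIG_TYPES = {f.name: f.type for f in dataclasses.fields(SimulationConfig)}


def write_config(config: SimulationConfig, path: str | Path) -> None:
    lines = [f"{k} = {json.dumps(v)}" for k, v in dataclasses.asdict(config).items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path) -> SimulationConfig:
    """Parse a ``key = value`` config file (values in JSON syntax)."""
    kwargs = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in _CONFIG_TYPES:
            raise ValueError(f"unknown config key: {key}")
        kwargs[key] = json.loads(value.strip())
    return SimulationConfig(**kwargs)
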