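"""Resting-state EEG preprocessing and group comparison.

Pipeline (order is fixed and enforced by the orchestrator): bandpass filter
0.5–35 Hz (2nd-order Butterworth, i.e. 12 dB/octave, applied zero-phase) →
common-average reference → selection of the first 45 artifact-free epochs of
2048 ms (any sample beyond ±75 uV rejects the whole window) → Morlet-wavelet
spectra averaged over time and electrodes.  Group-level statistics use the
two-sided Wilcoxon rank-sum test on per-subject band energies and dominant
alpha peaks; topographic maps report per-electrode patient-minus-control
differences after mirroring left-lesion subjects so that the right
hemisphere is always ipsi-lesional.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .spectral import (
    EEG_BANDS,
    BandSet,
    PowerSpectrum,
    WaveletBank,
    band_mse,
    dominant_peak,
    tf_power_multi,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ELECTRODES",
    "MIRROR_PAIRS",
    "Recording",
    "EpochSet",
    "SubjectResult",
    "GroupComparison",
    "PipelineOrderError",
    "bandpass",
    "rereference_car",
    "extract_epochs",
    "mirror_electrodes",
    "subject_spectrum",
    "run_pipeline",
    "compare_groups",
    "eeg_wavelet_bank",
]

#: The 17 electrodes common to both clinical montages (10–20 labels).
ELECTRODES = [
    "F3", "F4", "F7", "F8", "Fz", "C3", "C4", "Cz",
    "P3", "P4", "Pz", "T3", "T4", "T5", "T6", "O1", "O2",
]

#: Homologous left/right pairs swapped when mirroring left-lesion subjects.
MIRROR_PAIRS = [
    ("F3", "F4"), ("F7", "F8"), ("C3", "C4"), ("P3", "P4"),
    ("T3", "T4"), ("T5", "T6"), ("O1", "O2"),
]

EPOCH_SAMPLES = 1024          # 2048 ms at 500 Hz
MAX_EPOCHS = 45
ARTIFACT_UV = 75.0
ALPHA_SEARCH = (6.0, 13.0)

_PIPELINE_ORDER = ("bandpass", "car", "epochs")


class PipelineOrderError(RuntimeError):
    """Raised when preprocessing steps are applied out of order."""


@dataclass
class Recording:
    """Multichannel EEG: ``data`` is (n_channels, n_samples) in uV."""

    data: np.ndarray
    fs: float
    channels: list[str]
    metadata: dict = field(default_factory=dict)
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel labels must match data rows")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """Accepted artifact-free epochs: (n_epochs, n_channels, EPOCH_SAMPLES)."""

    epochs: np.ndarray
    fs: float
    channels: list[str]
    n_candidates: int
    n_rejected: int
    metadata: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.epochs.shape[0]


def bandpass(
    recording: Recording,
    lo: float = 0.5,
    hi: float = 35.0,
    order: int = 2,
) -> Recording:
    """Zero-phase Butterworth bandpass (12 dB/octave at the default order).

    Zero-phase (forward-backward) application preserves epoch timing; its
    side effect is a doubled effective roll-off relative to a single pass.
    """
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=recording.fs, output="sos")
    out = sps.sosfiltfilt(sos, recording.data, axis=1)
    return replace(recording, data=out, provenance=recording.provenance + ("bandpass",))


def rereference_car(recording: Recording) -> Recording:
    """Common-average reference: subtract the instantaneous channel mean."""
    out = recording.data - recording.data.mean(axis=0, keepdims=True)
    return replace(recording, data=out, provenance=recording.provenance + ("car",))


def extract_epochs(
    recording: Recording,
    n_epochs: int = MAX_EPOCHS,
    epoch_samples: int = EPOCH_SAMPLES,
    threshold: float = ARTIFACT_UV,
) -> EpochSet:
    """Scan consecutive non-overlapping windows from the recording start and
    keep the first ``n_epochs`` whose samples all stay within ±threshold uV.

    A shortfall (fewer clean windows than requested) is logged and returns
    the epochs found; an all-artifact recording yields an empty set with a
    warning.
    """
    n_cand = recording.n_samples // epoch_samples
    kept, rejected = [], 0
    for k in range(n_cand):
        win = recording.data[:, k * epoch_samples : (k + 1) * epoch_samples]
        if np.abs(win).max() > threshold:
            rejected += 1
            continue
        kept.append(win)
        if len(kept) == n_epochs:
            break
    if not kept:
        warnings.warn("no artifact-free epochs found", stacklevel=2)
        epochs = np.empty((0, recording.data.shape[0], epoch_samples))
    else:
        if len(kept) < n_epochs:
            logger.warning(
                "epoch shortfall: %d/%d accepted (%d rejected)", len(kept), n_epochs, rejected
            )
        epochs = np.stack(kept)
    return EpochSet(
        epochs=epochs,
        fs=recording.fs,
        channels=list(recording.channels),
        n_candidates=n_cand,
        n_rejected=rejected,
        metadata={**recording.metadata, "provenance": recording.provenance + ("epochs",)},
    )


def mirror_electrodes(values: pd.Series, lesion_side: str) -> pd.Series:
    """Swap homologous left/right electrode values for left-lesion subjects.

    ``values`` is indexed by electrode label.  Midline electrodes are left
    untouched; the operation is an involution and the identity for right or
    absent lesions.
    """
    if lesion_side != "left":
        return values.copy()
    out = values.copy()
    for a, b in MIRROR_PAIRS:
        if a in out.index and b in out.index:
            out[a], out[b] = values[b], values[a]
    return out


def eeg_wavelet_bank(fs: float = 500.0) -> WaveletBank:
    """Default EEG bank: log-spaced 1–35 Hz."""
    return WaveletBank.log_spaced(1.0, 35.0, fs=fs)


@dataclass
class SubjectResult:
    """Per-subject spectral summary produced by the pipeline."""

    spectrum: PowerSpectrum                # averaged over time and electrodes
    electrode_spectra: pd.DataFrame        # electrodes x frequencies power
    band_energy: dict[str, float]
    alpha_peak: float
    n_epochs: int
    metadata: dict


def subject_spectrum(
    epochs: EpochSet,
    bank: WaveletBank | None = None,
    bands: BandSet = EEG_BANDS,
) -> SubjectResult:
    """Wavelet spectra of an epoch set.

    Accepted epochs are concatenated per channel and convolved once (epochs
    are short relative to the lowest-frequency wavelets, so convolution is
    performed on the concatenated signal and only global edges are
    excluded).  Powers are averaged over time, then summarised per band and
    per electrode; the subject spectrum averages over electrodes.
    """
    if epochs.n == 0:
        raise ValueError("no epochs to analyse")
    bank = bank or eeg_wavelet_bank(epochs.fs)
    n_ch = len(epochs.channels)
    # (n_ch, n_epochs * EPOCH_SAMPLES)
    concat = np.concatenate(list(epochs.epochs), axis=1) if epochs.n > 1 else epochs.epochs[0]
    per_electrode = np.empty((n_ch, bank.freqs.size))
    for i in range(n_ch):
        per_electrode[i] = tf_power_multi(concat[i][None, :], bank).power
    mean_spec = PowerSpectrum(
        freqs=bank.freqs,
        power=per_electrode.mean(axis=0),
        provenance=dict(epochs.metadata),
    )
    return SubjectResult(
        spectrum=mean_spec,
        electrode_spectra=pd.DataFrame(
            per_electrode, index=epochs.channels, columns=bank.freqs
        ),
        band_energy=band_mse(mean_spec, bands),
        alpha_peak=dominant_peak(mean_spec, ALPHA_SEARCH),
        n_epochs=epochs.n,
        metadata=dict(epochs.metadata),
    )


def run_pipeline(
    recording: Recording,
    bank: WaveletBank | None = None,
    bands: BandSet = EEG_BANDS,
) -> SubjectResult:
    """Full per-subject pipeline: filter → CAR → epochs → spectra.

    The step order is part of the analysis contract; a recording that
    already carries preprocessing stamps in a different order is rejected.
    """
    if recording.provenance:
        expected = _PIPELINE_ORDER[: len(recording.provenance)]
        if tuple(recording.provenance) != expected:
            raise PipelineOrderError(
                f"preprocessing already applied out of order: {recording.provenance}"
            )
    rec = recording
    if "bandpass" not in rec.provenance:
        rec = bandpass(rec)
    if "car" not in rec.provenance:
        rec = rereference_car(rec)
    epochs = extract_epochs(rec)
    return subject_spectrum(epochs, bank=bank, bands=bands)


@dataclass
class GroupComparison:
    """Patient-vs-control statistics on band energies and alpha peaks."""

    subject_table: pd.DataFrame      # one row per subject: group, peaks, band MSEs
    band_tests: pd.DataFrame         # band, U-statistic, p, group means ± sem
    peak_test: dict                  # rank-sum on dominant alpha peaks
    electrode_differences: pd.DataFrame  # bands x electrodes, patient - control mean


def _sem(x: np.ndarray) -> float:
    return float(stats.sem(x)) if len(x) > 1 else float("nan")


def rank_sum_test(x: np.ndarray, y: np.ndarray):
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) test.

    Uses the exact null distribution for small tie-free samples and the
    tie-corrected normal approximation otherwise.
    """
    return stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")


def compare_groups(
    patients: list[SubjectResult],
    controls: list[SubjectResult],
    bands: BandSet = EEG_BANDS,
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum comparison of the two cohorts.

    Band energies (averaged over time and electrodes) and dominant alpha
    peaks are compared subject-wise; per-electrode band-energy difference
    maps are computed after lateral mirroring of left-lesion patients so the
    map's right side is ipsi-lesional.
    """
    if len(patients) < 2 or len(controls) < 2:
        raise ValueError("need at least two subjects per group")

    rows = []
    for grp, results in (("patient", patients), ("control", controls)):
        for r in results:
            row = {"group": grp, "alpha_peak": r.alpha_peak, **r.band_energy}
            rows.append(row)
    table = pd.DataFrame(rows)

    band_rows = []
    for band in bands:
        p_vals = table.loc[table.group == "patient", band.name].to_numpy()
        c_vals = table.loc[table.group == "control", band.name].to_numpy()
        stat = rank_sum_test(p_vals, c_vals)
        band_rows.append(
            {
                "band": band.name,
                "statistic": stat.statistic,
                "p_value": stat.pvalue,
                "patient_mean": p_vals.mean(),
                "patient_sem": _sem(p_vals),
                "control_mean": c_vals.mean(),
                "control_sem": _sem(c_vals),
            }
        )
    band_tests = pd.DataFrame(band_rows)

    p_peaks = table.loc[table.group == "patient", "alpha_peak"].to_numpy()
    c_peaks = table.loc[table.group == "control", "alpha_peak"].to_numpy()
    pk = rank_sum_test(p_peaks, c_peaks)
    ci = 1.96  # 95% CI half-width multiplier on the s.e.m.
    peak_test = {
        "statistic": float(pk.statistic),
        "p_value": float(pk.pvalue),
        "patient_mean": float(p_peaks.mean()),
        "patient_sem": _sem(p_peaks),
        "patient_ci95": (
            float(p_peaks.mean() - ci * _sem(p_peaks)),
            float(p_peaks.mean() + ci * _sem(p_peaks)),
        ),
        "control_mean": float(c_peaks.mean()),
        "control_sem": _sem(c_peaks),
        "control_ci95": (
            float(c_peaks.mean() - ci * _sem(c_peaks)),
            float(c_peaks.mean() + ci * _sem(c_peaks)),
        ),
    }

    # per-electrode band energies, mirrored so right = ipsi-lesional
    def electrode_band_table(results: list[SubjectResult]) -> dict[str, pd.DataFrame]:
        per_band: dict[str, list[pd.Series]] = {b.name: [] for b in bands}
        for r in results:
            freqs = r.electrode_spectra.columns.to_numpy(dtype=float)
            for b in bands:
                sel = (freqs >= b.lo) & (freqs <= b.hi)
                vals = pd.Series(
                    r.electrode_spectra.loc[:, sel].mean(axis=1), index=r.electrode_spectra.index
                )
                vals = mirror_electrodes(vals, r.metadata.get("lesion_side", "none"))
                per_band[b.name].append(vals)
        return {k: pd.concat(v, axis=1).mean(axis=1) for k, v in per_band.items()}

    pat = electrode_band_table(patients)
    ctl = electrode_band_table(controls)
    diff = pd.DataFrame({b.name: pat[b.name] - ctl[b.name] for b in bands}).T

    return GroupComparison(
        subject_table=table,
        band_tests=band_tests,
        peak_test=peak_test,
        electrode_differences=diff,
    )
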