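"""Morlet-wavelet time–frequency decomposition and band-power summaries.

The same machinery serves two signal families: local field potentials (LFPs)
built from the spiking model's membrane potentials (1 kHz, analysed 1–80 Hz)
and multichannel scalp EEG (500 Hz, analysed 1–35 Hz).  Power is estimated by
frequency-domain convolution with a bank of complex Morlet wavelets, squaring
the real part of the analytic signal at each time–frequency point, and
averaging over time.  Band summaries use the conventional delta/theta/alpha/
beta partition (plus gamma for the model, whose sampling rate supports it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import fft, ifft, next_fast_len

__all__ = [
    "Band",
    "BandSet",
    "EEG_BANDS",
    "MODEL_BANDS",
    "WaveletBank",
    "PowerSpectrum",
    "compute_lfp",
    "tf_power",
    "band_mse",
    "dominant_peak",
]


@dataclass(frozen=True)
class Band:
    name: str
    lo: float  # Hz, inclusive
    hi: float  # Hz, inclusive


@dataclass(frozen=True)
class BandSet:
    """Ordered, non-overlapping frequency bands."""

    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        for a, b in zip(self.bands, self.bands[1:]):
            if b.lo <= a.hi:
                raise ValueError(f"bands overlap or are unordered: {a} / {b}")

    def __iter__(self):
        return iter(self.bands)


#: Band edges used for all EEG summaries.  Note the partition is deliberately
#: non-contiguous (e.g. 4.0–4.2 Hz belongs to no band).
EEG_BANDS = BandSet(
    (
        Band("delta", 1.0, 4.0),
        Band("theta", 4.2, 7.9),
        Band("alpha", 8.3, 11.9),
        Band("beta", 12.4, 30.6),
    )
)

#: Model LFPs are sampled at 1 kHz, so a gamma band up to 80 Hz is added.
MODEL_BANDS = BandSet(EEG_BANDS.bands + (Band("gamma", 30.7, 80.0),))


@dataclass(frozen=True)
class WaveletBank:
    """Complex Morlet wavelets on a logarithmic frequency grid.

    Parameters
    ----------
    freqs
        Center frequencies in Hz, strictly increasing.
    cycles
        Number of cycles per wavelet, non-decreasing with frequency.  More
        cycles at higher frequencies trade temporal for spectral precision.
    fs
        Sampling rate of the signals this bank will analyse, in Hz.

    Each wavelet is a complex exponential under a Gaussian envelope with
    standard deviation ``sigma_t = cycles / (2 pi f)``, truncated at ±4
    sigma_t and normalised by its maximum value (so the envelope peaks at 1).
    """

    freqs: np.ndarray
    cycles: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        c = np.asarray(self.cycles, dtype=float)
        if f.ndim != 1 or f.size < 1 or np.any(np.diff(f) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if c.shape != f.shape or np.any(np.diff(c) < 0):
            raise ValueError("cycles must match freqs and be non-decreasing")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "cycles", c)

    @classmethod
    def log_spaced(
        cls,
        f_min: float,
        f_max: float,
        fs: float,
        n_freqs: int | None = None,
        points_per_decade: int = 50,
        cycles_min: float = 3.0,
        cycles_max: float = 10.0,
    ) -> "WaveletBank":
        """Build a log-spaced bank between ``f_min`` and ``f_max``.

        The frequency count defaults to ``points_per_decade`` per decade of
        bandwidth; cycles increase linearly from ``cycles_min`` at the lowest
        frequency to ``cycles_max`` at the highest.
        """
        if n_freqs is None:
            n_freqs = int(np.ceil(points_per_decade * np.log10(f_max / f_min))) + 1
        freqs = np.geomspace(f_min, f_max, n_freqs)
        cycles = np.linspace(cycles_min, cycles_max, n_freqs)
        return cls(freqs=freqs, cycles=cycles, fs=fs)

    def sigma_t(self) -> np.ndarray:
        """Gaussian envelope width per wavelet, in seconds."""
        return self.cycles / (2.0 * np.pi * self.freqs)

    def half_supports(self) -> np.ndarray:
        """Half-length of each truncated wavelet, in samples."""
        return np.ceil(4.0 * self.sigma_t() * self.fs).astype(int)

    def wavelet(self, i: int) -> np.ndarray:
        """Return wavelet ``i`` sampled on its truncated support."""
        half = int(self.half_supports()[i])
        t = np.arange(-half, half + 1) / self.fs
        st = self.sigma_t()[i]
        w = np.exp(2j * np.pi * self.freqs[i] * t) * np.exp(-(t**2) / (2 * st**2))
        return w / np.max(np.abs(w))


@dataclass
class TimeFrequencyPower:
    """Per-sample wavelet power with an edge-validity mask."""

    freqs: np.ndarray  # (F,)
    power: np.ndarray  # (F, T)
    valid: np.ndarray  # (F, T) bool; False within half a support of an edge
    fs: float

    def time_average(self) -> "PowerSpectrum":
        """Average power over valid samples at each frequency."""
        p = np.empty(self.freqs.size)
        for i in range(self.freqs.size):
            v = self.valid[i]
            p[i] = self.power[i, v].mean() if v.any() else np.nan
        return PowerSpectrum(freqs=self.freqs, power=p)


@dataclass
class PowerSpectrum:
    """Time-averaged wavelet power on the bank's frequency grid."""

    freqs: np.ndarray
    power: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("frequency grid and power must align")


def compute_lfp(membrane_traces: np.ndarray, lesion_mask: np.ndarray | None = None) -> np.ndarray:
    """Population LFP: per-sample mean membrane potential of intact neurons.

    Parameters
    ----------
    membrane_traces
        Array of shape (n_neurons, n_samples), in mV.
    lesion_mask
        Boolean per-neuron mask; True marks lesioned neurons, which are
        excluded from the average.  None means no lesion.
    """
    traces = np.asarray(membrane_traces, dtype=float)
    if traces.ndim != 2:
        raise ValueError("membrane_traces must be (n_neurons, n_samples)")
    if lesion_mask is not None:
        keep = ~np.asarray(lesion_mask, dtype=bool)
        if keep.shape[0] != traces.shape[0]:
            raise ValueError("lesion mask length must match neuron count")
        if not keep.any():
            raise ValueError("all neurons lesioned; LFP undefined")
        traces = traces[keep]
    return traces.mean(axis=0)


def tf_power(
    signal: np.ndarray,
    bank: WaveletBank,
    squared_real: bool = True,
    demean: bool = True,
) -> TimeFrequencyPower:
    """Wavelet power of a 1-D signal via frequency-domain convolution.

    The signal's FFT is multiplied with each wavelet's FFT and inverted back
    to the time domain; power at each time–frequency point is the square of
    the real part of that analytic signal (set ``squared_real=False`` for the
    conventional squared magnitude).  Samples within half a wavelet support
    of either end are flagged invalid and excluded from time averages.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    halves = bank.half_supports()
    if x.size < 2 * halves[0] + 1:
        raise ValueError(
            f"signal length {x.size} is shorter than the longest wavelet "
            f"support {2 * halves[0] + 1}"
        )
    if demean:
        x = x - x.mean()

    n = x.size
    n_fft = next_fast_len(n + 2 * int(halves[0]))
    xf = fft(x, n_fft)

    F = bank.freqs.size
    power = np.empty((F, n))
    valid = np.ones((F, n), dtype=bool)
    for i in range(F):
        w = bank.wavelet(i)
        half = int(halves[i])
        conv = ifft(xf * fft(w, n_fft))
        # 'same' alignment: wavelet center corresponds to lag `half`
        seg = conv[half : half + n]
        if squared_real:
            power[i] = np.real(seg) ** 2
        else:
            power[i] = np.abs(seg) ** 2
        if half > 0:
            valid[i, :half] = False
            valid[i, -half:] = False
    return TimeFrequencyPower(freqs=bank.freqs, power=power, valid=valid, fs=bank.fs)


def tf_power_multi(
    signals: np.ndarray,
    bank: WaveletBank,
    squared_real: bool = True,
    demean: bool = True,
) -> PowerSpectrum:
    """Time-averaged spectrum of (n_signals, n_samples), averaged over signals.

    Vectorised over wavelets and signals; used for multichannel EEG where
    only the channel-averaged, time-averaged spectrum is needed.
    """
    x = np.atleast_2d(np.asarray(signals, dtype=float))
    if demean:
        x = x - x.mean(axis=1, keepdims=True)
    halves = bank.half_supports()
    n = x.shape[1]
    if n < 2 * halves[0] + 1:
        raise ValueError("signals shorter than the longest wavelet support")
    n_fft = next_fast_len(n + 2 * int(halves[0]))
    xf = fft(x, n_fft, axis=1)  # (S, n_fft)

    F = bank.freqs.size
    out = np.empty(F)
    for i in range(F):
        w = bank.wavelet(i)
        half = int(halves[i])
        conv = ifft(xf * fft(w, n_fft)[None, :], axis=1)[:, half : half + n]
        p = np.real(conv) ** 2 if squared_real else np.abs(conv) ** 2
        sl = slice(half, n - half) if half > 0 else slice(None)
        out[i] = p[:, sl].mean()
    return PowerSpectrum(freqs=bank.freqs, power=out)


def band_mse(spectrum: PowerSpectrum, bands: BandSet) -> dict[str, float]:
    """Mean spectral energy per band: average power over grid frequencies
    falling inside each band's closed interval.

    A band containing no grid frequency yields NaN (the partition has gaps,
    e.g. 4.0–4.2 Hz, so a sparse grid can miss a band entirely).
    """
    out: dict[str, float] = {}
    for band in bands:
        sel = (spectrum.freqs >= band.lo) & (spectrum.freqs <= band.hi)
        out[band.name] = float(spectrum.power[sel].mean()) if sel.any() else float("nan")
    return out


def dominant_peak(
    spectrum: PowerSpectrum,
    search_range: tuple[float, float] = (6.0, 13.0),
) -> float:
    """Frequency of maximal power within ``search_range`` (inclusive).

    Ties are broken toward the lower frequency.  Raises if no grid point
    falls inside the range.
    """
    lo, hi = search_range
    sel = np.flatnonzero((spectrum.freqs >= lo) & (spectrum.freqs <= hi))
    if sel.size == 0:
        raise ValueError(f"no grid frequencies inside [{lo}, {hi}] Hz")
    p = spectrum.power[sel]
    return float(spectrum.freqs[sel[int(np.argmax(p))]])
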