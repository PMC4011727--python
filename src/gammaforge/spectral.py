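"""Power-spectral quantification of LFP traces.

The convention throughout: a spectrum is the average of single-segment
Hann-windowed periodograms over consecutive non-overlapping 4096-sample
segments of the epoch, with per-segment mean removal.  Power is reported
per frequency bin in squared signal units (µV² for field traces) and is
window-corrected so that the sum over all bins equals the windowed-signal
variance — a pure sinusoid of amplitude A contributes total power A²/2.

Gamma strength is quantified as summated power over 20–80 Hz; the peak
frequency is the bin-centre of the dominant bin in that band.  A trace is
classified as carrying spontaneous gamma when the mean bin power over
25–35 Hz strictly exceeds that over 10–20 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .trace import Trace

__all__ = [
    "PowerSpectrum",
    "GammaMetrics",
    "UndefinedPeakError",
    "power_spectrum",
    "summated_power",
    "peak_frequency",
    "is_spontaneous_gamma",
    "gamma_metrics",
    "spectrogram",
]

GAMMA_BAND = (20.0, 80.0)

_WINDOWS = {"hanning": "hann", "hann": "hann", "hamming": "hamming",
            "blackman": "blackman", "boxcar": "boxcar"}


class UndefinedPeakError(ValueError):
    """Raised when a band contains no power, so no peak frequency exists."""


@dataclass
class PowerSpectrum:
    """Averaged periodogram with its windowing contract attached."""

    frequencies: np.ndarray
    power: np.ndarray
    n_segments: int
    window_name: str
    fft_size: int
    sampling_rate: float

    @property
    def bin_width(self) -> float:
        return self.sampling_rate / self.fft_size

    @property
    def nyquist(self) -> float:
        return self.sampling_rate / 2.0

    def total_power(self) -> float:
        return float(np.sum(self.power))


@dataclass
class GammaMetrics:
    summated_power: float
    peak_frequency: float | None
    is_spontaneous_gamma: bool


def power_spectrum(trace: Trace, fft_size: int = 4096,
                   window: str = "hanning") -> PowerSpectrum:
    """Averaged periodogram of non-overlapping windowed segments.

    Per-bin power is scipy's Welch density estimate multiplied by the bin
    width, which makes the spectrum satisfy power conservation: summing
    the bins of a full spectrum returns the (per-segment detrended)
    signal variance.
    """
    x = trace.samples
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite samples")
    if x.size < fft_size:
        raise ValueError(
            f"trace ({x.size} samples) shorter than one segment ({fft_size})")
    win = _WINDOWS.get(window.lower())
    if win is None:
        raise ValueError(f"unknown window {window!r}")
    freqs, pxx = sps.welch(
        x, fs=trace.sampling_rate, window=win, nperseg=fft_size,
        noverlap=0, detrend="constant", scaling="density")
    power = pxx * (trace.sampling_rate / fft_size)
    return PowerSpectrum(
        frequencies=freqs,
        power=power,
        n_segments=x.size // fft_size,
        window_name=window,
        fft_size=fft_size,
        sampling_rate=trace.sampling_rate,
    )


def _band_mask(ps: PowerSpectrum, band: tuple[float, float]) -> np.ndarray:
    low, high = band
    if not high > low:
        raise ValueError("band must satisfy high > low")
    if low < 0 or high > ps.nyquist + 1e-9:
        raise ValueError("band outside [0, Nyquist]")
    return (ps.frequencies >= low) & (ps.frequencies < high)


def summated_power(ps: PowerSpectrum,
                   band: tuple[float, float] = GAMMA_BAND) -> float:
    """Sum of per-bin power over bins with centre in [low, high)."""
    mask = _band_mask(ps, band)
    if not mask.any():
        raise ValueError("band contains no frequency bins")
    return float(np.sum(ps.power[mask]))


def peak_frequency(ps: PowerSpectrum,
                   band: tuple[float, float] = GAMMA_BAND) -> float:
    """Bin-centre frequency of the maximum-power bin within the band.

    Ties break toward the lower frequency.  Raises
    :class:`UndefinedPeakError` when the band carries no power (distinct
    from a genuine 0 Hz peak).
    """
    mask = _band_mask(ps, band)
    if not mask.any():
        raise ValueError("band contains no frequency bins")
    p = ps.power[mask]
    if np.all(p == 0):
        raise UndefinedPeakError("all-zero power in band: peak undefined")
    return float(ps.frequencies[mask][int(np.argmax(p))])


def is_spontaneous_gamma(ps: PowerSpectrum) -> bool:
    """True iff mean bin power over 25–35 Hz strictly exceeds 10–20 Hz.

    Exact equality (e.g. an ideally flat spectrum) classifies as False.
    """
    if ps.frequencies[-1] < 35.0:
        raise ValueError("spectrum must cover 10–35 Hz")
    gamma = ps.power[_band_mask(ps, (25.0, 35.0))]
    beta = ps.power[_band_mask(ps, (10.0, 20.0))]
    if gamma.size == 0 or beta.size == 0:
        raise ValueError("insufficient frequency resolution for 10–35 Hz "
                         "classification")
    return bool(np.mean(gamma) > np.mean(beta))


def gamma_metrics(ps: PowerSpectrum,
                  band: tuple[float, float] = GAMMA_BAND) -> GammaMetrics:
    """Summated power, peak frequency and spontaneous-gamma flag."""
    try:
        peak = peak_frequency(ps, band)
    except UndefinedPeakError:
        peak = None
    return GammaMetrics(
        summated_power=summated_power(ps, band),
        peak_frequency=peak,
        is_spontaneous_gamma=is_spontaneous_gamma(ps),
    )


def spectrogram(
    trace: Trace,
    window_length: float,
    step: float,
    fft_size: int = 4096,
    window: str = "hanning",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sliding-window averaged-periodogram spectrogram.

    Returns ``(times, frequencies, power)`` where column ``power[:, j]``
    is the spectrum of the window starting at ``times[j]`` (seconds).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    fs = trace.sampling_rate
    n_win = int(round(window_length * fs))
    if n_win < fft_size:
        raise ValueError("window_length must cover at least one FFT segment")
    n_step = max(1, int(round(step * fs)))
    starts = np.arange(0, trace.n_samples - n_win + 1, n_step)
    if starts.size == 0:
        raise ValueError("trace shorter than one spectrogram window")
    cols = []
    for s in starts:
        sub = trace.copy_with(trace.samples[s:s + n_win])
        cols.append(power_spectrum(sub, fft_size=fft_size, window=window).power)
    freqs = power_spectrum(
        trace.copy_with(trace.samples[:n_win]), fft_size=fft_size,
        window=window).frequencies
    return starts / fs, freqs, np.column_stack(cols)
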