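"""Cross-correlogram analysis of multi-site LFP recordings.

For each roving channel against a fixed reference (the paper-style
protocol keeps one electrode in CA3c), the Pearson correlation of the
gamma band-passed signals is computed at every integer-sample lag within
+/- max_lag.  The correlogram peak gives the coherence strength
(max correlation) and timing (lag), and the lag is converted to a phase
lead in degrees of the dominant gamma cycle.

Sign convention: a positive lag / phase means the roving channel peaks
after (lags) the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace import Trace
from .waveform import bandpass_gamma

__all__ = [
    "CrossChannelResult",
    "cross_correlogram",
    "phase_lead",
    "compare_channels",
    "wrap_phase_deg",
]


@dataclass
class CrossChannelResult:
    """Peak of a cross-correlogram expressed as coherence / lag / phase.

    ``lag_at_max`` is on the integer-sample grid; ``lag_refined_ms`` adds
    parabolic sub-sample interpolation around the peak, with the
    corresponding ``phase_lead_refined``.
    """

    max_correlation: float
    lag_at_max: float
    phase_lead: float
    dominant_frequency_used: float
    lag_refined_ms: float
    phase_lead_refined: float


def wrap_phase_deg(phase: float) -> float:
    """Wrap a phase in degrees to (-180, 180]."""
    w = (phase + 180.0) % 360.0 - 180.0
    if w == -180.0:
        w = 180.0
    return float(w)


def cross_correlogram(
    ref: Trace,
    rov: Trace,
    max_lag_ms: float,
    band: tuple[float, float] | None = (20.0, 80.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation at every integer-sample lag in [-L, +L].

    Both channels are band-passed first unless ``band`` is None (raw
    mode).  ``values[k]`` correlates ``ref[t]`` with ``rov[t + lag_k]``,
    so a roving channel that is a delayed copy of the reference peaks at a
    positive lag equal to its delay.  Swapping the channels negates the
    lag axis of the result.
    """
    if ref.sampling_rate != rov.sampling_rate:
        raise ValueError("channels must share a sampling rate")
    n = min(ref.n_samples, rov.n_samples)
    if np.ptp(ref.samples[:n]) == 0 or np.ptp(rov.samples[:n]) == 0:
        raise ValueError("constant trace: correlation undefined")
    if band is not None:
        x = bandpass_gamma(ref, band=band).samples[:n]
        y = bandpass_gamma(rov, band=band).samples[:n]
    else:
        x = ref.samples[:n].copy()
        y = rov.samples[:n].copy()

    fs = ref.sampling_rate
    L = int(round(max_lag_ms * 1e-3 * fs))
    if L >= n - 2:
        raise ValueError("max_lag too large for trace length")
    lags = np.arange(-L, L + 1)
    vals = np.empty(lags.size)
    for j, k in enumerate(lags):
        if k >= 0:
            a, b = x[: n - k], y[k:]
        else:
            a, b = x[-k:], y[: n + k]
        a = a - a.mean()
        b = b - b.mean()
        denom = np.sqrt(np.dot(a, a) * np.dot(b, b))
        vals[j] = np.dot(a, b) / denom if denom > 0 else np.nan
    return lags * 1000.0 / fs, vals


def _parabolic_refine(lags_ms: np.ndarray, vals: np.ndarray,
                      i: int) -> float:
    """Sub-sample peak location by a parabola through 3 points."""
    if i == 0 or i == vals.size - 1:
        return float(lags_ms[i])
    y0, y1, y2 = vals[i - 1], vals[i], vals[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(lags_ms[i])
    delta = 0.5 * (y0 - y2) / denom
    step = lags_ms[1] - lags_ms[0]
    return float(lags_ms[i] + delta * step)


def phase_lead(
    lags_ms: np.ndarray,
    values: np.ndarray,
    dominant_frequency: float,
) -> CrossChannelResult:
    """Convert a correlogram peak into lag and phase of the gamma cycle.

    phase = lag(ms) x frequency(Hz) x 360 / 1000, wrapped to (-180, 180].
    The dominant frequency should come from the reference channel's
    spectral peak.
    """
    if not dominant_frequency > 0 or not np.isfinite(dominant_frequency):
        raise ValueError("dominant frequency must be positive and finite")
    vals = np.asarray(values, dtype=float)
    if np.all(np.isnan(vals)):
        raise ValueError("correlogram has no finite values")
    i = int(np.nanargmax(vals))
    lag = float(lags_ms[i])
    lag_ref = _parabolic_refine(np.asarray(lags_ms, float), vals, i)
    to_phase = dominant_frequency * 360.0 / 1000.0
    return CrossChannelResult(
        max_correlation=float(vals[i]),
        lag_at_max=lag,
        phase_lead=wrap_phase_deg(lag * to_phase),
        dominant_frequency_used=float(dominant_frequency),
        lag_refined_ms=lag_ref,
        phase_lead_refined=wrap_phase_deg(lag_ref * to_phase),
    )


def compare_channels(
    ref: Trace,
    rov: Trace,
    max_lag_ms: float = 50.0,
    dominant_frequency: float | None = None,
    band: tuple[float, float] | None = (20.0, 80.0),
) -> CrossChannelResult:
    """Correlogram + phase lead of one roving channel against a reference.

    When ``dominant_frequency`` is omitted it is measured from the
    reference channel's power spectrum over the gamma band.
    """
    if dominant_frequency is None:
        from .spectral import peak_frequency, power_spectrum
        fft = min(4096, 2 ** int(np.floor(np.log2(ref.n_samples))))
        dominant_frequency = peak_frequency(power_spectrum(ref, fft_size=fft))
    lags, vals = cross_correlogram(ref, rov, max_lag_ms, band=band)
    return phase_lead(lags, vals, dominant_frequency)
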