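"""Detection and summary of spontaneous postsynaptic currents.

A simple, parameter-transparent threshold detector: the baseline is the
trace median (robust to event load), candidate events are local maxima of
the baseline-subtracted, polarity-rectified signal that exceed the
threshold, and candidates closer together than the refractory interval
are merged keeping the larger.  A short boxcar pre-smoothing and a
prominence requirement of half the threshold suppress noise chatter on
the decay of each event, which would otherwise split one PSC into
several detections.  Summaries are event frequency (count / duration),
mean amplitude and mean inter-event interval; distributions are compared
with empirical CDFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import signal as sps
from statsmodels.distributions.empirical_distribution import ECDF

from .trace import Trace

__all__ = ["EventList", "detect_events", "summarize_events", "ecdf"]


@dataclass
class EventList:
    """Detected events: sorted times (s), magnitudes (pA), trace duration."""

    times: np.ndarray
    amplitudes: np.ndarray
    trace_duration: float
    detection_params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64)
        if self.times.shape != self.amplitudes.shape:
            raise ValueError("times and amplitudes must match in length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if self.times.size and (self.times[0] < 0
                                or self.times[-1] > self.trace_duration):
            raise ValueError("event times outside [0, trace_duration]")

    @property
    def n_events(self) -> int:
        return self.times.size


def detect_events(
    trace: Trace,
    threshold: float,
    refractory_ms: float = 2.0,
    polarity: int = 1,
    smooth_ms: float = 0.5,
    baseline: str = "median",
) -> EventList:
    """Threshold-and-refractory event detector.

    The trace median is subtracted as baseline; ``polarity`` (+1 upward,
    -1 downward) rectifies the search direction.  Candidate events are
    local maxima of the (optionally boxcar-smoothed, ``smooth_ms``)
    rectified signal that exceed ``threshold`` with a prominence of at
    least half the threshold; peaks closer than ``refractory_ms`` are
    merged keeping the larger.

    Amplitude is the peak magnitude above baseline, read from the
    unsmoothed signal at the detected peak.  ``baseline="median"`` uses
    the global trace median; ``baseline="local"`` additionally subtracts
    a per-event pre-event median (10–2 ms before the peak), which removes
    the upward bias from events riding on the decay of earlier events.
    """
    if refractory_ms < 0:
        raise ValueError("refractory must be >= 0")
    if polarity not in (-1, 1):
        raise ValueError("polarity must be +1 or -1")
    if baseline not in ("median", "local"):
        raise ValueError("baseline must be 'median' or 'local'")
    x = trace.samples
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite samples")
    fs = trace.sampling_rate
    y = polarity * (x - np.median(x))
    if smooth_ms > 0:
        w = max(1, int(round(smooth_ms * 1e-3 * fs)))
        yd = np.convolve(y, np.ones(w) / w, mode="same")
    else:
        yd = y
    distance = max(1, int(round(refractory_ms * 1e-3 * fs)))
    peaks, _ = sps.find_peaks(yd, height=threshold, distance=distance,
                              prominence=0.5 * threshold)
    amps = y[peaks]
    if baseline == "local":
        lo = np.maximum(peaks - int(round(10e-3 * fs)), 0)
        hi = np.maximum(peaks - int(round(2e-3 * fs)), 1)
        local = np.array([np.median(y[a:b]) if b > a else 0.0
                          for a, b in zip(lo, hi)])
        amps = amps - local
    times = peaks.astype(float) / fs
    return EventList(
        times=times,
        amplitudes=np.asarray(amps, dtype=float),
        trace_duration=trace.duration,
        detection_params={"threshold": float(threshold),
                          "refractory_ms": float(refractory_ms),
                          "polarity": polarity,
                          "smooth_ms": float(smooth_ms),
                          "baseline": baseline},
    )


def summarize_events(events: EventList) -> dict[str, float | None]:
    """Frequency (Hz), mean amplitude (pA) and mean IEI (s).

    An empty list yields frequency 0 with amplitude/IEI reported as None
    (undefined), never as zero.
    """
    if events.trace_duration <= 0:
        raise ValueError("trace_duration must be positive")
    n = events.n_events
    freq = n / events.trace_duration
    mean_amp = float(np.mean(events.amplitudes)) if n else None
    mean_iei = float(np.mean(np.diff(events.times))) if n >= 2 else None
    return {"frequency": float(freq), "mean_amplitude": mean_amp,
            "mean_iei": mean_iei, "n_events": n}


def ecdf(values: np.ndarray,
         grid: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous empirical CDF.

    Without a grid, returns the sorted unique step locations and the CDF
    just after each step (ending at 1).  With a grid (for cross-group
    comparison), returns the grid and the CDF evaluated on it.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("ecdf of an empty sample is undefined")
    f = ECDF(v, side="right")
    if grid is None:
        x = np.unique(v)
        return x, f(x)
    grid = np.asarray(grid, dtype=float)
    return grid, f(grid)
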