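"""Evoked synaptic response analysis.

Covers the three evoked protocols of the pipeline:

* stimulus–response curves: logistic (Boltzmann-equivalent) fit giving the
  half-maximal stimulus intensity, maximal response and slope;
* high-frequency trains (e.g. 10 stimuli at 33 Hz): per-pulse responses
  normalised to the first, with facilitation/depression summary metrics;
* readily-releasable-pool (RRP) estimation from 40-pulse, 20 Hz trains by
  cumulative-amplitude back-extrapolation: the cumulative evoked amplitude
  is plotted against pulse time, the late (1–2 s) linear phase is fitted by
  ordinary least squares and the intercept at t = 0 estimates the RRP in
  current units.  First-pulse amplitude / RRP gives the single-vesicle
  release probability P_ves; RRP / quantal amplitude gives the vesicle
  count N_syn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trace import Trace

__all__ = [
    "TrainResponse",
    "TrainMetrics",
    "RRPEstimate",
    "StimulusResponseFit",
    "average_sweeps",
    "fit_stimulus_response",
    "psp_slope",
    "train_metrics",
    "estimate_rrp",
]


@dataclass
class TrainResponse:
    """Ordered per-pulse response magnitudes for one stimulus train."""

    amplitudes: np.ndarray
    stim_freq: float
    unit: str = "pA"
    sweep_id: str | None = None

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64)
        if self.amplitudes.ndim != 1 or self.amplitudes.size < 1:
            raise ValueError("amplitudes must be a non-empty 1-D sequence")
        if not self.stim_freq > 0:
            raise ValueError("stim_freq must be positive")

    @property
    def n_pulses(self) -> int:
        return self.amplitudes.size

    @property
    def normalized(self) -> np.ndarray:
        """Amplitudes divided by the first response (normalized[0] == 1)."""
        first = self.amplitudes[0]
        if first == 0:
            raise ValueError("cannot normalise: first response is zero")
        return self.amplitudes / first

    @property
    def pulse_times(self) -> np.ndarray:
        """Pulse times in seconds; pulse i (1-based) occurs at i/stim_freq."""
        return np.arange(1, self.n_pulses + 1) / self.stim_freq


@dataclass
class TrainMetrics:
    """Facilitation/depression summary of a normalised train.

    ``pulse2_ratio`` and ``late_mean_8_10`` are None when the train has
    fewer than 10 pulses; ``steady_state_last5`` (percent of first
    response) requires at least 5 pulses.
    """

    pulse2_ratio: float | None
    late_mean_8_10: float | None
    steady_state_last5: float | None


@dataclass
class RRPEstimate:
    """Back-extrapolated readily-releasable-pool estimate.

    ``rrp_amplitude`` is the OLS intercept of the cumulative amplitude at
    t = 0 (pA); ``p_ves`` = first amplitude / rrp_amplitude; ``n_syn_raw``
    = rrp_amplitude / quantal amplitude, with ``n_syn`` its nearest
    integer. ``valid`` is False for a negative intercept.
    """

    rrp_amplitude: float
    p_ves: float
    n_syn: int | None
    n_syn_raw: float | None
    regression_slope: float
    r_squared: float
    fit_window: tuple[float, float]
    n_points: int
    valid: bool


@dataclass
class StimulusResponseFit:
    """Logistic stimulus–response fit max / (1 + exp(-k (V - h)))."""

    half_max_intensity: float
    max_response: float
    steepness: float
    linear_slope: float
    residual_rms: float
    reliable: bool
    intensity_range: tuple[float, float] = field(default=(np.nan, np.nan))


def average_sweeps(sweeps: Sequence[TrainResponse]) -> TrainResponse:
    """Pulse-wise mean across repeated sweeps of the same protocol."""
    if len(sweeps) == 0:
        raise ValueError("no sweeps given")
    freqs = {s.stim_freq for s in sweeps}
    npulses = {s.n_pulses for s in sweeps}
    if len(freqs) != 1 or len(npulses) != 1:
        raise ValueError("sweeps must share stim_freq and pulse count")
    amp = np.mean([s.amplitudes for s in sweeps], axis=0)
    return TrainResponse(amp, stim_freq=sweeps[0].stim_freq, unit=sweeps[0].unit)


def train_metrics(train: TrainResponse) -> TrainMetrics:
    """Summarise facilitation/depression of a stimulus train.

    pulse2_ratio is the second normalised response; late_mean_8_10 the mean
    of normalised pulses 8–10 (1-based, inclusive); steady_state_last5 the
    mean of the last 5 normalised responses expressed in percent.
    """
    norm = train.normalized
    n = train.n_pulses
    pulse2 = float(norm[1]) if n >= 10 else None
    late = float(np.mean(norm[7:10])) if n >= 10 else None
    steady = float(np.mean(norm[-5:]) * 100.0) if n >= 5 else None
    return TrainMetrics(pulse2_ratio=pulse2, late_mean_8_10=late,
                        steady_state_last5=steady)


def _logistic(v: np.ndarray, vmax: float, k: float, h: float) -> np.ndarray:
    return vmax / (1.0 + np.exp(-k * (v - h)))


def fit_stimulus_response(table: pd.DataFrame | Sequence) -> StimulusResponseFit:
    """Least-squares logistic fit of a stimulus–response table.

    Parameters
    ----------
    table
        DataFrame with columns ``intensity`` (V) and ``response``, or a
        2-column array-like in that order.

    The fit is flagged unreliable when the fitted half-max falls outside
    the sampled intensity range (non-saturating data) or the optimiser
    fails to converge.
    """
    if isinstance(table, pd.DataFrame):
        v = table["intensity"].to_numpy(dtype=float)
        r = table["response"].to_numpy(dtype=float)
    else:
        arr = np.asarray(table, dtype=float)
        v, r = arr[:, 0], arr[:, 1]
    if np.unique(v).size < 5:
        raise ValueError("need at least 5 distinct intensities")

    rmax0 = float(np.max(r))
    h0 = float(v[np.argmin(np.abs(r - rmax0 / 2.0))])
    k0 = 4.0 / max(np.ptp(v), 1e-9)
    reliable = True
    try:
        popt, _ = optimize.curve_fit(
            _logistic, v, r, p0=[rmax0, k0, h0],
            bounds=([0.0, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        vmax, k, h = (float(x) for x in popt)
        resid = r - _logistic(v, vmax, k, h)
        rms = float(np.sqrt(np.mean(resid**2)))
    except RuntimeError:
        vmax, k, h, rms = rmax0, k0, h0, float("nan")
        reliable = False
    # non-saturating data: half-max or plateau extrapolated beyond range
    if not (v.min() <= h <= v.max()) or vmax > 1.2 * rmax0:
        reliable = False
    return StimulusResponseFit(
        half_max_intensity=h,
        max_response=vmax,
        steepness=k,
        linear_slope=k * vmax / 4.0,
        residual_rms=rms,
        reliable=reliable,
        intensity_range=(float(v.min()), float(v.max())),
    )


def psp_slope(
    sweep: Trace,
    stimulus_time: float,
    polarity: int = 1,
    search_window_ms: float = 50.0,
    baseline_ms: float = 5.0,
    span: tuple[float, float] = (0.20, 0.80),
    noise_factor: float = 4.0,
) -> float | None:
    """Rising-phase slope of an evoked postsynaptic response.

    A line is least-squares fitted to the samples of the rising phase whose
    amplitude lies in the 20–80 % span between baseline and peak; the
    returned slope is in trace-units per second and follows the trace
    polarity.  Returns None (missing, not zero) when no response exceeds
    ``noise_factor`` times the pre-stimulus noise SD.
    """
    fs = sweep.sampling_rate
    i_stim = int(round(stimulus_time * fs))
    if not 0 <= i_stim < sweep.n_samples - 2:
        raise ValueError("stimulus_time outside sweep")
    x = polarity * sweep.samples
    i0 = max(0, i_stim - int(round(baseline_ms * 1e-3 * fs)))
    pre = x[i0:i_stim + 1]
    baseline = float(np.median(pre)) if pre.size else float(x[i_stim])
    noise_sd = float(np.std(pre)) if pre.size > 2 else 0.0

    i_end = min(sweep.n_samples, i_stim + int(round(search_window_ms * 1e-3 * fs)) + 1)
    seg = x[i_stim:i_end] - baseline
    i_peak = int(np.argmax(seg))
    amp = float(seg[i_peak])
    if amp <= 0 or (noise_sd > 0 and amp < noise_factor * noise_sd):
        return None

    rising = seg[: i_peak + 1]
    mask = (rising >= span[0] * amp) & (rising <= span[1] * amp)
    idx = np.flatnonzero(mask)
    if idx.size < 2:
        # steep response: fall back to the two samples bracketing mid-rise
        idx = np.array([max(i_peak - 1, 0), i_peak])
    t = idx / fs
    slope = float(np.polyfit(t, rising[idx], 1)[0])
    return polarity * slope


def estimate_rrp(
    train: TrainResponse | Sequence[TrainResponse],
    quantal_amplitude: float | None = None,
    fit_window: tuple[float, float] = (1.0, 2.0),
    first_pulse_at_zero: bool = False,
) -> RRPEstimate:
    """Estimate the readily releasable pool by back-extrapolation.

    The cumulative response amplitude is regressed on pulse time over
    ``fit_window`` (inclusive) and the intercept at t = 0 is the RRP
    amplitude.  When several sweeps are given they are averaged pulse-wise
    first, so P_ves uses the mean first-pulse amplitude.

    Pulse i (1-based) is placed at t = i/stim_freq by default; with
    ``first_pulse_at_zero`` at t = (i-1)/stim_freq.
    """
    if not isinstance(train, TrainResponse):
        train = average_sweeps(train)
    if quantal_amplitude is not None and not quantal_amplitude > 0:
        raise ValueError("quantal_amplitude must be positive")
    lo, hi = fit_window
    if not hi > lo >= 0:
        raise ValueError("fit window must satisfy 0 <= lo < hi")

    t = train.pulse_times
    if first_pulse_at_zero:
        t = t - 1.0 / train.stim_freq
    if t[-1] < hi:
        warnings.warn(
            "train shorter than the fit window; extrapolation is weakly "
            "constrained", stacklevel=2)
    cum = np.cumsum(train.amplitudes)
    mask = (t >= lo) & (t <= hi)
    if np.count_nonzero(mask) < 2:
        raise ValueError("fewer than 2 cumulative points in the fit window")

    res = stats.linregress(t[mask], cum[mask])
    intercept = float(res.intercept)
    valid = intercept >= 0
    if not valid:
        warnings.warn("negative back-extrapolated intercept; estimate "
                      "flagged invalid", stacklevel=2)
    p_ves = float(train.amplitudes[0] / intercept) if intercept > 0 else float("nan")
    n_syn_raw = (intercept / quantal_amplitude) if quantal_amplitude else None
    return RRPEstimate(
        rrp_amplitude=intercept,
        p_ves=p_ves,
        n_syn=int(round(n_syn_raw)) if n_syn_raw is not None else None,
        n_syn_raw=float(n_syn_raw) if n_syn_raw is not None else None,
        regression_slope=float(res.slope),
        r_squared=float(res.rvalue**2),
        fit_window=(float(lo), float(hi)),
        n_points=int(np.count_nonzero(mask)),
        valid=valid,
    )
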