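"""Synthetic-data generators with known ground truth.

Every input class of the pipeline can be generated here so that all
downstream stages are testable without recordings:

* LFP traces carrying a gamma-band sinusoid on broadband (white or 1/f)
  noise, single- or multi-channel with controlled inter-channel lag and
  attenuation;
* evoked IPSC/PSP trains from a mean-field vesicle depletion–replenishment
  model with optional additive facilitation of release probability;
* spontaneous postsynaptic-current traces as Poisson event trains convolved
  with a difference-of-exponentials kernel plus Gaussian noise;
* sigmoidal stimulus–response tables.

Each generator returns its output together with a :class:`GroundTruth`
sidecar carrying the generating parameters and the exact latent quantities
(event times, per-pulse released amounts, channel lags).  Identical spec +
seed give bit-identical output.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .synaptic import TrainResponse
from .trace import Trace

__all__ = [
    "OscillationSpec",
    "DepletionModelParams",
    "EventTrainSpec",
    "GroundTruth",
    "gen_lfp",
    "gen_multichannel_lfp",
    "simulate_train",
    "gen_psc_trace",
    "gen_stimulus_response",
]


@dataclass(frozen=True)
class OscillationSpec:
    """Parameters of a synthetic gamma-band LFP.

    frequency (Hz, 20–80 typical), amplitude (µV, peak sinusoid
    amplitude), noise_sd (µV, total SD of the broadband background),
    pink_exponent (power-law exponent of the background spectrum, 0 =
    white), duration (s), sampling_rate (Hz), seed.
    """

    frequency: float = 30.0
    amplitude: float = 10.0
    noise_sd: float = 5.0
    pink_exponent: float = 0.0
    duration: float = 60.0
    sampling_rate: float = 10_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if not self.frequency < self.sampling_rate / 2:
            raise ValueError(
                f"frequency {self.frequency} Hz is at or above the Nyquist "
                f"frequency {self.sampling_rate / 2} Hz")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be non-negative")


@dataclass(frozen=True)
class DepletionModelParams:
    """Mean-field vesicle depletion–replenishment model.

    n_vesicles (pool size N), quantal_amplitude (pA per vesicle, q),
    release_prob (fraction of the available pool released per pulse,
    P_ves), tau_recovery (s, replenishment time constant),
    facilitation_increment (additive per-pulse increase of release
    probability), tau_facilitation (s, its decay), noise_cv
    (multiplicative per-pulse amplitude noise CV), seed.
    """

    n_vesicles: float = 34.0
    quantal_amplitude: float = 43.0
    release_prob: float = 0.08
    tau_recovery: float = 20.0
    facilitation_increment: float = 0.0
    tau_facilitation: float = 0.2
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_vesicles >= 1:
            raise ValueError("n_vesicles must be >= 1")
        if not self.quantal_amplitude > 0:
            raise ValueError("quantal_amplitude must be positive")
        if not 0 < self.release_prob <= 1:
            raise ValueError("release_prob must be in (0, 1]")
        if not self.tau_recovery > 0:
            raise ValueError("tau_recovery must be positive")
        if self.facilitation_increment < 0 or self.noise_cv < 0:
            raise ValueError("facilitation_increment and noise_cv must be "
                             ">= 0")
        if not self.tau_facilitation > 0:
            raise ValueError("tau_facilitation must be positive")


@dataclass(frozen=True)
class EventTrainSpec:
    """Poisson PSC train convolved with a difference-of-exponentials kernel.

    rate (Hz), amplitude_mean (pA), amplitude_cv, kernel_rise / kernel_decay
    (ms, with decay > rise > 0), noise_sd (pA), duration (s),
    sampling_rate (Hz), seed.
    """

    rate: float = 12.6
    amplitude_mean: float = 38.3
    amplitude_cv: float = 0.2
    kernel_rise: float = 0.5
    kernel_decay: float = 8.0
    noise_sd: float = 3.8
    duration: float = 120.0
    sampling_rate: float = 10_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if not self.kernel_decay > self.kernel_rise > 0:
            raise ValueError("require kernel_decay > kernel_rise > 0 (ms)")
        if self.kernel_decay * 1e-3 >= self.duration:
            raise ValueError("kernel time constant exceeds trace duration")
        if not self.duration > 0 or not self.sampling_rate > 0:
            raise ValueError("duration and sampling_rate must be positive")
        if self.amplitude_mean <= 0 or self.amplitude_cv < 0 or self.noise_sd < 0:
            raise ValueError("invalid amplitude/noise parameters")


@dataclass(frozen=True)
class GroundTruth:
    """Latent generating quantities carried alongside generated data."""

    params: dict[str, Any]
    seed: int | None = None
    event_times: np.ndarray | None = None
    event_amplitudes: np.ndarray | None = None
    per_pulse_released: np.ndarray | None = None
    replenished: np.ndarray | None = None
    channel_lags_ms: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("event_times", "event_amplitudes", "per_pulse_released",
                     "replenished", "channel_lags_ms"):
            v = getattr(self, name)
            if v is not None:
                arr = np.asarray(v, dtype=np.float64)
                arr.flags.writeable = False
                object.__setattr__(self, name, arr)

    def to_json(self) -> str:
        def _clean(v: Any) -> Any:
            if isinstance(v, np.ndarray):
                return v.tolist()
            return v
        payload = {k: _clean(v) for k, v in asdict(self).items()
                   if v is not None}
        return json.dumps(payload, indent=2)


def _background_noise(n: int, sd: float, exponent: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Gaussian background, optionally spectrally shaped to 1/f**exponent.

    Shaping multiplies the rFFT of white noise by f**(-exponent/2) (DC
    zeroed) and renormalises to the requested total SD, so the realised
    time-domain variance equals sd**2 regardless of exponent.
    """
    if sd == 0:
        return np.zeros(n)
    white = rng.normal(0.0, 1.0, n)
    if exponent == 0:
        return sd * white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n)
    x *= sd / np.std(x)
    return x


def _oscillation(spec: OscillationSpec, n: int, lag_s: float = 0.0,
                 gain: float = 1.0) -> np.ndarray:
    t = np.arange(n) / spec.sampling_rate
    return gain * spec.amplitude * np.sin(
        2.0 * np.pi * spec.frequency * (t - lag_s))


def gen_lfp(spec: OscillationSpec) -> tuple[Trace, GroundTruth]:
    """Generate one LFP channel: sinusoid plus broadband background.

    The trace has exactly round(duration x sampling_rate) samples and the
    sinusoid contributes variance amplitude**2 / 2 (noise on top).
    """
    n = int(round(spec.duration * spec.sampling_rate))
    rng = np.random.default_rng(spec.seed)
    x = _oscillation(spec, n) + _background_noise(
        n, spec.noise_sd, spec.pink_exponent, rng)
    trace = Trace(x, spec.sampling_rate, unit="µV", name="lfp",
                  metadata={"kind": "synthetic_lfp"})
    return trace, GroundTruth(params=asdict(spec), seed=spec.seed)


def gen_multichannel_lfp(
    spec: OscillationSpec,
    lags_ms: Sequence[float],
    attenuations: Sequence[float],
) -> tuple[list[Trace], GroundTruth]:
    """Multi-site LFP: the reference oscillation delayed and attenuated.

    Channel k carries the reference sinusoid delayed by ``lags_ms[k]`` and
    scaled by ``attenuations[k]``, plus an independent noise realisation.
    Lag 0 / attenuation 1 reproduces the reference oscillatory component
    exactly.  A lag of one oscillation period or more triggers a
    phase-wrap warning.
    """
    lags = np.asarray(lags_ms, dtype=float)
    atts = np.asarray(attenuations, dtype=float)
    if lags.shape != atts.shape:
        raise ValueError("lags and attenuations must have the same length")
    if np.any((atts <= 0) | (atts > 1)):
        raise ValueError("attenuations must lie in (0, 1]")
    period_ms = 1000.0 / spec.frequency
    if np.any(np.abs(lags) >= period_ms):
        warnings.warn(
            "lag magnitude >= one oscillation period: cross-correlogram "
            "phase is ambiguous (wrapped)", stacklevel=2)

    n = int(round(spec.duration * spec.sampling_rate))
    children = np.random.SeedSequence(spec.seed).spawn(len(lags))
    traces = []
    for k, (lag, att) in enumerate(zip(lags, atts)):
        rng = np.random.default_rng(children[k])
        x = _oscillation(spec, n, lag_s=lag * 1e-3, gain=att)
        x += _background_noise(n, spec.noise_sd, spec.pink_exponent, rng)
        traces.append(Trace(x, spec.sampling_rate, unit="µV", name=f"ch{k}",
                            metadata={"kind": "synthetic_lfp",
                                      "lag_ms": float(lag),
                                      "attenuation": float(att)}))
    gt = GroundTruth(params=asdict(spec), seed=spec.seed,
                     channel_lags_ms=lags)
    return traces, gt


def simulate_train(
    params: DepletionModelParams,
    n_pulses: int = 40,
    stim_freq: float = 20.0,
) -> tuple[TrainResponse, GroundTruth]:
    """Simulate an evoked train from the depletion–replenishment model.

    The available pool R starts at N.  Pulse i releases
    ``A_i = P_i * R_i * q`` with ``P_i = clip(P + F_i, 0, 1)``; after
    release the pool recovers toward N over the inter-pulse interval
    dt = 1/stim_freq as ``R <- R_rem + (N - R_rem) (1 - exp(-dt/tau_rec))``.
    Facilitation F gains ``facilitation_increment`` per pulse and decays
    with ``tau_facilitation``.  Multiplicative Gaussian noise of CV
    ``noise_cv`` perturbs the measured amplitudes only; the pool dynamics
    and the GroundTruth released amounts are exact.
    """
    if n_pulses < 1:
        raise ValueError("n_pulses must be >= 1")
    if not stim_freq > 0:
        raise ValueError("stim_freq must be positive")
    dt = 1.0 / stim_freq
    N = float(params.n_vesicles)
    q = params.quantal_amplitude
    R = N
    F = 0.0
    released = np.empty(n_pulses)
    replenished = np.zeros(n_pulses)
    for i in range(n_pulses):
        P_i = min(max(params.release_prob + F, 0.0), 1.0)
        rel = P_i * R
        released[i] = rel * q
        R_rem = R - rel
        recov = (N - R_rem) * (1.0 - np.exp(-dt / params.tau_recovery))
        replenished[i] = recov * q
        R = R_rem + recov
        F = (F + params.facilitation_increment) * np.exp(
            -dt / params.tau_facilitation)

    amplitudes = released.copy()
    if params.noise_cv > 0:
        rng = np.random.default_rng(params.seed)
        amplitudes = np.maximum(
            amplitudes * (1.0 + params.noise_cv * rng.normal(size=n_pulses)),
            0.0)

    train = TrainResponse(amplitudes, stim_freq=stim_freq, unit="pA")
    gt = GroundTruth(params=asdict(params), seed=params.seed,
                     per_pulse_released=released, replenished=replenished)
    return train, gt


def gen_psc_trace(spec: EventTrainSpec) -> tuple[Trace, GroundTruth]:
    """Spontaneous PSC trace: Poisson events x unit-peak kernel + noise.

    Event count is Poisson(rate x duration); event times are uniform over
    the trace; amplitudes are Gaussian around ``amplitude_mean`` with CV
    ``amplitude_cv``, floored at 1 % of the mean so all magnitudes stay
    positive.  The kernel exp(-t/tau_d) - exp(-t/tau_r) is normalised to
    unit peak, so each event's peak excursion equals its amplitude.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.sampling_rate))
    n_events = int(rng.poisson(spec.rate * spec.duration))
    times = np.sort(rng.uniform(0.0, spec.duration, n_events))
    amps = rng.normal(spec.amplitude_mean,
                      spec.amplitude_cv * spec.amplitude_mean, n_events)
    amps = np.maximum(amps, 0.01 * spec.amplitude_mean)

    tau_r = spec.kernel_rise * 1e-3
    tau_d = spec.kernel_decay * 1e-3
    t_k = np.arange(0.0, 8.0 * tau_d, 1.0 / spec.sampling_rate)
    kernel = np.exp(-t_k / tau_d) - np.exp(-t_k / tau_r)
    kernel /= kernel.max()

    x = np.zeros(n)
    for t0, a in zip(times, amps):
        i0 = int(round(t0 * spec.sampling_rate))
        seg = kernel[: max(0, n - i0)]
        x[i0:i0 + seg.size] += a * seg
    if spec.noise_sd > 0:
        x += rng.normal(0.0, spec.noise_sd, n)

    trace = Trace(x, spec.sampling_rate, unit="pA", name="psc",
                  metadata={"kind": "synthetic_psc"})
    gt = GroundTruth(params=asdict(spec), seed=spec.seed,
                     event_times=times, event_amplitudes=amps)
    return trace, gt


def gen_stimulus_response(
    half_max: float,
    max_response: float,
    steepness: float,
    intensities: Sequence[float],
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sigmoidal stimulus–response table.

    Noise-free responses lie exactly on
    ``max_response / (1 + exp(-steepness (V - half_max)))``.
    """
    v = np.asarray(intensities, dtype=float)
    if v.size == 0 or np.any(np.diff(v) <= 0):
        raise ValueError("intensities must be non-empty, strictly increasing")
    r = max_response / (1.0 + np.exp(-steepness * (v - half_max)))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        r = r + rng.normal(0.0, noise_sd, v.size)
    return pd.DataFrame({"intensity": v, "response": r})
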