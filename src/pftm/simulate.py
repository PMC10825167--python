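"""Synthetic pupil sessions and 2AFC data with known ground truth.

No recorded pupil data ships with the package, so a generative observer
model provides test beds with the statistical structure the analysis
exploits:

* the disc's perceived luminance is a square wave alternating between the
  fixed luminance and ``gain * variable`` every half-period, against a
  background matched to the fixed colour;
* the pupil responds sluggishly through a gamma-shaped impulse response
  (shape 8, peak at 0.45 s by default) with constriction for brighter
  stimuli, producing an onset latency, a baseline offset proportional to
  the mean perceived-luminance difference from the background, and an
  oscillation at the tagging frequency whose amplitude grows with the
  perceived fixed-variable difference and whose phase flips by 180
  degrees across the equiluminant point ``variable = fixed/gain``;
* measurement noise is AR(1) Gaussian, strongly autocorrelated like real
  pupil traces.

All randomness flows from an explicit master seed; per-trial seeds are
spawned deterministically from it, so sessions are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal, stats

from .psychophysics import quick_pf
from .types import PupilTrace, QuickParams, SessionConfig, Trial, Unit

__all__ = [
    "ObserverModel",
    "ResponseTable",
    "perceived_drive",
    "simulate_trial",
    "simulate_session",
    "simulate_2afc",
]


@dataclass(frozen=True)
class ObserverModel:
    """Generative observer: perception gain, pupil dynamics and noise.

    Parameters
    ----------
    gain : float
        Perceived-luminance multiplier for the variable colour; the
        observer's equiluminant point is at variable = fixed/gain, giving
        a ground-truth fixed:variable ratio equal to ``gain``.
    baseline_mm : float
        Resting pupil diameter.
    k_dc : float
        Diameter change per cd/m^2 of sustained perceived-luminance
        difference from the background (mm, applied with constriction
        sign: brighter means smaller).
    k_osc : float
        Diameter change per cd/m^2 of the alternating component (mm).
    latency_s : float
        Pure transport delay before the impulse response; together with
        the kernel peak (0.45 s) the visible onset lag is ~0.5-0.7 s.
    kernel_shape, kernel_scale : float
        Gamma impulse-response parameters; the default scale places the
        kernel mode at 0.45 s.
    noise_sd : float
        Stationary SD of the additive AR(1) measurement noise (mm).
    ar1 : float
        Lag-one autocorrelation of the noise, in [0, 1).
    rate : float
        Sampling rate of the simulated tracker, Hz.
    """

    gain: float = 1.0
    baseline_mm: float = 5.0
    k_dc: float = 0.01
    k_osc: float = 0.02
    latency_s: float = 0.15
    kernel_shape: float = 8.0
    kernel_scale: float = 0.45 / 7.0
    noise_sd: float = 0.02
    ar1: float = 0.97
    rate: float = 1000.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.k_osc < 0 or self.k_dc < 0:
            raise ValueError("response gains must be >= 0")
        if self.latency_s < 0:
            raise ValueError("latency must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.ar1 < 1.0):
            raise ValueError("ar1 must lie in [0, 1)")


@dataclass(frozen=True)
class ResponseTable:
    """Per-level 2AFC counts: levels, times chosen, times presented."""

    levels: np.ndarray
    n_chose: np.ndarray
    n_total: np.ndarray

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels, float)
        n_chose = np.asarray(self.n_chose, int)
        n_total = np.asarray(self.n_total, int)
        for name, arr in (("levels", levels), ("n_chose", n_chose), ("n_total", n_total)):
            object.__setattr__(self, name, arr)
        if np.unique(levels).size != levels.size:
            raise ValueError("levels must be distinct")
        if np.any((n_chose < 0) | (n_chose > n_total)):
            raise ValueError("need 0 <= n_chose <= n_total")


def perceived_drive(config: SessionConfig, condition: float,
                    model: ObserverModel, t) -> np.ndarray:
    """Perceived luminance of the display at time(s) ``t``.

    Before disc onset (t < 0) the observer views the background, matched
    to the fixed luminance.  From onset the disc alternates fixed colour
    first, then the variable colour scaled by the observer's gain, every
    half-period.
    """
    t = np.asarray(t, dtype=float)
    fixed = config.fixed_luminance
    variable = model.gain * condition
    # epsilon guards against grid times landing a float ulp below a boundary
    half_index = np.floor(t / config.half_period_s + 1e-9).astype(int)
    on_variable = (half_index % 2) == 1
    drive = np.where(t < 0, fixed, np.where(on_variable, variable, fixed))
    return drive if drive.ndim else float(drive)


def _gamma_kernel(model: ObserverModel, dt: float) -> np.ndarray:
    """Unit-area pupil impulse response (gamma pdf, delayed by latency)."""
    support = model.latency_s + stats.gamma.ppf(0.999, model.kernel_shape,
                                                scale=model.kernel_scale)
    t = np.arange(0.0, support, dt)
    k = stats.gamma.pdf(t - model.latency_s, model.kernel_shape,
                        scale=model.kernel_scale)
    return k * dt  # discrete unit-sum (up to truncation)


def _deterministic_response(config: SessionConfig, condition: float,
                            model: ObserverModel, times: np.ndarray) -> np.ndarray:
    """Noise-free pupil diameter for one condition on ``times``."""
    dt = 1.0 / model.rate
    drive = perceived_drive(config, condition, model, times)
    background = config.fixed_luminance
    mean_level = 0.5 * (config.fixed_luminance + model.gain * condition)
    dc = np.where(times < 0, 0.0, mean_level - background)
    osc = drive - background - dc
    stimulus = model.k_dc * dc + model.k_osc * osc
    kernel = _gamma_kernel(model, dt)
    response = signal.fftconvolve(stimulus, kernel)[: times.size]
    # constriction: brighter perceived stimulus -> smaller diameter
    return model.baseline_mm - response


def _ar1_noise(rng: np.random.Generator, n: int, model: ObserverModel) -> np.ndarray:
    if model.noise_sd == 0:
        return np.zeros(n)
    innov_sd = model.noise_sd * np.sqrt(1.0 - model.ar1 ** 2)
    eps = rng.normal(0.0, innov_sd, size=n)
    x0 = rng.normal(0.0, model.noise_sd)
    noise, _ = signal.lfilter([1.0], [1.0, -model.ar1], eps,
                              zi=np.array([model.ar1 * x0]))
    return noise


def _time_grid(config: SessionConfig, model: ObserverModel,
               prestim_s: float) -> np.ndarray:
    dt = 1.0 / model.rate
    n_pre = int(round(prestim_s * model.rate))
    n_post = int(round(config.trial_duration_s * model.rate))
    return np.arange(-n_pre, n_post) * dt


def simulate_trial(config: SessionConfig, condition: float, model: ObserverModel,
                   seed, trial_id: int = 0, prestim_s: float = 0.5) -> Trial:
    """One synthetic trial: deterministic pupil response plus AR(1) noise."""
    times = _time_grid(config, model, prestim_s)
    clean = _deterministic_response(config, condition, model, times)
    rng = np.random.default_rng(seed)
    values = clean + _ar1_noise(rng, times.size, model)
    trace = PupilTrace(times=times, values=values, rate=model.rate, unit=Unit.MM)
    return Trial(trial_id=trial_id, condition=condition, trace=trace)


def simulate_session(config: SessionConfig, model: ObserverModel, seed,
                     prestim_s: float = 0.5) -> list:
    """A full randomised session: ``repeats`` trials of every level.

    Trial order is fully randomised; each trial draws its noise from a
    child seed spawned deterministically from the master seed, so the
    session is reproducible sample-for-sample.
    """
    times = _time_grid(config, model, prestim_s)
    clean = {lv: _deterministic_response(config, lv, model, times)
             for lv in config.variable_levels}
    schedule = [lv for lv in config.variable_levels for _ in range(config.repeats)]
    master = np.random.SeedSequence(seed)
    order_rng = np.random.default_rng(master.spawn(1)[0])
    order = order_rng.permutation(len(schedule))
    children = master.spawn(len(schedule))
    trials = []
    for trial_id, idx in enumerate(order):
        level = schedule[idx]
        rng = np.random.default_rng(children[idx])
        values = clean[level] + _ar1_noise(rng, times.size, model)
        trace = PupilTrace(times=times, values=values, rate=model.rate,
                           unit=Unit.MM)
        trials.append(Trial(trial_id=trial_id, condition=level, trace=trace))
    return trials


def simulate_2afc(levels: Sequence[float], params: QuickParams,
                  n_per_level: int, seed) -> ResponseTable:
    """Binomial 2AFC responses from a Quick-function observer."""
    if n_per_level < 1:
        raise ValueError("n_per_level must be >= 1")
    levels = np.asarray(levels, dtype=float)
    rng = np.random.default_rng(seed)
    p = quick_pf(levels, params)
    n_chose = rng.binomial(n_per_level, p)
    return ResponseTable(levels=levels, n_chose=n_chose,
                         n_total=np.full(levels.size, n_per_level))
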