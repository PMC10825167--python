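"""Trace conditioning ahead of spectral analysis.

The read-out of interest is a small oscillation riding on a slow pupil
response, so each trial is lightly smoothed (30 ms Gaussian), baseline
corrected (pre-stimulus mean or the mean over the FFT window itself) and
then averaged per luminance condition.  Optional integer-factor
downsampling supports lower-rate eye-trackers; it must not move energy at
the tagging frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .types import PupilTrace, Trial

__all__ = [
    "ConditionAverage",
    "smooth_pupil",
    "gaussian_kernel",
    "baseline_correct",
    "average_trials",
    "downsample",
    "interpolate_gaps",
]


@dataclass(frozen=True)
class ConditionAverage:
    """Across-trial mean trace (and SEM) for one luminance condition."""

    condition: float
    mean_trace: PupilTrace
    sem: np.ndarray
    n: int

    def __post_init__(self) -> None:
        sem = np.asarray(self.sem, float)
        object.__setattr__(self, "sem", sem)
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if sem.shape != self.mean_trace.values.shape:
            raise ValueError("sem must match the mean trace shape")
        if np.any(sem < 0):
            raise ValueError("sem must be >= 0")


def gaussian_kernel(window_ms: float, rate: float) -> np.ndarray:
    """Unit-sum Gaussian smoothing kernel of total width ``window_ms``.

    The kernel is truncated at +/- window_ms/2 and uses sigma = window_ms/5,
    so the window holds +/-2.5 sigma of the Gaussian before renormalisation.
    """
    if window_ms < 0:
        raise ValueError("window_ms must be >= 0")
    half_width_s = window_ms / 2000.0
    n_half = int(np.floor(half_width_s * rate))
    if window_ms == 0 or n_half == 0:
        return np.array([1.0])
    sigma_s = window_ms / 5000.0
    offsets = np.arange(-n_half, n_half + 1) / rate
    kernel = np.exp(-0.5 * (offsets / sigma_s) ** 2)
    return kernel / kernel.sum()


def smooth_pupil(trace: PupilTrace, window_ms: float = 30.0) -> PupilTrace:
    """Gaussian-smooth a trace; time axis and length are unchanged.

    Edges use a shrinking window: the kernel is renormalised over the
    samples actually available, so a constant trace stays exactly constant
    up to the boundaries.
    """
    if trace.values.size == 0:
        raise ValueError("empty trace")
    kernel = gaussian_kernel(window_ms, trace.rate)
    if kernel.size == 1:
        return trace
    num = np.convolve(trace.values, kernel, mode="same")
    den = np.convolve(np.ones_like(trace.values), kernel, mode="same")
    return trace.with_values(num / den)


def baseline_correct(trace: PupilTrace, window: tuple = (-0.1, 0.1)) -> PupilTrace:
    """Subtract the scalar mean of the samples falling inside ``window``.

    With the pre-stimulus window (default (-0.1, 0.1) s around onset) this
    is pre-stimulus baseline correction; passing the FFT analysis window
    gives mean-baseline correction, after which the corrected trace has
    zero mean over that window by construction.
    """
    a, b = window
    if b <= a:
        raise ValueError("baseline window must have positive extent")
    mask = (trace.times >= a) & (trace.times <= b)
    if trace.gaps is not None:
        mask &= ~trace.gaps
    if not mask.any():
        raise ValueError(
            f"baseline window ({a}, {b}) s does not overlap the trace "
            f"support [{trace.times[0]:.3f}, {trace.times[-1]:.3f}] s"
        )
    return trace.with_values(trace.values - trace.values[mask].mean())


def average_trials(trials: Sequence[Trial]) -> ConditionAverage:
    """Pointwise mean and SEM across trials of a single condition.

    All traces must share the same time grid and rate; no resampling is
    attempted.  SEM is SD/sqrt(n) with the n-1 denominator (all-zero when
    n = 1).
    """
    if not trials:
        raise ValueError("no trials to average")
    conditions = {round(t.condition, 12) for t in trials}
    if len(conditions) > 1:
        raise ValueError("average_trials expects trials of a single condition")
    first = trials[0].trace
    for t in trials[1:]:
        tr = t.trace
        if tr.rate != first.rate or tr.times.size != first.times.size or \
                np.max(np.abs(tr.times - first.times)) > 1e-9:
            raise ValueError("trials have mismatched time grids; refusing to resample")
    stack = np.vstack([t.trace.values for t in trials])
    mean = stack.mean(axis=0)
    n = stack.shape[0]
    sem = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return ConditionAverage(condition=trials[0].condition,
                            mean_trace=first.with_values(mean), sem=sem, n=n)


def downsample(trace: PupilTrace, target_hz: float) -> PupilTrace:
    """Anti-alias filter then decimate to an integer divisor of the rate."""
    if target_hz > trace.rate:
        raise ValueError("target_hz must not exceed the current rate")
    factor = trace.rate / target_hz
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"decimation factor {factor:.6g} is not an integer "
            f"({trace.rate} -> {target_hz} Hz)"
        )
    factor = int(round(factor))
    if factor == 1:
        return trace
    # zero-phase FIR anti-alias + decimation; linear-trend padding keeps
    # constants and slow drifts intact at the boundaries
    values = signal.resample_poly(trace.values, 1, factor, padtype="line")
    times = trace.times[::factor][: values.size]
    return PupilTrace(times=times, values=values, rate=target_hz, unit=trace.unit)


def interpolate_gaps(trace: PupilTrace, max_gap_ms: float = 200.0) -> PupilTrace:
    """Fill short flagged gaps (blinks) by linear interpolation.

    Gaps longer than ``max_gap_ms`` make the trial unusable and raise;
    callers should drop such trials.  Traces without a gap mask pass
    through unchanged.
    """
    if trace.gaps is None or not trace.gaps.any():
        return trace
    gaps = trace.gaps
    # contiguous runs of flagged samples
    edges = np.flatnonzero(np.diff(np.concatenate(([0], gaps.view(np.int8), [0]))))
    starts, ends = edges[::2], edges[1::2]
    longest_s = ((ends - starts).max()) / trace.rate
    if longest_s * 1000.0 > max_gap_ms:
        raise ValueError(
            f"gap of {longest_s * 1000:.0f} ms exceeds max_gap_ms={max_gap_ms}; "
            "reject this trial"
        )
    if gaps[0] or gaps[-1]:
        raise ValueError("gap touches the trace boundary; reject this trial")
    values = trace.values.copy()
    good = ~gaps
    values[gaps] = np.interp(trace.times[gaps], trace.times[good], values[good])
    return PupilTrace(times=trace.times, values=values, rate=trace.rate,
                      unit=trace.unit, gaps=None)
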