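"""Shared domain types for the pupil frequency-tagging pipeline.

The pipeline works on stimulus-locked pupil-diameter time series recorded
while a disc alternates between a *fixed* colour/luminance and a *variable*
one at a known tagging frequency.  These dataclasses carry the data and the
session design between the preprocessing, spectral-analysis and estimation
stages; every constructor validates its own invariants so that downstream
code can assume well-formed inputs.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Unit",
    "PupilTrace",
    "Trial",
    "SessionConfig",
    "AnalysisWindow",
    "TaggingResult",
    "EquiluminanceEstimate",
    "QuickParams",
    "CalibrationFactor",
    "ComparisonStats",
    "validate_session",
]

#: Tolerance used when matching a trial's luminance condition against the
#: session's configured levels (conditions are floats, not labels).
CONDITION_TOL = 1e-9


class Unit(str, enum.Enum):
    """Pupil diameter units: raw eye-tracker arbitrary units or millimetres."""

    AU = "au"
    MM = "mm"


@dataclass(frozen=True)
class PupilTrace:
    """A uniformly sampled pupil-diameter series, time-locked to stimulus onset.

    Parameters
    ----------
    times : ndarray
        Sample times in seconds relative to disc onset (fixation samples are
        negative).  Must be strictly increasing on a uniform grid.
    values : ndarray
        Pupil diameter per sample, in ``unit``.
    rate : float
        Samples per second; must equal ``1/dt`` of the time grid.
    unit : Unit
        ``Unit.AU`` for raw tracker units, ``Unit.MM`` after calibration.
    gaps : ndarray of bool, optional
        Per-sample flag marking unusable samples (blinks, track loss).
        Values at flagged samples are carried but should not be trusted.
    """

    times: np.ndarray
    values: np.ndarray
    rate: float
    unit: Unit = Unit.AU
    gaps: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1:
            raise ValueError("times and values must be 1-D")
        if times.size != values.size:
            raise ValueError("times and values must have equal length")
        if times.size < 2:
            raise ValueError("a trace needs at least two samples")
        dts = np.diff(times)
        if np.any(dts <= 0):
            raise ValueError("times must be strictly increasing")
        dt = (times[-1] - times[0]) / (times.size - 1)
        if np.max(np.abs(dts - dt)) > 1e-9:
            raise ValueError("times must lie on a uniform grid (1 ns tolerance)")
        if abs(self.rate * dt - 1.0) > 1e-6:
            raise ValueError(
                f"rate {self.rate} inconsistent with sample spacing {dt:.9g}"
            )
        gaps = self.gaps
        if gaps is not None:
            gaps = np.asarray(gaps, dtype=bool)
            if gaps.shape != values.shape:
                raise ValueError("gaps mask must match values shape")
            object.__setattr__(self, "gaps", gaps)
        finite = np.isfinite(values)
        if gaps is None:
            if not finite.all():
                raise ValueError(
                    "non-finite pupil values present but not flagged as gaps"
                )
        elif not finite[~gaps].all():
            raise ValueError("non-finite pupil values outside flagged gaps")
        if not isinstance(self.unit, Unit):
            object.__setattr__(self, "unit", Unit(self.unit))

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def with_values(self, values: np.ndarray, unit: Optional[Unit] = None) -> "PupilTrace":
        """Return a copy with new sample values (and optionally a new unit)."""
        return replace(self, values=np.asarray(values, float),
                       unit=self.unit if unit is None else unit)


@dataclass(frozen=True)
class Trial:
    """One stimulus presentation: a pupil trace plus its luminance condition."""

    trial_id: int
    condition: float  # variable-colour luminance, cd/m^2
    trace: PupilTrace

    def __post_init__(self) -> None:
        if self.condition < 0:
            raise ValueError("condition luminance must be >= 0 cd/m^2")


@dataclass(frozen=True)
class SessionConfig:
    """Stimulus timing and luminance design of a frequency-tagging session.

    The disc alternates fixed and variable colours every ``half_period_s``
    seconds, so one full tagging period is two half-periods and the tagging
    frequency is its reciprocal (0.283 s half-period -> 1.77 Hz).
    """

    fixed_colour: str
    fixed_luminance: float
    variable_colour: str
    variable_levels: tuple
    half_period_s: float = 0.283
    refresh_hz: float = 120.0
    frames_per_half_period: int = 34
    repeats: int = 5
    trial_duration_s: float = 3.5

    def __post_init__(self) -> None:
        levels = tuple(float(v) for v in self.variable_levels)
        object.__setattr__(self, "variable_levels", levels)
        if self.fixed_luminance <= 0:
            raise ValueError("fixed_luminance must be positive")
        if len(levels) < 1:
            raise ValueError("need at least one variable luminance level")
        if any(v < 0 for v in levels):
            raise ValueError("variable levels must be >= 0")
        if list(levels) != sorted(levels):
            raise ValueError("variable_levels must be sorted ascending")
        if self.half_period_s <= 0:
            raise ValueError("half_period_s must be positive")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.trial_duration_s <= 0:
            raise ValueError("trial_duration_s must be positive")
        frame_time = self.frames_per_half_period / self.refresh_hz
        if abs(frame_time - self.half_period_s) > 1e-3:
            raise ValueError(
                f"frames_per_half_period/refresh_hz = {frame_time:.4f} s "
                f"disagrees with half_period_s = {self.half_period_s} s (>1 ms)"
            )

    @property
    def period_s(self) -> float:
        """Duration of one full fixed+variable alternation cycle."""
        return 2.0 * self.half_period_s

    @property
    def tag_frequency_hz(self) -> float:
        """The tagging frequency: one over the full alternation period."""
        return 1.0 / self.period_s

    def find_level(self, condition: float) -> float:
        """Map a trial's condition onto a configured level (1e-9 tolerance)."""
        for lv in self.variable_levels:
            if abs(lv - condition) <= CONDITION_TOL:
                return lv
        raise KeyError(f"condition {condition} is not a configured level")


@dataclass(frozen=True)
class AnalysisWindow:
    """An FFT analysis window spanning an exact integer number of tag periods."""

    t1: float
    cycles: int
    period_s: float
    t2: float = field(init=False)

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ValueError("cycles must be a positive integer")
        if self.period_s <= 0:
            raise ValueError("period_s must be positive")
        # Endpoints are specified as decimals (e.g. t1=0.3, period 0.567 s);
        # doing the sum in exact decimal arithmetic on the shortest float
        # representations keeps t2 = t1 + cycles*period free of binary
        # round-off (0.3 + 4*0.567 -> exactly 2.568).
        from fractions import Fraction
        t2 = Fraction(repr(float(self.t1))) + self.cycles * Fraction(repr(float(self.period_s)))
        object.__setattr__(self, "t2", float(t2))

    @property
    def duration(self) -> float:
        return self.t2 - self.t1


@dataclass(frozen=True)
class TaggingResult:
    """Amplitude/phase read-out for one luminance condition.

    ``mean_amplitude`` is the 0 Hz (DC) component over the analysis window;
    ``tag_amplitude`` the single-sided amplitude at the tagging frequency and
    ``tag_phase_deg`` its phase (cosine convention, referenced to window
    start), wrapped to (-180, 180].
    """

    condition: float
    mean_amplitude: float
    tag_amplitude: float
    tag_phase_deg: float
    n_trials: int

    def __post_init__(self) -> None:
        if self.mean_amplitude < 0 or self.tag_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        if not (-180.0 < self.tag_phase_deg <= 180.0):
            raise ValueError("phase must lie in (-180, 180] degrees")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass(frozen=True)
class EquiluminanceEstimate:
    """The estimated equiluminant point of a session.

    ``min_luminance`` is the variable luminance minimising the fitted
    amplitude tuning curve; ``ratio`` the fixed:variable luminance ratio at
    that point.  ``phase_transition`` carries (start, midpoint, end) of the
    ~180 deg phase inversion when one was detected, and ``confirmed`` says
    whether its midpoint agrees with the amplitude minimum.
    """

    min_luminance: float
    ratio: float
    phase_transition: Optional[tuple] = None
    confirmed: Optional[bool] = None
    combined_luminance: Optional[float] = None
    raw_argmin_luminance: Optional[float] = None
    boundary: bool = False

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")


@dataclass(frozen=True)
class QuickParams:
    """Parameters of the Quick (Weibull-family) psychometric function.

    ``alpha`` is the threshold level, ``beta`` the slope, ``gamma`` the lower
    asymptote (guess rate) and ``lam`` the lapse rate; the upper asymptote is
    ``1 - lam``.
    """

    alpha: float
    beta: float
    gamma: float = 0.0
    lam: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.gamma < 0 or self.lam < 0:
            raise ValueError("gamma and lam must be >= 0")
        if self.gamma + self.lam >= 1:
            raise ValueError("gamma + lam must be < 1")


@dataclass(frozen=True)
class CalibrationFactor:
    """Eye-tracker arbitrary-unit to millimetre scaling.

    Derived from an artificial pupil of known diameter: recording a
    ``reference_mm`` target yields ``source_units`` in the tracker's area-like
    arbitrary units, so diameters scale as ``scale * sqrt(units)`` with
    ``scale = reference_mm / sqrt(source_units)``.
    """

    scale: float
    source_units: float
    reference_mm: float = 8.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        expected = self.reference_mm / math.sqrt(self.source_units)
        if not math.isclose(self.scale, expected, rel_tol=1e-9):
            raise ValueError("scale inconsistent with reference_mm/sqrt(source_units)")


@dataclass(frozen=True)
class ComparisonStats:
    """Between-method agreement statistics for paired ratio measurements."""

    r: float
    rho: Optional[float] = None
    fisher_z: Optional[float] = None
    p_one_tailed: Optional[float] = None
    ba_mean: Optional[float] = None
    ba_lo: Optional[float] = None
    ba_hi: Optional[float] = None

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")
        if self.rho is not None and abs(self.rho) > 1 + 1e-12:
            raise ValueError("|rho| must be <= 1")
        if self.ba_lo is not None and self.ba_hi is not None:
            if not (self.ba_lo <= self.ba_mean <= self.ba_hi):
                raise ValueError("Bland-Altman limits must bracket the mean")


def validate_session(config: SessionConfig, trials: Sequence[Trial]) -> dict:
    """Group trials by configured luminance level and check the design.

    Returns an ordered mapping ``{level: [Trial, ...]}`` over the configured
    ``variable_levels``.  Raises if any trial's condition is not a configured
    level, if trial ids repeat, or if any level has no trials.
    """
    if not trials:
        raise ValueError("session contains no trials")
    ids = [t.trial_id for t in trials]
    if len(set(ids)) != len(ids):
        raise ValueError("trial_id values must be unique within a session")
    groups: dict = {lv: [] for lv in config.variable_levels}
    for trial in trials:
        level = config.find_level(trial.condition)  # KeyError if unknown
        groups[level].append(trial)
    empty = [lv for lv, g in groups.items() if not g]
    if empty:
        raise ValueError(f"no trials for configured level(s): {empty}")
    return groups
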