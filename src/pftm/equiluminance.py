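"""Equiluminant-point estimation from the amplitude tuning curve.

The tagging-frequency amplitude, plotted against the variable luminance,
forms a V-shaped tuning curve whose minimum marks the luminance at which
the variable colour is perceptually matched to the fixed one.  A cubic
smoothing spline (smoothing level chosen by generalised cross-validation)
is fitted to the curve and its minimum located by dense grid search inside
the tested range — no extrapolation.  The ~180 degree inversion of the
oscillation phase across the same point provides an independent
confirmation: the estimate is flagged ``confirmed`` when the phase-
transition midpoint falls within a tolerance (default: one luminance step)
of the spline minimum.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import make_smoothing_spline
from sklearn.base import BaseEstimator, RegressorMixin

from .types import EquiluminanceEstimate, SessionConfig, TaggingResult

__all__ = [
    "EquiluminanceEstimator",
    "fit_minimum",
    "detect_phase_transition",
    "estimate_equiluminance",
    "ratio",
]


def ratio(fixed_luminance: float, min_luminance: float) -> float:
    """Fixed:variable luminance ratio at the equiluminant point."""
    if fixed_luminance <= 0 or min_luminance <= 0:
        raise ValueError("luminances must be positive")
    return fixed_luminance / min_luminance


class EquiluminanceEstimator(RegressorMixin, BaseEstimator):
    """Smoothing-spline fit of the amplitude tuning curve and its minimum.

    Parameters
    ----------
    fixed_luminance : float, optional
        Luminance of the fixed colour (cd/m^2).  When given, the fitted
        ``ratio_`` = fixed_luminance / min_luminance_ is exposed.
    lam : float, optional
        Smoothing-spline regularisation weight.  ``None`` (default) selects
        it by generalised cross-validation.
    grid_points : int
        Size of the dense search grid for the minimum (>= 1000).
    phase_tolerance : float, optional
        Maximum |spline minimum - phase midpoint| (cd/m^2) for the phase
        transition to confirm the minimum.  ``None`` uses one luminance
        step of the fitted levels.

    Attributes
    ----------
    min_luminance_ : float
        Location of the spline minimum within the tested range.
    boundary_ : bool
        True when the minimum sits on an edge of the tested range
        (unbracketed; the session design should be re-centred).
    ratio_ : float
        fixed_luminance / min_luminance_ (only with ``fixed_luminance``).
    phase_transition_ : tuple or None
        (start, midpoint, end) luminances of the phase inversion, when
        phases were supplied and an inversion was found.
    confirmed_ : bool or None
        Whether the phase midpoint agrees with the amplitude minimum.
    combined_luminance_ : float or None
        Unweighted mean of spline minimum and phase midpoint.

    Examples
    --------
    >>> est = EquiluminanceEstimator(fixed_luminance=20.0)
    >>> levels = np.linspace(10, 40, 11)
    >>> est.fit(levels, np.abs(levels - 25.0) + 0.1)
    EquiluminanceEstimator(fixed_luminance=20.0)
    >>> round(est.ratio_, 2)
    0.8
    """

    def __init__(self, fixed_luminance: Optional[float] = None,
                 lam: Optional[float] = None, grid_points: int = 2001,
                 phase_tolerance: Optional[float] = None):
        self.fixed_luminance = fixed_luminance
        self.lam = lam
        self.grid_points = grid_points
        self.phase_tolerance = phase_tolerance

    def fit(self, X, y, phases_deg=None):
        """Fit the tuning curve.

        Parameters
        ----------
        X : array-like of shape (n_levels,) or (n_levels, 1)
            Tested variable luminances, cd/m^2.
        y : array-like of shape (n_levels,)
            Tagging-frequency amplitude per level (any common scale).
        phases_deg : array-like, optional
            Tagging-frequency phase per level, degrees; enables the
            phase-transition confirmation.
        """
        levels = np.asarray(X, dtype=float)
        if levels.ndim == 2 and levels.shape[1] == 1:
            levels = levels[:, 0]
        amps = np.asarray(y, dtype=float)
        if levels.ndim != 1 or levels.shape != amps.shape:
            raise ValueError("X and y must be 1-D arrays of equal length")
        if np.unique(levels).size < 4:
            raise ValueError("need at least 4 distinct luminance levels")
        if not np.all(np.isfinite(levels)) or not np.all(np.isfinite(amps)):
            raise ValueError("levels and amplitudes must be finite")
        if np.any(amps < 0):
            raise ValueError("amplitudes must be >= 0")
        if self.grid_points < 1000:
            raise ValueError("grid_points must be >= 1000")

        order = np.argsort(levels)
        levels, amps = levels[order], amps[order]
        self.spline_ = make_smoothing_spline(levels, amps, lam=self.lam)
        grid = np.linspace(levels[0], levels[-1], self.grid_points)
        fitted = self.spline_(grid)
        imin = int(np.argmin(fitted))
        self.levels_ = levels
        self.grid_ = grid
        self.fitted_ = fitted
        self.min_luminance_ = float(grid[imin])
        self.min_amplitude_ = float(fitted[imin])
        self.boundary_ = imin in (0, self.grid_points - 1)
        self.raw_argmin_luminance_ = float(levels[int(np.argmin(amps))])

        self.phase_transition_ = None
        self.confirmed_ = None
        self.combined_luminance_ = None
        if phases_deg is not None:
            phases = np.asarray(phases_deg, dtype=float)[order]
            self.phase_transition_ = detect_phase_transition(levels, phases)
            if self.phase_transition_ is not None:
                midpoint = self.phase_transition_[1]
                tol = self.phase_tolerance
                if tol is None:
                    tol = float(np.median(np.diff(levels)))
                self.confirmed_ = bool(abs(self.min_luminance_ - midpoint) <= tol)
                self.combined_luminance_ = 0.5 * (self.min_luminance_ + midpoint)
        if self.fixed_luminance is not None:
            self.ratio_ = ratio(self.fixed_luminance, self.min_luminance_)
        return self

    def predict(self, X):
        """Evaluate the fitted tuning curve at luminances ``X``."""
        if not hasattr(self, "spline_"):
            raise AttributeError("estimator is not fitted yet")
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        return self.spline_(x)

    def to_estimate(self) -> EquiluminanceEstimate:
        """Bundle the fitted attributes into an EquiluminanceEstimate."""
        if not hasattr(self, "ratio_"):
            raise AttributeError("fit with fixed_luminance set to build an estimate")
        return EquiluminanceEstimate(
            min_luminance=self.min_luminance_,
            ratio=self.ratio_,
            phase_transition=self.phase_transition_,
            confirmed=self.confirmed_,
            combined_luminance=self.combined_luminance_,
            raw_argmin_luminance=self.raw_argmin_luminance_,
            boundary=self.boundary_,
        )


def fit_minimum(levels: Sequence[float], amplitudes: Sequence[float],
                lam: Optional[float] = None,
                grid_points: int = 2001) -> Tuple[float, np.ndarray, np.ndarray, bool]:
    """Spline-fit the tuning curve and locate its minimum.

    Returns ``(min_luminance, grid, fitted, boundary)`` where ``boundary``
    flags a minimum on the edge of the tested range.
    """
    est = EquiluminanceEstimator(lam=lam, grid_points=grid_points)
    est.fit(np.asarray(levels, float), np.asarray(amplitudes, float))
    return est.min_luminance_, est.grid_, est.fitted_, est.boundary_


def detect_phase_transition(levels: Sequence[float], phases_deg: Sequence[float],
                            plateau_tol_deg: float = 20.0) -> Optional[Tuple[float, float, float]]:
    """Locate the ~180 degree phase inversion across the equiluminant point.

    The phase is unwrapped over the sorted levels; the low/high plateaus
    are the medians over the first/last quartile of levels.  The
    transition starts at the last level still within ``plateau_tol_deg``
    of the departing plateau and ends at the first level within tolerance
    of the arriving plateau; the midpoint interpolates the level at which
    the unwrapped phase crosses the mean of the two plateaus.

    Returns ``None`` when the total plateau-to-plateau excursion is below
    90 degrees (no inversion present).
    """
    levels = np.asarray(levels, dtype=float)
    phases = np.asarray(phases_deg, dtype=float)
    if levels.ndim != 1 or levels.shape != phases.shape:
        raise ValueError("levels and phases must be 1-D of equal length")
    n = levels.size
    if n < 4:
        raise ValueError("need at least 4 levels to detect a transition")
    order = np.argsort(levels)
    levels, phases = levels[order], phases[order]
    unwrapped = np.unwrap(phases, period=360.0)
    q = max(1, n // 4)
    lo = float(np.median(unwrapped[:q]))
    hi = float(np.median(unwrapped[-q:]))
    if abs(hi - lo) < 90.0:
        return None
    mid_value = 0.5 * (lo + hi)
    resid = unwrapped - mid_value
    cross = None
    for i in range(n - 1):
        if resid[i] == 0.0:
            cross = float(levels[i])
            break
        if resid[i] * resid[i + 1] < 0:
            frac = resid[i] / (resid[i] - resid[i + 1])
            cross = float(levels[i] + frac * (levels[i + 1] - levels[i]))
            break
    if cross is None:
        cross = float(levels[-1]) if resid[-1] == 0 else float(levels[n // 2])
    at_lo = np.abs(unwrapped - lo) <= plateau_tol_deg
    at_hi = np.abs(unwrapped - hi) <= plateau_tol_deg
    before = np.flatnonzero(at_lo & (levels <= cross))
    after = np.flatnonzero(at_hi & (levels >= cross))
    start = float(levels[before[-1]]) if before.size else float(levels[0])
    end = float(levels[after[0]]) if after.size else float(levels[-1])
    return (start, cross, end)


def estimate_equiluminance(results: Sequence[TaggingResult], config: SessionConfig,
                           phase_tolerance: Optional[float] = None,
                           lam: Optional[float] = None) -> EquiluminanceEstimate:
    """Full equiluminance estimate from a session's tagging table."""
    if len(results) < 4:
        raise ValueError("need results for at least 4 conditions")
    levels = np.array([r.condition for r in results], float)
    amps = np.array([r.tag_amplitude for r in results], float)
    phases = np.array([r.tag_phase_deg for r in results], float)
    est = EquiluminanceEstimator(fixed_luminance=config.fixed_luminance,
                                 lam=lam, phase_tolerance=phase_tolerance)
    est.fit(levels, amps, phases_deg=phases)
    return est.to_estimate()
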