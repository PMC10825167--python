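"""Arbitrary-unit to millimetre pupil calibration.

Video eye-trackers report pupil size in arbitrary units that scale with
image area.  Recording an artificial pupil of known physical diameter
(default 8 mm) at the subject's eye position gives a scaling factor

    theta = reference_mm / sqrt(units)

after which any recorded value maps to a diameter ``theta * sqrt(value)``.
The square root reflects area-mode tracking, where the reported unit grows
with the pupil's image area rather than its diameter.

Calibration is optional for equiluminance estimation: the location of the
amplitude minimum is invariant to an overall scale, so the pipeline runs
unchanged on raw arbitrary units.
"""

from __future__ import annotations

import math

import numpy as np

from .types import CalibrationFactor, PupilTrace, Unit

__all__ = ["compute_scale_factor", "apply_calibration"]


def compute_scale_factor(artificial_units: float, reference_mm: float = 8.0) -> CalibrationFactor:
    """Scaling factor from an artificial-pupil recording.

    Parameters
    ----------
    artificial_units : float
        Arbitrary-unit value the tracker reported for the artificial pupil.
    reference_mm : float
        Physical diameter of the artificial pupil target, millimetres.
    """
    if artificial_units <= 0:
        raise ValueError("artificial_units must be positive")
    if reference_mm <= 0:
        raise ValueError("reference_mm must be positive")
    scale = reference_mm / math.sqrt(artificial_units)
    return CalibrationFactor(scale=scale, source_units=float(artificial_units),
                             reference_mm=float(reference_mm))


def apply_calibration(trace: PupilTrace, factor: CalibrationFactor) -> PupilTrace:
    """Convert a raw arbitrary-unit trace to millimetres (theta * sqrt(value))."""
    if trace.unit is not Unit.AU:
        raise ValueError("trace is already calibrated (unit is not 'au')")
    values = np.asarray(trace.values, float)
    valid = values if trace.gaps is None else values[~trace.gaps]
    if np.any(valid < 0):
        raise ValueError("raw pupil values must be >= 0 for sqrt calibration")
    with np.errstate(invalid="ignore"):
        mm = factor.scale * np.sqrt(values)
    return trace.with_values(mm, unit=Unit.MM)
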