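"""Amplitude and phase extraction at the tagging frequency.

Because the stimulus alternates at a known frequency, the pupil read-out
is a single DFT bin.  The analysis window must span an exact integer
number of tagging periods so that the tagging frequency falls exactly on
a bin and no taper is needed: with window length rho * period the bin
index of the tag frequency is exactly rho and spectral leakage at that
bin vanishes for on-bin components.

Conventions: single-sided amplitude (a pure sinusoid of amplitude A
yields A at its bin, i.e. 2|X_k|/N for k > 0 and |X_0|/N at DC), phase in
degrees with the cosine convention referenced to the window start, and
samples taken from the half-open interval [t1, t2) so that N equals
rho * period * rate exactly on a uniform grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .preprocess import ConditionAverage
from .types import AnalysisWindow, PupilTrace, SessionConfig, TaggingResult

__all__ = [
    "Spectrum",
    "analysis_window",
    "default_t1",
    "fft_component",
    "spectrum",
    "tag_table",
    "normalise_amplitudes",
]


@dataclass(frozen=True)
class Spectrum:
    """Single-sided amplitude spectrum over 0..fmax for one condition."""

    freqs: np.ndarray
    amplitudes: np.ndarray
    phases_deg: np.ndarray

    def __post_init__(self) -> None:
        if self.freqs[0] != 0.0:
            raise ValueError("spectrum must start at 0 Hz")
        if not (self.freqs.shape == self.amplitudes.shape == self.phases_deg.shape):
            raise ValueError("freqs/amplitudes/phases must share a shape")


def analysis_window(t1: float, period_s: float, cycles: int) -> AnalysisWindow:
    """Window starting at ``t1`` spanning ``cycles`` tagging periods.

    t2 = t1 + cycles * period_s; e.g. t1=0.3, period 0.567 s, 4 cycles
    gives t2 = 2.568 s.
    """
    return AnalysisWindow(t1=t1, cycles=int(cycles), period_s=period_s)


def default_t1(config: SessionConfig, settle_s: float = 1.0) -> float:
    """First colour-reversal boundary at or after ``settle_s`` post-onset.

    The pupil response lags the stimulus by roughly half a second, so the
    first second after disc onset is excluded by default; starting on a
    reversal boundary keeps the phase origin aligned with the stimulus.
    """
    k = int(np.ceil(settle_s / config.half_period_s - 1e-9))
    return k * config.half_period_s


def _window_slice(trace: PupilTrace, window: AnalysisWindow) -> np.ndarray:
    """Samples of ``trace`` in [t1, t2), validated against the support."""
    dt = trace.dt
    n = int(round(window.duration * trace.rate))
    if n < 1:
        raise ValueError("analysis window shorter than one sample")
    i1 = int(np.searchsorted(trace.times, window.t1 - 0.5 * dt))
    if i1 >= trace.times.size or trace.times[i1] - window.t1 > 0.5 * dt:
        raise ValueError("window start t1 lies outside the trace support")
    if i1 + n > trace.times.size:
        raise ValueError(
            f"window [{window.t1}, {window.t2}) s exceeds the trace "
            f"(ends at {trace.times[-1]:.3f} s)"
        )
    return trace.values[i1:i1 + n]


def fft_component(trace: PupilTrace, window: AnalysisWindow,
                  freq: float) -> Tuple[float, float]:
    """Single-sided amplitude and phase (degrees) at one on-bin frequency.

    ``freq`` must fall on a DFT bin of the window, i.e. (t2-t1)*freq must
    be an integer to within 1e-6; the integer-cycle window guarantees this
    for the tagging frequency and all its harmonics.
    """
    x = _window_slice(trace, window)
    n = x.size
    k_float = window.duration * freq
    k = int(round(k_float))
    if abs(k_float - k) > 1e-6:
        raise ValueError(
            f"frequency {freq} Hz is off-bin for a {window.duration:.6g} s "
            f"window (bin index {k_float:.6g})"
        )
    if k < 0 or k > n // 2:
        raise ValueError("frequency outside the representable band")
    coef = np.fft.rfft(x)[k]
    if k == 0:
        amplitude = abs(coef) / n
    else:
        amplitude = 2.0 * abs(coef) / n
    phase = float(np.degrees(np.angle(coef)))
    if phase <= -180.0:
        phase += 360.0
    return float(amplitude), phase


def spectrum(trace: PupilTrace, window: AnalysisWindow, fmax: float) -> Spectrum:
    """All on-grid bins from 0 Hz up to ``fmax`` (inclusive)."""
    if fmax > trace.rate / 2:
        raise ValueError("fmax exceeds the Nyquist frequency")
    x = _window_slice(trace, window)
    n = x.size
    coefs = np.fft.rfft(x)
    freqs = np.arange(coefs.size) / window.duration
    keep = freqs <= fmax + 1e-12
    coefs, freqs = coefs[keep], freqs[keep]
    amplitudes = 2.0 * np.abs(coefs) / n
    amplitudes[0] = np.abs(coefs[0]) / n
    phases = np.degrees(np.angle(coefs))
    phases[phases <= -180.0] += 360.0
    return Spectrum(freqs=freqs, amplitudes=amplitudes, phases_deg=phases)


def tag_table(averages: Sequence[ConditionAverage], config: SessionConfig,
              window: AnalysisWindow) -> list:
    """Mean (0 Hz) and tagging-frequency amplitude/phase per condition."""
    results = []
    for avg in averages:
        mean_amp, _ = fft_component(avg.mean_trace, window, 0.0)
        tag_amp, tag_phase = fft_component(avg.mean_trace, window,
                                           config.tag_frequency_hz)
        results.append(TaggingResult(condition=avg.condition,
                                     mean_amplitude=mean_amp,
                                     tag_amplitude=tag_amp,
                                     tag_phase_deg=tag_phase,
                                     n_trials=avg.n))
    return results


def normalise_amplitudes(results: Sequence[TaggingResult]) -> np.ndarray:
    """Tag amplitudes scaled so the largest condition maps to 1."""
    amps = np.array([r.tag_amplitude for r in results], float)
    peak = amps.max() if amps.size else 0.0
    if peak <= 0:
        raise ValueError("cannot normalise: all tag amplitudes are zero")
    return amps / peak
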