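"""End-to-end session analysis: trials in, equiluminance estimate out."""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

from .equiluminance import estimate_equiluminance
from .preprocess import average_trials, baseline_correct, interpolate_gaps, smooth_pupil
from .tagging import analysis_window, default_t1, tag_table
from .types import (AnalysisWindow, EquiluminanceEstimate, SessionConfig,
                    Trial, validate_session)

__all__ = ["analyze_session"]


def analyze_session(config: SessionConfig, trials: Sequence[Trial],
                    t1: Optional[float] = None, cycles: int = 4,
                    baseline: str = "window_mean", smooth_ms: float = 30.0,
                    phase_tolerance: Optional[float] = None,
                    lam: Optional[float] = None,
                    max_gap_ms: float = 200.0,
                    ) -> Tuple[list, EquiluminanceEstimate, AnalysisWindow]:
    """Run the full frequency-tagging analysis on one session.

    Each trial is smoothed (30 ms Gaussian), baseline corrected and the
    trials of each luminance condition averaged; the mean (0 Hz) and
    tagging-frequency amplitude/phase are extracted over a window of
    ``cycles`` exact tagging periods starting at ``t1`` (default: the
    first colour-reversal boundary at or after 1 s post-onset), and the
    equiluminant point estimated from the resulting tuning curve.

    Parameters
    ----------
    baseline : {"window_mean", "prestim"}
        Mean over the FFT window itself, or over (-0.1, +0.1) s around
        stimulus onset.
    max_gap_ms : float
        Trials whose flagged gaps exceed this are dropped; shorter gaps
        are linearly interpolated.

    Returns
    -------
    (results, estimate, window)
        Per-condition tagging results, the equiluminance estimate, and
        the analysis window used.
    """
    if baseline not in ("window_mean", "prestim"):
        raise ValueError("baseline must be 'window_mean' or 'prestim'")
    window = analysis_window(default_t1(config) if t1 is None else t1,
                             config.period_s, cycles)
    bl_window = (window.t1, window.t2) if baseline == "window_mean" else (-0.1, 0.1)

    kept = []
    for trial in trials:
        try:
            trace = interpolate_gaps(trial.trace, max_gap_ms=max_gap_ms)
        except ValueError:
            continue  # gap too long: reject the trial
        trace = smooth_pupil(trace, window_ms=smooth_ms)
        trace = baseline_correct(trace, window=bl_window)
        kept.append(Trial(trial.trial_id, trial.condition, trace))
    groups = validate_session(config, kept)
    averages = [average_trials(g) for g in groups.values()]
    results = tag_table(averages, config, window)
    estimate = estimate_equiluminance(results, config,
                                      phase_tolerance=phase_tolerance, lam=lam)
    return results, estimate, window
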