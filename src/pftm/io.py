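"""Tabular I/O: sample CSVs, session configs, result tables.

CSV (UTF-8, '.' decimal) is the single interchange dialect; times are
seconds as decimals so that traces stay self-describing across sampling
rates.  Numbers are written with 9 significant digits, which round-trips
the analysis outputs bit-identically as decimal text for practical
purposes.
"""

from __future__ import annotations

import json
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .simulate import ResponseTable
from .types import (EquiluminanceEstimate, PupilTrace, SessionConfig,
                    TaggingResult, Trial, Unit)

__all__ = [
    "read_samples",
    "write_samples",
    "read_config",
    "write_results",
    "read_results",
    "read_responses",
    "read_ratios",
]

_SAMPLE_COLUMNS = ("trial_id", "condition", "time_s", "pupil")

_CONFIG_KEYS = {
    "fixed_colour", "fixed_luminance", "variable_colour", "variable_levels",
    "half_period_s", "refresh_hz", "frames_per_half_period", "repeats",
    "trial_duration_s",
}


def read_samples(path, unit: str = "mm", rate_tolerance: float = 1e-6) -> list:
    """Read per-sample trial rows into Trials.

    The file must have columns ``trial_id, condition, time_s, pupil`` and
    may carry an optional 0/1 ``blink`` column flagging gap samples.  Rows
    may appear in any order; they are sorted per trial on read.  Each
    trial's time grid must be uniform (rate inferred from the median
    spacing).
    """
    df = pd.read_csv(path)
    missing = [c for c in _SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"samples file is missing column(s): {', '.join(missing)}")
    unit = Unit(unit)
    trials = []
    for trial_id, group in df.groupby("trial_id", sort=True):
        group = group.sort_values("time_s")
        times = group["time_s"].to_numpy(float)
        values = group["pupil"].to_numpy(float)
        conditions = group["condition"].to_numpy(float)
        if np.ptp(conditions) > 1e-9:
            raise ValueError(f"trial {trial_id} has inconsistent condition labels")
        gaps = None
        if "blink" in group.columns:
            blink = group["blink"].to_numpy(float)
            if blink.any():
                gaps = blink > 0.5
        dt = float(np.median(np.diff(times)))
        rate = 1.0 / dt
        trace = PupilTrace(times=times, values=values, rate=rate, unit=unit,
                           gaps=gaps)
        trials.append(Trial(trial_id=int(trial_id), condition=float(conditions[0]),
                            trace=trace))
    if not trials:
        raise ValueError("samples file contains no trials")
    return trials


def write_samples(trials: Sequence[Trial], path) -> None:
    """Write Trials in the dialect ``read_samples`` reads."""
    frames = []
    for t in trials:
        frame = pd.DataFrame({
            "trial_id": t.trial_id,
            "condition": t.condition,
            "time_s": t.trace.times,
            "pupil": t.trace.values,
        })
        if t.trace.gaps is not None:
            frame["blink"] = t.trace.gaps.astype(int)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.9g")


def read_config(path) -> SessionConfig:
    """Read a session configuration from a YAML key-value file.

    Derived quantities (period, tagging frequency) are always computed
    from the primary fields, never read; unknown keys are an error so
    that typos do not silently fall back to defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("config file must be a key-value mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    required = {"fixed_colour", "fixed_luminance", "variable_colour",
                "variable_levels"}
    missing = required - set(raw)
    if missing:
        raise ValueError(f"config missing key(s): {', '.join(sorted(missing))}")
    return SessionConfig(**raw)


def _estimate_dict(estimate: EquiluminanceEstimate) -> dict:
    pt = estimate.phase_transition
    return {
        "min_luminance": estimate.min_luminance,
        "ratio": estimate.ratio,
        "phase_start": None if pt is None else pt[0],
        "phase_midpoint": None if pt is None else pt[1],
        "phase_end": None if pt is None else pt[2],
        "confirmed": estimate.confirmed,
        "combined_luminance": estimate.combined_luminance,
        "raw_argmin_luminance": estimate.raw_argmin_luminance,
        "boundary": estimate.boundary,
    }


def write_results(results: Sequence[TaggingResult],
                  estimate: Optional[EquiluminanceEstimate],
                  csv_path, json_path=None) -> None:
    """Write the tagging table as CSV and the estimate as JSON.

    Optional estimate fields are written as JSON ``null``, never omitted,
    so the schema is stable across sessions.
    """
    df = pd.DataFrame([{
        "condition": r.condition,
        "mean_amplitude": r.mean_amplitude,
        "tag_amplitude": r.tag_amplitude,
        "tag_phase_deg": r.tag_phase_deg,
        "n_trials": r.n_trials,
    } for r in results], columns=["condition", "mean_amplitude", "tag_amplitude",
                                  "tag_phase_deg", "n_trials"])
    df.to_csv(csv_path, index=False, float_format="%.9g")
    if json_path is not None:
        if estimate is None:
            raise ValueError("no estimate to write")
        payload = {k: (float(f"{float(v):.9g}") if isinstance(v, float) else v)
                   for k, v in _estimate_dict(estimate).items()}
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


def read_results(csv_path) -> list:
    """Read back a tagging-results CSV written by ``write_results``."""
    df = pd.read_csv(csv_path)
    return [TaggingResult(condition=row.condition,
                          mean_amplitude=row.mean_amplitude,
                          tag_amplitude=row.tag_amplitude,
                          tag_phase_deg=row.tag_phase_deg,
                          n_trials=int(row.n_trials))
            for row in df.itertuples()]


def read_responses(path) -> ResponseTable:
    """Read a 2AFC response CSV with columns level, n_chose, n_total."""
    df = pd.read_csv(path)
    missing = [c for c in ("level", "n_chose", "n_total") if c not in df.columns]
    if missing:
        raise ValueError(f"responses file is missing column(s): {', '.join(missing)}")
    return ResponseTable(levels=df["level"].to_numpy(float),
                         n_chose=df["n_chose"].to_numpy(int),
                         n_total=df["n_total"].to_numpy(int))


def read_ratios(path) -> pd.DataFrame:
    """Read a long-format ratios CSV (participant, method, ratio) to wide."""
    df = pd.read_csv(path)
    missing = [c for c in ("participant", "method", "ratio") if c not in df.columns]
    if missing:
        raise ValueError(f"ratios file is missing column(s): {', '.join(missing)}")
    return df.pivot(index="participant", columns="method", values="ratio")
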