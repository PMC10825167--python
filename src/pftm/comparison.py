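"""Between-method agreement statistics.

Given per-participant equiluminance ratios from two or more methods
(e.g. minimum flicker, minimum motion, pupil frequency tagging), these
helpers compute the usual method-comparison battery: Pearson and Spearman
(midrank) correlations with the Fisher-z effect size and a one-tailed p
from the t approximation on n-2 degrees of freedom, and Bland-Altman
limits of agreement with confidence intervals on the mean difference and
on the limits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import ComparisonStats

__all__ = [
    "pearson",
    "spearman",
    "fisher_z",
    "bland_altman",
    "BlandAltman",
    "summarise_ratios",
    "correlation_matrix",
]


def fisher_z(r: float) -> float:
    """Fisher z transform (arctanh) of a correlation coefficient."""
    if abs(r) >= 1.0:
        raise ValueError("Fisher z is undefined at |r| = 1")
    return float(np.arctanh(r))


def _one_tailed_p(r: float, n: int) -> float:
    """Upper-tail p for a positive association via t = r*sqrt(n-2)/sqrt(1-r^2)."""
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(stats.t.sf(t, df=n - 2))


def _check_pair(x, y, min_n: int = 3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("inputs must be paired 1-D arrays of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} pairs")
    return x, y


def pearson(x: Sequence[float], y: Sequence[float],
            one_tailed: bool = True) -> ComparisonStats:
    """Pearson r with Fisher-z effect size and (one-tailed) p value."""
    x, y = _check_pair(x, y)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    if abs(r) >= 1.0:
        return ComparisonStats(r=r, fisher_z=float("inf") * np.sign(r),
                               p_one_tailed=0.0 if r > 0 else 1.0)
    p = _one_tailed_p(r, n)
    if not one_tailed:
        p = 2.0 * min(p, 1.0 - p)
    return ComparisonStats(r=r, fisher_z=fisher_z(r), p_one_tailed=p)


def spearman(x: Sequence[float], y: Sequence[float],
             one_tailed: bool = True) -> ComparisonStats:
    """Spearman rho (Pearson correlation of midranks) with z and p."""
    x, y = _check_pair(x, y)
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("correlation undefined for constant ranks")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if abs(rho) >= 1.0:
        return ComparisonStats(r=rho, rho=rho,
                               fisher_z=float("inf") * np.sign(rho),
                               p_one_tailed=0.0 if rho > 0 else 1.0)
    p = _one_tailed_p(rho, n)
    if not one_tailed:
        p = 2.0 * min(p, 1.0 - p)
    return ComparisonStats(r=rho, rho=rho, fisher_z=fisher_z(rho), p_one_tailed=p)


@dataclass(frozen=True)
class BlandAltman:
    """Bland-Altman agreement summary for differences ``second - first``."""

    mean_diff: float
    lo: float
    hi: float
    sd: float
    n: int
    mean_ci: tuple
    lo_ci: tuple
    hi_ci: tuple


def bland_altman(first: Sequence[float], second: Sequence[float]) -> BlandAltman:
    """Limits of agreement between two paired methods.

    Differences are taken ``second - first``; the limits are the mean
    difference -/+ 1.96 SD (n-1 denominator).  The CI half-width is
    t(0.975, n-1) * SD/sqrt(n) for the mean and t(0.975, n-1) *
    SD * sqrt(3/n) for each limit.
    """
    x, y = _check_pair(first, second, min_n=2)
    d = y - x
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    lo = mean - 1.96 * sd
    hi = mean + 1.96 * sd
    tcrit = float(stats.t.ppf(0.975, df=n - 1))
    hw_mean = tcrit * sd / np.sqrt(n)
    hw_loa = tcrit * sd * np.sqrt(3.0 / n)
    return BlandAltman(mean_diff=mean, lo=lo, hi=hi, sd=sd, n=n,
                       mean_ci=(mean - hw_mean, mean + hw_mean),
                       lo_ci=(lo - hw_loa, lo + hw_loa),
                       hi_ci=(hi - hw_loa, hi + hw_loa))


def summarise_ratios(table: pd.DataFrame) -> pd.DataFrame:
    """Per-method mean +/- SEM of a participant x method ratio table."""
    if table.isna().any().any():
        raise ValueError("ratio table has missing cells")
    mean = table.mean(axis=0)
    n = table.shape[0]
    sem = table.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else mean * 0.0
    return pd.DataFrame({"mean": mean, "sem": sem})


def correlation_matrix(table: pd.DataFrame, kind: str = "pearson") -> pd.DataFrame:
    """Pairwise correlation matrix over the methods (columns) of a table."""
    if kind not in ("pearson", "spearman"):
        raise ValueError("kind must be 'pearson' or 'spearman'")
    fn = pearson if kind == "pearson" else spearman
    cols = list(table.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if i < j:
                r = fn(table[a].to_numpy(), table[b].to_numpy()).r
                out.loc[a, b] = out.loc[b, a] = r
    return out
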