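"""Psychometric estimators for the companion subjective tasks.

Two traditional equiluminance measurements accompany the pupil method:

* minimum motion — a 2AFC direction task whose proportion-rightward curve
  crosses 50% at the perceptual null; fitted with the Quick function

      p(x) = gamma + (1 - gamma - lambda) * (1 - 2**(-(x/alpha)**beta))

  by binomial maximum likelihood.  With symmetric asymptotes the point of
  subjective equality (PSE) equals the threshold alpha.
* minimum flicker — a matching task; each repeat records the variable
  luminance at which perceived flicker is minimal, summarised as the mean
  and SD of the fixed:match ratio.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from .types import QuickParams

__all__ = [
    "QuickPsychometric",
    "quick_pf",
    "fit_quick_mle",
    "pse",
    "flicker_summary",
]

_BETA_STARTS = (1.0, 2.0, 4.0, 8.0)
_BETA_CEILING = 64.0  # slopes at/above this are treated as step-like (separation)


def quick_pf(x, params: QuickParams):
    """Quick psychometric function evaluated at stimulus level(s) ``x``."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("stimulus level must be >= 0")
    with np.errstate(over="ignore"):  # (x/alpha)^beta -> inf maps cleanly to p=1
        core = 1.0 - np.power(2.0, -np.power(x / params.alpha, params.beta))
    out = params.gamma + (1.0 - params.gamma - params.lam) * core
    return float(out) if out.ndim == 0 else out


def pse(params: QuickParams) -> float:
    """Stimulus level at which the Quick function crosses 50%.

    Requires 0.5 to lie strictly between the asymptotes gamma and
    1 - lambda; with gamma = lambda = 0 (or symmetric asymptotes) the PSE
    equals alpha in closed form.
    """
    if not (params.gamma < 0.5 < 1.0 - params.lam):
        raise ValueError("0.5 is outside the asymptote range (gamma, 1-lambda)")
    q = (0.5 - params.gamma) / (1.0 - params.gamma - params.lam)
    u = -np.log2(1.0 - q)
    return float(params.alpha * u ** (1.0 / params.beta))


class QuickPsychometric(BaseEstimator):
    """Binomial MLE fit of the Quick function to 2AFC response counts.

    The guess and lapse rates are fixed (defaults 0, 0: a direction task
    coded as proportion rightward runs the full 0..1 range); alpha and
    beta are free.  The likelihood surface can hold local optima in beta,
    so optimisation restarts from a log-spaced alpha grid crossed with
    beta in {1, 2, 4, 8} and keeps the best converged fit.

    Attributes
    ----------
    alpha_, beta_ : float
        Fitted threshold and slope.
    params_ : QuickParams
        Fitted parameter bundle (includes the fixed gamma/lambda).
    loglik_ : float
        Maximised binomial log-likelihood.
    boundary_ : bool
        True when the fitted slope ran into the step-function regime
        (perfectly separable data).
    pse_ : float
        Level of the 50% crossing.
    """

    def __init__(self, gamma: float = 0.0, lam: float = 0.0,
                 n_alpha_starts: int = 7):
        self.gamma = gamma
        self.lam = lam
        self.n_alpha_starts = n_alpha_starts

    @staticmethod
    def _loglik(alpha: float, beta: float, gamma: float, lam: float,
                levels: np.ndarray, k: np.ndarray, n: np.ndarray) -> float:
        p = quick_pf(levels, QuickParams(alpha, beta, gamma, lam))
        eps = 1e-12
        p = np.clip(p, eps, 1.0 - eps)
        return float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))

    def fit(self, X, y, n_total=None):
        """Fit to per-level counts.

        Parameters
        ----------
        X : array-like of shape (n_levels,)
            Stimulus levels (cd/m^2), strictly positive.
        y : array-like of shape (n_levels,)
            Number of trials on which the designated alternative was
            chosen, per level.
        n_total : array-like of shape (n_levels,)
            Trials presented per level.
        """
        levels = np.asarray(X, dtype=float)
        if levels.ndim == 2 and levels.shape[1] == 1:
            levels = levels[:, 0]
        k = np.asarray(y, dtype=float)
        if n_total is None:
            raise ValueError("n_total (trials per level) is required")
        n = np.asarray(n_total, dtype=float)
        if not (levels.shape == k.shape == n.shape) or levels.ndim != 1:
            raise ValueError("levels, counts and totals must be 1-D, equal length")
        if np.any(levels <= 0):
            raise ValueError("levels must be positive")
        if np.any((k < 0) | (k > n)) or np.any(n < 1):
            raise ValueError("need 0 <= n_chose <= n_total and n_total >= 1")
        if np.unique(levels).size < 2:
            raise ValueError("need at least 2 distinct levels")
        if np.all(k == 0) or np.all(k == n):
            raise ValueError("all responses identical: the PSE is unidentifiable")

        gamma, lam = self.gamma, self.lam
        alphas = np.geomspace(levels.min(), levels.max(), self.n_alpha_starts)
        best = None
        for a0 in alphas:
            for b0 in _BETA_STARTS:
                res = optimize.minimize(
                    lambda th: -self._loglik(np.exp(th[0]), np.exp(th[1]),
                                             gamma, lam, levels, k, n),
                    x0=[np.log(a0), np.log(b0)], method="Nelder-Mead",
                    options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
                if best is None or res.fun < best.fun:
                    best = res
        alpha = float(np.exp(best.x[0]))
        beta = float(np.exp(best.x[1]))
        self.alpha_, self.beta_ = alpha, beta
        self.boundary_ = beta >= _BETA_CEILING
        self.params_ = QuickParams(alpha, min(beta, 1e6), gamma, lam)
        self.loglik_ = self._loglik(alpha, beta, gamma, lam, levels, k, n)
        self.pse_ = pse(self.params_)
        return self

    def predict_proba(self, X):
        """Probability of the designated alternative at level(s) ``X``."""
        if not hasattr(self, "params_"):
            raise AttributeError("estimator is not fitted yet")
        return quick_pf(np.asarray(X, float), self.params_)


def fit_quick_mle(levels: Sequence[float], n_chose: Sequence[int],
                  n_total: Sequence[int], gamma: float = 0.0,
                  lam: float = 0.0) -> Tuple[QuickParams, float]:
    """Fit the Quick function; returns (params, log-likelihood)."""
    est = QuickPsychometric(gamma=gamma, lam=lam)
    est.fit(np.asarray(levels, float), np.asarray(n_chose, float),
            n_total=np.asarray(n_total, float))
    return est.params_, est.loglik_


def flicker_summary(matches: Sequence[float], fixed_luminance: float) -> Tuple[float, float]:
    """Mean and SD of the fixed:match luminance ratio over flicker repeats."""
    matches = np.asarray(matches, dtype=float)
    if matches.size == 0:
        raise ValueError("no flicker matches provided")
    if np.any(matches <= 0):
        raise ValueError("matched luminances must be positive")
    if fixed_luminance <= 0:
        raise ValueError("fixed luminance must be positive")
    ratios = fixed_luminance / matches
    sd = float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0
    return float(ratios.mean()), sd
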