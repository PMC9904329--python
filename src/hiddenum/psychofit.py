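"""Psychometric and confidence-curve fitting.

The 2AFC selection data are summarised as per-level proportions of
"standard more numerous" responses against the numerosity difference
``x = n_standard - n_comparison`` and fitted with a cumulative Gaussian

    Psi(x; alpha, beta, gamma, lambda)
        = gamma + (1 - gamma - lambda)/2 * (1 + erf((x - alpha)/(beta*sqrt(2))))

with the guess rate tied to the lapse rate (gamma = lambda); the point of
subjective equality (PSE) is the fitted ``alpha``.  High-confidence
proportions are fitted with an inverted Gaussian profile

    C(x; mu, sigma, a) = 1 - a * exp(-((x - mu)^2) / (2 sigma^2))

whose minimum ``1 - a`` sits at ``mu``.  Both fits minimise the unweighted
sum of squared deviations of the per-level proportions, from a small grid
of multi-start initialisations, matching how such curves are typically fit
to binned psychophysical data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import erf
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = ["psi", "confidence_curve", "PsychometricModel", "ConfidenceModel",
           "FitResult", "fit_psychometric", "fit_confidence"]


def psi(x, alpha: float, beta: float, gamma: float, lam: float):
    """Cumulative-Gaussian psychometric function with guess and lapse rates.

    Monotone nondecreasing in ``x``, with asymptotes ``gamma`` (left) and
    ``1 - lam`` (right); equals ``(gamma + 1 - lam)/2`` at ``x = alpha``.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    x = np.asarray(x, dtype=float)
    return gamma + (1.0 - gamma - lam) / 2.0 * (1.0 + erf((x - alpha) / (beta * np.sqrt(2.0))))


def confidence_curve(x, mu: float, sigma: float, a: float):
    """Inverted-Gaussian confidence profile; minimum ``1 - a`` at ``mu``."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(x, dtype=float)
    return 1.0 - a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


@dataclass
class FitResult:
    """Parameters and diagnostics of a least-squares curve fit."""

    params: dict[str, float]
    rss: float
    proportions: np.ndarray
    levels: np.ndarray
    converged: bool
    n_levels: int
    n_trials: int

    @property
    def pse(self) -> float:
        """Location parameter (alpha for the psychometric fit, mu for the
        confidence fit)."""
        return self.params.get("alpha", self.params.get("mu"))


def _aggregate(x, y, n_trials):
    """Validate and return per-level arrays (levels, proportions, counts)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if np.unique(x).size < 4:
        raise ValueError("need at least 4 distinct stimulus levels")
    if ((y < 0) | (y > 1)).any():
        raise ValueError("proportions must lie in [0, 1]")
    if n_trials is None:
        n = np.ones_like(x)
    else:
        n = np.asarray(n_trials, dtype=float).ravel()
        if (n < 1).any():
            raise ValueError("each level needs at least one trial")
    return x, y, n


class _CurveFitter(BaseEstimator):
    """Shared multi-start bounded least-squares machinery."""

    def __init__(self, max_iter: int = 500, tol: float = 1e-9):
        self.max_iter = max_iter
        self.tol = tol

    # subclasses define: _curve(x, theta), _starts(x, y), _bounds(x),
    # _param_names, and _degenerate(y)

    def fit(self, X, y, n_trials=None):
        x, y, n = _aggregate(X, y, n_trials)
        lo, hi = self._bounds(x)

        def residuals(theta):
            return self._curve(x, theta) - y

        def jac(theta):
            return self._jac(x, theta)

        best = None
        for theta0 in self._starts(x, y):
            theta0 = np.clip(theta0, lo, hi)
            try:
                sol = least_squares(residuals, theta0, jac=jac,
                                    bounds=(lo, hi),
                                    max_nfev=self.max_iter, xtol=self.tol,
                                    ftol=self.tol, gtol=self.tol)
            except Exception:       # singular start; skip
                continue
            rss = float(np.sum(sol.fun ** 2))
            if best is None or rss < best[0] - 1e-12 or \
               (abs(rss - best[0]) <= 1e-12 and abs(sol.x[0]) < abs(best[1][0])):
                best = (rss, sol.x, sol.success)
        if best is None:
            raise RuntimeError("all optimization starts failed")
        rss, theta, success = best
        for name, value in zip(self._param_names, theta):
            setattr(self, name + "_", float(value))
        self.rss_ = rss
        self.levels_ = x
        self.proportions_ = y
        self.n_trials_ = int(np.sum(n))
        self.converged_ = bool(success and not self._degenerate(y))
        return self

    def predict(self, X):
        check_is_fitted(self, "rss_")
        theta = [getattr(self, name + "_") for name in self._param_names]
        return self._curve(np.asarray(X, dtype=float), theta)

    def result(self) -> FitResult:
        check_is_fitted(self, "rss_")
        params = {name: getattr(self, name + "_") for name in self._param_names}
        return FitResult(params=params, rss=self.rss_,
                         proportions=self.proportions_, levels=self.levels_,
                         converged=self.converged_,
                         n_levels=int(np.unique(self.levels_).size),
                         n_trials=self.n_trials_)


class PsychometricModel(_CurveFitter):
    """Cumulative-Gaussian psychometric fit with tied guess/lapse rates.

    Free parameters ``(alpha, beta, lambda)`` with ``gamma = lambda``;
    fitted attributes ``alpha_`` (the PSE), ``beta_``, ``lambda_``,
    ``rss_``, ``converged_``.

    Parameters
    ----------
    beta_bounds, lambda_max : parameter box constraints.
    max_iter, tol : optimizer budget per start.
    """

    _param_names = ("alpha", "beta", "lambda")

    def __init__(self, beta_bounds: tuple[float, float] = (0.1, 50.0),
                 lambda_max: float = 0.25, max_iter: int = 500,
                 tol: float = 1e-9):
        super().__init__(max_iter=max_iter, tol=tol)
        self.beta_bounds = beta_bounds
        self.lambda_max = lambda_max

    def _curve(self, x, theta):
        alpha, beta, lam = theta
        return psi(x, alpha, max(beta, 1e-9), lam, lam)

    def _jac(self, x, theta):
        alpha, beta, lam = theta
        beta = max(beta, 1e-9)
        z = (x - alpha) / (beta * np.sqrt(2.0))
        gauss = (1.0 - 2.0 * lam) / np.sqrt(np.pi) * np.exp(-z * z)
        d_alpha = -gauss / (beta * np.sqrt(2.0))
        d_beta = -gauss * (x - alpha) / (np.sqrt(2.0) * beta ** 2)
        d_lam = 1.0 - (1.0 + erf(z))
        return np.stack([d_alpha, d_beta, d_lam], axis=1)

    def _bounds(self, x):
        span = x.max() - x.min()
        lo = np.array([x.min() - span, self.beta_bounds[0], 0.0])
        hi = np.array([x.max() + span, self.beta_bounds[1], self.lambda_max])
        return lo, hi

    def _starts(self, x, y):
        # alpha from the empirical 50% crossing plus the level extremes;
        # beta and lambda from a small log/linear grid
        order = np.argsort(x)
        xs, ys = x[order], y[order]
        cross = xs[np.argmin(np.abs(ys - 0.5))]
        alphas = [cross, xs[len(xs) // 4], xs[3 * len(xs) // 4]]
        betas = [1.0, 3.0, 9.0]
        lams = [0.0, 0.05, 0.15]
        return [np.array([a, b, l]) for a in alphas for b in betas for l in lams]

    @staticmethod
    def _degenerate(y):
        # all-0/all-1 (or constant) proportions leave alpha unidentified
        return float(np.ptp(y)) < 1e-9


class ConfidenceModel(_CurveFitter):
    """Inverted-Gaussian confidence-curve fit.

    Free parameters ``(mu, sigma, a)``; fitted attributes ``mu_`` (the
    minimum-confidence point), ``sigma_``, ``a_`` (amplitude; minimum
    confidence is ``1 - a_``), ``rss_``, ``converged_``.
    """

    _param_names = ("mu", "sigma", "a")

    def __init__(self, sigma_bounds: tuple[float, float] = (0.1, 50.0),
                 max_iter: int = 500, tol: float = 1e-9):
        super().__init__(max_iter=max_iter, tol=tol)
        self.sigma_bounds = sigma_bounds

    def _curve(self, x, theta):
        mu, sigma, a = theta
        return confidence_curve(x, mu, max(sigma, 1e-9), a)

    def _jac(self, x, theta):
        mu, sigma, a = theta
        sigma = max(sigma, 1e-9)
        t = (x - mu) / sigma
        env = np.exp(-0.5 * t * t)
        d_mu = -a * env * t / sigma
        d_sigma = -a * env * t * t / sigma
        d_a = -env
        return np.stack([d_mu, d_sigma, d_a], axis=1)

    def _bounds(self, x):
        span = x.max() - x.min()
        lo = np.array([x.min() - span, self.sigma_bounds[0], 0.0])
        hi = np.array([x.max() + span, self.sigma_bounds[1], 1.0])
        return lo, hi

    def _starts(self, x, y):
        mus = [x[np.argmin(y)], np.median(x), x[np.argmax(np.abs(x))] * -0.5]
        sigmas = [1.0, 4.0, 12.0]
        amps = [0.3, 0.6, 0.9]
        return [np.array([m, s, a]) for m in mus for s in sigmas for a in amps]

    @staticmethod
    def _degenerate(y):
        # flat high confidence: a -> 0 and mu is unidentified
        return float(np.ptp(y)) < 1e-9 or float(1.0 - np.min(y)) < 1e-6


def fit_psychometric(levels, proportions, n_trials=None, **kwargs) -> FitResult:
    """Fit the psychometric function to per-level choice proportions."""
    return PsychometricModel(**kwargs).fit(levels, proportions, n_trials).result()


def fit_confidence(levels, proportions, n_trials=None, **kwargs) -> FitResult:
    """Fit the confidence curve to per-level high-confidence proportions."""
    return ConfidenceModel(**kwargs).fit(levels, proportions, n_trials).result()
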