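"""Bayesian observer for the number of hidden objects.

The board is treated as an urn of ``N_v`` visible and ``N_h`` hidden
cells.  Dropping ``n_total`` pieces uniformly onto distinct cells makes
the visible count hypergeometric,

    P(n_v | n_total) = C(N_v, n_v) C(N_h, n_total - n_v) / C(N_v + N_h, n_total),

and an observer who sees ``n_v`` pieces inverts this with a Gaussian prior
over the total count ("constant total") or over the hidden count
("constant hidden", a prior on ``n_total - n_v``):

    P(n_total | n_v) ~ P(n_v | n_total) P(n_total).

The predicted number of hidden pieces is the posterior mean of
``n_total - n_v`` (posterior mode available as an alternative readout).
The two-parameter priors are fitted to condition-mean hidden-count
estimates by nonlinear least squares, and the two prior families are
compared per observer with BIC and relative model weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
from scipy import stats
from scipy.optimize import minimize
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

PRIOR_KINDS = ("constant_total", "constant_hidden")


@dataclass(frozen=True)
class UrnSpec:
    """Visible/hidden cell counts of the board urn."""

    N_v: int
    N_h: int

    def __post_init__(self):
        if self.N_v < 0 or self.N_h < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def N_total(self) -> int:
        return self.N_v + self.N_h


@dataclass(frozen=True)
class GaussianPrior:
    """Discrete Gaussian prior over the total (or hidden) piece count.

    The Gaussian density with the given mean and sd is evaluated on the
    integer support and renormalized.  ``constant_total`` places the prior
    on the total count directly; ``constant_hidden`` places it on the
    hidden count, i.e. on ``n_total - n_v``, which shifts with ``n_v``.
    """

    kind: str
    mean: float
    sd: float

    def __post_init__(self):
        if self.kind not in PRIOR_KINDS:
            raise ValueError(f"kind must be one of {PRIOR_KINDS}, got {self.kind!r}")
        if self.sd <= 0:
            raise ValueError("prior sd must be positive")

    def log_weights(self, support: np.ndarray, n_v: int) -> np.ndarray:
        """Unnormalized log prior on a grid of total counts."""
        center = self.mean if self.kind == "constant_total" else n_v + self.mean
        return -0.5 * ((support - center) / self.sd) ** 2


@dataclass
class PosteriorOverTotal:
    """Discrete posterior P(n_total | n_v) on integer support."""

    support: np.ndarray
    probabilities: np.ndarray
    n_v: int
    urn: UrnSpec

    @property
    def mean_total(self) -> float:
        return float(np.dot(self.support, self.probabilities))

    @property
    def mean_hidden(self) -> float:
        return self.mean_total - self.n_v

    @property
    def mode_total(self) -> int:
        return int(self.support[np.argmax(self.probabilities)])


def hypergeom_likelihood(n_v: int, n_total: int, urn: UrnSpec,
                         lenient: bool = True) -> float:
    """Probability of seeing ``n_v`` visible pieces given ``n_total`` placed.

    Out-of-support combinations return 0 when ``lenient`` (the default)
    and raise otherwise; negative counts always raise.
    """
    if n_v < 0 or n_total < 0:
        raise ValueError("counts must be non-negative")
    in_support = (n_v <= urn.N_v and n_total - n_v >= 0
                  and n_total - n_v <= urn.N_h and n_total <= urn.N_total)
    if not in_support:
        if lenient:
            return 0.0
        raise ValueError(f"(n_v={n_v}, n_total={n_total}) outside the "
                         f"support of urn {urn}")
    return float(stats.hypergeom.pmf(n_v, urn.N_total, urn.N_v, n_total))


def _likelihood_over_totals(n_v: int, support: np.ndarray,
                            urn: UrnSpec) -> np.ndarray:
    return stats.hypergeom.pmf(n_v, urn.N_total, urn.N_v, support)


def posterior_total(n_v: int, urn: UrnSpec,
                    prior: GaussianPrior) -> PosteriorOverTotal:
    """Posterior over the total count given the visible count.

    The support is the admissible range ``[n_v, n_v + N_h]``; the
    hypergeometric likelihood is multiplied pointwise by the discretized
    prior and renormalized.
    """
    if n_v < 0 or n_v > urn.N_v:
        raise ValueError(f"n_v={n_v} incompatible with urn {urn}")
    support = np.arange(n_v, n_v + urn.N_h + 1)
    like = _likelihood_over_totals(n_v, support, urn)
    log_prior = prior.log_weights(support.astype(float), n_v)
    # stabilized product; renormalization absorbs the constants
    weights = like * np.exp(log_prior - log_prior.max())
    norm = weights.sum()
    if not np.isfinite(norm) or norm <= 0:
        raise ValueError("empty posterior: prior and likelihood do not overlap")
    return PosteriorOverTotal(support=support, probabilities=weights / norm,
                              n_v=n_v, urn=urn)


def predict_hidden(n_v: int, urn: UrnSpec, prior: GaussianPrior,
                   readout: str = "mean") -> float:
    """Model-predicted number of hidden pieces for one condition."""
    post = posterior_total(n_v, urn, prior)
    if readout == "mean":
        return post.mean_hidden
    if readout == "mode":
        return float(post.mode_total - n_v)
    raise ValueError(f"readout must be 'mean' or 'mode', got {readout!r}")


class BayesianObserverModel(BaseEstimator):
    """Two-parameter Bayesian observer fitted to condition-mean estimates.

    Fits the prior's ``(mean, sd)`` by least squares so that the posterior
    readout of the hidden count matches the observed mean hidden-count
    estimates across design cells.

    Parameters
    ----------
    kind : "constant_total" or "constant_hidden" prior family.
    readout : posterior summary used as the model prediction.
    mean_bounds, sd_bounds : box constraints on the prior parameters.

    Attributes (after fit)
    ----------------------
    prior_mean_, prior_sd_ : fitted prior parameters.
    prior_ : the fitted :class:`GaussianPrior`.
    rss_ : residual sum of squares; converged_ : optimizer success.
    """

    def __init__(self, kind: str = "constant_hidden", readout: str = "mean",
                 mean_bounds: tuple[float, float] = (1e-6, 117.0),
                 sd_bounds: tuple[float, float] = (0.1, 50.0)):
        self.kind = kind
        self.readout = readout
        self.mean_bounds = mean_bounds
        self.sd_bounds = sd_bounds

    def _predictions(self, cells, mean, sd, cache=None):
        if cache is None:
            cache = self._likelihood_cache(cells)
        prior = GaussianPrior(self.kind, mean, sd)
        preds = np.empty(len(cells))
        for i, ((n_v, _urn), (support, like)) in enumerate(zip(cells, cache)):
            log_prior = prior.log_weights(support.astype(float), n_v)
            w = like * np.exp(log_prior - log_prior.max())
            norm = w.sum()
            if norm <= 0 or not np.isfinite(norm):
                raise ValueError("empty posterior during prior fit")
            post = w / norm
            if self.readout == "mean":
                preds[i] = float(np.dot(support, post)) - n_v
            else:
                preds[i] = float(support[np.argmax(post)]) - n_v
        return preds

    @staticmethod
    def _likelihood_cache(cells):
        # the hypergeometric likelihood of each design cell is fixed across
        # prior parameters, so it is computed once per fit
        cache = []
        for (n_v, urn) in cells:
            support = np.arange(n_v, n_v + urn.N_h + 1)
            cache.append((support, _likelihood_over_totals(n_v, support, urn)))
        return cache

    def fit(self, X: Sequence[tuple[int, UrnSpec]], y):
        """Fit to design cells ``X = [(n_v, urn), ...]`` and mean
        hidden-count estimates ``y``."""
        cells = list(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(cells) < 3:
            raise ValueError("need at least 3 design cells")
        if len(cells) != y.size:
            raise ValueError("X and y length mismatch")
        cache = self._likelihood_cache(cells)

        def objective(theta):
            return float(np.sum(
                (self._predictions(cells, *theta, cache=cache) - y) ** 2))

        bounds = [self.mean_bounds, self.sd_bounds]
        starts = [(m, s) for m in (1.0, 2.5, 5.0, 8.0, 12.0, 20.0)
                  for s in (0.5, 1.0, 2.0, 4.0, 8.0)]
        best = None
        for theta0 in starts:
            sol = minimize(objective, np.array(theta0), method="L-BFGS-B",
                           bounds=bounds)
            if best is None or sol.fun < best.fun:
                best = sol
        self.prior_mean_ = float(best.x[0])
        self.prior_sd_ = float(best.x[1])
        self.prior_ = GaussianPrior(self.kind, self.prior_mean_, self.prior_sd_)
        self.rss_ = float(best.fun)
        self.converged_ = bool(best.success)
        if not self.converged_:
            warnings.warn("prior fit did not converge", stacklevel=2)
        self.n_cells_ = len(cells)
        return self

    def predict(self, X: Sequence[tuple[int, UrnSpec]]):
        check_is_fitted(self, "prior_")
        return self._predictions(list(X), self.prior_mean_, self.prior_sd_)


def fit_prior(cells: Sequence[tuple[int, UrnSpec]], mean_estimates,
              kind: str, readout: str = "mean") -> tuple[GaussianPrior, float]:
    """Least-squares fit of a prior family to condition-mean estimates.

    Returns the fitted :class:`GaussianPrior` and the residual sum of
    squares.
    """
    model = BayesianObserverModel(kind=kind, readout=readout)
    model.fit(cells, mean_estimates)
    return model.prior_, model.rss_


@dataclass
class ModelComparison:
    """BIC-based comparison of candidate models fitted to the same data."""

    labels: tuple[str, ...]
    bic: tuple[float, ...]
    weights: tuple[float, ...]

    @property
    def winner(self) -> str:
        return self.labels[int(np.argmin(self.bic))]


def bic_from_rss(rss: float, n: int, k: int = 2) -> float:
    """Gaussian-error BIC from a residual sum of squares."""
    if n <= k:
        raise ValueError("need more data points than parameters")
    if rss <= 0:
        warnings.warn("RSS is zero; flooring at machine epsilon for BIC",
                      stacklevel=2)
        rss = np.finfo(float).tiny
    return n * np.log(rss / n) + k * np.log(n)


def compare_models(rss_by_model: dict[str, float], n_points: int,
                   k: int = 2) -> ModelComparison:
    """Compare fitted models via BIC and relative model weights.

    Weights are ``exp(-Delta_i / 2)`` normalized over models, with
    ``Delta_i = BIC_i - min(BIC)``.
    """
    labels = tuple(rss_by_model)
    bic = np.array([bic_from_rss(rss_by_model[m], n_points, k) for m in labels])
    delta = bic - bic.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    return ModelComparison(labels=labels, bic=tuple(map(float, bic)),
                           weights=tuple(map(float, w)))
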