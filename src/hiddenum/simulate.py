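"""Synthetic observers: trial-level response generators for every task.

Each generator consumes a trial table (see
:func:`hiddenum.geometry.enumerate_trials`) and emits a tidy response
table with one row per analyzed trial.  Choices and confidence reports
are Bernoulli draws from the psychometric / confidence curves; direct
numerosity estimates come either from a noisy linear observer or from the
Bayesian urn observer, discretized to the 0-40 response menu.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes import GaussianPrior, UrnSpec, predict_hidden
from .psychofit import confidence_curve, psi

RESPONSE_COLUMNS = ["experiment", "trial", "condition", "n_visible",
                    "delta_n", "occluder", "response_type", "response",
                    "seed"]
#: drop-down response menu bounds for direct estimates
ESTIMATE_MIN, ESTIMATE_MAX = 0, 40


@dataclass(frozen=True)
class PsychometricParams:
    """Generating parameters of the 2AFC choice curve."""

    alpha: float
    beta: float
    gamma: float = 0.02
    lam: float = 0.02

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not (0 <= self.gamma < 0.5 and 0 <= self.lam < 0.5):
            raise ValueError("guess/lapse rates must lie in [0, 0.5)")


@dataclass(frozen=True)
class ConfidenceParams:
    """Generating parameters of the high-confidence curve."""

    mu: float
    sigma: float
    a: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 <= self.a <= 1:
            raise ValueError("amplitude a must lie in [0, 1]")


def _analyzed_pairs(trials: pd.DataFrame) -> pd.DataFrame:
    t = trials[trials["analyzed"]].copy()
    if t["n_visible_cmp"].isna().any():
        raise ValueError("trials must carry standard/comparison pairs")
    t["delta_n"] = t["n_visible_std"].astype(float) - t["n_visible_cmp"].astype(float)
    return t


def _table(t: pd.DataFrame, responses, response_type: str,
           seed) -> pd.DataFrame:
    out = pd.DataFrame({
        "experiment": t["experiment"].to_numpy(),
        "trial": t["trial"].to_numpy(),
        "condition": t["condition"].to_numpy(),
        "n_visible": t["n_visible_std"].to_numpy(),
        "delta_n": t.get("delta_n", pd.Series(np.nan, index=t.index)).to_numpy(),
        "occluder": t["occluder"].to_numpy(),
        "response_type": response_type,
        "response": responses,
        "seed": seed,
    })
    return out[RESPONSE_COLUMNS]


def simulate_selection(trials: pd.DataFrame, params: PsychometricParams,
                       rng_seed: int | None = None) -> pd.DataFrame:
    """Bernoulli 2AFC choices: P(standard chosen as more numerous) follows
    the psychometric curve evaluated at ``delta_n = standard - comparison``."""
    t = _analyzed_pairs(trials)
    rng = np.random.default_rng(rng_seed)
    p = psi(t["delta_n"].to_numpy(), params.alpha, params.beta,
            params.gamma, params.lam)
    choices = (rng.random(len(t)) < p).astype(int)
    return _table(t, choices, "choice", rng_seed)


def simulate_confidence(trials: pd.DataFrame, params: ConfidenceParams,
                        rng_seed: int | None = None) -> pd.DataFrame:
    """Bernoulli high/low confidence reports from the confidence curve."""
    t = _analyzed_pairs(trials)
    rng = np.random.default_rng(rng_seed)
    p = confidence_curve(t["delta_n"].to_numpy(), params.mu, params.sigma,
                         params.a)
    high = (rng.random(len(t)) < p).astype(int)
    return _table(t, high, "confidence", rng_seed)


def _discretize(values: np.ndarray) -> np.ndarray:
    """Round half up and clamp to the 0-40 drop-down menu."""
    rounded = np.floor(values + 0.5)
    return np.clip(rounded, ESTIMATE_MIN, ESTIMATE_MAX).astype(int)


def simulate_linear_estimates(trials: pd.DataFrame,
                              slope: float, intercept: float,
                              noise_sd: float = 0.0,
                              rng_seed: int | None = None) -> pd.DataFrame:
    """Noisy linear direct-estimation observer.

    ``estimate = round(slope * n_true + intercept + eps)`` with Gaussian
    noise, clamped to the response menu.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    t = trials[trials["analyzed"]].copy()
    rng = np.random.default_rng(rng_seed)
    n_true = t["n_visible_std"].astype(float).to_numpy()
    raw = slope * n_true + intercept + rng.normal(0.0, noise_sd, len(t)) \
        if noise_sd > 0 else slope * n_true + intercept
    return _table(t, _discretize(np.asarray(raw, dtype=float)), "estimate",
                  rng_seed)


def simulate_bayesian_estimates(trials: pd.DataFrame,
                                urns: dict[str, UrnSpec],
                                prior: GaussianPrior,
                                noise_sd: float = 0.0,
                                readout: str = "mean",
                                rng_seed: int | None = None) -> pd.DataFrame:
    """Hidden-count estimates from the Bayesian urn observer.

    ``urns`` maps the trial table's occluder labels to urn geometries.
    The estimate is the posterior readout of the hidden count, plus
    optional Gaussian response noise (default none, i.e. the pure model
    mean), discretized to the response menu.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    t = trials[trials["analyzed"]].copy()
    t = t[t["occluder"].isin(urns)]
    rng = np.random.default_rng(rng_seed)
    cache: dict[tuple[str, int], float] = {}
    preds = np.empty(len(t))
    for i, (occ, n_v) in enumerate(zip(t["occluder"], t["n_visible_std"])):
        key = (occ, int(n_v))
        if key not in cache:
            cache[key] = predict_hidden(int(n_v), urns[occ], prior, readout)
        preds[i] = cache[key]
    if noise_sd > 0:
        preds = preds + rng.normal(0.0, noise_sd, len(t))
    return _table(t, _discretize(preds), "hidden_estimate", rng_seed)
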