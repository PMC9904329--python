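"""Parameter-recovery harnesses.

Closed-loop checks of the fitting stages: simulate responses from known
generating parameters on a published trial design, refit the matching
model per simulated observer, and summarise how well the generating
values come back.  These harnesses back the package's validation suite
and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bayes import GaussianPrior, UrnSpec, fit_prior, predict_hidden
from .psychofit import ConfidenceModel, PsychometricModel, confidence_curve, psi

#: numerosity-difference levels of the 2AFC design (standard minus
#: comparison, standard at 10 visible pieces)
EXP1_LEVELS = np.array([-8.0, -6.0, -4.0, -2.0, -1.0, 0.0, 1.0, 2.0,
                        4.0, 6.0, 8.0])


@dataclass
class RecoveryResult:
    """Replicate-level recovered locations and their summary."""

    estimates: np.ndarray
    generating: float

    @property
    def mean(self) -> float:
        return float(self.estimates.mean())

    @property
    def bias(self) -> float:
        return self.mean - self.generating

    @property
    def n(self) -> int:
        return int(self.estimates.size)


def recover_psychometric_pse(alpha: float, beta: float = 3.0,
                             lapse: float = 0.02,
                             levels: np.ndarray = EXP1_LEVELS,
                             reps_per_level: int = 10,
                             n_replicates: int = 2000,
                             rng_seed: int | None = 0) -> RecoveryResult:
    """Simulate 2AFC choices per replicate observer and refit the PSE.

    Bernoulli choices are drawn from the psychometric curve at each level,
    aggregated to per-level proportions, and the cumulative-Gaussian model
    (guess rate tied to lapse rate) is refit per replicate; the recovered
    PSE is the fitted location.
    """
    rng = np.random.default_rng(rng_seed)
    p = psi(levels, alpha, beta, lapse, lapse)
    draws = rng.random((n_replicates, reps_per_level, levels.size)) < p
    props = draws.mean(axis=1)
    model = PsychometricModel()
    est = np.array([model.fit(levels, props[i]).alpha_
                    for i in range(n_replicates)])
    return RecoveryResult(estimates=est, generating=alpha)


def recover_confidence_minimum(mu: float, sigma: float = 4.0,
                               amplitude: float = 0.73,
                               levels: np.ndarray = EXP1_LEVELS,
                               reps_per_level: int = 10,
                               n_replicates: int = 2000,
                               rng_seed: int | None = 0) -> RecoveryResult:
    """Simulate high/low confidence reports and refit the minimum point."""
    rng = np.random.default_rng(rng_seed)
    p = confidence_curve(levels, mu, sigma, amplitude)
    draws = rng.random((n_replicates, reps_per_level, levels.size)) < p
    props = draws.mean(axis=1)
    model = ConfidenceModel()
    est = np.array([model.fit(levels, props[i]).mu_
                    for i in range(n_replicates)])
    return RecoveryResult(estimates=est, generating=mu)


def exp2_design_cells(urns: dict[str, UrnSpec],
                      numerosities=range(6, 15)) -> list[tuple[int, UrnSpec]]:
    """The 18 estimation-task design cells: 9 numerosities x 2 occluders."""
    return [(int(n_v), urn) for urn in urns.values() for n_v in numerosities]


def recover_prior_mean(kind: str, mean: float, sd: float,
                       urns: dict[str, UrnSpec],
                       readout: str = "mean") -> tuple[GaussianPrior, float]:
    """Noiseless closed loop for one prior family on the estimation design.

    Generates posterior-readout hidden-count estimates for every design
    cell under the given prior and refits the two prior parameters by
    least squares; returns the fitted prior and the RSS.
    """
    cells = exp2_design_cells(urns)
    gen = GaussianPrior(kind, mean, sd)
    y = [predict_hidden(n_v, urn, gen, readout) for (n_v, urn) in cells]
    return fit_prior(cells, y, kind, readout)
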