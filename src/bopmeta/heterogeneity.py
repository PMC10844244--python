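"""Uncertainty in the between-study heterogeneity estimate and the two
uncertainty intervals (with and without the heterogeneity component).

The sampling SD of ``gamma_hat`` comes from the inverse Fisher information of
the marginal likelihood in ``gamma``; its 95th quantile feeds the
heterogeneity-inclusive interval and the conservative risk function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import FitResult, _study_blocks
from .observations import InvalidInputError, ObservationSet

__all__ = [
    "HeterogeneitySummary",
    "gamma_fisher_sd",
    "gamma_quantile",
    "gamma_quantile_sampled",
    "uncertainty_interval",
    "summarize_heterogeneity",
]


@dataclass(frozen=True)
class HeterogeneitySummary:
    gamma_hat: float
    gamma_sd: float
    gamma_q95: float
    method: str = "fisher-closed-form"


def gamma_fisher_sd(obs_set: ObservationSet, fit: FitResult) -> float:
    """SD of ``gamma_hat`` from the inverse Fisher information.

    For block covariance ``V_i = S_i + gamma J_i`` the information is
    ``I(gamma) = 1/2 sum_i tr[(V_i^-1 J_i)^2] = 1/2 sum_i (1' V_i^-1 1)^2``;
    trimmed rows are excluded.
    """
    if len(obs_set) == 0:
        raise InvalidInputError("empty observation set")
    include = np.array([fit.trim_weights.get(o, 1) for o in obs_set.obs_ids], dtype=bool)
    if not include.any():
        raise InvalidInputError("no untrimmed observations")
    var = obs_set.se() ** 2
    g = fit.gamma_hat
    info = 0.0
    for ix in _study_blocks(obs_set.study_ids, include):
        d = var[ix]
        t = float(np.sum(1.0 / d))
        # 1' V^-1 1 via Woodbury: t / (1 + gamma t)
        info += 0.5 * (t / (1.0 + g * t)) ** 2
    return 1.0 / math.sqrt(info)


def gamma_quantile(gamma_hat: float, gamma_sd: float, q: float = 0.95) -> float:
    """Closed-form ``max(0, gamma_hat + z_q gamma_sd)``."""
    if not 0 < q < 1:
        raise InvalidInputError("q must be in (0, 1)")
    return max(0.0, gamma_hat + stats.norm.ppf(q) * gamma_sd)


def gamma_quantile_sampled(
    gamma_hat: float, gamma_sd: float, q: float = 0.95,
    n_draws: int = 10_000, seed: int = 0,
) -> float:
    """Monte-Carlo alternative: quantile of N(gamma_hat, sd^2) draws floored
    at zero (floor applied to the draws, quantile taken after)."""
    if not 0 < q < 1:
        raise InvalidInputError("q must be in (0, 1)")
    rng = np.random.default_rng(seed)
    draws = np.maximum(rng.normal(gamma_hat, gamma_sd, size=n_draws), 0.0)
    return float(np.quantile(draws, q))


def uncertainty_interval(
    beta0: float,
    se_beta0: float,
    gamma_q95: float = 0.0,
    include_gamma: bool = False,
    level: float = 0.95,
) -> tuple[float, float]:
    """Ratio-scale interval for the pooled effect.

    Without the heterogeneity component the half-width is ``z se``; with it
    the variances combine in quadrature, ``z sqrt(se^2 + gamma_q95)``.
    """
    if se_beta0 < 0 or gamma_q95 < 0:
        raise InvalidInputError("variance inputs must be non-negative")
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(se_beta0**2 + (gamma_q95 if include_gamma else 0.0))
    return math.exp(beta0 - half), math.exp(beta0 + half)


def summarize_heterogeneity(
    obs_set: ObservationSet, fit: FitResult, q: float = 0.95
) -> HeterogeneitySummary:
    sd = gamma_fisher_sd(obs_set, fit)
    return HeterogeneitySummary(
        gamma_hat=fit.gamma_hat,
        gamma_sd=sd,
        gamma_q95=gamma_quantile(fit.gamma_hat, sd, q),
    )
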