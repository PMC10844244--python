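"""Conservative risk-function scoring: BPRF, risk-outcome score, star rating.

The BPRF is the 5th-quantile relative risk closest to the null under
``N(beta0, se^2 + gamma_q95)`` on the log scale.  The score is the signed
half-log of the BPRF, and the star rating bins the score, gated on the
fixed-effects (no-heterogeneity) interval excluding the null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats

from .heterogeneity import HeterogeneitySummary, uncertainty_interval
from .model import FitResult
from .observations import InvalidInputError
from .pubbias import EggerResult

__all__ = ["RiskSummary", "bprf", "ros", "star_rating", "summarize"]

#: score thresholds for 2..5 stars (upper bounds inclusive)
STAR_THRESHOLDS = (0.0, 0.14, 0.41, 0.62)


@dataclass
class RiskSummary:
    """One reportable row: pooled RR, both intervals, conservative scores."""

    outcome: str
    rr: float
    ui_no_gamma: tuple[float, float]
    ui_with_gamma: tuple[float, float]
    gamma_hat: float
    bprf: float | None
    ros: float | None
    stars: int
    pub_bias: bool
    n_studies: int
    n_obs: int
    selected_covariates: list[str] = field(default_factory=list)
    gamma_q95: float = 0.0
    beta0: float = 0.0
    se_beta0: float = 0.0

    def as_dict(self, digits: int = 2) -> dict:
        r = lambda v: None if v is None else round(v, digits)
        return {
            "outcome": self.outcome,
            "rr": r(self.rr),
            "ui_no_gamma_lower": r(self.ui_no_gamma[0]),
            "ui_no_gamma_upper": r(self.ui_no_gamma[1]),
            "ui_with_gamma_lower": r(self.ui_with_gamma[0]),
            "ui_with_gamma_upper": r(self.ui_with_gamma[1]),
            "gamma": self.gamma_hat,
            "bprf": r(self.bprf),
            "ros": r(self.ros),
            "stars": self.stars,
            "pub_bias": "Yes" if self.pub_bias else "No",
            "n_studies": self.n_studies,
            "n_obs": self.n_obs,
            "selected_covariates": "; ".join(self.selected_covariates) or "None",
        }


def bprf(beta0: float, se_beta0: float, gamma_q95: float = 0.0) -> float:
    """5th-quantile effect closest to the null on the ratio scale.

    Harmful direction (``beta0 > 0``) takes the lower 5th quantile of
    ``exp(N(beta0, se^2 + gamma_q95))``; protective the upper.  A null mean
    returns 1.
    """
    if beta0 == 0.0:
        return 1.0
    z05 = stats.norm.ppf(0.95)
    sigma = math.sqrt(se_beta0**2 + gamma_q95)
    sign = -1.0 if beta0 > 0 else 1.0
    return math.exp(beta0 + sign * z05 * sigma)


def ros(bprf_value: float, direction_sign: int) -> float:
    """Signed half-log of the BPRF; ``direction_sign`` is the sign of beta0."""
    if bprf_value <= 0:
        raise InvalidInputError("BPRF must be positive")
    if direction_sign not in (-1, 1):
        raise InvalidInputError("direction_sign must be -1 or +1")
    return direction_sign * math.log(bprf_value) / 2.0


def star_rating(ros_value: float | None, fixed_ui_excludes_null: bool) -> int:
    """Ordinal 0-5 evidence grade.

    Zero when the no-heterogeneity interval crosses the null (score undefined);
    one for a negative score; then bins with inclusive upper bounds at
    0.14 / 0.41 / 0.62.
    """
    if not fixed_ui_excludes_null:
        return 0
    if ros_value is None:
        raise InvalidInputError("score required when the fixed-effects gate passes")
    t0, t2, t3, t4 = STAR_THRESHOLDS
    if ros_value < t0:
        return 1
    if ros_value <= t2:
        return 2
    if ros_value <= t3:
        return 3
    if ros_value <= t4:
        return 4
    return 5


def summarize(
    fit: FitResult,
    het: HeterogeneitySummary,
    pub: EggerResult | None = None,
    outcome: str = "",
    n_studies: int | None = None,
    selected_covariates: list[str] | None = None,
    level: float = 0.95,
) -> RiskSummary:
    """Assemble a reportable row from a fitted model."""
    if abs(fit.gamma_hat - het.gamma_hat) > 1e-9:
        raise InvalidInputError("fit and heterogeneity summary disagree on gamma")
    b0, se = fit.beta0, fit.se_beta0
    ui0 = uncertainty_interval(b0, se, include_gamma=False, level=level)
    ui1 = uncertainty_interval(b0, se, het.gamma_q95, include_gamma=True, level=level)
    gate = ui0[0] > 1.0 or ui0[1] < 1.0
    if gate:
        bp = bprf(b0, se, het.gamma_q95)
        score = ros(bp, 1 if b0 > 0 else -1) if b0 != 0.0 else 0.0
    else:
        bp = score = None
    return RiskSummary(
        outcome=outcome,
        rr=math.exp(b0),
        ui_no_gamma=ui0,
        ui_with_gamma=ui1,
        gamma_hat=fit.gamma_hat,
        bprf=bp,
        ros=score,
        stars=star_rating(score, gate),
        pub_bias=bool(pub.flagged) if pub is not None else False,
        n_studies=n_studies if n_studies is not None else 0,
        n_obs=fit.n_obs_used,
        selected_covariates=list(selected_covariates or []),
        gamma_q95=het.gamma_q95,
        beta0=b0,
        se_beta0=se,
    )
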