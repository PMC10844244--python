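"""Publication/reporting-bias diagnostics: Egger's regression on model
residuals and the data behind the modified funnel plot."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .model import FitResult, design_matrix
from .observations import InvalidInputError, ObservationSet

__all__ = ["EggerResult", "eggers_test", "funnel_points"]


class InsufficientDataError(InvalidInputError):
    pass


@dataclass(frozen=True)
class EggerResult:
    slope: float
    slope_se: float
    p_value: float
    flagged: bool
    n: int
    alpha: float = 0.05


def _residuals(obs_set: ObservationSet, fit: FitResult):
    include = np.array([fit.trim_weights.get(o, 1) for o in obs_set.obs_ids], dtype=bool)
    X = design_matrix(obs_set, fit.covariates, fit.covariate_reference)
    resid = obs_set.y() - X @ fit.beta
    total_se = np.sqrt(obs_set.se() ** 2 + fit.gamma_hat)
    return resid, total_se, include


def eggers_test(obs_set: ObservationSet, fit: FitResult, alpha: float = 0.05) -> EggerResult:
    """Weighted regression of model residuals on total SE.

    Residuals are taken against the fitted model including covariate terms;
    the regressor is ``sqrt(se^2 + gamma_hat)`` and the weights are its
    inverse square.  Trimmed rows are excluded.  Flags when the two-sided p
    for a zero slope falls below ``alpha``.
    """
    resid, total_se, include = _residuals(obs_set, fit)
    n = int(include.sum())
    if n < 3:
        raise InsufficientDataError(f"Egger's test needs >= 3 untrimmed observations, got {n}")
    r, s = resid[include], total_se[include]
    if np.allclose(r, 0.0) or np.ptp(s) == 0.0:
        return EggerResult(0.0, 0.0, 1.0, flagged=False, n=n, alpha=alpha)
    Xr = sm.add_constant(s)
    wls = sm.WLS(r, Xr, weights=1.0 / s**2).fit()
    slope = float(wls.params[1])
    slope_se = float(wls.bse[1])
    p = float(wls.pvalues[1])
    return EggerResult(slope, slope_se, p, flagged=p < alpha, n=n, alpha=alpha)


def funnel_points(obs_set: ObservationSet, fit: FitResult) -> tuple[pd.DataFrame, dict]:
    """Per-observation (residual, total SE) pairs plus reference lines for the
    modified funnel plot: null, mean effect, BPRF placeholder, and both
    interval half-widths are supplied by the caller via the lines dict."""
    resid, total_se, include = _residuals(obs_set, fit)
    df = pd.DataFrame(
        {
            "obs_id": obs_set.obs_ids,
            "residual_mean": resid,
            "residual_sd": total_se,
            "trimmed": ~include,
        }
    )
    lines = {
        "null": -fit.beta0,  # null effect relative to the fitted mean
        "mean": 0.0,
        "beta0": fit.beta0,
        "se_beta0": fit.se_beta0,
    }
    return df, lines
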