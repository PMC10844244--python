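"""Mixed-effects meta-regression of log relative risk.

The model is ``y_ij = x_ij' beta + u_i + eps_ij`` with a single study-level
random effect ``u_i ~ N(0, gamma)`` shared by every observation of study
``i`` (block all-ones covariance) and independent sampling noise
``eps_ij ~ N(0, s_ij^2)``.  The fixed-effect vector starts with the pooled
mean (intercept, the dichotomous-exposure effect) followed by optional bias
covariates, which may carry Gaussian ridge priors.

``gamma`` is estimated by maximum marginal likelihood with a non-negativity
bound.  For a fixed ``gamma`` the fixed effects have a closed-form penalized
GLS solution, so the optimization is a profiled one-dimensional search over
``ln gamma`` (quasi-Newton with jittered, seeded restarts).

Outlier handling is concentrated least-trimmed-squares: iterated
fit / rank standardized residuals / drop until the retained set is stable.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .observations import InvalidInputError, ObservationSet

__all__ = ["FitResult", "design_matrix", "marginal_loglik", "fit", "lts_trim"]

logger = logging.getLogger(__name__)

_LOG2PI = math.log(2.0 * math.pi)
#: trimming is disabled for sparse models
MIN_OBS_FOR_TRIMMING = 10


@dataclass
class FitResult:
    beta0: float
    beta_cov: dict[str, float]
    se_beta0: float
    gamma_hat: float
    trim_weights: dict[str, int]
    loglik: float
    n_obs_used: int
    converged: bool
    gamma_sd: float | None = None
    covariates: list[str] = field(default_factory=list)
    cov_beta: np.ndarray | None = None
    covariate_reference: dict[str, int] = field(default_factory=dict)

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.beta0] + [self.beta_cov[c] for c in self.covariates])

    def se_cov(self, name: str) -> float:
        """Standard error of a covariate coefficient."""
        j = 1 + self.covariates.index(name)
        return float(np.sqrt(self.cov_beta[j, j]))


def design_matrix(
    obs_set: ObservationSet,
    covariates: list[str] | None = None,
    covariate_reference: dict[str, int] | None = None,
) -> np.ndarray:
    """Intercept-as-exposure design plus selected 0/1 covariate columns.

    ``covariate_reference`` optionally recenters each covariate column at its
    gold-standard value so the intercept is the effect at the reference level.
    """
    covariates = covariates or []
    ref = covariate_reference or {}
    n = len(obs_set)
    X = np.ones((n, 1 + len(covariates)))
    for j, c in enumerate(covariates):
        X[:, 1 + j] = obs_set.covariate_column(c) - ref.get(c, 0)
    return X


def _study_blocks(study_ids: list[str], include: np.ndarray) -> list[np.ndarray]:
    by_study: dict[str, list[int]] = {}
    for i, s in enumerate(study_ids):
        if include[i]:
            by_study.setdefault(s, []).append(i)
    return [np.array(ix) for ix in by_study.values()]


def _block_ll(r: np.ndarray, d: np.ndarray, gamma: float) -> float:
    """Log density of one study block, N(r; 0, diag(d) + gamma * ones)."""
    t = float(np.sum(1.0 / d))
    c = gamma / (1.0 + gamma * t)
    quad = float(np.sum(r * r / d)) - c * float(np.sum(r / d)) ** 2
    logdet = float(np.sum(np.log(d))) + math.log1p(gamma * t)
    return -0.5 * (len(r) * _LOG2PI + logdet + quad)


def marginal_loglik(
    beta: np.ndarray,
    gamma: float,
    obs_set: ObservationSet,
    weights: np.ndarray | None = None,
    covariates: list[str] | None = None,
    covariate_reference: dict[str, int] | None = None,
) -> float:
    """Gaussian marginal log-likelihood with the study random effect
    integrated out: sum over studies of ``log N(y_i; X_i beta, S_i + gamma J_i)``.

    Only rows with weight 1 contribute.
    """
    if gamma < 0:
        raise InvalidInputError("gamma must be non-negative")
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    n = len(obs_set)
    include = np.ones(n, dtype=bool) if weights is None else np.asarray(weights).astype(bool)
    if not include.any():
        raise InvalidInputError("no observations included")
    X = design_matrix(obs_set, covariates, covariate_reference)
    resid = obs_set.y() - X @ beta
    var = obs_set.se() ** 2
    ll = 0.0
    for ix in _study_blocks(obs_set.study_ids, include):
        ll += _block_ll(resid[ix], var[ix], gamma)
    return ll


def _profiled(
    gamma: float,
    y: np.ndarray,
    X: np.ndarray,
    var: np.ndarray,
    blocks: list[np.ndarray],
    P: np.ndarray,
):
    """Penalized GLS at fixed gamma.

    Returns (penalized loglik, beta_hat, unpenalized loglik, A) with
    ``A = X' V^-1 X + P`` the curvature of the penalized objective in beta.
    """
    p = X.shape[1]
    A = P.copy()
    b = np.zeros(p)
    for ix in blocks:
        Xb, yb, db = X[ix], y[ix], var[ix]
        Xw = Xb / db[:, None]
        t = float(np.sum(1.0 / db))
        c = gamma / (1.0 + gamma * t)
        u = Xw.sum(axis=0)
        A += Xb.T @ Xw - c * np.outer(u, u)
        b += Xw.T @ yb - c * u * float(np.sum(yb / db))
    beta = np.linalg.solve(A, b)
    ll = 0.0
    resid = y - X @ beta
    for ix in blocks:
        ll += _block_ll(resid[ix], var[ix], gamma)
    return ll - 0.5 * float(beta @ P @ beta), beta, ll, A


def _moment_gamma(y: np.ndarray, var: np.ndarray) -> float:
    w = 1.0 / var
    mu = float(np.sum(w * y) / np.sum(w))
    return max(float(np.mean((y - mu) ** 2 - var)), 1e-4)


def fit(
    obs_set: ObservationSet,
    covariates: list[str] | None = None,
    trim_fraction: float = 0.0,
    seed: int = 0,
    prior_sds: dict[str, float] | None = None,
    covariate_reference: dict[str, int] | None = None,
    gamma: float | None = None,
    tol: float = 1e-8,
) -> FitResult:
    """Maximum-marginal-likelihood fit with optional LTS trimming.

    ``gamma`` may be pinned (e.g. 0 during covariate selection); otherwise it
    is estimated with a non-negativity bound.  ``prior_sds`` adds independent
    Gaussian (ridge) priors on covariate coefficients; the intercept is never
    penalized.  The seed affects only jittered optimizer restarts.
    """
    covariates = list(covariates or [])
    n = len(obs_set)
    if n < 1:
        raise InvalidInputError("need at least one observation")
    if not 0.0 <= trim_fraction < 0.5:
        raise InvalidInputError("trim_fraction must be in [0, 0.5)")

    if trim_fraction > 0 and n > MIN_OBS_FOR_TRIMMING:
        trim_weights = lts_trim(
            obs_set, trim_fraction, covariates, seed=seed,
            prior_sds=prior_sds, covariate_reference=covariate_reference,
        )
    else:
        if trim_fraction > 0:
            logger.info("trimming skipped: %d observations (need > %d)", n, MIN_OBS_FOR_TRIMMING)
        trim_weights = {o: 1 for o in obs_set.obs_ids}

    include = np.array([trim_weights[o] for o in obs_set.obs_ids], dtype=bool)
    return _fit_included(
        obs_set, include, covariates, seed, prior_sds, covariate_reference,
        gamma, tol, trim_weights,
    )


def _fit_included(
    obs_set, include, covariates, seed, prior_sds, covariate_reference,
    gamma_fixed, tol, trim_weights,
) -> FitResult:
    y = obs_set.y()
    var = obs_set.se() ** 2
    X = design_matrix(obs_set, covariates, covariate_reference)
    blocks = _study_blocks(obs_set.study_ids, include)
    p = X.shape[1]
    P = np.zeros((p, p))
    for j, c in enumerate(covariates):
        sd = (prior_sds or {}).get(c, 1.0)
        P[1 + j, 1 + j] = 1.0 / sd**2

    n_used = int(include.sum())
    n_studies = len(blocks)
    converged = True

    if gamma_fixed is not None:
        if gamma_fixed < 0:
            raise InvalidInputError("gamma must be non-negative")
        gamma_hat = float(gamma_fixed)
    elif n_studies < 2 or n_used < 2:
        warnings.warn(
            "between-study heterogeneity not identifiable with a single study; gamma set to 0",
            stacklevel=2,
        )
        gamma_hat = 0.0
    else:
        def neg(eta: np.ndarray) -> float:
            return -_profiled(math.exp(float(eta[0])), y, X, var, blocks, P)[0]

        rng = np.random.default_rng(seed)
        eta0 = math.log(_moment_gamma(y[include], var[include]))
        best_eta, best_val = None, np.inf
        ok = False
        for k in range(3):
            start = eta0 if k == 0 else eta0 + rng.normal(0, 2.0)
            res = optimize.minimize(
                neg, x0=[start], method="L-BFGS-B",
                bounds=[(-30.0, 6.0)], options={"ftol": tol, "gtol": 1e-10},
            )
            ok = ok or res.success
            if res.fun < best_val:
                best_val, best_eta = res.fun, float(res.x[0])
        converged = ok
        gamma_hat = math.exp(best_eta)
        # boundary check: prefer the gamma = 0 solution when it is as good
        if _profiled(0.0, y, X, var, blocks, P)[0] >= -best_val - 1e-10 or gamma_hat < 1e-12:
            gamma_hat = 0.0

    pll, beta, ll, A = _profiled(gamma_hat, y, X, var, blocks, P)
    cov_beta = np.linalg.inv(A)
    return FitResult(
        beta0=float(beta[0]),
        beta_cov={c: float(beta[1 + j]) for j, c in enumerate(covariates)},
        se_beta0=float(math.sqrt(cov_beta[0, 0])),
        gamma_hat=float(gamma_hat),
        trim_weights=dict(trim_weights),
        loglik=float(ll),
        n_obs_used=n_used,
        converged=bool(converged),
        covariates=covariates,
        cov_beta=cov_beta,
        covariate_reference=dict(covariate_reference or {}),
    )


def lts_trim(
    obs_set: ObservationSet,
    trim_fraction: float,
    covariates: list[str] | None = None,
    seed: int = 0,
    prior_sds: dict[str, float] | None = None,
    covariate_reference: dict[str, int] | None = None,
    max_iter: int = 100,
) -> dict[str, int]:
    """Concentrated least-trimmed-squares weights (1 = retained).

    The heterogeneity variance is estimated once on the full data and held
    fixed, so residuals are standardized by ``sqrt(se^2 + gamma_full)`` —
    the distance from the mean in total-SE units.  The retained subset of
    size ``h = ceil((1 - trim_fraction) n)`` minimizes the trimmed sum of
    squared standardized residuals under refitting of the fixed effects
    (concentration steps from an all-ones start plus seeded random restarts);
    ties broken toward the lexicographically smaller ``obs_id``.  Models with
    ``n <= 10`` are ineligible and keep every row.
    """
    covariates = list(covariates or [])
    n = len(obs_set)
    obs_ids = obs_set.obs_ids
    if n <= MIN_OBS_FOR_TRIMMING:
        logger.info("trimming ineligible at n=%d; keeping all observations", n)
        return {o: 1 for o in obs_ids}
    h = math.ceil((1.0 - trim_fraction) * n)

    y = obs_set.y()
    se = obs_set.se()
    X = design_matrix(obs_set, covariates, covariate_reference)
    p = X.shape[1]
    P = np.zeros((p, p))
    for j, c in enumerate(covariates):
        P[1 + j, 1 + j] = 1.0 / (prior_sds or {}).get(c, 1.0) ** 2

    full = _fit_included(
        obs_set, np.ones(n, dtype=bool), covariates, seed, prior_sds,
        covariate_reference, None, 1e-8, {o: 1 for o in obs_ids},
    )
    w = 1.0 / (se**2 + full.gamma_hat)

    def wls_beta(include: np.ndarray) -> np.ndarray:
        Xw = X[include] * w[include, None]
        return np.linalg.solve(X[include].T @ Xw + P, Xw.T @ y[include])

    def concentrate(include: np.ndarray) -> tuple[np.ndarray, float]:
        for _ in range(max_iter):
            z2 = w * (y - X @ wls_beta(include)) ** 2
            order = sorted(range(n), key=lambda i: (z2[i], obs_ids[i]))
            new = np.zeros(n, dtype=bool)
            new[order[:h]] = True
            if np.array_equal(new, include):
                break
            include = new
        z2 = w * (y - X @ wls_beta(include)) ** 2
        return include, float(z2[include].sum())

    rng = np.random.default_rng(seed)
    starts = [np.ones(n, dtype=bool)]
    for _ in range(3):
        s0 = np.zeros(n, dtype=bool)
        s0[rng.choice(n, size=h, replace=False)] = True
        starts.append(s0)
    best_inc, best_ssr = None, np.inf
    for s0 in starts:
        inc, ssr = concentrate(s0)
        if ssr < best_ssr - 1e-12:
            best_inc, best_ssr = inc, ssr
    return {o: int(k) for o, k in zip(obs_ids, best_inc)}
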