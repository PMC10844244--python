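"""Binary bias covariates: registry, eligibility, step-wise Lasso selection,
and gold-standard adjustment of observations.

Each covariate flags one dimension of systematic bias (confounder-adjustment
level, aggregate outcome definitions, product-specific exposure definitions,
sub-population samples, ascertainment, representativeness).  Selection runs an
L1 path on the covariate terms of the fixed-effects log-RR regression to order
candidates, then retains each in turn iff its ridge-refit coefficient is
significant; cascade children require their parent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from . import model as _model
from .observations import InvalidInputError, ObservationSet

__all__ = [
    "BiasCovariate",
    "SelectionResult",
    "DEFAULT_REGISTRY",
    "load_registry",
    "eligibility",
    "select",
    "apply_adjustment",
]


@dataclass(frozen=True)
class BiasCovariate:
    name: str
    gold_standard_value: int = 0
    cascade_parent: str | None = None
    prior_sd: float = 1.0


def _registry(*covs: BiasCovariate) -> dict[str, BiasCovariate]:
    reg = {}
    for c in covs:
        if c.name in reg:
            raise InvalidInputError(f"duplicate covariate name {c.name!r}")
        reg[c.name] = c
    _check_acyclic(reg)
    return reg


def _check_acyclic(reg: dict[str, BiasCovariate]) -> None:
    for start in reg:
        seen, cur = set(), start
        while cur is not None:
            if cur in seen:
                raise InvalidInputError(f"cascade cycle involving {start!r}")
            seen.add(cur)
            cur = reg[cur].cascade_parent if cur in reg else None


#: The ten candidate study-characteristic flags.  Gold standard 1 for the
#: confounding-control flags (observations adjusted toward full control),
#: 0 elsewhere (outcome-specific, broad-product, representative designs).
DEFAULT_REGISTRY = _registry(
    BiasCovariate("maximally_adjusted", gold_standard_value=1),
    BiasCovariate("adjusted_age_sex", gold_standard_value=1),
    BiasCovariate("adjusted_smoking_age_sex", gold_standard_value=1, cascade_parent="adjusted_age_sex"),
    BiasCovariate("aggregate_outcome", gold_standard_value=0),
    BiasCovariate("specific_product", gold_standard_value=0),
    BiasCovariate("subpopulation", gold_standard_value=0),
    BiasCovariate("exposure_ascertainment", gold_standard_value=0),
    BiasCovariate("outcome_ascertainment", gold_standard_value=0),
    BiasCovariate("representativeness", gold_standard_value=0),
    BiasCovariate("exposure_definition_deviation", gold_standard_value=0),
)


def load_registry(path) -> dict[str, BiasCovariate]:
    """Read a covariate registry from YAML or JSON:
    ``name: {gold_standard_value, cascade_parent, prior_sd}``."""
    text = open(path).read()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    covs = [
        BiasCovariate(
            name=name,
            gold_standard_value=int(spec.get("gold_standard_value", 0)),
            cascade_parent=spec.get("cascade_parent"),
            prior_sd=float(spec.get("prior_sd", 1.0)),
        )
        for name, spec in (raw or {}).items()
    ]
    return _registry(*covs)


@dataclass
class SelectionResult:
    selected: list[str]
    eligible: list[str]
    path: list[dict] = field(default_factory=list)


def eligibility(covariate: BiasCovariate, obs_set: ObservationSet) -> bool:
    """A covariate is testable iff both values occur in at least two
    observations."""
    col = obs_set.covariate_column(covariate.name)
    return int((col == 0).sum()) >= 2 and int((col == 1).sum()) >= 2


def _lasso_entry_order(
    y: np.ndarray, se: np.ndarray, cols: dict[str, np.ndarray],
    n_lambda: int = 60, lambda_min_ratio: float = 1e-3,
) -> tuple[list[str], list[dict]]:
    """Order covariates by first non-zero coefficient along a decreasing L1
    path on the whitened fixed-effects regression (intercept unpenalized)."""
    names = list(cols)
    w = 1.0 / se
    yt = y * w
    ic = w.copy()  # whitened intercept column
    Z = np.column_stack([(c - c.mean()) / (c.std() if c.std() > 0 else 1.0) for c in cols.values()])
    Zt = Z * w[:, None]

    # residual after the unpenalized intercept fit
    def resid(beta: np.ndarray, b0: float) -> np.ndarray:
        return yt - ic * b0 - Zt @ beta

    b0 = float(ic @ yt / (ic @ ic))
    lam_max = float(np.max(np.abs(Zt.T @ resid(np.zeros(len(names)), b0)))) if names else 0.0
    if lam_max <= 0:
        return [], []
    lams = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
    beta = np.zeros(len(names))
    colsq = (Zt**2).sum(axis=0)
    entry: dict[str, float] = {}
    path: list[dict] = []
    for lam in lams:
        for _ in range(300):
            delta = 0.0
            b0_new = float(ic @ (yt - Zt @ beta) / (ic @ ic))
            delta = max(delta, abs(b0_new - b0))
            b0 = b0_new
            r = resid(beta, b0)
            for j in range(len(names)):
                if colsq[j] == 0:
                    continue
                rho = float(Zt[:, j] @ r) + colsq[j] * beta[j]
                bj = math.copysign(max(abs(rho) - lam, 0.0), rho) / colsq[j]
                if bj != beta[j]:
                    r -= Zt[:, j] * (bj - beta[j])
                    delta = max(delta, abs(bj - beta[j]))
                    beta[j] = bj
            if delta < 1e-9:
                break
        for j, name in enumerate(names):
            if name not in entry and abs(beta[j]) > 1e-10:
                entry[name] = float(lam)
        path.append({"penalty": float(lam), "coef": {n: float(b) for n, b in zip(names, beta)}})
    order = sorted(entry, key=lambda n: (-entry[n], names.index(n)))
    return order, path


def select(
    obs_set: ObservationSet,
    candidates: list[BiasCovariate],
    seed: int = 0,
    z_threshold: float = 1.96,
) -> SelectionResult:
    """Step-wise Lasso covariate selection.

    Heterogeneity is profiled at zero during selection.  Candidates enter in
    L1-path order; each is retained iff its coefficient, refit without the L1
    penalty but with its Gaussian prior, satisfies ``|coef| / SE >= z``.
    Cascade children are dropped unless their parent is retained.
    """
    reg = {c.name: c for c in candidates}
    _check_acyclic(reg)
    eligible = [c.name for c in candidates if eligibility(c, obs_set)]
    if not eligible:
        return SelectionResult(selected=[], eligible=[])

    cols = {n: obs_set.covariate_column(n) for n in eligible}
    order, path = _lasso_entry_order(obs_set.y(), obs_set.se(), cols)

    prior_sds = {n: reg[n].prior_sd for n in eligible}
    kept: list[str] = []
    for name in order:
        trial = kept + [name]
        fit = _model.fit(obs_set, covariates=trial, gamma=0.0, seed=seed, prior_sds=prior_sds)
        coef, se = fit.beta_cov[name], fit.se_cov(name)
        if se > 0 and abs(coef) / se >= z_threshold:
            kept.append(name)

    # cascade: children may stay only if their parent stayed
    changed = True
    while changed:
        changed = False
        for name in list(kept):
            parent = reg[name].cascade_parent
            if parent is not None and parent not in kept:
                kept.remove(name)
                changed = True
    return SelectionResult(selected=kept, eligible=eligible, path=path)


def apply_adjustment(
    obs_set: ObservationSet,
    fit: _model.FitResult,
    selected: list[str],
    registry: dict[str, BiasCovariate] | None = None,
) -> ObservationSet:
    """Shift each observation toward the gold-standard covariate values:
    ``log_effect -= beta_c (x_c - gold_c)`` for every selected covariate."""
    registry = registry or DEFAULT_REGISTRY
    for c in selected:
        if c not in fit.beta_cov:
            raise InvalidInputError(f"selected covariate {c!r} missing from fit")
    out = []
    for o in obs_set:
        shift = 0.0
        for c in selected:
            gold = registry[c].gold_standard_value if c in registry else 0
            shift -= fit.beta_cov[c] * (o.covariates[c] - gold)
        f = math.exp(shift)
        out.append(
            replace(
                o,
                log_effect=o.log_effect + shift,
                effect=o.effect * f,
                ci_lower=o.ci_lower * f,
                ci_upper=o.ci_upper * f,
            )
        )
    return ObservationSet(out, outcome=obs_set.outcome, provenance=obs_set.provenance)
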