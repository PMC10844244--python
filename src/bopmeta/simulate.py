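"""Synthetic observation sets with known truth.

Generates effect-size tables with the structure the analysis assumes:
study-level random effects, observation-level sampling noise with
case-control-scale SEs, binary bias-covariate shifts, overlapping
observations sharing a study sample, gross outliers, and optional
significance-based selective reporting.  Everything is reproducible from
(config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy import stats

from .observations import Observation, ObservationSet
from .observations import InvalidInputError

__all__ = ["SimulationConfig", "SyntheticTruth", "generate", "make_paper_like_fixture", "load_config"]


@dataclass(frozen=True)
class SimulationConfig:
    n_studies: int = 20
    obs_per_study: int | tuple[int, int] = 1
    true_beta0: float = math.log(2.0)
    gamma: float = 0.0
    covariate_effects: dict[str, float] = field(default_factory=dict)
    covariate_prevalence: dict[str, float] = field(default_factory=dict)
    se_range: tuple[float, float] = (0.05, 0.6)
    overlap_fraction: float = 0.0
    outlier_fraction: float = 0.0
    outlier_shift: float = 0.0
    censor_nonsignificant_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name, p in [
            ("overlap_fraction", self.overlap_fraction),
            ("outlier_fraction", self.outlier_fraction),
            ("censor_nonsignificant_prob", self.censor_nonsignificant_prob),
            *[(f"prevalence[{k}]", v) for k, v in self.covariate_prevalence.items()],
        ]:
            if not 0.0 <= p <= 1.0:
                raise InvalidInputError(f"{name} must be in [0, 1]")
        if self.gamma < 0:
            raise InvalidInputError("gamma must be non-negative")
        lo, hi = self.se_range
        if not 0 < lo <= hi:
            raise InvalidInputError("se_range must satisfy 0 < low <= high")


@dataclass
class SyntheticTruth:
    config: SimulationConfig
    study_effects: dict[str, float]
    true_means: dict[str, float]
    outlier_flags: dict[str, bool]
    censored_obs: list[str]


def load_config(path) -> SimulationConfig:
    raw = yaml.safe_load(open(path)) or {}
    if "se_range" in raw:
        raw["se_range"] = tuple(raw["se_range"])
    if isinstance(raw.get("obs_per_study"), list):
        raw["obs_per_study"] = tuple(raw["obs_per_study"])
    return SimulationConfig(**raw)


def _obs_counts(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if isinstance(cfg.obs_per_study, tuple):
        lo, hi = cfg.obs_per_study
        return rng.integers(lo, hi + 1, size=cfg.n_studies)
    return np.full(cfg.n_studies, int(cfg.obs_per_study))


def generate(config: SimulationConfig, seed: int | None = None) -> tuple[ObservationSet, SyntheticTruth]:
    """Draw one observation set and its generating truth.

    ``y_ij ~ N(beta0 + sum_k beta_k x_ijk + u_i, s_ij^2)`` with
    ``u_i ~ N(0, gamma)`` and ``s_ij`` log-uniform over ``se_range``.
    Overlapping studies emit >= 2 observations sharing one overlap group (and
    the same random effect).  Outliers are shifted by ``outlier_shift``;
    censoring drops non-significant rows (``|y|/s < 1.96``) with the stated
    probability.  SEs are emitted raw — downweighting is a pipeline step.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.Generator(np.random.Philox(seed))
    z95 = stats.norm.ppf(0.975)
    cov_names = sorted(set(config.covariate_effects) | set(config.covariate_prevalence))

    counts = _obs_counts(config, rng)
    n_overlap = int(round(config.overlap_fraction * config.n_studies))
    overlap_studies = set(range(n_overlap))
    counts = np.array([max(c, 2) if i in overlap_studies else c for i, c in enumerate(counts)])

    u = rng.normal(0.0, math.sqrt(config.gamma), size=config.n_studies)
    lo, hi = config.se_range

    obs: list[Observation] = []
    study_effects: dict[str, float] = {}
    true_means: dict[str, float] = {}
    outlier_flags: dict[str, bool] = {}
    censored: list[str] = []
    for i in range(config.n_studies):
        sid = f"study_{i:04d}"
        study_effects[sid] = float(u[i])
        group = f"{sid}_grp" if i in overlap_studies else None
        for j in range(counts[i]):
            oid = f"{sid}_obs{j}"
            x = {
                k: int(rng.random() < config.covariate_prevalence.get(k, 0.5))
                for k in cov_names
            }
            mean = config.true_beta0 + sum(
                config.covariate_effects.get(k, 0.0) * x[k] for k in cov_names
            ) + u[i]
            s = math.exp(rng.uniform(math.log(lo), math.log(hi)))
            y = rng.normal(mean, s)
            is_outlier = rng.random() < config.outlier_fraction
            if is_outlier:
                y += config.outlier_shift
            if config.censor_nonsignificant_prob > 0 and abs(y) / s < z95:
                if rng.random() < config.censor_nonsignificant_prob:
                    censored.append(oid)
                    continue
            true_means[oid] = float(mean)
            outlier_flags[oid] = bool(is_outlier)
            obs.append(
                Observation(
                    obs_id=oid,
                    study_id=sid,
                    measure="RR",
                    effect=math.exp(y),
                    ci_lower=math.exp(y - z95 * s),
                    ci_upper=math.exp(y + z95 * s),
                    log_effect=y,
                    log_se=s,
                    raw_log_se=s,
                    covariates=x,
                    overlap_group=group,
                )
            )
    if not obs:
        raise InvalidInputError("configuration produced an empty observation set after censoring")
    truth = SyntheticTruth(config, study_effects, true_means, outlier_flags, censored)
    return ObservationSet(obs, outcome="synthetic", provenance=f"simulated(seed={seed})"), truth


#: (n_studies, n_obs, gamma, beta0) per named profile
_PROFILES = {
    "stroke-like": (3, 4, 0.0, math.log(1.46)),
    "esophageal-like": (22, 31, 0.09, math.log(2.14)),
    "lip-oral-like": (70, 106, 0.53, math.log(3.64)),
}


def make_paper_like_fixture(outcome_profile: str, seed: int = 0) -> ObservationSet:
    """Seeded fixture matching a named study/observation-count and
    heterogeneity profile; effect sizes are synthetic."""
    if outcome_profile not in _PROFILES:
        raise InvalidInputError(
            f"unknown profile {outcome_profile!r}; choose from {sorted(_PROFILES)}"
        )
    n_studies, n_obs, gamma, beta0 = _PROFILES[outcome_profile]
    extra = n_obs - n_studies
    cfg = SimulationConfig(
        n_studies=n_studies,
        obs_per_study=1,
        true_beta0=beta0,
        gamma=gamma,
        overlap_fraction=extra / n_studies,
        se_range=(0.08, 0.5),
        seed=seed,
    )
    obs_set, _ = generate(cfg)
    # the overlap mechanism gives the first `extra` studies 2 observations
    assert len(obs_set) == n_obs, (len(obs_set), n_obs)
    return ObservationSet(obs_set.observations, outcome=outcome_profile, provenance="fixture")
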