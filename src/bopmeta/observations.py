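"""Observation data model, harmonization into log space, CSV I/O, validation,
and overlap downweighting.

An :class:`Observation` is one extracted effect size (RR/OR/HR) with its 95%
interval, carried on both the ratio scale and the natural-log scale.  An
:class:`ObservationSet` is the per-outcome input table for the whole pipeline.
Observations from a non-mutually-exclusive analytical sample within a study
share an ``overlap_group``; their standard errors are inflated so the shared
sample is not over-represented in the fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Observation",
    "ObservationSet",
    "ValidationIssue",
    "se_from_interval",
    "log_or_from_counts",
    "harmonize",
    "downweight_overlaps",
    "validate",
    "read_csv",
    "write_csv",
    "to_frame",
]

MEASURES = ("RR", "OR", "HR")
SEXES = ("both", "male", "female")
TEMPORALITIES = ("current", "ever", "unspecified")
DESIGNS = (
    "prospective_cohort",
    "retrospective_cohort",
    "case_cohort",
    "nested_case_control",
    "case_control",
)

#: CSV schema, in column order. ``cv_``-prefixed covariate columns follow.
CSV_COLUMNS = [
    "obs_id",
    "study_id",
    "measure",
    "effect",
    "ci_lower",
    "ci_upper",
    "overlap_group",
    "sex",
    "exposure_definition",
    "exposure_temporality",
    "outcome_aggregate",
    "sample_size",
    "design",
]
DERIVED_COLUMNS = ["log_effect", "log_se", "raw_log_se"]


class InvalidInputError(ValueError):
    """Raised when a record or argument violates a precondition."""


@dataclass(frozen=True)
class Observation:
    """A single harmonized effect size in log space.

    ``log_se`` is the working standard error (after any overlap adjustment);
    ``raw_log_se`` is the extracted value before adjustment.  ``covariates``
    maps ``cv_``-stripped bias-covariate names to 0/1 flags.
    """

    obs_id: str
    study_id: str
    measure: str
    effect: float
    ci_lower: float
    ci_upper: float
    log_effect: float
    log_se: float
    raw_log_se: float
    covariates: dict[str, int] = field(default_factory=dict)
    overlap_group: str | None = None
    sex: str = "both"
    exposure_definition: str = "unspecified"
    exposure_temporality: str = "unspecified"
    outcome_aggregate: int = 0
    sample_size: int | None = None
    design: str = "case_control"


@dataclass
class ObservationSet:
    """Ordered collection of observations for one outcome."""

    observations: list[Observation]
    outcome: str = ""
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self):
        return iter(self.observations)

    @property
    def obs_ids(self) -> list[str]:
        return [o.obs_id for o in self.observations]

    @property
    def study_ids(self) -> list[str]:
        return [o.study_id for o in self.observations]

    @property
    def n_studies(self) -> int:
        return len(set(self.study_ids))

    def y(self) -> np.ndarray:
        return np.array([o.log_effect for o in self.observations], dtype=float)

    def se(self) -> np.ndarray:
        return np.array([o.log_se for o in self.observations], dtype=float)

    def covariate_names(self) -> list[str]:
        names: list[str] = []
        for o in self.observations:
            for k in o.covariates:
                if k not in names:
                    names.append(k)
        return names

    def covariate_column(self, name: str) -> np.ndarray:
        try:
            return np.array([o.covariates[name] for o in self.observations], dtype=float)
        except KeyError:
            raise InvalidInputError(f"covariate column {name!r} missing from observations")

    def subset(self, keep: list[bool] | np.ndarray) -> "ObservationSet":
        obs = [o for o, k in zip(self.observations, keep) if k]
        return ObservationSet(obs, outcome=self.outcome, provenance=self.provenance)


@dataclass(frozen=True)
class ValidationIssue:
    obs_id: str
    field: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.obs_id}: {self.field}: {self.rule}"


def se_from_interval(lower: float, upper: float, level: float = 0.95) -> float:
    """Standard error of the log effect from a ratio-scale confidence interval.

    Uses the full log-width: ``(ln upper - ln lower) / (2 z)`` with ``z`` the
    standard-normal quantile at ``(1 + level) / 2``.  A degenerate interval
    (``lower == upper``) returns 0.
    """
    if lower <= 0 or upper <= 0:
        raise InvalidInputError("interval bounds must be positive")
    if lower > upper:
        raise InvalidInputError("lower bound exceeds upper bound")
    if not 0 < level < 1:
        raise InvalidInputError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (math.log(upper) - math.log(lower)) / (2.0 * z)


def log_or_from_counts(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    """Log odds ratio and SE from a 2x2 table (exposed cases a, exposed
    controls b, unexposed cases c, unexposed controls d)."""
    if min(a, b, c, d) <= 0:
        raise InvalidInputError("all four cell counts must be positive")
    return math.log((a * d) / (b * c)), math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)


def harmonize(row: dict, level: float = 0.95) -> Observation:
    """Build an :class:`Observation` from a raw extracted record.

    The record must carry either a ratio-scale ``effect`` with ``ci_lower`` /
    ``ci_upper``, or ``log_effect`` with ``log_se``.  OR and HR values are kept
    as-is as approximations of the RR on the log scale; ``measure`` is
    retained as metadata.
    """
    row = dict(row)
    has_ci = _present(row.get("effect")) and _present(row.get("ci_lower")) and _present(row.get("ci_upper"))
    has_log = _present(row.get("log_effect")) and _present(row.get("log_se"))
    if not has_ci and not has_log:
        raise InvalidInputError(
            "record needs (effect, ci_lower, ci_upper) or (log_effect, log_se)"
        )

    if has_ci:
        effect = float(row["effect"])
        lo, hi = float(row["ci_lower"]), float(row["ci_upper"])
        if effect <= 0:
            raise InvalidInputError("effect must be positive")
        log_effect = math.log(effect)
        row_level = float(row.get("ci_level", level))
        raw_log_se = se_from_interval(lo, hi, row_level)
    else:
        log_effect = float(row["log_effect"])
        raw_log_se = float(row["log_se"])
        if raw_log_se <= 0:
            raise InvalidInputError("log_se must be positive")
        effect = math.exp(log_effect)
        z = stats.norm.ppf(0.5 + level / 2.0)
        lo, hi = math.exp(log_effect - z * raw_log_se), math.exp(log_effect + z * raw_log_se)

    covariates = {
        k[3:]: int(v) for k, v in row.items() if k.startswith("cv_") and _present(v)
    }
    measure = str(row.get("measure", "RR")).upper()
    if measure not in MEASURES:
        raise InvalidInputError(f"unknown measure {measure!r}")

    overlap = row.get("overlap_group")
    overlap = None if not _present(overlap) else str(overlap)

    n = row.get("sample_size")
    n = None if not _present(n) else int(float(n))

    return Observation(
        obs_id=str(row["obs_id"]),
        study_id=str(row["study_id"]),
        measure=measure,
        effect=effect,
        ci_lower=lo,
        ci_upper=hi,
        log_effect=log_effect,
        log_se=raw_log_se,
        raw_log_se=raw_log_se,
        covariates=covariates,
        overlap_group=overlap,
        sex=str(row.get("sex", "both")),
        exposure_definition=str(row.get("exposure_definition", "unspecified")),
        exposure_temporality=str(row.get("exposure_temporality", "unspecified")),
        outcome_aggregate=int(row.get("outcome_aggregate", 0) or 0),
        sample_size=n,
        design=str(row.get("design", "case_control")),
    )


def downweight_overlaps(obs_set: ObservationSet, factor: str = "sqrt") -> ObservationSet:
    """Inflate standard errors of overlapping observations.

    Each overlap group of size ``k`` gets ``log_se = raw_log_se * k**p`` with
    ``p = 1/2`` (default, group information equals one average observation) or
    ``p = 1`` when ``factor == "linear"``.  Singletons and ungrouped rows are
    left at their raw SE.
    """
    if factor not in ("sqrt", "linear"):
        raise InvalidInputError("factor must be 'sqrt' or 'linear'")
    power = 0.5 if factor == "sqrt" else 1.0

    sizes: dict[str, int] = {}
    studies: dict[str, set] = {}
    for o in obs_set:
        if o.overlap_group is not None:
            sizes[o.overlap_group] = sizes.get(o.overlap_group, 0) + 1
            studies.setdefault(o.overlap_group, set()).add(o.study_id)
    for g, s in studies.items():
        if len(s) > 1:
            raise InvalidInputError(f"overlap group {g!r} spans multiple studies: {sorted(s)}")

    out = []
    for o in obs_set:
        k = sizes.get(o.overlap_group, 1) if o.overlap_group is not None else 1
        out.append(replace(o, log_se=o.raw_log_se * k**power))
    return ObservationSet(out, outcome=obs_set.outcome, provenance=obs_set.provenance)


def validate(obs_set: ObservationSet) -> list[ValidationIssue]:
    """Check all invariants; returns one issue record per violation."""
    issues: list[ValidationIssue] = []
    seen: set[str] = set()
    for o in obs_set:
        if o.obs_id in seen:
            issues.append(ValidationIssue(o.obs_id, "obs_id", "duplicate obs_id"))
        seen.add(o.obs_id)
        if not (o.ci_lower > 0 and o.ci_upper > 0 and o.effect > 0):
            issues.append(ValidationIssue(o.obs_id, "effect", "effect and CI bounds must be positive"))
            continue
        if not o.ci_lower <= o.effect <= o.ci_upper:
            issues.append(ValidationIssue(o.obs_id, "ci_lower", "CI must bracket the effect"))
        if abs(o.log_effect - math.log(o.effect)) > 1e-12:
            issues.append(ValidationIssue(o.obs_id, "log_effect", "log_effect != ln(effect)"))
        if o.log_se <= 0:
            issues.append(ValidationIssue(o.obs_id, "log_se", "log_se must be positive"))
        elif o.log_se < o.raw_log_se - 1e-12:
            issues.append(ValidationIssue(o.obs_id, "log_se", "downweighting must not shrink SE"))
        for name, v in o.covariates.items():
            if v not in (0, 1):
                issues.append(ValidationIssue(o.obs_id, f"cv_{name}", "covariate values must be 0 or 1"))
        if o.measure not in MEASURES:
            issues.append(ValidationIssue(o.obs_id, "measure", f"measure must be one of {MEASURES}"))
        if o.sex not in SEXES:
            issues.append(ValidationIssue(o.obs_id, "sex", f"sex must be one of {SEXES}"))
        if o.design not in DESIGNS:
            issues.append(ValidationIssue(o.obs_id, "design", f"design must be one of {DESIGNS}"))

    group_studies: dict[str, set] = {}
    for o in obs_set:
        if o.overlap_group is not None:
            group_studies.setdefault(o.overlap_group, set()).add(o.study_id)
    for g, s in group_studies.items():
        if len(s) > 1:
            issues.append(ValidationIssue(g, "overlap_group", "overlap group spans multiple studies"))
    return issues


def to_frame(obs_set: ObservationSet) -> pd.DataFrame:
    """Observation set as a flat table in the CSV schema plus derived columns."""
    cov_names = obs_set.covariate_names()
    rows = []
    for o in obs_set:
        r = {
            "obs_id": o.obs_id,
            "study_id": o.study_id,
            "measure": o.measure,
            "effect": o.effect,
            "ci_lower": o.ci_lower,
            "ci_upper": o.ci_upper,
            "overlap_group": o.overlap_group if o.overlap_group is not None else "",
            "sex": o.sex,
            "exposure_definition": o.exposure_definition,
            "exposure_temporality": o.exposure_temporality,
            "outcome_aggregate": o.outcome_aggregate,
            "sample_size": o.sample_size if o.sample_size is not None else "",
            "design": o.design,
        }
        for c in cov_names:
            r[f"cv_{c}"] = o.covariates.get(c, 0)
        r["log_effect"] = o.log_effect
        r["log_se"] = o.log_se
        r["raw_log_se"] = o.raw_log_se
        rows.append(r)
    cols = CSV_COLUMNS + [f"cv_{c}" for c in cov_names] + DERIVED_COLUMNS
    return pd.DataFrame(rows, columns=cols)


def write_csv(obs_set: ObservationSet, path) -> None:
    to_frame(obs_set).to_csv(path, index=False, float_format="%.12g")


def read_csv(path, outcome: str = "") -> ObservationSet:
    """Read an observation table, harmonizing each row into log space.

    If the table already carries ``log_se`` (a previously written set), the
    working SE is taken from it so a downweighted table round-trips.
    """
    df = pd.read_csv(path, dtype={"obs_id": str, "study_id": str, "overlap_group": str})
    obs = []
    for _, row in df.iterrows():
        rec = row.to_dict()
        o = harmonize(rec)
        if _present(rec.get("log_se")) and _present(rec.get("raw_log_se")):
            o = replace(o, log_se=float(rec["log_se"]), raw_log_se=float(rec["raw_log_se"]))
        obs.append(o)
    return ObservationSet(obs, outcome=outcome, provenance=str(path))


def _present(v) -> bool:
    if v is None:
        return False
    if isinstance(v, float) and math.isnan(v):
        return False
    if isinstance(v, str) and v.strip() == "":
        return False
    return True
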