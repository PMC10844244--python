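"""Per-outcome orchestration: downweighting, covariate selection, trimmed
mixed-effects fit, heterogeneity-aware intervals, conservative scoring,
publication-bias test, sensitivity grid, and report rendering."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import covariates as _cov
from . import model as _model
from . import observations as _obs
from . import pubbias as _pub
from .burden import RiskSummary, summarize
from .heterogeneity import summarize_heterogeneity
from .observations import InvalidInputError, ObservationSet

__all__ = ["RunConfig", "run_model", "run_sensitivity_grid", "render_report"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    input_path: str | None = None
    outcome: str = ""
    trim_fraction: float = 0.10
    registry_path: str | None = None
    covariate_selection: bool = True
    downweight: bool = True
    overlap_factor: str = "sqrt"
    filters: dict = field(default_factory=dict)
    alpha: float = 0.05
    level: float = 0.95
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(open(path)) or {}
        return cls(**raw)

    def echo(self) -> dict:
        return dataclasses.asdict(self)


def _apply_filters(obs_set: ObservationSet, filters: dict) -> ObservationSet:
    """Conjunctive row filters on observation metadata."""
    keep = []
    min_n = filters.get("min_sample_size")
    for o in obs_set:
        ok = True
        if "exposure_temporality" in filters:
            ok &= o.exposure_temporality == filters["exposure_temporality"]
        if "sex" in filters:
            ok &= o.sex == filters["sex"]
        if filters.get("outcome_specific_only"):
            ok &= o.outcome_aggregate == 0
        if min_n is not None:
            ok &= o.sample_size is not None and o.sample_size > min_n
        if "exposure_definition" in filters:
            ok &= o.exposure_definition == filters["exposure_definition"]
        if "exclude_obs" in filters:
            ok &= o.obs_id not in set(filters["exclude_obs"])
        keep.append(ok)
    return obs_set.subset(keep)


def run_model(config: RunConfig, obs_set: ObservationSet | None = None) -> RiskSummary:
    """Execute the full per-outcome analysis; deterministic given config+seed."""
    if obs_set is None:
        if config.input_path is None:
            raise InvalidInputError("no input path or observation set supplied")
        obs_set = _obs.read_csv(config.input_path, outcome=config.outcome)

    issues = _obs.validate(obs_set)
    if issues:
        raise InvalidInputError(
            "input validation failed:\n" + "\n".join(str(i) for i in issues)
        )
    obs_set = _apply_filters(obs_set, config.filters)
    if len(obs_set) < 1:
        raise InvalidInputError("no observations left after filtering")

    if config.downweight:
        obs_set = _obs.downweight_overlaps(obs_set, factor=config.overlap_factor)

    registry = (
        _cov.load_registry(config.registry_path)
        if config.registry_path
        else _cov.DEFAULT_REGISTRY
    )
    available = set(obs_set.covariate_names())
    candidates = [c for name, c in registry.items() if name in available]

    selected: list[str] = []
    if config.covariate_selection and candidates:
        sel = _cov.select(obs_set, candidates, seed=config.seed)
        selected = sel.selected
        logger.info("selected bias covariates: %s", selected or "none")

    prior_sds = {c.name: c.prior_sd for c in candidates}
    reference = {c.name: c.gold_standard_value for c in candidates}
    fit = _model.fit(
        obs_set,
        covariates=selected,
        trim_fraction=config.trim_fraction,
        seed=config.seed,
        prior_sds=prior_sds,
        covariate_reference=reference,
    )
    het = summarize_heterogeneity(obs_set, fit, q=0.95)
    fit.gamma_sd = het.gamma_sd

    n_untrimmed = sum(fit.trim_weights.values())
    pub = None
    if n_untrimmed >= 3:
        pub = _pub.eggers_test(obs_set, fit, alpha=config.alpha)
    else:
        logger.info("Egger's test skipped: %d untrimmed observations", n_untrimmed)

    used = obs_set.subset([bool(fit.trim_weights[o]) for o in obs_set.obs_ids])
    summary = summarize(
        fit,
        het,
        pub,
        outcome=config.outcome or obs_set.outcome,
        n_studies=used.n_studies,
        selected_covariates=selected,
        level=config.level,
    )
    summary._fit = fit  # attach internals for reporting
    summary._obs_set = obs_set
    return summary


def run_sensitivity_grid(config: RunConfig, grid: list[dict], obs_set: ObservationSet | None = None) -> pd.DataFrame:
    """One row per (variant x {trim, no-trim}).

    Each variant is ``{"name": ..., "filters": {...}, **config overrides}``.
    Variants with fewer than 3 observations after filtering are infeasible;
    the trimming cell requires more than 10 observations.
    """
    if not grid:
        raise InvalidInputError("empty sensitivity grid")
    if obs_set is None and config.input_path is not None:
        obs_set = _obs.read_csv(config.input_path, outcome=config.outcome)

    rows = []
    for variant in grid:
        variant = dict(variant)
        name = variant.pop("name", "variant")
        extra_filters = variant.pop("filters", {})
        overrides = {k: v for k, v in variant.items() if k in RunConfig.__dataclass_fields__}
        base = replace(config, filters={**config.filters, **extra_filters}, **overrides)
        n_after = len(_apply_filters(obs_set, base.filters)) if obs_set is not None else None
        for trim in (True, False):
            row = {"variant": name, "trimming": trim, "feasible": True,
                   "ros": None, "stars": None, "n_obs": n_after}
            if n_after is not None and n_after < 3:
                row["feasible"] = False
                rows.append(row)
                continue
            if trim and n_after is not None and n_after <= _model.MIN_OBS_FOR_TRIMMING:
                row["feasible"] = False
                rows.append(row)
                continue
            cfg = replace(base, trim_fraction=base.trim_fraction if trim else 0.0)
            try:
                s = run_model(cfg, obs_set)
            except InvalidInputError:
                row["feasible"] = False
                rows.append(row)
                continue
            row["ros"] = s.ros
            row["stars"] = s.stars
            rows.append(row)
    return pd.DataFrame(rows)


def render_report(summary: RiskSummary, output_dir, config: RunConfig | None = None) -> dict[str, Path]:
    """Write the forest plot, funnel plot, result row (CSV + JSON), and a
    config echo into ``output_dir``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fit = getattr(summary, "_fit", None)
    obs_set = getattr(summary, "_obs_set", None)
    files: dict[str, Path] = {}

    row = summary.as_dict()
    files["json"] = out / "summary.json"
    files["json"].write_text(json.dumps(row, indent=2))
    files["csv"] = out / "summary.csv"
    pd.DataFrame([row]).to_csv(files["csv"], index=False)
    if config is not None:
        files["config"] = out / "config_echo.yaml"
        files["config"].write_text(yaml.safe_dump(config.echo()))

    if fit is None or obs_set is None:
        return files

    # forest plot
    fig, ax = plt.subplots(figsize=(7, max(2.5, 0.3 * len(obs_set) + 1.5)))
    ys = np.arange(len(obs_set))[::-1]
    for o, yy in zip(obs_set, ys):
        trimmed = not fit.trim_weights.get(o.obs_id, 1)
        color = "red" if trimmed else "black"
        marker = "x" if trimmed else "o"
        ax.plot([o.ci_lower, o.ci_upper], [yy, yy], color=color, lw=1)
        ax.plot([o.effect], [yy], marker=marker, color=color, ms=4)
        label = o.obs_id + ("*" if o.overlap_group else "")
        ax.text(-0.02, yy, label, transform=ax.get_yaxis_transform(),
                ha="right", va="center", fontsize=7)
    ax.axvline(1.0, color="k", ls=":", lw=1)
    ax.axvline(summary.rr, color="tab:blue", lw=1.5)
    ax.axvspan(*summary.ui_no_gamma, color="tab:blue", alpha=0.35)
    ax.axvspan(*summary.ui_with_gamma, color="tab:blue", alpha=0.15)
    if summary.bprf is not None:
        ax.axvline(summary.bprf, color="tab:red", lw=1.5)
    ax.set_xscale("log")
    ax.set_xlabel("relative risk")
    ax.set_yticks([])
    ax.set_title(summary.outcome or "forest")
    fig.tight_layout()
    for ext in ("png", "svg"):
        p = out / f"forest.{ext}"
        fig.savefig(p)
        files[f"forest_{ext}"] = p
    plt.close(fig)

    # funnel plot
    df, _lines = _pub.funnel_points(obs_set, fit)
    files["funnel_table"] = out / "funnel_points.csv"
    df.to_csv(files["funnel_table"], index=False)
    fig, ax = plt.subplots(figsize=(5, 5))
    kept = ~df["trimmed"]
    ax.plot(df.loc[kept, "residual_mean"], df.loc[kept, "residual_sd"], "o", color="k", ms=4)
    if (~kept).any():
        ax.plot(df.loc[~kept, "residual_mean"], df.loc[~kept, "residual_sd"], "x", color="red", ms=5)
    ax.axvline(-summary.beta0, color="grey", ls=":", label="null")
    ax.axvline(0.0, color="tab:blue", label="mean")
    if summary.bprf is not None:
        ax.axvline(np.log(summary.bprf) - summary.beta0, color="tab:red", label="conservative 5th quantile")
    ax.invert_yaxis()
    ax.set_xlabel("residual of log RR")
    ax.set_ylabel("total SE")
    ax.legend(fontsize=7)
    fig.tight_layout()
    for ext in ("png", "svg"):
        p = out / f"funnel.{ext}"
        fig.savefig(p)
        files[f"funnel_{ext}"] = p
    plt.close(fig)
    return files
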