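import json

import numpy as np
import pytest

from bopmeta.covariates import (
    DEFAULT_REGISTRY,
    BiasCovariate,
    apply_adjustment,
    eligibility,
    load_registry,
    select,
)
from bopmeta.model import fit
from bopmeta.observations import InvalidInputError, ObservationSet

from conftest import make_set


def _sim_set(rng, n=40, beta0=0.0, effects=None, n_cov=1, s=0.15, names=None):
    names = names or [f"c{j}" for j in range(n_cov)]
    effects = effects or {}
    x = {name: rng.integers(0, 2, size=n) for name in names}
    ys = beta0 + sum(effects.get(k, 0.0) * x[k] for k in names) + rng.normal(0, s, size=n)
    return make_set(ys, [s] * n, covariates={k: v for k, v in x.items()})


class TestEligibility:
    @pytest.mark.parametrize(
        "values,expected",
        [((0, 0, 1, 1), True), ((0, 0, 0, 1), False), ((0, 0, 0, 0), False), ((1, 1, 1, 1), False)],
    )
    def test_two_per_value_rule(self, values, expected):
        s = make_set([0.1] * 4, [0.1] * 4, covariates={"flag": list(values)})
        assert eligibility(BiasCovariate("flag"), s) is expected

    def test_missing_column(self):
        s = make_set([0.1] * 4, [0.1] * 4)
        with pytest.raises(InvalidInputError):
            eligibility(BiasCovariate("nope"), s)


class TestSelect:
    def test_no_candidates(self):
        s = make_set([0.1] * 6, [0.1] * 6)
        res = select(s, [])
        assert res.selected == [] and res.eligible == []

    def test_constant_columns_not_selected(self):
        s = make_set([0.1] * 6, [0.1] * 6, covariates={"flag": [0] * 6})
        res = select(s, [BiasCovariate("flag")])
        assert res.selected == [] and res.eligible == []
        # and the covariate-free model is unchanged
        assert fit(s).beta0 == pytest.approx(fit(s, covariates=[]).beta0)

    def test_strong_covariate_selected(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            s = _sim_set(rng, n=40, effects={"c0": 0.8})
            hits += "c0" in select(s, [BiasCovariate("c0")], seed=seed).selected
        assert hits >= 48  # >= 95% selection rate

    def test_null_false_selection_rate(self):
        names = [f"c{j}" for j in range(10)]
        false_hits = 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            s = _sim_set(rng, n=40, n_cov=10)
            false_hits += len(select(s, [BiasCovariate(n) for n in names], seed=seed).selected)
        # per-candidate false-selection rate <= 10%
        assert false_hits / (n_rep * 10) <= 0.10

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        s = _sim_set(rng, n=30, effects={"c0": 0.7}, n_cov=2)
        res1 = select(s, [BiasCovariate("c0"), BiasCovariate("c1")])
        perm = np.random.default_rng(1).permutation(len(s))
        shuffled = ObservationSet([s.observations[i] for i in perm])
        res2 = select(shuffled, [BiasCovariate("c0"), BiasCovariate("c1")])
        assert res1.selected == res2.selected

    def test_cascade_child_requires_parent(self):
        rng = np.random.default_rng(3)
        # child column carries a real shift, parent is pure noise
        n = 40
        child = rng.integers(0, 2, size=n)
        parent = rng.integers(0, 2, size=n)
        ys = 0.9 * child + rng.normal(0, 0.15, size=n)
        s = make_set(ys, [0.15] * n, covariates={"parent": parent, "child": child})
        cands = [BiasCovariate("parent"), BiasCovariate("child", cascade_parent="parent")]
        res = select(s, cands)
        assert "child" not in res.selected or "parent" in res.selected

    def test_cycle_rejected(self):
        cands = [
            BiasCovariate("a", cascade_parent="b"),
            BiasCovariate("b", cascade_parent="a"),
        ]
        s = make_set([0.1] * 6, [0.1] * 6, covariates={"a": [0, 1, 0, 1, 0, 1], "b": [1, 0, 1, 0, 1, 0]})
        with pytest.raises(InvalidInputError):
            select(s, cands)


class TestApplyAdjustment:
    def test_gold_standard_unchanged(self):
        s = make_set([0.5, 0.5], [0.1, 0.1], covariates={"flag": [0, 1]})
        r = fit(s, covariates=["flag"], gamma=0.0)
        out = apply_adjustment(s, r, ["flag"], {"flag": BiasCovariate("flag", gold_standard_value=0)})
        assert out.observations[0].log_effect == s.observations[0].log_effect

    def test_direct_shift(self):
        s = make_set([0.5, 0.8], [0.1, 0.1], covariates={"flag": [0, 1]})
        r = fit(s, covariates=["flag"], gamma=0.0)
        r.beta_cov["flag"] = 0.3
        out = apply_adjustment(s, r, ["flag"], {"flag": BiasCovariate("flag", gold_standard_value=0)})
        assert out.observations[1].log_effect == pytest.approx(0.8 - 0.3, rel=1e-12)
        # ratio-scale fields shifted consistently
        assert out.observations[1].effect == pytest.approx(np.exp(0.5), rel=1e-12)

    def test_adjustment_toward_gold_one(self):
        s = make_set([0.5, 0.8], [0.1, 0.1], covariates={"flag": [0, 1]})
        r = fit(s, covariates=["flag"], gamma=0.0)
        r.beta_cov["flag"] = 0.3
        out = apply_adjustment(s, r, ["flag"], {"flag": BiasCovariate("flag", gold_standard_value=1)})
        assert out.observations[0].log_effect == pytest.approx(0.5 + 0.3, rel=1e-12)
        assert out.observations[1].log_effect == pytest.approx(0.8, rel=1e-12)

    def test_missing_coefficient(self):
        s = make_set([0.5, 0.8], [0.1, 0.1], covariates={"flag": [0, 1]})
        r = fit(s, gamma=0.0)
        with pytest.raises(InvalidInputError):
            apply_adjustment(s, r, ["flag"])

    def test_self_consistency_refit(self):
        rng = np.random.default_rng(12)
        s = _sim_set(rng, n=60, beta0=0.4, effects={"c0": 0.6})
        r = fit(s, covariates=["c0"], gamma=0.0)
        adj = apply_adjustment(s, r, ["c0"], {"c0": BiasCovariate("c0", gold_standard_value=0)})
        r2 = fit(adj, covariates=["c0"], gamma=0.0)
        assert abs(r2.beta_cov["c0"]) < 2 * r2.se_cov("c0")


class TestRegistry:
    def test_default_has_ten_acyclic(self):
        assert len(DEFAULT_REGISTRY) == 10
        assert DEFAULT_REGISTRY["adjusted_smoking_age_sex"].cascade_parent == "adjusted_age_sex"

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "reg.yaml"
        p.write_text(
            "maximally_adjusted:\n  gold_standard_value: 1\n"
            "subpopulation:\n  prior_sd: 0.5\n"
            "child:\n  cascade_parent: maximally_adjusted\n"
        )
        reg = load_registry(p)
        assert reg["maximally_adjusted"].gold_standard_value == 1
        assert reg["subpopulation"].prior_sd == 0.5
        assert reg["child"].cascade_parent == "maximally_adjusted"

    def test_json(self, tmp_path):
        p = tmp_path / "reg.json"
        p.write_text(json.dumps({"flag": {"gold_standard_value": 1}}))
        assert load_registry(p)["flag"].gold_standard_value == 1

    def test_cyclic_registry_rejected(self, tmp_path):
        p = tmp_path / "reg.yaml"
        p.write_text("a:\n  cascade_parent: b\nb:\n  cascade_parent: a\n")
        with pytest.raises(InvalidInputError):
            load_registry(p)
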