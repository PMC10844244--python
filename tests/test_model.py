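import itertools
import math

import numpy as np
import pytest
from scipy import stats

from bopmeta.model import fit, lts_trim, marginal_loglik
from bopmeta.observations import InvalidInputError, ObservationSet

from conftest import make_obs, make_set


class TestMarginalLoglik:
    def test_single_obs_exact_density(self):
        s = make_set([0.5], [0.1])
        ll = marginal_loglik(np.array([0.5]), 0.0, s)
        assert ll == pytest.approx(stats.norm.logpdf(0.5, 0.5, 0.1), rel=1e-12)
        assert ll == pytest.approx(-math.log(math.sqrt(2 * math.pi) * 0.1), rel=1e-12)

    def test_gamma_zero_is_wls_loglik(self, rng):
        ys = rng.normal(0.3, 0.2, size=8)
        ses = rng.uniform(0.1, 0.4, size=8)
        s = make_set(ys, ses, study_ids=["a", "a", "b", "b", "c", "c", "d", "d"])
        ll = marginal_loglik(np.array([0.3]), 0.0, s)
        assert ll == pytest.approx(stats.norm.logpdf(ys, 0.3, ses).sum(), rel=1e-12)

    def test_matches_dense_mvn_oracle(self, rng):
        # 6 observations in 3 studies vs a full block-covariance MVN density
        ys = rng.normal(0.5, 0.3, size=6)
        ses = rng.uniform(0.1, 0.5, size=6)
        studies = ["a", "a", "a", "b", "b", "c"]
        gamma = 0.07
        s = make_set(ys, ses, study_ids=studies)
        V = np.diag(ses**2)
        for st_id in set(studies):
            ix = [i for i, x in enumerate(studies) if x == st_id]
            V[np.ix_(ix, ix)] += gamma
        oracle = stats.multivariate_normal.logpdf(ys, mean=np.full(6, 0.4), cov=V)
        assert marginal_loglik(np.array([0.4]), gamma, s) == pytest.approx(oracle, rel=1e-10)

    def test_negative_gamma_rejected(self):
        with pytest.raises(InvalidInputError):
            marginal_loglik(np.array([0.0]), -0.1, make_set([0.0], [0.1]))

    def test_empty_inclusion_rejected(self):
        with pytest.raises(InvalidInputError):
            marginal_loglik(np.array([0.0]), 0.0, make_set([0.0], [0.1]), weights=np.array([0]))

    def test_order_and_relabel_invariance(self, rng):
        ys = rng.normal(0, 0.5, size=6)
        ses = rng.uniform(0.1, 0.4, size=6)
        studies = ["a", "b", "a", "c", "b", "c"]
        base = marginal_loglik(np.array([0.1]), 0.05, make_set(ys, ses, study_ids=studies))
        perm = rng.permutation(6)
        relabel = {"a": "z9", "b": "q1", "c": "m5"}
        shuffled = make_set(ys[perm], ses[perm], study_ids=[relabel[studies[i]] for i in perm])
        assert marginal_loglik(np.array([0.1]), 0.05, shuffled) == pytest.approx(base, rel=1e-12)


class TestFit:
    def test_single_observation(self):
        with pytest.warns(UserWarning, match="single study"):
            r = fit(make_set([0.5], [0.1]))
        assert r.beta0 == pytest.approx(0.5, abs=1e-10)
        assert r.gamma_hat == 0.0
        assert r.se_beta0 == pytest.approx(0.1, rel=1e-9)

    def test_two_studies_grid_oracle(self):
        s_val = 0.3
        r = fit(make_set([0.0, 1.0], [s_val, s_val]))
        assert r.beta0 == pytest.approx(0.5, abs=1e-6)
        # closed form: ML variance 0.25 so gamma = 0.25 - s^2
        assert r.gamma_hat == pytest.approx(0.25 - s_val**2, abs=1e-6)
        # 1-D grid search oracle on the profile likelihood
        grid = np.linspace(0.0, 1.0, 20001)
        obs = make_set([0.0, 1.0], [s_val, s_val])
        lls = [marginal_loglik(np.array([0.5]), g, obs) for g in grid]
        assert r.gamma_hat == pytest.approx(grid[int(np.argmax(lls))], abs=1e-4)

    def test_gamma_boundary_at_zero(self):
        # homogeneous data: ML gamma is 0
        r = fit(make_set([0.2, 0.2, 0.2], [0.3, 0.3, 0.3]))
        assert r.gamma_hat == 0.0

    def test_fixed_effects_closed_form(self, rng):
        ys = rng.normal(0.4, 0.3, size=9)
        ses = rng.uniform(0.1, 0.5, size=9)
        r = fit(make_set(ys, ses), gamma=0.0)
        w = 1.0 / ses**2
        assert r.beta0 == pytest.approx(float(np.sum(w * ys) / np.sum(w)), rel=1e-10)
        assert r.se_beta0 == pytest.approx(float(np.sum(w) ** -0.5), rel=1e-10)

    def test_shift_equivariance(self, rng):
        ys = rng.normal(0.0, 0.4, size=12)
        ses = rng.uniform(0.1, 0.4, size=12)
        studies = [f"s{i // 2}" for i in range(12)]
        a = fit(make_set(ys, ses, study_ids=studies), seed=1)
        b = fit(make_set(ys + 0.7, ses, study_ids=studies), seed=1)
        assert b.beta0 == pytest.approx(a.beta0 + 0.7, abs=1e-6)
        assert b.gamma_hat == pytest.approx(a.gamma_hat, abs=1e-6)
        assert b.se_beta0 == pytest.approx(a.se_beta0, rel=1e-6)

    def test_deterministic_given_seed(self, rng):
        ys = rng.normal(0.3, 0.4, size=15)
        ses = rng.uniform(0.1, 0.4, size=15)
        a = fit(make_set(ys, ses), trim_fraction=0.1, seed=7)
        b = fit(make_set(ys, ses), trim_fraction=0.1, seed=7)
        assert (a.beta0, a.gamma_hat, a.se_beta0) == (b.beta0, b.gamma_hat, b.se_beta0)
        assert a.trim_weights == b.trim_weights

    def test_trim_fraction_bounds(self):
        with pytest.raises(InvalidInputError):
            fit(make_set([0.0, 1.0], [0.1, 0.1]), trim_fraction=0.6)

    def test_empty_set_rejected(self):
        with pytest.raises(InvalidInputError):
            fit(ObservationSet([]))


class TestLtsTrim:
    def test_gross_outlier(self):
        ys = [0.01 * i for i in range(11)] + [10.0]
        ses = [0.1] * 12
        w = lts_trim(make_set(ys, ses), 0.1)
        assert sum(w.values()) == 11
        assert w["o011"] == 0

    def test_ineligible_at_ten(self):
        ys = list(np.linspace(-1, 1, 10))
        w = lts_trim(make_set(ys, [0.1] * 10), 0.1)
        assert all(v == 1 for v in w.values())

    def test_fit_skips_trimming_at_ten(self):
        ys = list(np.linspace(-1, 1, 10))
        r = fit(make_set(ys, [0.1] * 10), trim_fraction=0.1)
        assert all(v == 1 for v in r.trim_weights.values())

    def test_matches_enumeration_oracle(self):
        # brute force over all C(12, 11) retained subsets, scored by the
        # trimmed sum of squared standardized residuals with the refitted
        # weighted mean (heterogeneity fixed at its full-data estimate)
        rng = np.random.default_rng(42)
        ys = rng.normal(0.5, 0.6, size=12)
        ses = rng.uniform(0.1, 0.4, size=12)
        obs = make_set(ys, ses)
        h = math.ceil(0.9 * 12)
        wts = 1.0 / (np.asarray(ses) ** 2 + fit(obs, seed=0).gamma_hat)
        best, best_ssr = None, np.inf
        for keep in itertools.combinations(range(12), h):
            ix = list(keep)
            beta = float(np.sum(wts[ix] * np.asarray(ys)[ix]) / np.sum(wts[ix]))
            ssr = float(np.sum(wts[ix] * (np.asarray(ys)[ix] - beta) ** 2))
            if ssr < best_ssr:
                best_ssr, best = ssr, set(keep)
        w = lts_trim(obs, 0.1, seed=0)
        retained = {i for i, o in enumerate(obs.obs_ids) if w[o] == 1}
        assert retained == best


def test_parameter_recovery_smoke(rng):
    # small-scale version of the full recovery experiment (see acceptance)
    from bopmeta.simulate import SimulationConfig, generate

    b_est, g_est = [], []
    for rep in range(40):
        s, _ = generate(SimulationConfig(n_studies=50, true_beta0=math.log(2), gamma=0.1, seed=rep))
        r = fit(s, seed=rep)
        b_est.append(r.beta0)
        g_est.append(r.gamma_hat)
    assert np.mean(b_est) == pytest.approx(math.log(2), abs=0.05)
    assert np.mean(g_est) == pytest.approx(0.1, abs=0.05)
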