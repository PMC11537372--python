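import numpy as np
import pandas as pd
import pytest

from disaggval.model_search import (
    CovariateSpec,
    ModelSpec,
    SearchConfig,
    enumerate_model_space,
    expected_space_size,
    fit_baseline,
    fit_candidate,
    fit_model_space,
    information_criteria,
    offset_constant,
    rank_models,
)


class TestOffsetConstant:
    def test_half_minimum_nonzero(self):
        assert offset_constant([0, 2, 8]) == 1.0
        assert offset_constant([5, 5, 5]) == 2.5

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            offset_constant([0.0, 0.0])


class TestFitBaseline:
    def test_noise_free_log_relationship_gives_perfect_fit(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.5, 10, 40)
        y = 2.0 + 1.5 * np.log(x)
        res = fit_baseline(y, x, transform="log")
        assert res.converged
        assert res.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_coefficients_match_normal_equations_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.1, 2.9, 4.2, 4.8, 6.1])
        res = fit_baseline(y, x, transform="linear")
        # normal equations for simple regression
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        intercept = y.mean() - slope * x.mean()
        assert res.fit.params[0] == pytest.approx(intercept, abs=1e-9)
        assert res.fit.params[1] == pytest.approx(slope, abs=1e-9)

    def test_independent_response_has_near_zero_adj_r2(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(1, 10, 50)
        y = rng.normal(size=50)
        vals = []
        for _ in range(200):
            vals.append(fit_baseline(rng.permutation(y), x, transform="log").adj_r2)
        vals = np.array(vals)
        assert abs(vals.mean()) < 0.05
        assert np.quantile(vals, 0.95) < 0.15

    def test_constant_covariate_flagged_not_converged(self):
        res = fit_baseline([1.0, 2.0, 3.0], [4.0, 4.0, 4.0], transform="linear")
        assert not res.converged


class TestEnumeration:
    def test_minimal_configuration_yields_single_spec(self):
        cfg = SearchConfig(
            cass_types=("production",),
            cass_distances=(0,),
            cass_summaries=("mean",),
            cass_forms=("linear",),
            include_population=False,
            include_settlement=False,
            allow_joint_2d=False,
        )
        specs = enumerate_model_space(cfg)
        assert len(specs) == 1 == expected_space_size(cfg)

    def test_sixteen_spec_example(self):
        # 2 types x distances {0, 2} x {mean} x 4 forms = 2 x 2 x 4 = 16
        cfg = SearchConfig(
            cass_distances=(0, 2),
            cass_summaries=("mean",),
            include_population=False,
            include_settlement=False,
            allow_joint_2d=False,
        )
        specs = enumerate_model_space(cfg)
        assert len(specs) == 16 == expected_space_size(cfg)

    def test_full_default_configuration_matches_closed_form_count(self):
        cfg = SearchConfig()
        specs = enumerate_model_space(cfg)
        assert len(specs) == expected_space_size(cfg)
        assert len(specs) == len({s.key() for s in specs})  # deduplicated

    def test_point_extraction_forces_mean_summary(self):
        cfg = SearchConfig(
            cass_distances=(0,),
            cass_summaries=("median", "sd"),
            include_population=False,
            include_settlement=False,
            allow_joint_2d=False,
        )
        specs = enumerate_model_space(cfg)
        assert all(s.cassava.statistic == "mean" for s in specs)

    def test_invalid_configurations_rejected(self):
        with pytest.raises(ValueError):
            SearchConfig(cass_types=())
        with pytest.raises(ValueError):
            SearchConfig(cass_distances=(0, 7))
        with pytest.raises(ValueError):
            ModelSpec("y", CovariateSpec("production", 0, "median", "linear"))


def _toy_data(n=120, seed=5):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.5, 10, n)
    pop = rng.uniform(1, 100, n)
    y = 1.0 + np.sin(x) + rng.normal(0, 0.1, n)
    return pd.DataFrame(
        {
            "tot_density": y,
            "production_0km_mean": x,
            "population_0km_mean": pop,
        }
    )


class TestFitCandidate:
    def test_linear_spec_matches_baseline_fit(self):
        data = _toy_data()
        spec = ModelSpec("tot_density", CovariateSpec("production", 0, "mean", "log"))
        cand = fit_candidate(spec, data)
        base = fit_baseline(data["tot_density"], data["production_0km_mean"], transform="log")
        assert cand.loglik == pytest.approx(base.loglik, abs=1e-9)
        assert cand.aic == pytest.approx(base.aic, abs=1e-9)
        assert cand.p == base.p

    def test_spline_spec_recovers_sine(self):
        data = _toy_data()
        spec = ModelSpec("tot_density", CovariateSpec("production", 0, "mean", "spline"))
        res = fit_candidate(spec, data)
        assert res.converged
        assert res.spec.modeltype == "gam"
        assert np.corrcoef(res.fit.fitted, np.sin(data["production_0km_mean"]))[0, 1] > 0.95

    def test_spline2d_uses_tensor_and_reports_gam(self):
        data = _toy_data()
        spec = ModelSpec(
            "tot_density",
            CovariateSpec("production", 0, "mean", "linear"),
            population=CovariateSpec("population", 0, "mean", "spline2d"),
        )
        res = fit_candidate(spec, data)
        assert res.converged
        assert res.spec.modeltype == "gam"

    def test_degenerate_covariate_retained_as_non_converged(self):
        data = _toy_data(n=30)
        data["production_0km_mean"] = 1.0
        spec = ModelSpec("tot_density", CovariateSpec("production", 0, "mean", "linear"))
        res = fit_candidate(spec, data)
        assert not res.converged
        assert np.isnan(res.aic)


class TestInformationCriteria:
    def test_as_printed_formula_at_p_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        aic, bic, _ = information_criteria(-5.0, 0, 3, y, y, convention="as_printed")
        assert aic == 5.0
        assert bic == 5.0

    def test_perfect_fit_gives_adj_r2_one(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        _, _, adj = information_criteria(0.0, 2, 4, y, y)
        assert adj == 1.0

    def test_gaussian_ols_closed_form(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=10)
        y = 2 + x + rng.normal(size=10)
        X = np.column_stack([np.ones(10), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        fitted = X @ beta
        rss = np.sum((y - fitted) ** 2)
        sigma2 = rss / 10
        loglik = -(10 / 2) * (np.log(2 * np.pi * sigma2) + 1)
        aic, bic, adj = information_criteria(loglik, 2, 10, y, fitted)
        assert aic == pytest.approx(-2 * loglik + 4, abs=1e-9)
        assert bic == pytest.approx(-2 * loglik + np.log(10) * 2, abs=1e-9)
        expected_adj = 1 - (rss / 8) / (np.sum((y - y.mean()) ** 2) / 9)
        assert adj == pytest.approx(expected_adj, abs=1e-9)

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError):
            information_criteria(0.0, 1, 5, np.ones(5), np.ones(5), convention="other")


class TestRankModels:
    def _results(self):
        data = _toy_data()
        cfg = SearchConfig(
            cass_types=("production",),
            cass_distances=(0,),
            cass_summaries=("mean",),
            include_population=False,
            include_settlement=False,
            allow_joint_2d=False,
        )
        return fit_model_space(enumerate_model_space(cfg), data)

    def test_lowest_aic_ranks_first(self):
        results = self._results()
        table, best = rank_models(results)
        assert best.aic == min(r.aic for r in results if r.converged)
        assert table["AIC"].is_monotonic_increasing

    def test_ranking_invariant_under_permutation(self):
        results = self._results()
        t1, b1 = rank_models(results)
        t2, b2 = rank_models(list(reversed(results)))
        pd.testing.assert_frame_equal(t1, t2)
        assert b1.spec == b2.spec

    def test_aic_tie_broken_by_smaller_p(self):
        results = self._results()
        a, b = results[0], results[1]
        a.aic = b.aic = -12.0
        a.p, b.p = 5, 3
        _, best = rank_models([a, b])
        assert best.p == 3

    def test_no_converged_results_rejected(self):
        r = self._results()[0]
        r.converged = False
        with pytest.raises(ValueError):
            rank_models([r])


def test_nested_linear_models_have_non_decreasing_loglik():
    data = _toy_data()
    small = ModelSpec("tot_density", CovariateSpec("production", 0, "mean", "linear"))
    big = ModelSpec(
        "tot_density",
        CovariateSpec("production", 0, "mean", "linear"),
        population=CovariateSpec("population", 0, "mean", "linear"),
    )
    r_small = fit_candidate(small, data)
    r_big = fit_candidate(big, data)
    assert r_big.loglik >= r_small.loglik - 1e-9


def test_conventions_agree_on_ordering_of_equal_p_models():
    rng = np.random.default_rng(77)
    for _ in range(500):
        ll1, ll2 = rng.normal(0, 50, 2)
        p = rng.integers(1, 10)
        n = int(rng.integers(p + 2, 200))
        y = rng.normal(size=n)
        a1s, _, _ = information_criteria(ll1, p, n, y, y, "standard")
        a2s, _, _ = information_criteria(ll2, p, n, y, y, "standard")
        a1p, _, _ = information_criteria(ll1, p, n, y, y, "as_printed")
        a2p, _, _ = information_criteria(ll2, p, n, y, y, "as_printed")
        assert np.sign(a1s - a2s) == np.sign(a1p - a2p)
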