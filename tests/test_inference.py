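"""Design matrix, OLS, sandwich covariances, and the two effect models."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from conftest import did_2x2_oracle, make_records, sandwich_oracle
from mpaeval import (
    BeforeAfterEstimator,
    DesignError,
    DifferenceInDifferencesRegressor,
    ValidationError,
    before_after_effect,
    build_design_matrix,
    did_effect,
    ols_fit,
    robust_vcov,
    t_and_p,
)
from mpaeval.surveys import transect_units


def balanced_table(means, years=(2005, 2007), n=6, rng=None, noise=0.0):
    """Tidy indicator table with given cell means keyed (zone, period)."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for zi, zone in enumerate(("control", "reserve")):
        for yi, year in enumerate(years):
            mu = means[(zone, "post" if yi else "pre")]
            for t in range(n):
                rows.append({
                    "site": zone, "zone": zone, "year": year,
                    "transect": f"T{t}",
                    "value": mu + (noise * rng.normal() if noise else 0.0),
                })
    return pd.DataFrame(rows)


class TestDesignMatrix:
    def test_two_year_column_count(self):
        tab = balanced_table({("control", "pre"): 5, ("control", "post"): 8,
                              ("reserve", "pre"): 10, ("reserve", "post"): 20})
        rng = np.random.default_rng(0)
        for c in ("temperature", "visibility", "depth"):
            tab[c] = rng.normal(10, 2, len(tab))
        _, X, _ = build_design_matrix(tab, 2006)
        assert X.shape[1] == 7  # const + 1 year + Z + PZ + 3 covariates

    def test_eleven_year_column_count(self):
        rng = np.random.default_rng(1)
        rows = []
        for zone in ("control", "reserve"):
            for year in range(2006, 2017):
                for t in range(3):
                    rows.append({"zone": zone, "year": year,
                                 "transect": f"T{t}",
                                 "value": rng.normal(),
                                 "temperature": rng.normal(18, 1),
                                 "visibility": rng.uniform(5, 10),
                                 "depth": rng.uniform(5, 20)})
        _, X, _ = build_design_matrix(pd.DataFrame(rows), 2007)
        assert X.shape[1] == 16  # const + 10 years + Z + PZ + 3 covariates

    def test_single_zone_is_design_error(self):
        tab = balanced_table({("control", "pre"): 5, ("control", "post"): 8,
                              ("reserve", "pre"): 10, ("reserve", "post"): 20})
        with pytest.raises(DesignError, match="zone"):
            build_design_matrix(tab[tab["zone"] == "reserve"], 2006)

    def test_no_post_period_is_design_error(self):
        tab = balanced_table({("control", "pre"): 5, ("control", "post"): 8,
                              ("reserve", "pre"): 10, ("reserve", "post"): 20})
        with pytest.raises(DesignError, match="post-implementation"):
            build_design_matrix(tab, implementation_year=2099)

    def test_covariate_fallback_when_mostly_missing(self, caplog):
        tab = balanced_table({("control", "pre"): 5, ("control", "post"): 8,
                              ("reserve", "pre"): 10, ("reserve", "post"): 20})
        tab["temperature"] = np.nan
        tab["visibility"] = np.nan
        tab["depth"] = np.nan
        _, X, info = build_design_matrix(tab, 2006)
        assert info["used_covariates"] == ()
        assert X.shape[1] == 4


class TestOlsAndSandwich:
    def test_constant_response(self):
        tab = balanced_table({k: 4.0 for k in [("control", "pre"),
                                               ("control", "post"),
                                               ("reserve", "pre"),
                                               ("reserve", "post")]})
        y, X, _ = build_design_matrix(tab, 2006)
        fr = ols_fit(y, X)
        assert fr.params["const"] == pytest.approx(4.0)
        for term in fr.params.index[1:]:
            assert fr.params[term] == pytest.approx(0.0, abs=1e-10)

    def test_exact_linear_covariate_r2_one(self):
        rng = np.random.default_rng(2)
        tab = balanced_table({("control", "pre"): 0, ("control", "post"): 0,
                              ("reserve", "pre"): 0, ("reserve", "post"): 0})
        tab["temperature"] = rng.normal(18, 2, len(tab))
        tab["value"] = 3.0 * tab["temperature"] - 5
        y, X, _ = build_design_matrix(tab, 2006,
                                      covariates=("temperature",))
        fr = ols_fit(y, X)
        assert fr.rsquared == pytest.approx(1.0)

    def test_did_reduces_to_difference_of_differences(self):
        tab = balanced_table({("control", "pre"): 5, ("control", "post"): 8,
                              ("reserve", "pre"): 10, ("reserve", "post"): 20})
        eff = did_effect(tab, 2006)
        assert eff.beta == pytest.approx((20 - 10) - (8 - 5), abs=1e-12)

    @pytest.mark.parametrize("flavor", ["HC0", "HC1", "HC2", "HC3"])
    def test_sandwich_matches_bruteforce_oracle(self, flavor):
        rng = np.random.default_rng(7)
        X = np.column_stack([np.ones(20), rng.normal(size=(20, 2))])
        beta = rng.normal(size=3)
        y = X @ beta + rng.normal(size=20) * (1 + np.abs(X[:, 1]))
        e = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        got = robust_vcov(X, e, flavor)
        want = sandwich_oracle(X, e, flavor)
        np.testing.assert_allclose(got, want, rtol=1e-10)

    def test_hc1_is_scaled_hc0(self):
        rng = np.random.default_rng(8)
        X = np.column_stack([np.ones(25), rng.normal(size=(25, 3))])
        e = rng.normal(size=25)
        n, k = X.shape
        np.testing.assert_allclose(robust_vcov(X, e, "HC1"),
                                   robust_vcov(X, e, "HC0") * n / (n - k),
                                   rtol=1e-12)

    def test_matches_statsmodels_covariances(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(9)
        X = np.column_stack([np.ones(30), rng.normal(size=(30, 2))])
        y = rng.normal(size=30)
        res = sm.OLS(y, X).fit()
        for flavor, attr in [("HC0", "cov_HC0"), ("HC1", "cov_HC1"),
                             ("HC2", "cov_HC2"), ("HC3", "cov_HC3")]:
            np.testing.assert_allclose(robust_vcov(X, res.resid, flavor),
                                       getattr(res, attr), rtol=1e-9)

    def test_noiseless_fit_zero_sandwich(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        y = 2 + 3 * X[:, 1]
        e = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(robust_vcov(X, e, "HC0"), 0, atol=1e-18)

    def test_unknown_flavor_rejected(self):
        with pytest.raises(ValidationError):
            robust_vcov(np.ones((5, 1)), np.zeros(5), "HC9")


class TestTAndP:
    @pytest.mark.parametrize("est, se, t4", [
        (10344.85, 3982.20, 2.5978),
        (14372.85, 3634.64, 3.9544),
        (-5800.46, 1867.50, -3.1060),
        (131.49, 185.66, 0.7082),
    ])
    def test_published_income_ratios(self, est, se, t4):
        t, p = t_and_p(est, se, df=13)
        assert round(t, 4) == t4

    def test_zero_estimate(self):
        t, p = t_and_p(0.0, 1.5, 10)
        assert t == 0 and p == 1

    def test_zero_se_flags_infinite_t(self):
        t, p = t_and_p(2.0, 0.0, 10)
        assert np.isinf(t) and p == 0


class TestEstimators:
    def test_sklearn_protocol(self):
        est = DifferenceInDifferencesRegressor(implementation_year=2006,
                                               cov_type="HC3")
        params = est.get_params()
        assert params["cov_type"] == "HC3"
        est2 = clone(est).set_params(cov_type="HC0")
        assert est2.get_params()["cov_type"] == "HC0"
        assert not hasattr(est2, "effect_")

    def test_row_order_and_transect_label_invariance(self):
        rng = np.random.default_rng(11)
        tab = balanced_table({("control", "pre"): 5, ("control", "post"): 9,
                              ("reserve", "pre"): 7, ("reserve", "post"): 16},
                             n=10, rng=rng, noise=2.0)
        e1 = did_effect(tab, 2006)
        shuffled = tab.sample(frac=1.0, random_state=3).copy()
        shuffled["transect"] = [f"Q{i}" for i in range(len(shuffled))]
        e2 = did_effect(shuffled, 2006)
        assert e1.beta == pytest.approx(e2.beta, rel=1e-12)
        assert e1.se == pytest.approx(e2.se, rel=1e-12)

    def test_post_from_convention_switch(self):
        tab = balanced_table({("control", "pre"): 5, ("control", "post"): 8,
                              ("reserve", "pre"): 10, ("reserve", "post"): 20},
                             years=(2005, 2006))
        # with post-from impl-year, 2006 is post; with impl-year+1 there is
        # no post year at all and the design is degenerate
        assert did_effect(tab, 2006).beta == pytest.approx(7.0)
        with pytest.raises(DesignError):
            did_effect(tab, 2006, post_from="impl-year+1")

    def test_before_after_difference_of_means(self):
        s = pd.Series({2003: 1.0, 2004: 2.0, 2005: 3.0,
                       2006: 4.0, 2007: 5.0, 2008: 6.0})
        eff = before_after_effect(s, 2006)
        assert eff.beta == pytest.approx(3.0, abs=1e-12)
        assert eff.causal is False

    def test_before_after_constant_series(self):
        s = pd.Series({y: 2.5 for y in range(2000, 2008)})
        eff = before_after_effect(s, 2004)
        assert eff.beta == pytest.approx(0.0, abs=1e-12)

    def test_before_after_constructed_shift(self):
        s = pd.Series({2004: 100.0, 2005: 120.0,
                       2006: 174.2, 2007: 174.2})
        eff = before_after_effect(s, 2006)
        assert eff.beta == pytest.approx(64.20, abs=1e-10)

    def test_before_after_one_sided_is_error(self):
        s = pd.Series({2006: 1.0, 2007: 2.0, 2008: 1.5})
        with pytest.raises(DesignError):
            before_after_effect(s, 2006)

    def test_did_matches_2x2_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            means = {(z, p): float(rng.normal(10, 4))
                     for z in ("control", "reserve") for p in ("pre", "post")}
            tab = balanced_table(means, n=int(rng.integers(3, 9)), rng=rng,
                                 noise=1.5)
            eff = did_effect(tab, 2006)
            assert eff.beta == pytest.approx(
                did_2x2_oracle(tab, 2006), rel=1e-10, abs=1e-10)


class TestSimulationCalibration:
    def test_null_pvalues_uniform(self):
        """Under no effect, DiD p-values are uniform across seeds (KS test)."""
        import scipy.stats
        from dataclasses import replace
        from mpaeval.simulate import COUNTS_ONLY, simulate_baci
        from mpaeval import compute_indicator_table

        spec0 = replace(COUNTS_ONLY, years=tuple(range(2003, 2009)),
                        implementation_year=2006)
        pvals = []
        seeds = np.random.SeedSequence(42).generate_state(200) % (2**31)
        for s in seeds:
            rec = simulate_baci(replace(spec0, seed=int(s)))
            tab = compute_indicator_table(rec, indicators=("B4",))
            tab = tab[(tab["community"] == "invertebrate")
                      & (tab["scope"] == "all")]
            pvals.append(did_effect(tab, 2006).p)
        assert scipy.stats.kstest(pvals, "uniform").pvalue > 0.01
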