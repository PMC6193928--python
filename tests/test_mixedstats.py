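import warnings

import numpy as np
import pandas as pd
import pytest

from driftwatch.errors import InsufficientDataError, InvalidParameterError
from driftwatch.mixedstats import (
    RandomSpec,
    build_design,
    centre_scale,
    fit_lmm,
    kendall_tau,
    nakagawa_r2,
    stepwise_aic,
)

from conftest import utc


def simulate_lmm(
    seed,
    n_groups=25,
    per_group=80,
    beta=(1.0, 0.4, -0.2, 0.0),
    re_sd=0.3,
    resid_sd=1.0,
    slope_sd=0.0,
):
    """Draw from a known random-intercept (optionally random-slope) LMM.

    Covariates: x1 binary (a 'period'-like indicator), x2 and x3 continuous.
    beta = (intercept, x1, x2, x3).
    """
    rng = np.random.default_rng(seed)
    n = n_groups * per_group
    g = np.repeat(np.arange(n_groups), per_group)
    x1 = rng.integers(0, 2, n).astype(float)
    x1 = (x1 - x1.mean()) / x1.std(ddof=1)  # z-scored, like the pipeline design
    x2 = rng.normal(size=n)
    x3 = rng.normal(size=n)
    b0 = rng.normal(0, re_sd, n_groups)
    b1 = rng.normal(0, slope_sd, n_groups) if slope_sd else np.zeros(n_groups)
    y = (
        beta[0]
        + beta[1] * x1
        + beta[2] * x2
        + beta[3] * x3
        + b0[g]
        + b1[g] * x2
        + rng.normal(0, resid_sd, n)
    )
    return pd.DataFrame(dict(y=y, x1=x1, x2=x2, x3=x3, g=g))


class TestFitLmm:
    def test_recovers_known_effects_within_tolerance(self):
        errs = []
        for seed in range(5):
            tab = simulate_lmm(seed)
            fit = fit_lmm(tab, "y", ["x1", "x2", "x3"], RandomSpec("g"))
            errs.append(
                [
                    fit.terms["x1"].estimate - 0.4,
                    fit.terms["x2"].estimate + 0.2,
                    fit.terms["x3"].estimate,
                ]
            )
            assert fit.terms["x1"].p < 0.05 and fit.terms["x1"].estimate > 0
        assert np.max(np.abs(errs)) < 0.06

    def test_agrees_with_statsmodels_random_intercept(self):
        import statsmodels.formula.api as smf

        tab = simulate_lmm(1, n_groups=20, per_group=50)
        fit = fit_lmm(tab, "y", ["x1", "x2"], RandomSpec("g"))
        sm = smf.mixedlm("y ~ x1 + x2", tab, groups=tab["g"]).fit(reml=True)
        assert fit.terms["intercept"].estimate == pytest.approx(
            sm.fe_params["Intercept"], abs=1e-4
        )
        assert fit.terms["x1"].estimate == pytest.approx(sm.fe_params["x1"], abs=1e-4)
        assert fit.sigma2_e == pytest.approx(sm.scale, rel=1e-3)
        assert fit.cov_re[0, 0] == pytest.approx(sm.cov_re.iloc[0, 0], rel=2e-3)

    def test_r2_plugin_formula_closed_form(self):
        r2m, r2c = nakagawa_r2(1.0, 1.0, 2.0)
        assert r2m == pytest.approx(0.25)
        assert r2c == pytest.approx(0.50)

    def test_zero_random_variance_gives_equal_r2_and_ols_betas(self):
        tab = simulate_lmm(2, re_sd=0.0, n_groups=10, per_group=60)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_lmm(tab, "y", ["x1", "x2", "x3"], RandomSpec("g"))
        assert fit.r2_marginal == pytest.approx(fit.r2_conditional, abs=1e-6)
        X = np.column_stack(
            [np.ones(len(tab)), tab[["x1", "x2", "x3"]].to_numpy()]
        )
        ols = np.linalg.lstsq(X, tab["y"].to_numpy(), rcond=None)[0]
        assert np.allclose(fit.beta, ols, atol=1e-6)

    def test_one_observation_per_group_degenerates_to_ols(self):
        rng = np.random.default_rng(9)
        n = 200
        tab = pd.DataFrame(
            dict(
                y=rng.normal(size=n),
                x1=rng.normal(size=n),
                g=np.arange(n),
            )
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_lmm(tab, "y", ["x1"], RandomSpec("g"))
        X = np.column_stack([np.ones(n), tab["x1"].to_numpy()])
        ols = np.linalg.lstsq(X, tab["y"].to_numpy(), rcond=None)[0]
        assert np.allclose(fit.beta, ols, atol=1e-6)

    def test_satterthwaite_df_bounded_by_ols_residual_df(self):
        tab = simulate_lmm(3, n_groups=12, per_group=30, slope_sd=0.2)
        fit = fit_lmm(tab, "y", ["x1", "x2"], RandomSpec("g", slopes=("x2",)))
        n, p = len(tab), 3
        for term in fit.terms.values():
            assert 1.0 <= term.df <= n - p
        # the grouped structure must shrink the intercept's effective df far
        # below the residual df
        assert fit.terms["intercept"].df < 30

    def test_r2_ordering_invariant(self):
        for seed in range(4):
            tab = simulate_lmm(seed, slope_sd=0.2)
            fit = fit_lmm(tab, "y", ["x1", "x2"], RandomSpec("g", slopes=("x2",)))
            assert 0.0 <= fit.r2_marginal <= fit.r2_conditional <= 1.0

    def test_single_level_grouping_is_insufficient(self):
        tab = simulate_lmm(0, n_groups=1)
        with pytest.raises(InsufficientDataError):
            fit_lmm(tab, "y", ["x1"], RandomSpec("g"))


class TestStepwise:
    def test_null_covariate_eliminated_strong_ones_retained(self):
        removed_null, kept_strong = 0, 0
        for seed in range(10):
            tab = simulate_lmm(seed, n_groups=15, per_group=40)
            sel, final, trace = stepwise_aic(
                tab, "y", ("x1", "x2", "x3"), RandomSpec("g")
            )
            removed_null += "x3" not in sel
            kept_strong += ("x1" in sel) and ("x2" in sel)
            assert trace and all("aic" in step for step in trace)
        assert removed_null >= 8
        assert kept_strong == 10

    def test_all_strong_covariates_keep_full_model(self):
        tab = simulate_lmm(4, beta=(1.0, 0.5, -0.5, 0.5))
        sel, final, _ = stepwise_aic(tab, "y", ("x1", "x2", "x3"), RandomSpec("g"))
        assert set(sel) == {"x1", "x2", "x3"}

    def test_deterministic_given_data(self):
        tab = simulate_lmm(5)
        a = stepwise_aic(tab, "y", ("x1", "x2", "x3"), RandomSpec("g"))
        b = stepwise_aic(tab, "y", ("x1", "x2", "x3"), RandomSpec("g"))
        assert a[0] == b[0]
        assert a[1].aic == b[1].aic


class TestKendall:
    def test_perfect_concordance_and_discordance(self):
        x = np.arange(10.0)
        assert kendall_tau(x, x)[0] == pytest.approx(1.0)
        assert kendall_tau(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_brute_force_counting_with_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(5, 41))
            x = rng.integers(0, 8, n).astype(float)  # heavy ties
            y = rng.integers(0, 8, n).astype(float)
            tau, _ = kendall_tau(x, y)
            conc = disc = 0
            for i in range(n):
                for j in range(i + 1, n):
                    s = np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
                    conc += s > 0
                    disc += s < 0
            n0 = n * (n - 1) / 2
            tx = sum(c * (c - 1) / 2 for c in np.unique(x, return_counts=True)[1])
            ty = sum(c * (c - 1) / 2 for c in np.unique(y, return_counts=True)[1])
            denom = np.sqrt((n0 - tx) * (n0 - ty))
            if denom == 0:
                continue
            assert tau == pytest.approx((conc - disc) / denom, abs=1e-12)

    def test_small_sample_p_by_enumeration(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        tau, p = kendall_tau(x, x)
        assert p == pytest.approx(2 / 720, abs=1e-12)  # only ±identity orderings

    def test_permutation_p_is_seeded_and_reproducible(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert kendall_tau(x, y, seed=7) == kendall_tau(x, y, seed=7)


class TestDesignAndScaling:
    def _inputs(self):
        bins = pd.date_range(utc("2017-04-01"), periods=24, freq="1h")
        eggs = pd.Series(np.arange(24.0), index=bins)
        bleak = pd.DataFrame(
            {"b1": np.tile([1.0, 0.0], 12), "b2": 0.5}, index=bins
        )
        temp = pd.DataFrame(
            {"timestamp": bins, "temp_c": np.linspace(7, 8, 24)}
        )
        from driftwatch import diel

        dayf = diel.day_fraction(bins)
        return eggs, bleak, temp, dayf

    def test_egg_and_bleak_table_shapes(self):
        eggs, bleak, temp, dayf = self._inputs()
        egg_tab, flagged = build_design(eggs, bleak, temp, dayf, "eggs")
        bleak_tab, _ = build_design(eggs, bleak, temp, dayf, "bleak")
        assert len(egg_tab) == 24 and flagged == 0
        assert len(bleak_tab) == 48
        assert set(bleak_tab["bleak_id"]) == {"b1", "b2"}

    def test_missing_temperature_hours_flagged_and_dropped(self):
        eggs, bleak, temp, dayf = self._inputs()
        temp = temp.iloc[:20]  # last hours >90 min from any reading
        egg_tab, flagged = build_design(eggs, bleak, temp, dayf, "eggs")
        assert flagged == 3 and len(egg_tab) == 21

    def test_scaled_columns_have_zero_mean_unit_sd(self):
        eggs, bleak, temp, dayf = self._inputs()
        tab, _ = build_design(eggs, bleak, temp, dayf, "eggs")
        scaled, meta = centre_scale(tab, ["eggs", "temp_c", "period_night"])
        for col in ("eggs", "temp_c", "period_night"):
            assert scaled[col].mean() == pytest.approx(0.0, abs=1e-12)
            assert scaled[col].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_scaling_metadata_inverts(self):
        eggs, bleak, temp, dayf = self._inputs()
        tab, _ = build_design(eggs, bleak, temp, dayf, "eggs")
        scaled, meta = centre_scale(tab, ["eggs"])
        mu, sd = meta["eggs"]
        back = scaled["eggs"] * sd + mu
        assert np.allclose(back.to_numpy(), tab["eggs"].to_numpy())

    def test_constant_column_error_names_it(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0]})
        with pytest.raises(InvalidParameterError, match="'a'"):
            centre_scale(df, ["a"])
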