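"""Linear models, backward elimination, correlation and group summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from flytrack.fixtures import day_of_year
from flytrack.stats import (backward_eliminate, compare_groups, fit_lm,
                            group_summary, lrt, pearson_test)


class TestFitLM:
    def test_exact_line(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        df["y"] = 3.0 + 2.0 * df["x"]
        fit = fit_lm("y", ["x"], df)
        assert fit.estimates == pytest.approx([3.0, 2.0], abs=1e-10)
        assert fit.df_resid == 8

    def test_matches_normal_equations_oracle(self):
        """OLS coefficients equal the closed-form (X'X)^-1 X'y solution."""
        rng = np.random.default_rng(42)
        df = pd.DataFrame({"x1": rng.normal(size=25), "x2": rng.normal(size=25)})
        df["y"] = 1.5 - 0.7 * df.x1 + 0.3 * df.x2 + rng.normal(0, 0.5, 25)
        fit = fit_lm("y", ["x1", "x2"], df)
        X = np.column_stack([np.ones(25), df.x1, df.x2])
        beta = np.linalg.solve(X.T @ X, X.T @ df.y)
        assert fit.estimates == pytest.approx(beta, rel=1e-8)
        # standard errors from the same normal equations
        resid = df.y - X @ beta
        s2 = float(resid @ resid) / (25 - 3)
        se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
        assert fit.se == pytest.approx(se, rel=1e-8)

    def test_loglik_increases_with_added_terms(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"x1": rng.normal(size=30), "x2": rng.normal(size=30)})
        df["y"] = df.x1 + rng.normal(size=30)
        ll0 = fit_lm("y", [], df).loglik
        ll1 = fit_lm("y", ["x1"], df).loglik
        ll2 = fit_lm("y", ["x1", "x2"], df).loglik
        assert ll0 <= ll1 <= ll2

    def test_rank_deficiency_rejected(self):
        df = pd.DataFrame({"x1": np.arange(10.0)})
        df["x2"] = 2 * df.x1
        df["y"] = df.x1
        with pytest.raises(ValueError, match="rank"):
            fit_lm("y", ["x1", "x2"], df)

    def test_site_model_reproduces_published_coefficients(self, table1):
        """Distance ~ site with DF as reference: intercept 2,999 km and a
        1,571 km RPL contrast (nearest km)."""
        fit = fit_lm("spring_distance_km", ["site"], table1)
        assert round(fit["Intercept"]) == 2999
        assert round(fit["site[T.RPL]"]) == 1571
        assert round(fit["site[T.RED]"]) == 1322
        assert fit.df_resid == 24


class TestBackwardElimination:
    def test_noise_terms_eliminated(self):
        """With one true predictor and two pure-noise covariates, only the
        true predictor survives elimination."""
        rng = np.random.default_rng(17)
        n = 100
        df = pd.DataFrame({
            "x": rng.normal(size=n),
            "noise1": rng.normal(size=n),
            "noise2": rng.normal(size=n),
        })
        df["y"] = 2.0 * df.x + rng.normal(size=n)
        fit, trace = backward_eliminate("y", ["x", "noise1", "noise2"], df)
        assert fit.terms == ["x"]
        assert {s.dropped for s in trace} == {"noise1", "noise2"}
        assert all(s.p > 0.05 for s in trace)

    def test_minimal_model_unchanged(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"x": rng.normal(size=50)})
        df["y"] = 3.0 * df.x + rng.normal(0, 0.3, 50)
        fit, trace = backward_eliminate("y", ["x"], df)
        assert fit.terms == ["x"] and trace == []

    def test_interaction_protects_main_effects(self):
        """An interaction must be considered before its main effects."""
        rng = np.random.default_rng(11)
        n = 80
        df = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        df["y"] = rng.normal(size=n)  # nothing real
        _, trace = backward_eliminate("y", ["a", "b", "a:b"], df, alpha=1e-9)
        dropped = [s.dropped for s in trace]
        assert dropped[0] == "a:b"

    def test_lrt_statistic_nonnegative(self, table1):
        full = fit_lm("spring_distance_km", ["site"], table1)
        reduced = fit_lm("spring_distance_km", [], table1)
        chi2, df, p = lrt(full, reduced)
        assert chi2 >= 0 and df == 3 and 0 <= p <= 1


class TestPearson:
    def test_formula_oracle(self):
        """r, t, p agree with the textbook formulas to 1e-10."""
        rng = np.random.default_rng(23)
        x = rng.normal(size=10)
        y = 0.5 * x + rng.normal(size=10)
        res = pearson_test(x, y)
        sx, sy = x - x.mean(), y - y.mean()
        r = float(sx @ sy / np.sqrt((sx @ sx) * (sy @ sy)))
        t = r * np.sqrt(8) / np.sqrt(1 - r * r)
        p = 2 * sps.t.sf(abs(t), 8)
        assert res.r == pytest.approx(r, abs=1e-10)
        assert res.t == pytest.approx(t, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)
        assert res.df == 8

    def test_perfect_line(self):
        x = np.arange(5.0)
        res = pearson_test(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_published_site_correlation(self, table1):
        """Initiation vs arrival day-of-year at the EEI site (7 birds):
        r = 0.81, t = 3.12, df = 5, p = 0.026."""
        eei = table1[table1.site == "EEI"]
        res = pearson_test(day_of_year(eei.spring_initiation),
                           day_of_year(eei.spring_arrival))
        assert round(res.r, 2) == 0.81
        assert round(res.t, 2) == 3.12
        assert res.df == 5
        assert round(res.p, 3) == 0.026

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            pearson_test([1.0, 2.0], [1.0, 2.0])


class TestCompareGroups:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = compare_groups(a, a)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_welch_formula_oracle(self):
        rng = np.random.default_rng(31)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 2, 9)
        t, p = compare_groups(a, b)
        va, vb = a.var(ddof=1) / 12, b.var(ddof=1) / 9
        t_ref = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_ref = (va + vb) ** 2 / (va**2 / 11 + vb**2 / 8)
        p_ref = 2 * sps.t.sf(abs(t_ref), df_ref)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_sexes_not_separable_on_austral_rates(self, table1):
        """Male and female austral migrants do not differ detectably in
        spring migration rate (p > 0.05)."""
        aus = table1[table1.group == "austral"]
        _, p = compare_groups(
            aus[aus.sex == "M"].spring_rate_km_per_day.dropna(),
            aus[aus.sex == "F"].spring_rate_km_per_day.dropna(),
        )
        assert p > 0.05


class TestGroupSummary:
    # every Mean/SD cell of the migration-history table, printed precision
    EXPECTED = {
        ("austral", "n_winter_sites"): (2.2, 1.03),
        ("austral", "winter_duration_days"): (154.6, 20.31),
        ("austral", "n_spring_stopovers"): (2.8, 1.42),
        ("austral", "spring_duration_days"): (35.6, 11.24),
        ("austral", "spring_distance_km"): (4438.4, 578.62),
        ("austral", "spring_rate_km_per_day"): (134.3, 39.55),
        ("austral", "spring_stopover_days"): (22.1, 13.30),
        ("intratropical", "n_winter_sites"): (1.5, 0.93),
        ("intratropical", "winter_duration_days"): (139.4, 24.82),
        ("intratropical", "n_spring_stopovers"): (2.6, 1.03),
        ("intratropical", "spring_duration_days"): (24.0, 5.00),
        ("intratropical", "spring_distance_km"): (3355.0, 388.90),
        ("intratropical", "spring_rate_km_per_day"): (143.8, 25.69),
        ("intratropical", "spring_stopover_days"): (13.2, 4.87),
    }

    def test_reproduces_every_summary_cell(self, table1):
        variables = sorted({v for _, v in self.EXPECTED})
        gs = group_summary(table1, "group", variables)
        gs = gs.set_index(["group", "variable"])
        for (grp, var), (mean, sd) in self.EXPECTED.items():
            row = gs.loc[(grp, var)]
            tol_mean = 1.0 if "distance" in var else 0.1
            assert row["mean"] == pytest.approx(mean, abs=tol_mean), (grp, var)
            assert row["sd"] == pytest.approx(sd, abs=tol_mean), (grp, var)

    def test_date_variables_summarised_on_day_of_year(self, table1):
        gs = group_summary(table1, "group", ["spring_initiation"])
        aus = gs[gs.group == "austral"].iloc[0]
        assert aus["mean_date"] == "8-Sep"

    def test_single_row_group_has_no_sd(self):
        df = pd.DataFrame({"g": ["a"], "v": [3.0]})
        out = group_summary(df, "g", ["v"])
        assert np.isnan(out["sd"].iloc[0])
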