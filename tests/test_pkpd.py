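"""In vivo statistics: normalization, EC fits, ESS F-test, AUC, slopes, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chemmap import (
    ECUndefinedError,
    SemilogECModel,
    anova2_posttests,
    auc_vs_baseline,
    ess_f_test,
    fit_semilog_ec,
    normalize_to_predose,
    recovery_slope_compare,
    sidak_adjust,
)


class TestNormalizeToPredose:
    def test_basic(self):
        df = pd.DataFrame(
            {"group": "g", "animal": "a1", "day": [0.0, 7.0], "value": [50.0, 25.0]}
        )
        out = normalize_to_predose(df)
        assert out["value"].tolist() == [100.0, 50.0]

    def test_constant_series_all_100(self):
        df = pd.DataFrame(
            {"group": "g", "animal": "a1", "day": [0.0, 7.0, 14.0], "value": 42.0}
        )
        out = normalize_to_predose(df)
        assert (out["value"] == 100.0).all()

    def test_zero_predose_rejected(self):
        df = pd.DataFrame(
            {"group": "g", "animal": "a1", "day": [0.0, 7.0], "value": [0.0, 10.0]}
        )
        with pytest.raises(ValueError, match="pre-dose"):
            normalize_to_predose(df)

    def test_missing_predose_rejected(self):
        df = pd.DataFrame(
            {"group": "g", "animal": "a1", "day": [7.0, 14.0], "value": [50.0, 60.0]}
        )
        with pytest.raises(ValueError, match="exactly one"):
            normalize_to_predose(df)

    def test_per_animal_normalization(self):
        df = pd.DataFrame(
            {
                "group": "g",
                "animal": ["a1", "a1", "a2", "a2"],
                "day": [0.0, 7.0, 0.0, 7.0],
                "value": [50.0, 25.0, 200.0, 50.0],
            }
        )
        out = normalize_to_predose(df)
        assert out["value"].tolist() == [100.0, 50.0, 100.0, 25.0]


class TestSemilogEC:
    def test_closed_form_line(self):
        x = np.array([0.5, 1.0, 10.0, 100.0, 500.0])
        y = 20.0 + 30.0 * np.log10(x)
        fit = fit_semilog_ec(x, y)
        assert fit.ec50 == pytest.approx(10.0, abs=1e-10)
        assert fit.ec80 == pytest.approx(100.0, abs=1e-10)
        assert fit.residual_ss == pytest.approx(0.0, abs=1e-18)

    def test_constant_loading_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_semilog_ec([1.0, 1.0, 1.0], [10.0, 20.0, 30.0])

    def test_nonpositive_loading_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_semilog_ec([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])

    def test_flat_slope_undefined(self):
        with pytest.raises(ECUndefinedError):
            fit_semilog_ec([1.0, 10.0, 100.0], [50.0, 50.0, 50.0])

    def test_extrapolation_flagged(self):
        x = np.array([1.0, 2.0, 4.0])
        y = 10.0 + 5.0 * np.log10(x)  # ec50 far above the observed range
        with pytest.warns(UserWarning, match="extrapolated"):
            model = SemilogECModel().fit(x, y)
        assert model.extrapolated_["ec50"] and model.extrapolated_["ec80"]

    def test_inversion_identity(self):
        """Refitting exact points regenerated from a fit reproduces (a, b)."""
        x = np.array([0.02, 0.1, 0.5, 2.0])
        rng = np.random.default_rng(0)
        y = 40.0 + 25.0 * np.log10(x) + rng.normal(0, 3, size=4)
        fit = fit_semilog_ec(x, y)
        fit2 = fit_semilog_ec(x, fit.predict(x))
        assert fit2.a == pytest.approx(fit.a, abs=1e-10)
        assert fit2.b == pytest.approx(fit.b, abs=1e-10)


class TestESSFTest:
    def test_identical_groups_f_zero(self):
        x = np.array([0.01, 0.1, 1.0, 10.0])
        y = 20.0 + 30.0 * np.log10(x) + np.array([0.5, -0.5, 0.5, -0.5])
        res = ess_f_test([(x, y), (x, y)])
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0, abs=1e-10)

    def test_f_nonnegative_and_p_monotone(self):
        rng = np.random.default_rng(7)
        x = np.logspace(-2, 1, 8)
        fs, ps = [], []
        for shift in (0.0, 5.0, 15.0):
            y1 = 20 + 30 * np.log10(x) + rng.normal(0, 2, 8)
            y2 = 20 + shift + 30 * np.log10(x) + rng.normal(0, 2, 8)
            res = ess_f_test([(x, y1), (x, y2)])
            assert res.statistic >= 0
            fs.append(res.statistic)
            ps.append(res.p)
        order = np.argsort(fs)
        assert np.all(np.diff(np.asarray(ps)[order]) <= 0)

    def test_power_against_different_slopes(self):
        """Slopes 30 vs 60, n=10/group, sigma=2: detected in >=95% of reps."""
        rng = np.random.default_rng(11)
        x = np.logspace(-2, 1, 10)
        hits = 0
        reps = 100
        for _ in range(reps):
            y1 = 20 + 30 * np.log10(x) + rng.normal(0, 2, 10)
            y2 = 20 + 60 * np.log10(x) + rng.normal(0, 2, 10)
            if ess_f_test([(x, y1), (x, y2)]).p < 0.05:
                hits += 1
        assert hits >= 95


class TestAUC:
    def test_constant_baseline_zero(self):
        assert auc_vs_baseline([0, 1, 2], [100.0, 100.0, 100.0]) == 0.0

    def test_hand_trapezoid(self):
        assert auc_vs_baseline([0, 1, 2, 3], [100, 50, 50, 100]) == pytest.approx(100.0)

    def test_subthreshold_dip_ignored(self):
        # main dip to 60 (range 40); second dip depth 3 < 10% of 40
        days = [0, 1, 2, 3, 4, 5, 6]
        vals = [100, 60, 100, 97, 100, 100, 100]
        with_dip = auc_vs_baseline(days, vals)
        vals_no_dip = [100, 60, 100, 100, 100, 100, 100]
        without = auc_vs_baseline(days, vals_no_dip)
        assert with_dip == pytest.approx(without)

    def test_above_baseline_counts_positive(self):
        """Excursions above baseline also contribute |area|."""
        a = auc_vs_baseline([0, 1, 2], [100, 140, 100])
        assert a == pytest.approx(40.0)

    def test_refinement_invariance(self):
        days = [0.0, 2.0, 4.0]
        vals = [100.0, 60.0, 100.0]
        refined_days = [0.0, 1.0, 2.0, 3.0, 4.0]
        refined_vals = [100.0, 80.0, 60.0, 80.0, 100.0]  # collinear insertions
        assert auc_vs_baseline(days, vals) == pytest.approx(
            auc_vs_baseline(refined_days, refined_vals)
        )

    def test_linear_scaling(self):
        days = [0, 1, 2, 3]
        v1 = np.array([100, 80, 90, 100], dtype=float)
        v2 = 100 + 2 * (v1 - 100)
        assert auc_vs_baseline(days, v2) == pytest.approx(2 * auc_vs_baseline(days, v1))

    def test_unordered_days_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            auc_vs_baseline([0, 2, 1], [100, 90, 95])


def _line_records(slopes, days, sigma=0.0, n_animals=1, rng=None):
    rows = []
    for g, slope in slopes.items():
        for d in days:
            for a in range(n_animals):
                noise = rng.normal(0, sigma) if rng is not None else 0.0
                rows.append(
                    {"group": g, "animal": f"{g}{a}", "day": float(d),
                     "value": 10.0 + slope * d + noise}
                )
    return pd.DataFrame(rows)


class TestRecoverySlopes:
    def test_exact_lines(self):
        df = _line_records({"A": 1.0, "B": 2.0}, days=[30, 40, 50, 60, 70])
        res = recovery_slope_compare(df, day_window=(29, 71))
        assert res["slopes"]["A"] == pytest.approx(1.0, abs=1e-10)
        assert res["slopes"]["B"] == pytest.approx(2.0, abs=1e-10)
        assert res["slope_difference"] == pytest.approx(1.0, abs=1e-10)

    def test_same_line_zero_difference(self):
        df = _line_records({"A": 1.5, "B": 1.5}, days=[30, 45, 60, 71])
        res = recovery_slope_compare(df)
        assert res["slope_difference"] == pytest.approx(0.0, abs=1e-10)

    def test_window_endpoints_inclusive(self):
        df = _line_records({"A": 1.0, "B": 2.0}, days=[29, 50, 71, 80])
        res = recovery_slope_compare(df, day_window=(29, 71))
        # the day-80 point is excluded, endpoints kept: 3 points per group
        assert res["slopes"]["A"] == pytest.approx(1.0, abs=1e-10)

    def test_too_few_points_names_group(self):
        df = _line_records({"A": 1.0, "B": 2.0}, days=[30, 40])
        with pytest.raises(ValueError, match="'A'|'B'"):
            recovery_slope_compare(df)

    def test_sign_recovery_under_noise(self):
        """Slope difference sign (0.9 vs 0.6 %/day) recovered in >=95% of seeds."""
        days = [29, 36, 43, 50, 57, 64, 71]
        hits = 0
        seeds = 200
        for seed in range(seeds):
            rng = np.random.default_rng(seed)
            df = _line_records({"parent": 0.9, "DV22": 0.6}, days=days,
                               sigma=3.0, n_animals=3, rng=rng)
            res = recovery_slope_compare(df)
            if res["slopes"]["parent"] > res["slopes"]["DV22"]:
                hits += 1
        assert hits >= 0.95 * seeds


def _anova_table(effects, n=3, sigma=1.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for (g, d), mu in effects.items():
        for _ in range(n):
            rows.append({"group": g, "day": d, "value": mu + rng.normal(0, sigma)})
    return pd.DataFrame(rows)


class TestAnovaPosttests:
    @pytest.mark.parametrize("p, m, expected", [(0.05, 1, 0.05), (0.01, 3, 0.029701)])
    def test_sidak_closed_form(self, p, m, expected):
        assert sidak_adjust(p, m) == pytest.approx(expected, abs=1e-9)

    def test_balanced_matches_statsmodels(self):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        df = _anova_table(
            {(g, d): 10.0 * (g == "B") + d for g in "ABC" for d in (7.0, 22.0)},
            n=4, seed=3,
        )
        res = anova2_posttests(df, control="A", post="sidak")
        ref = anova_lm(
            smf.ols("value ~ C(group) * C(day)", data=df).fit(), typ=2
        )
        tab = res["anova"].set_index("effect")
        assert tab.loc["design", "F"] == pytest.approx(ref.loc["C(group)", "F"], rel=1e-8)
        assert tab.loc["time", "F"] == pytest.approx(ref.loc["C(day)", "F"], rel=1e-8)
        assert tab.loc["design:time", "F"] == pytest.approx(
            ref.loc["C(group):C(day)", "F"], rel=1e-8
        )

    def test_dunnett_single_comparison_matches_t_test(self):
        """With one treated group, Dunnett reduces to the two-sided t-test."""
        df = _anova_table(
            {(g, d): 2.0 * (g == "B") for g in "AB" for d in (7.0, 22.0)},
            n=5, seed=1,
        )
        res = anova2_posttests(df, control="A", post="dunnett", seed=0, n_mc=200_000)
        for _, row in res["comparisons"].iterrows():
            assert row["p_adjusted"] == pytest.approx(row["p_unadjusted"], abs=0.005)

    def test_dunnett_adjusted_at_least_unadjusted(self):
        df = _anova_table(
            {(g, d): 1.5 * (g != "A") for g in "ABCD" for d in (7.0, 22.0)},
            n=3, seed=2,
        )
        res = anova2_posttests(df, control="A", post="dunnett", seed=1)
        comp = res["comparisons"]
        assert (comp["p_adjusted"] >= comp["p_unadjusted"] - 1e-12).all()
        # with 3 comparisons per time point, real adjustment occurs
        assert (comp["p_adjusted"] > comp["p_unadjusted"]).any()

    def test_planted_design_effect_detected(self):
        df = _anova_table(
            {(g, d): -30.0 * (g == "DV22") for g in ("parent", "DV22")
             for d in (7.0, 22.0)},
            n=3, sigma=3.0, seed=4,
        )
        res = anova2_posttests(df, control="parent", post="dunnett", seed=0)
        tab = res["anova"].set_index("effect")
        assert tab.loc["design", "p"] < 0.001
        assert res["comparisons"]["significant"].all()

    def test_missing_control_rejected(self):
        df = _anova_table({(g, d): 0.0 for g in "AB" for d in (1.0, 2.0)})
        with pytest.raises(ValueError, match="control"):
            anova2_posttests(df, control="Z")

    def test_unbalanced_falls_back_with_warning(self):
        df = _anova_table({(g, d): 0.0 for g in "AB" for d in (1.0, 2.0)}, n=4, seed=5)
        df = df.iloc[:-2]  # unbalance one cell
        with pytest.warns(UserWarning, match="unbalanced"):
            res = anova2_posttests(df, control="A", post="sidak")
        assert set(res["anova"]["effect"]) >= {"design", "time", "design:time"}

    def test_dunnett_type_i_error_calibrated(self):
        """Under the null the max-|T| adjustment keeps the familywise rate near 5%."""
        hits = 0
        reps = 200
        for seed in range(reps):
            df = _anova_table(
                {(g, d): 0.0 for g in "ABC" for d in (1.0, 2.0)}, n=3, seed=seed
            )
            res = anova2_posttests(df, control="A", post="dunnett", seed=0, n_mc=20_000)
            comp = res["comparisons"]
            # familywise over the two comparisons at day 1
            sub = comp[comp["time"] == 1.0]
            if (sub["p_adjusted"] < 0.05).any():
                hits += 1
        assert 0.01 <= hits / reps <= 0.12
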