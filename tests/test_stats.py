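"""Regression, ANOVA, rank-test and screening machinery against oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from dlwater.stats import (
    CohortModel,
    ModelSpec,
    ReferenceModel,
    fit_model,
    group_summaries,
    kruskal_wallis,
    prepare_regression_frame,
    residual_adjust_anova,
)

SPEC_BEST = ModelSpec("lnTEE", ("lnFFM", "lnFM", "sex"))


def _frame(n, seed, with_groups=False):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "lnTEE": rng.normal(7.8, 0.3, n),
            "lnFFM": rng.normal(3.7, 0.15, n),
            "lnFM": rng.normal(2.0, 0.5, n),
            "age": rng.uniform(20, 56, n),
            "sex": rng.choice(["F", "M"], n),
        }
    )
    if with_groups:
        df["community"] = rng.choice(["Illeret", "El Bokoch", "Roto"], n)
    return df


class TestOLS:
    def test_matches_normal_equations_oracle(self):
        """Coefficients agree with explicit (X'X)^-1 X'y to 1e-10."""
        frame = _frame(10, seed=42)
        res = CohortModel(ModelSpec("lnTEE", ("lnFFM", "lnFM", "age", "sex")), frame).fit()
        X = np.column_stack(
            [np.ones(10), frame.lnFFM, frame.lnFM, frame.age,
             (frame.sex == "M").astype(float)]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ frame.lnTEE.to_numpy())
        np.testing.assert_allclose(res.params.to_numpy(), beta, atol=1e-10)
        # adjusted R^2 from its definition
        n, p = 10, 4
        adj = 1 - (1 - res.rsquared) * (n - 1) / (n - p - 1)
        assert res.rsquared_adj == pytest.approx(adj, rel=1e-12)

    def test_exact_linear_data_recovered_to_machine_precision(self):
        frame = _frame(30, seed=1)
        frame["lnTEE"] = 2.0 + 1.5 * frame.lnFFM - 0.3 * frame.lnFM + 0.1 * (
            frame.sex == "M"
        )
        res = CohortModel(SPEC_BEST, frame).fit()
        assert res.rsquared_adj == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(
            res.params.to_numpy(), [2.0, 1.5, -0.3, 0.1], atol=1e-10
        )
        assert abs(res.resid.sum()) < 1e-9

    def test_adding_predictor_never_decreases_r2(self):
        frame = _frame(40, seed=3)
        small = CohortModel(ModelSpec("lnTEE", ("lnFFM",)), frame).fit()
        big = CohortModel(ModelSpec("lnTEE", ("lnFFM", "lnFM", "age")), frame).fit()
        assert big.rsquared >= small.rsquared

    def test_rank_deficiency_names_collinear_columns(self):
        frame = _frame(20, seed=5)
        frame["FFM"] = np.exp(frame.lnFFM)
        frame["lnFM"] = 2 * frame.lnFFM  # exact collinearity
        with pytest.raises(ValueError, match="collinear.*ln"):
            CohortModel(ModelSpec("lnTEE", ("lnFFM", "lnFM")), frame)

    def test_log_of_nonpositive_names_participant(self):
        derived = pd.DataFrame(
            {"participant_id": ["a", "b"], "TEE_kcal_day": [2000.0, -5.0],
             "FFM_kg": [40.0, 40.0], "FM_kg": [10.0, 10.0], "sex": ["F", "M"]}
        )
        with pytest.raises(ValueError, match="TEE.*'b'"):
            prepare_regression_frame(derived)

    def test_reference_level_validation_and_tidy(self):
        frame = _frame(20, seed=6)
        with pytest.raises(ValueError, match="reference level"):
            CohortModel(
                ModelSpec("lnTEE", ("lnFFM", "sex"), {"sex": "X"}), frame
            ).fit()
        res = CohortModel(SPEC_BEST, frame).fit()
        tidy = res.tidy()
        assert list(tidy.columns) == ["term", "estimate", "se", "p"]
        assert "sex[M]" in tidy.term.tolist()

    def test_printed_rounded_inputs_move_coefficients_under_two_percent(
        self, reference_table, derived_cohort
    ):
        """Fitting on the table's rounded derived columns instead of the
        recomputed ones perturbs the slope coefficients by < 2%."""
        recomputed = fit_model(SPEC_BEST, derived_cohort)
        printed = reference_table.assign(
            FM_kg=reference_table.body_mass_kg - reference_table.FFM_kg
        )
        from_printed = fit_model(SPEC_BEST, printed)
        for term in ("lnFFM", "lnFM", "sex[M]"):
            assert from_printed.params[term] == pytest.approx(
                recomputed.params[term], rel=0.02
            )


class TestResidualAnova:
    def test_two_groups_equal_squared_t_statistic(self):
        frame = _frame(24, seed=9, with_groups=True)
        frame["community"] = np.where(np.arange(24) < 12, "A", "B")
        res = CohortModel(ModelSpec("lnTEE", ("lnFFM",)), frame).fit()
        an = residual_adjust_anova(res, frame["community"])
        a = res.resid[frame.community == "A"]
        b = res.resid[frame.community == "B"]
        t = scipy.stats.ttest_ind(a, b).statistic
        assert an.F == pytest.approx(t**2, rel=1e-10)
        assert (an.df_between, an.df_within) == (1, 22)

    def test_identical_group_means_give_zero_f(self):
        # duplicate x values with symmetric +/- offsets: OLS recovers the
        # line exactly and each pair-group has residual mean zero
        rng = np.random.default_rng(10)
        x = np.repeat(rng.uniform(3.4, 4.0, 6), 2)
        y = 2.0 + 0.5 * x + np.tile([0.3, -0.3], 6)
        frame = pd.DataFrame({"lnTEE": y, "lnFFM": x})
        res = CohortModel(ModelSpec("lnTEE", ("lnFFM",)), frame).fit()
        groups = pd.Series(np.repeat(list("ABCDEF"), 2), index=res.resid.index)
        an = residual_adjust_anova(res, groups)
        assert an.F == pytest.approx(0.0, abs=1e-10)

    def test_grouping_already_in_model_yields_near_zero_f(self):
        frame = _frame(60, seed=11, with_groups=True)
        res = CohortModel(ModelSpec("lnTEE", ("lnFFM", "community")), frame).fit()
        an = residual_adjust_anova(res, frame["community"])
        assert an.F == pytest.approx(0.0, abs=1e-12)

    def test_small_group_rejected(self):
        frame = _frame(10, seed=12)
        res = CohortModel(ModelSpec("lnTEE", ("lnFFM",)), frame).fit()
        labels = pd.Series(["A"] * 9 + ["B"], index=res.resid.index)
        with pytest.raises(ValueError, match="fewer than 2"):
            residual_adjust_anova(res, labels)


def brute_force_kruskal(values, labels):
    """H from the explicit rank-sum formula with tie correction."""
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    N = len(values)
    ranks = scipy.stats.rankdata(values)
    H = 0.0
    for g in np.unique(labels):
        r = ranks[labels == g]
        H += r.sum() ** 2 / len(r)
    H = 12 / (N * (N + 1)) * H - 3 * (N + 1)
    _, counts = np.unique(values, return_counts=True)
    tie = 1 - ((counts**3 - counts).sum()) / (N**3 - N)
    return H / tie


class TestKruskalWallis:
    def test_matches_rank_formula_oracle(self):
        rng = np.random.default_rng(21)
        values = np.round(rng.normal(size=30), 1)  # induce ties
        labels = rng.choice(["x", "y", "z"], 30)
        H, df, p = kruskal_wallis(values, labels)
        assert H == pytest.approx(brute_force_kruskal(values, labels), abs=1e-10)
        assert df == 2

    def test_all_identical_returns_zero_with_warning(self):
        with pytest.warns(UserWarning, match="identical"):
            H, df, p = kruskal_wallis([5.0] * 8, ["a"] * 4 + ["b"] * 4)
        assert H == 0.0 and df == 1 and p == 1.0

    def test_group_validation(self):
        with pytest.raises(ValueError, match="two groups"):
            kruskal_wallis([1, 2, 3], ["a", "a", "a"])

    def test_runs_on_reference_step_counts(self, reference_table):
        """Steps of the ten accelerometry wearers across community x sex:
        the statistic is computed generically (df = groups - 1)."""
        t = reference_table.dropna(subset=["steps"])
        labels = t.community + ":" + t.sex
        H, df, p = kruskal_wallis(t.steps.to_numpy(), labels.to_numpy())
        assert df == len(labels.unique()) - 1
        assert H >= 0 and 0 <= p <= 1


class TestReferenceScreening:
    def test_zero_residual_reference_collapses_interval(self):
        ref = ReferenceModel(
            "lnTEE", {"intercept": 1.0, "lnFFM": 2.0}, resid_sd=0.0, n=100
        )
        frame = pd.DataFrame({"lnFFM": [3.0, 4.0], "lnTEE": [7.0, 9.1]})
        out = ref.predict_with_interval(frame)
        np.testing.assert_allclose(out.pi_lo, out.point)
        np.testing.assert_allclose(out.pi_hi, out.point)
        assert out.flag.tolist() == ["inside", "above"]

    def test_missing_covariate_skips_row_with_warning(self):
        ref = ReferenceModel(
            "lnTEE", {"intercept": 1.0, "lnFFM": 2.0, "sex[M]": -0.2},
            resid_sd=0.1, n=50,
        )
        frame = pd.DataFrame(
            {"lnFFM": [3.0, np.nan], "sex": ["M", "F"], "lnTEE": [7.0, 7.5]}
        )
        with pytest.warns(UserWarning, match="skipped"):
            out = ref.predict_with_interval(frame)
        assert len(out) == 1

    def test_yaml_round_trip(self):
        text = """
response: lnTEE
coefficients: {intercept: 4.7, lnFFM: 0.84, lnFM: -0.02, age: -0.002, "sex[M]": 0.01}
resid_sd: 0.18
n: 6000
"""
        ref = ReferenceModel.from_yaml(text)
        assert ref.n == 6000 and ref.terms[0] == "lnFFM"


class TestGroupSummaries:
    def test_single_member_group_has_na_sd(self):
        df = pd.DataFrame(
            {"sex": ["F", "F", "M"], "TEE_kcal_day": [2000.0, 2200.0, 2600.0]}
        )
        out = group_summaries(df, ["sex"])
        m = out.set_index("sex")
        assert m.loc["M", "TEE_kcal_day_mean"] == 2600.0
        assert np.isnan(m.loc["M", "TEE_kcal_day_std"])
        assert m.loc["F", "TEE_kcal_day_count"] == 2
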