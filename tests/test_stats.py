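"""Temporal summaries, ANOVA/Tukey, beta regression, transformed LMs."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vaximg import stats


class TestAuc:
    def test_constant_curve_is_rectangle(self):
        assert stats.auc([0, 72], [5.0, 5.0]) == pytest.approx(360.0)

    def test_hand_trapezoid(self):
        assert stats.auc([0, 24, 48], [0.0, 10.0, 0.0]) == pytest.approx(240.0)

    @given(scale=st.floats(0.1, 100.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_linearity_under_rescaling(self, scale):
        t = [0.0, 4.0, 24.0, 48.0, 72.0]
        v = [0.0, 3.0, 8.0, 5.0, 1.0]
        assert stats.auc(t, np.asarray(v) * scale) == pytest.approx(
            scale * stats.auc(t, v))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            stats.auc([0.0], [1.0])

    def test_missing_values_flagged_in_table(self):
        df = pd.DataFrame({
            "subject": "r1", "group": "g", "cohort": "Prime",
            "time_hr": [0.0, 4.0, 24.0], "value": [0.0, np.nan, 2.0],
        })
        out = stats.auc_table(df)
        assert not out["complete"].iloc[0]
        assert out["auc"].iloc[0] == pytest.approx(24.0)


class TestGroupMax:
    def _series(self, values_by_subject, times=(4.0, 24.0, 48.0)):
        rows = []
        for subj, vals in values_by_subject.items():
            for t, v in zip(times, vals):
                rows.append({"subject": subj, "group": "g", "time_hr": t,
                             "value": v})
        return pd.DataFrame(rows)

    def test_single_subject_peak(self):
        df = self._series({"r1": [1.0, 5.0, 3.0]})
        out = stats.group_max(df)
        assert out["peak_time_hr"].iloc[0] == 24.0
        assert out["value"].iloc[0] == 5.0

    def test_all_subjects_read_at_group_peak(self):
        df = self._series({"r1": [1.0, 5.0, 3.0], "r2": [1.0, 5.0, 30.0]})
        # group means: {1, 5, 16.5} → peak at 48 hr for everyone
        out = stats.group_max(df)
        assert (out["peak_time_hr"] == 48.0).all()
        assert sorted(out["value"]) == [3.0, 30.0]

    def test_tie_resolves_to_earliest(self):
        df = self._series({"r1": [5.0, 5.0, 1.0]})
        out = stats.group_max(df)
        assert out["peak_time_hr"].iloc[0] == 4.0

    def test_recovers_simulator_peak_time_without_noise(self):
        from vaximg import synth
        s = synth.make_endpoint_series(
            group_params={"g": {"peak_time": 24.0, "peak_amplitude": 10.0}},
            noise_cv=0.0, seed=0)
        out = stats.group_max(s)
        assert (out["peak_time_hr"] == 24.0).all()


class TestAnovaLogTukey:
    def test_identical_groups_p_is_one(self):
        res = stats.anova_log_tukey([2.0, 3.0, 2.0, 3.0],
                                    ["a", "a", "b", "b"])
        assert res[0].estimate == pytest.approx(0.0, abs=1e-12)
        assert res[0].p_value == pytest.approx(1.0)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            stats.anova_log_tukey([1.0, 0.0], ["a", "b"])

    def test_type_one_error_calibrated(self):
        # null: both groups lognormal with identical parameters, n=4/group
        rng = np.random.default_rng(2024)
        n_sim, hits = 300, 0
        for _ in range(n_sim):
            vals = rng.lognormal(0.0, 0.3, 8)
            res = stats.anova_log_tukey(vals, ["a"] * 4 + ["b"] * 4)
            hits += res[0].p_value < 0.05
        rate = hits / n_sim
        assert abs(rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / n_sim)

    def test_two_factor_model_with_interaction_runs(self):
        rng = np.random.default_rng(5)
        vals = rng.lognormal(0, 0.2, 16)
        groups = (["a"] * 4 + ["b"] * 4) * 2
        cohorts = ["Prime"] * 8 + ["PrimeBoost"] * 8
        res = stats.anova_log_tukey(vals, groups, cohorts=cohorts, interaction=True)
        assert len(res) == 1
        assert res[0].adjustment == "tukey"
        assert 0.0 <= res[0].p_value <= 1.0

    def test_all_pairwise_contrasts_reported(self):
        rng = np.random.default_rng(6)
        res = stats.anova_log_tukey(rng.lognormal(0, 0.2, 12),
                                    ["a", "b", "c"] * 4)
        assert len(res) == 3  # C(3, 2) pairs


class TestBetaRegression:
    def test_zero_ratio_maps_to_pseudocount(self):
        y = stats.shrink_unit_interval([0.0, 0.5, 1.0])
        assert y[0] == 1e-5
        assert y[1] == 0.5
        assert y[2] == 1.0 - 1e-5

    def test_recovers_logit_effect_within_three_se(self):
        rng = np.random.default_rng(11)
        phi = 20.0
        mu_a = 1.0 / (1.0 + np.exp(0.0))          # logit 0
        mu_b = 1.0 / (1.0 + np.exp(-1.0))         # logit 1
        n = 30
        ya = rng.beta(mu_a * phi, (1 - mu_a) * phi, n)
        yb = rng.beta(mu_b * phi, (1 - mu_b) * phi, n)
        fit = stats.beta_regression(np.r_[ya, yb], ["a"] * n + ["b"] * n)
        comp = fit.comparisons[0]      # "a - b" on the logit scale
        assert abs(abs(comp.estimate) - 1.0) <= 3 * comp.se

    def test_equal_groups_give_null_effect(self):
        rng = np.random.default_rng(3)
        y = rng.beta(3, 7, 40)
        fit = stats.beta_regression(np.r_[y, y], ["a"] * 40 + ["b"] * 40)
        assert fit.comparisons[0].estimate == pytest.approx(0.0, abs=1e-6)

    def test_estimate_variance_shrinks_with_precision(self):
        # higher φ concentrates ratios at the mean → smaller contrast SE
        rng = np.random.default_rng(9)
        ses = []
        for phi in (5.0, 20.0, 100.0):
            mu = 0.3
            y = np.r_[rng.beta(mu * phi, (1 - mu) * phi, 40),
                      rng.beta(mu * phi, (1 - mu) * phi, 40)]
            fit = stats.beta_regression(y, ["a"] * 40 + ["b"] * 40)
            ses.append(fit.comparisons[0].se)
        assert ses[0] > ses[1] > ses[2]

    def test_out_of_range_ratio_rejected(self):
        with pytest.raises(ValueError):
            stats.beta_regression([0.5, 1.2], ["a", "b"])


class TestTransformedLM:
    def test_identical_groups_effect_zero(self):
        res = stats.transformed_lm([4.0, 9.0, 4.0, 9.0], ["a", "a", "b", "b"],
                                   transform="sqrt")
        assert res[0].estimate == pytest.approx(0.0, abs=1e-12)

    def test_sqrt_shift_recovered_within_three_se(self):
        rng = np.random.default_rng(14)
        n = 40
        base = rng.normal(5.0, 0.5, n)          # sqrt-scale location 5
        shifted = rng.normal(6.0, 0.5, n)       # sqrt-scale location 6
        res = stats.transformed_lm(np.r_[base ** 2, shifted ** 2],
                                   ["a"] * n + ["b"] * n, transform="sqrt")
        comp = res[0]
        assert abs(abs(comp.estimate) - 1.0) <= 3 * comp.se
        assert comp.transformation == "sqrt"

    def test_log_domain_enforced(self):
        with pytest.raises(ValueError):
            stats.transformed_lm([1.0, 0.0], ["a", "b"], transform="log")

    def test_single_observation_per_group_rejected(self):
        with pytest.raises(ValueError):
            stats.transformed_lm([1.0, 2.0], ["a", "b"], transform="sqrt")


class TestPearsonMatrix:
    def test_column_against_itself(self, rng):
        x = pd.DataFrame({"e": rng.normal(0, 1, 10)})
        r, p = stats.pearson_matrix(x, x.rename(columns={"e": "c"}))
        assert r.loc["e", "c"] == pytest.approx(1.0)

    def test_orthogonal_pair_is_zero(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])  # exactly orthogonal, mean 0
        r, _ = stats.pearson_matrix(pd.DataFrame({"a": a}), pd.DataFrame({"b": b}))
        assert abs(r.loc["a", "b"]) < 1e-12

    def test_minimal_n_returns_finite_p(self, rng):
        x = pd.DataFrame({"a": [1.0, 2.0, 4.0]})
        y = pd.DataFrame({"b": [1.0, 3.0, 2.0]})
        r, p = stats.pearson_matrix(x, y)
        assert np.isfinite(p.loc["a", "b"])

    def test_constant_column_flagged_nan(self):
        x = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0]})
        y = pd.DataFrame({"b": [1.0, 2.0, 3.0, 4.0]})
        r, p = stats.pearson_matrix(x, y)
        assert np.isnan(r.loc["a", "b"]) and np.isnan(p.loc["a", "b"])

    def test_pairwise_complete_handling(self, rng):
        a = rng.normal(0, 1, 20)
        b = a + rng.normal(0, 0.1, 20)
        a[3] = np.nan
        r, _ = stats.pearson_matrix(pd.DataFrame({"a": a}), pd.DataFrame({"b": b}))
        assert r.loc["a", "b"] > 0.9
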