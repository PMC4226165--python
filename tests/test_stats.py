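import numpy as np
import pandas as pd
import pytest

from entrobeat import stats
from entrobeat.stats import (StatsError, gg_epsilon, pearson_matrix, pearson_p,
                             rm_anova, roi_covariate_correlation,
                             seed_connectivity,
                             standardized_ols_from_correlations,
                             stepwise_regression)


class TestPearsonMatrix:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        cm = pearson_matrix(pd.DataFrame({"x": x, "y": 3 * x + 2}))
        assert cm.r[0, 1] == pytest.approx(1.0)

    def test_significance_at_study_scale(self):
        # |r| = 0.63 at n = 16 gives t = 3.03 on 14 df, p < 0.01 two-sided
        p = float(pearson_p(np.array(0.63), 16))
        assert 0.001 < p < 0.01

    def test_constructed_sample_r(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=16)
        z = rng.normal(size=16)
        x = (x - x.mean()) / x.std(ddof=1)
        z = z - z @ x / (x @ x) * x
        z = (z - z.mean()) / z.std(ddof=1)
        y = 0.63 * x + np.sqrt(1 - 0.63 ** 2) * z
        cm = pearson_matrix(pd.DataFrame({"x": x, "y": y}))
        assert cm.r[0, 1] == pytest.approx(0.63, abs=1e-10)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        cm0 = pearson_matrix(df)
        df2 = df.copy()
        df2["b"] = 100.0 * df2["b"] - 7.0
        cm1 = pearson_matrix(df2)
        assert np.allclose(cm0.r, cm1.r)

    def test_zero_variance_column_named(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "flat": [5.0, 5, 5, 5]})
        with pytest.raises(StatsError, match="flat"):
            pearson_matrix(df)


class TestStandardizedOls:
    def test_single_predictor_beta_equals_r(self):
        res = standardized_ols_from_correlations([0.4], [[1.0]], 20)
        assert res.standardized_betas[0] == pytest.approx(0.4)

    def test_two_predictor_normal_equations(self):
        res = standardized_ols_from_correlations(
            [0.63, -0.31], [[1.0, 0.07], [0.07, 1.0]], 16)
        assert res.standardized_betas[0] == pytest.approx(
            (0.63 + 0.31 * 0.07) / (1 - 0.07 ** 2), abs=1e-12)
        assert round(res.standardized_betas[0], 2) == 0.65
        assert res.r_squared == pytest.approx(0.5229, abs=1e-3)
        assert res.adjusted_r_squared == pytest.approx(0.4495, abs=1e-3)
        assert res.df == (2, 13)

    def test_oracle_equivalence_on_zscored_data(self):
        """Correlation-matrix solve equals least squares on z-scores for
        100 random well-conditioned problems."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            n, k = rng.integers(12, 40), rng.integers(1, 5)
            X = rng.normal(size=(n, k))
            y = X @ rng.normal(size=k) + rng.normal(size=n)
            Z = (X - X.mean(0)) / X.std(0, ddof=1)
            zy = (y - y.mean()) / y.std(ddof=1)
            beta_ls, *_ = np.linalg.lstsq(Z, zy, rcond=None)
            R = np.corrcoef(np.column_stack([y, X]), rowvar=False)
            res = standardized_ols_from_correlations(R[0, 1:], R[1:, 1:], n)
            assert np.allclose(res.standardized_betas, beta_ls, atol=1e-10)
            ss_res = ((zy - Z @ beta_ls) ** 2).sum()
            assert res.r_squared == pytest.approx(1 - ss_res / (n - 1), abs=1e-10)

    def test_singular_predictors_rejected(self):
        with pytest.raises(StatsError, match="collinearity|singular"):
            standardized_ols_from_correlations(
                [0.5, 0.5], [[1.0, 1.0], [1.0, 1.0]], 20)


class TestStepwise:
    def test_recovers_true_predictor(self):
        """The true predictor is always selected; the pure-noise predictor
        joins it only at about the nominal entry rate."""
        x1_in, noise_in = 0, 0
        n_seeds = 300
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            x1, x2 = rng.normal(size=200), rng.normal(size=200)
            y = 0.8 * x1 + rng.normal(size=200)
            res = stepwise_regression(y, pd.DataFrame({"x1": x1, "x2": x2}))
            x1_in += "x1" in res.predictors
            noise_in += "x2" in res.predictors
        assert x1_in == n_seeds
        assert 0.01 <= noise_in / n_seeds <= 0.10
        assert (x1_in - noise_in) / n_seeds >= 0.90  # x1-only in >= 90%

    def test_type_i_rate_with_noise_predictor(self):
        empty = 0
        for seed in range(400):
            rng = np.random.default_rng(1000 + seed)
            x = rng.normal(size=200)
            y = rng.normal(size=200)
            res = stepwise_regression(y, pd.DataFrame({"x": x}))
            if not res.predictors:
                empty += 1
        assert 0.91 <= empty / 400 <= 0.985  # ~95% empty at p_enter=.05

    def test_trace_records_entries(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        y = 2 * x + 0.1 * rng.normal(size=100)
        res = stepwise_regression(y, pd.DataFrame({"x": x}))
        assert res.selection_trace[0]["action"] == "enter"
        assert res.selection_trace[0]["variable"] == "x"


class TestRmAnova:
    def test_identical_levels_give_zero_f(self):
        rows = [{"s": s, "c": c, "b": b, "y": float(s)}
                for s in range(6) for c in "ab" for b in range(3)]
        res = rm_anova(pd.DataFrame(rows), "y", "s", ["c", "b"])
        assert all(e.F == 0.0 for e in res.effects)

    def test_two_level_factor_epsilon_exactly_one(self, anova_fixture):
        res = rm_anova(anova_fixture, "y", "subj", ["cond", "block"])
        assert res["cond"].epsilon == 1.0

    def test_matches_general_linear_model_oracle(self, anova_fixture):
        """F statistics equal statsmodels' repeated-measures GLM to 1e-8."""
        from statsmodels.stats.anova import AnovaRM
        res = rm_anova(anova_fixture, "y", "subj", ["cond", "block"])
        oracle = AnovaRM(anova_fixture, "y", "subj",
                         within=["cond", "block"]).fit().anova_table
        assert res["cond"].F == pytest.approx(oracle.loc["cond", "F Value"],
                                              abs=1e-8)
        assert res["block"].F == pytest.approx(oracle.loc["block", "F Value"],
                                               abs=1e-8)
        assert res["cond x block"].F == pytest.approx(
            oracle.loc["cond:block", "F Value"], abs=1e-8)

    def test_epsilon_matches_pingouin(self, anova_fixture):
        import pingouin as pg
        res = rm_anova(anova_fixture, "y", "subj", ["cond", "block"])
        oracle = pg.rm_anova(data=anova_fixture, dv="y",
                             within=["cond", "block"], subject="subj",
                             correction=True)
        eps = dict(zip(oracle["Source"], oracle["eps"]))
        assert res["block"].epsilon == pytest.approx(eps["block"], abs=1e-10)
        assert res["cond x block"].epsilon == pytest.approx(
            eps["cond * block"], abs=1e-10)

    def test_three_way_runs_and_epsilon_bounds(self):
        rng = np.random.default_rng(9)
        rows = [{"s": s, "c": c, "p": p, "b": b, "y": rng.normal()}
                for s in range(8) for c in "ab" for p in "xy" for b in range(3)]
        res = rm_anova(pd.DataFrame(rows), "y", "s", ["c", "p", "b"])
        assert len(res.effects) == 7
        for e in res.effects:
            d = e.df[0]
            assert 1.0 / d - 1e-12 <= e.epsilon <= 1.0
            assert 0.0 <= e.partial_eta_squared <= 1.0

    def test_missing_cell_named(self):
        rows = [{"s": s, "c": c, "y": 1.0} for s in range(4) for c in "ab"]
        rows.pop(3)
        with pytest.raises(StatsError, match="missing cell"):
            rm_anova(pd.DataFrame(rows), "y", "s", ["c"])

    def test_partial_eta_squared_definition(self, anova_fixture):
        res = rm_anova(anova_fixture, "y", "subj", ["cond", "block"])
        e = res["cond"]
        assert e.partial_eta_squared == pytest.approx(
            e.ss_effect / (e.ss_effect + e.ss_error))


class TestRoiAnalyses:
    @staticmethod
    def _roi_table(rng, n=16, rois=("a", "b", "c")):
        df = pd.DataFrame({r: rng.normal(size=n) for r in rois})
        df.index = pd.Index(range(n), name="subject_id")
        return df

    def test_self_covariate_flagged(self):
        rng = np.random.default_rng(10)
        roi = self._roi_table(rng)
        out = roi_covariate_correlation(roi, roi["a"])
        by_label = {rc.roi_label: rc for rc in out}
        assert by_label["a"].r == pytest.approx(1.0)
        assert by_label["a"].flagged

    def test_permutation_calibration(self):
        """Permuting the covariate flags each ROI at about the alpha rate."""
        rng = np.random.default_rng(11)
        roi = self._roi_table(rng, n=16, rois=("a",))
        cov = rng.normal(size=16)
        alpha = 0.05
        flags = 0
        n_perm = 1000
        for _ in range(n_perm):
            perm = pd.Series(rng.permutation(cov), index=roi.index)
            flags += roi_covariate_correlation(roi, perm, alpha=alpha)[0].flagged
        rate = flags / n_perm
        assert abs(rate - alpha) < 3 * np.sqrt(alpha * (1 - alpha) / n_perm)

    def test_subject_mismatch_rejected(self):
        rng = np.random.default_rng(12)
        roi = self._roi_table(rng)
        cov = pd.Series(rng.normal(size=16), index=range(100, 116))
        with pytest.raises(StatsError, match="subject mismatch"):
            roi_covariate_correlation(roi, cov)

    def test_seed_connectivity_self_excluded(self):
        rng = np.random.default_rng(13)
        roi = self._roi_table(rng)
        out = seed_connectivity(roi, "a")
        assert {rc.roi_label for rc in out} == {"b", "c"}

    def test_unknown_seed_rejected(self):
        rng = np.random.default_rng(14)
        with pytest.raises(StatsError, match="unknown seed"):
            seed_connectivity(self._roi_table(rng), "nope")


def test_gg_epsilon_lower_bound():
    # strongly non-spherical data pushes epsilon toward 1/(L-1)
    rng = np.random.default_rng(15)
    base = rng.normal(size=(12, 1))
    arr = np.concatenate([base, base * 1.001, rng.normal(size=(12, 1)) * 0.01,
                          rng.normal(size=(12, 1)) * 0.01], axis=1)[:, None, :]
    arr = arr.reshape(12, 4)
    eps = gg_epsilon(arr[:, :], axes=(1,))
    assert 1 / 3 <= eps < 0.9
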