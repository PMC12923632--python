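"""Mixed-model slopes, LRTs, BH FDR, stepwise AIC, seasonal and group scans."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from actisleep import SimulationConfig, simulate_feature_cohort
from actisleep.association import (
    bh_fdr,
    fit_day_level_model,
    group_compare,
    lrt,
    seasonal_scan,
    spearman_matrix,
    stepwise_aic,
)


class TestDayLevelModel:
    def test_zero_noise_slopes_exact(self):
        cfg = SimulationConfig(
            n_participants=30, n_days=6, seed=1, slope_case=-23.5, slope_control=-17.1,
            sigma_individual=0.0, sigma_family=0.0, sigma_resid=0.0,
        )
        df, _ = simulate_feature_cohort(cfg)
        res = fit_day_level_model(df, do_lrt=False)
        assert res.slope_case == pytest.approx(-23.5, abs=1e-6)
        assert res.slope_control == pytest.approx(-17.1, abs=1e-6)
        assert res.method == "ols"  # degenerate deterministic data

    def test_slope_identity_exact(self):
        cfg = SimulationConfig(n_participants=60, n_days=8, seed=2)
        df, _ = simulate_feature_cohort(cfg)
        res = fit_day_level_model(df, do_lrt=False)
        assert res.slope_case - res.slope_control == pytest.approx(res.interaction, abs=1e-10)

    def test_recovery_within_monte_carlo_tolerance(self):
        cases, controls = [], []
        for seed in (3, 4, 5):
            cfg = SimulationConfig(n_participants=300, n_days=18, seed=seed)
            df, truth = simulate_feature_cohort(cfg)
            res = fit_day_level_model(df, do_lrt=False)
            assert res.method == "mixedlm" and res.converged
            cases.append(res.slope_case)
            controls.append(res.slope_control)
        assert np.mean(cases) == pytest.approx(truth.slopes["case"], abs=1.0)
        assert np.mean(controls) == pytest.approx(truth.slopes["control"], abs=1.0)

    def test_zero_variance_components_flagged(self):
        cfg = SimulationConfig(
            n_participants=200, n_days=10, seed=4, sigma_individual=0.0, sigma_family=0.0,
        )
        df, _ = simulate_feature_cohort(cfg)
        res = fit_day_level_model(df, do_lrt=False)
        assert res.vc["family_var"] < 0.01 * res.vc["resid_var"]
        assert res.vc["participant_var"] < 0.01 * res.vc["resid_var"]
        assert res.singular

    def test_variance_components_recovered(self):
        cfg = SimulationConfig(n_participants=300, n_days=18, seed=5)
        df, _ = simulate_feature_cohort(cfg)
        res = fit_day_level_model(df, do_lrt=False)
        assert res.vc["resid_var"] == pytest.approx(40.0**2, rel=0.15)
        assert res.vc["participant_var"] == pytest.approx(20.0**2, rel=0.5)

    def test_non_nested_ids_rejected(self):
        cfg = SimulationConfig(n_participants=20, n_days=4, seed=6)
        df, _ = simulate_feature_cohort(cfg)
        df.loc[df.index[-1], "family_id"] = "F9999"
        with pytest.raises(ValueError):
            fit_day_level_model(df, do_lrt=False)

    def test_constant_outcome_rejected(self):
        cfg = SimulationConfig(n_participants=20, n_days=4, seed=7)
        df, _ = simulate_feature_cohort(cfg)
        df["total_sleep_min"] = 450.0
        with pytest.raises(ValueError):
            fit_day_level_model(df, do_lrt=False)

    def test_lrt_detects_real_exposure_effect(self):
        cfg = SimulationConfig(n_participants=100, n_days=8, seed=8)
        df, _ = simulate_feature_cohort(cfg)
        res = fit_day_level_model(df, do_lrt=True)
        assert res.lrt_exposure["p_value"] < 1e-6  # strong true slopes


class TestLRT:
    def _ols(self, y, X):
        return sm.OLS(y, sm.add_constant(X)).fit()

    def test_identical_models_statistic_zero(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=50)
        X = rng.normal(size=(50, 2))
        m = self._ols(y, X)
        out = lrt(m, m)
        assert out["statistic"] == 0.0 and out["p_value"] == 1.0

    def test_chi2_reference_quantile(self):
        assert stats.chi2.sf(3.84, 1) == pytest.approx(0.05, abs=0.001)

    def test_matches_deviance_difference_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 3))
        y = X[:, 0] * 2 + rng.normal(size=50)
        full = self._ols(y, X)
        red = self._ols(y, X[:, :2])
        out = lrt(red, full)
        assert out["statistic"] == pytest.approx(2 * (full.llf - red.llf))
        assert out["df"] == 1

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=30)
        big = self._ols(y, rng.normal(size=(30, 3)))
        small = self._ols(y, rng.normal(size=(30, 1)))
        with pytest.raises(ValueError):
            lrt(big, small)  # reversed order


class TestBH:
    def test_closed_form_triple(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        p = rng.random(100)
        got = bh_fdr(p)
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
        expect = np.empty_like(p)
        expect[order] = np.minimum(q_sorted, 1.0)
        assert np.allclose(got, expect)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(4)
        p = rng.random(50)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q <= 1.0).all() and (q >= p - 1e-12).all()

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, np.nan])


class TestStepwiseAIC:
    def test_informative_feature_selected_first(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(120, 11)), columns=[f"f{i}" for i in range(11)])
        y = 2.0 * X["f0"] + rng.normal(0, 1, 120)
        out = stepwise_aic(y, X)
        assert out["selected"][0] == "f0"

    def test_adding_true_feature_lowers_aic(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame({"f0": rng.normal(size=80)})
        y = 3.0 * X["f0"] + rng.normal(0, 0.5, 80)
        null_aic = sm.OLS(y, np.ones(80)).fit().aic
        out = stepwise_aic(y, X)
        assert out["aic"] < null_aic
        assert out["selected"] == ["f0"]

    def test_null_outcome_selects_little(self):
        """Zero-signal outcome: the intercept-only (or one-variable)
        model is typical. Each null candidate enters with chance
        ~P(chi2_1 > 2) = 0.157, so the check uses a small candidate set."""
        counts = []
        for seed in range(100):
            rng = np.random.default_rng(200 + seed)
            X = pd.DataFrame(rng.normal(size=(60, 3)), columns=[f"f{i}" for i in range(3)])
            y = pd.Series(rng.normal(size=60))
            counts.append(len(stepwise_aic(y, X)["selected"]))
        assert np.mean(np.array(counts) <= 1) >= 0.8

    def test_collinear_pair_dropped_before_search(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame({"a": rng.normal(size=50)})
        X["b"] = 2.0 * X["a"]
        X["c"] = rng.normal(size=50)
        y = X["a"] + rng.normal(0, 0.1, 50)
        out = stepwise_aic(y, X)
        assert out["dropped_collinear"] == ["b"]

    def test_r2_reported(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame({"a": rng.normal(size=100)})
        y = X["a"] + rng.normal(0, 1, 100)
        out = stepwise_aic(y, X)
        assert 0 < out["adj_r2"] <= out["r2"] < 1


def _season_frame(n_participants=30, days=40, effect_trait=None, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_participants):
        start = pd.Timestamp("2023-01-01") + pd.Timedelta(days=int(rng.integers(0, 330)))
        u = rng.normal(0, 1)
        for d in range(days):
            date = start + pd.Timedelta(days=d)
            row = {"participant_id": f"P{i}", "date": date}
            for t in ("t1", "t2", "t3"):
                val = u + rng.normal(0, 1)
                if t == effect_trait:
                    val += 2.0 * np.sin(2 * np.pi * date.dayofyear / 365.0)
                row[t] = val
            rows.append(row)
    return pd.DataFrame(rows)


class TestSeasonalScan:
    def test_injected_seasonality_flagged(self):
        df = _season_frame(effect_trait="t2", seed=9)
        out = seasonal_scan(df, ["t1", "t2", "t3"])
        assert out["t2"]["q_value"] < 0.05
        assert out["t2"]["pairwise"] is not None

    def test_all_four_seasons_give_six_pairs(self):
        df = _season_frame(effect_trait="t1", seed=10)
        out = seasonal_scan(df, ["t1", "t2", "t3"])
        assert len(out["t1"]["pairwise"]) == 6

    def test_null_traits_rarely_flagged(self):
        flags = 0
        for seed in range(5):
            df = _season_frame(effect_trait=None, seed=20 + seed)
            out = seasonal_scan(df, ["t1", "t2", "t3"])
            flags += sum(out[t]["q_value"] < 0.05 for t in ("t1", "t2", "t3"))
        assert flags <= 2  # ~5% expected rate over 15 trait-tests


def _group_frame(shift_features=(), shift=1.0, seed=0, n=40, groups=("sp", "ur")):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        g = groups[i % len(groups)]
        row = {
            "participant_id": f"P{i}", "group": g,
            "age": rng.uniform(18, 60), "sex": rng.choice(["F", "M"]),
        }
        for f in [f"f{j}" for j in range(10)]:
            v = rng.normal()
            if g == groups[0] and f in shift_features:
                v += shift
            row[f] = v
        rows.append(row)
    return pd.DataFrame(rows)


class TestGroupCompare:
    def test_shifted_features_rank_smallest_q(self):
        shifted = {"f0", "f1", "f2", "f3", "f4"}
        ranks = []
        for seed in range(5):
            df = _group_frame(shift_features=shifted, shift=1.2, seed=seed, n=80)
            out = group_compare(df, [f"f{j}" for j in range(10)], ("sp", "ur"))
            top5 = set(out.nsmallest(5, "q_value")["feature"])
            ranks.append(len(top5 & shifted))
        assert np.median(ranks) == 5

    def test_identical_groups_null_q_distribution(self):
        hits = 0
        for seed in range(5):
            df = _group_frame(seed=100 + seed, n=60)
            out = group_compare(df, [f"f{j}" for j in range(10)], ("sp", "ur"))
            hits += (out["p_value"] < 0.05).sum()
        assert hits <= 8  # binomial(50, 0.05) upper range

    def test_self_contrast_zero(self):
        df = _group_frame(seed=11)
        out = group_compare(df, ["f0"], ("sp", "sp"))
        assert out["estimate"].iloc[0] == 0.0

    def test_small_group_flagged_unstable(self):
        df = _group_frame(seed=12, n=40)
        df.loc[df["group"] == "ur", "group"] = "sp"
        df.loc[df.index[:2], "group"] = "tiny"
        out = group_compare(df, ["f0"], ("sp", "tiny"))
        assert out["unstable"].iloc[0]


class TestSpearman:
    def test_monotone_transform_rho_one(self):
        x = pd.DataFrame({"act": [1.0, 2.0, 5.0, 9.0]})
        y = pd.DataFrame({"slp": np.exp(x["act"])})
        out = spearman_matrix(x, y)
        assert out.loc["act", "slp"] == pytest.approx(1.0)

    def test_generator_coupling_negative_rho(self):
        cfg = SimulationConfig(n_participants=80, n_days=10, seed=13)
        df, _ = simulate_feature_cohort(cfg)
        means = df.groupby("participant_id")[["sedentary_hours", "total_sleep_min"]].mean()
        out = spearman_matrix(means[["sedentary_hours"]], means[["total_sleep_min"]])
        assert out.loc["sedentary_hours", "total_sleep_min"] < 0

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(14)
        a = pd.DataFrame({"a": rng.normal(size=20)})
        b = pd.DataFrame({"b": rng.normal(size=20)})
        out = spearman_matrix(a, b)
        ra, rb = stats.rankdata(a["a"]), stats.rankdata(b["b"])
        assert out.loc["a", "b"] == pytest.approx(np.corrcoef(ra, rb)[0, 1])

    def test_constant_column_missing(self):
        a = pd.DataFrame({"a": np.ones(5)})
        b = pd.DataFrame({"b": np.arange(5.0)})
        assert np.isnan(spearman_matrix(a, b).loc["a", "b"])

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            spearman_matrix(pd.DataFrame({"a": [1.0, 2.0]}), pd.DataFrame({"b": [1.0, 2.0]}))
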