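import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pmcal import calibration as cal
from pmcal.errors import ContractError, FormatError

from conftest import EQ1, make_exact_obs


class TestDewPoint:
    def test_saturation_identity(self):
        assert cal.dew_point(20.0, 100.0) == pytest.approx(20.0, abs=1e-9)

    def test_hand_evaluated_formula(self):
        assert cal.dew_point(25.0, 60.0) == pytest.approx(16.69, abs=0.01)

    def test_monotone_in_rh_and_below_temperature(self):
        rhs = np.linspace(5, 100, 40)
        dps = cal.dew_point(np.full(40, 30.0), rhs)
        assert np.all(np.diff(dps) > 0)
        assert np.all(dps <= 30.0 + 1e-9)

    def test_nonpositive_rh_rejected(self):
        with pytest.raises(ContractError):
            cal.dew_point(20.0, 0.0)


class TestBuildCollocation:
    def _sensor(self, hours):
        return pd.DataFrame({
            "hour": hours, "pa_cf1": 20.0, "rh": 80.0,
            "temperature": 25.0, "pressure": 1013.0,
        })

    def test_identical_grids_all_complete(self):
        hours = pd.date_range("2023-01-01", periods=100, freq="h")
        ref = pd.DataFrame({"hour": hours, "pm25_ref": 10.0})
        obs = cal.build_collocation(self._sensor(hours), ref)
        assert len(obs) == 100
        assert "dew_point" in obs.columns

    def test_partial_overlap_counts(self):
        sensor_hours = pd.date_range("2023-01-01", periods=100, freq="h")
        ref_hours = pd.date_range("2023-01-01 10:00", periods=90, freq="h")
        ref = pd.DataFrame({"hour": ref_hours, "pm25_ref": 10.0})
        obs = cal.build_collocation(self._sensor(sensor_hours), ref)
        assert len(obs) == 90  # hours 10..99 of the sensor grid

    def test_disjoint_ranges_error(self):
        ref = pd.DataFrame({
            "hour": pd.date_range("2024-06-01", periods=10, freq="h"),
            "pm25_ref": 10.0,
        })
        with pytest.raises(ContractError):
            cal.build_collocation(
                self._sensor(pd.date_range("2023-01-01", periods=10, freq="h")), ref
            )


class TestResidualFilter:
    def test_noise_free_data_loses_nothing(self):
        obs = make_exact_obs(300, seed=1, sigma=0.0)
        _, removed = cal.residual_outlier_filter(obs)
        assert removed == 0

    def test_gaussian_residual_removal_near_two_sided_tail(self):
        obs = make_exact_obs(20_000, seed=2, sigma=4.44)
        _, removed = cal.residual_outlier_filter(obs, k_sd=2.0)
        assert removed / 20_000 == pytest.approx(0.0455, abs=0.007)

    def test_small_samples_rejected(self):
        with pytest.raises(ContractError):
            cal.residual_outlier_filter(make_exact_obs(30))


class TestSplitAndCv:
    def test_whole_day_split_counts(self):
        obs = make_exact_obs(7236, seed=3)
        train, test = cal.chronological_split(obs)
        assert len(train) == 5784 and len(test) == 1452

    def test_small_example_split(self):
        train, test = cal.chronological_split(make_exact_obs(240, seed=4))
        assert len(train) == 192 and len(test) == 48

    def test_partition_preserves_order(self):
        obs = make_exact_obs(120, seed=5)
        train, test = cal.chronological_split(obs)
        rebuilt = pd.concat([train, test], ignore_index=True)
        pd.testing.assert_frame_equal(rebuilt, obs)

    def test_expanding_window_folds(self):
        folds = cal.expanding_window_cv(2304)
        assert [f[0].stop for f in folds] == [576, 1152, 1728]
        assert all(len(f[1]) == 576 for f in folds)

    def test_single_fold_boundary(self):
        assert len(cal.expanding_window_cv(1152)) == 1

    def test_validation_blocks_disjoint_contiguous(self):
        folds = cal.expanding_window_cv(24 * 200, initial=500, horizon=300, step=300)
        stops = [(f[1].start, f[1].stop) for f in folds]
        for (s1, e1), (s2, e2) in zip(stops, stops[1:]):
            assert s2 == e1

    def test_too_small_training_set(self):
        with pytest.raises(ContractError):
            cal.expanding_window_cv(1000)


class TestLinearFits:
    def test_noise_free_recovery_of_final_model(self):
        obs = make_exact_obs(500, seed=6, sigma=0.0)
        fit = cal.fit_model(cal.ModelSpec.from_id("lin3"), obs)
        assert fit.coefficients["Intercept"] == pytest.approx(EQ1["Intercept"], abs=1e-8)
        assert fit.coefficients["pa_cf1"] == pytest.approx(EQ1["pa_cf1"], abs=1e-10)
        assert fit.coefficients["rh"] == pytest.approx(EQ1["rh"], abs=1e-10)

    def test_identity_data_gives_identity_line(self):
        obs = make_exact_obs(100, seed=7)
        obs["pm25_ref"] = obs["pa_cf1"]
        fit = cal.fit_model(cal.ModelSpec.from_id("lin1"), obs)
        assert fit.coefficients["Intercept"] == pytest.approx(0.0, abs=1e-8)
        assert fit.coefficients["pa_cf1"] == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("spec_id", [f"lin{i}" for i in range(1, 12)])
    def test_matches_normal_equations_oracle(self, spec_id):
        obs = make_exact_obs(150, seed=8, sigma=2.0)
        fit = cal.fit_model(cal.ModelSpec.from_id(spec_id), obs)
        # brute-force design matrix from the formula's term names
        names = list(fit.coefficients)
        X = np.ones((len(obs), len(names)))
        for j, name in enumerate(names):
            if name == "Intercept":
                continue
            parts = name.split(":")
            col = np.ones(len(obs))
            for p in parts:
                col = col * obs[p].to_numpy()
            X[:, j] = col
        beta = np.linalg.solve(X.T @ X, X.T @ obs["pm25_ref"].to_numpy())
        assert np.allclose(beta, [fit.coefficients[n] for n in names], atol=1e-8)

    def test_degrees_of_freedom_bookkeeping(self):
        obs = make_exact_obs(600, seed=9, sigma=1.0)
        fit = cal.fit_model(cal.ModelSpec.from_id("lin3"), obs)
        assert fit.df_resid == 600 - 3

    def test_nonfinite_training_data_rejected(self):
        obs = make_exact_obs(100, seed=10)
        obs.loc[5, "pa_cf1"] = np.nan
        with pytest.raises(ContractError):
            cal.fit_model(cal.ModelSpec.from_id("lin3"), obs)


class TestPredict:
    def _point(self, pa, rh):
        return pd.DataFrame({
            "pa_cf1": [pa], "rh": [rh], "temperature": [25.0],
            "pressure": [1013.0], "dew_point": [16.0],
        })

    def test_benchmark_at_origin(self):
        fit = cal.fit_model(cal.ModelSpec.from_id("barkjohn"), None)
        assert cal.predict(fit, self._point(0.0, 0.0))[0] == pytest.approx(5.75)

    def test_benchmark_ignores_training_data_and_seed(self):
        f1 = cal.fit_model(cal.ModelSpec.from_id("barkjohn"), make_exact_obs(60), seed=1)
        f2 = cal.fit_model(cal.ModelSpec.from_id("barkjohn"), None, seed=99)
        pt = self._point(33.3, 77.0)
        assert cal.predict(f1, pt)[0] == cal.predict(f2, pt)[0]

    def test_final_model_worked_value(self):
        fit = cal.fit_model(cal.ModelSpec.from_id("lin3"), make_exact_obs(300, sigma=0.0))
        assert cal.predict(fit, self._point(20.0, 80.0))[0] == pytest.approx(7.5151, abs=1e-6)

    def test_noise_free_fit_reproduces_training_targets(self):
        obs = make_exact_obs(200, seed=11, sigma=0.0)
        fit = cal.fit_model(cal.ModelSpec.from_id("lin3"), obs)
        assert np.allclose(cal.predict(fit, obs), obs["pm25_ref"], atol=1e-8)

    def test_missing_covariate_is_a_format_error(self):
        fit = cal.fit_model(cal.ModelSpec.from_id("lin3"), make_exact_obs(100))
        with pytest.raises(FormatError, match="rh"):
            cal.predict(fit, pd.DataFrame({"pa_cf1": [1.0]}))


class TestEvaluate:
    def test_perfect_prediction(self):
        m = cal.evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.rmse == 0 and m.bias == 0 and m.mae == 0 and m.mape == 0
        assert m.r2_pearson == pytest.approx(1.0)
        assert m.ba_loa_low == 0 and m.ba_loa_high == 0

    def test_hand_computed_metrics(self):
        m = cal.evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert m.bias == pytest.approx(-1 / 3)
        assert m.mae == pytest.approx(1 / 3)
        assert m.rmse == pytest.approx(1 / math.sqrt(3), abs=1e-4)
        assert m.mape == pytest.approx(100 / 12, abs=1e-3)
        assert m.r2_pearson == pytest.approx(0.9643, abs=1e-4)

    def test_constant_reference_nulls_correlations(self):
        m = cal.evaluate([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert m.r2_pearson is None and m.spearman_rho is None
        assert m.rmse > 0

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=20),
           st.integers(0, 10_000))
    def test_rmse_dominates_bias_and_loa_bracket_mean(self, pred, seed):
        rng = np.random.default_rng(seed)
        obs = rng.uniform(1, 50, len(pred))
        m = cal.evaluate(pred, obs)
        assert m.rmse >= abs(m.bias) - 1e-12
        assert m.ba_loa_low <= m.ba_mean_diff <= m.ba_loa_high


class TestApplyCalibration:
    def test_floor_rule_after_prediction(self):
        fit = cal.fit_model(cal.ModelSpec.from_id("lin3"), make_exact_obs(300, sigma=0.0))
        pts = pd.DataFrame({"pa_cf1": [0.0, 0.0], "rh": [0.0 + 1e-9, 40.0]})
        out = cal.apply_calibration(fit, pts)
        assert out.iloc[0] == pytest.approx(2.9271, abs=1e-6)
        # 2.9271 − 0.0675·40 = 0.2271 < 1 → substituted with 1/√2
        assert out.iloc[1] == pytest.approx(1 / math.sqrt(2))

    def test_monotone_in_raw_signal(self):
        fit = cal.fit_model(cal.ModelSpec.from_id("lin3"), make_exact_obs(300, sigma=0.0))
        pts = pd.DataFrame({"pa_cf1": np.linspace(0, 100, 30), "rh": 50.0})
        out = cal.apply_calibration(fit, pts)
        assert (np.diff(out) >= -1e-12).all()


class TestMlAndTimeSeries:
    def test_tree_models_beat_raw_sensor_error(self):
        train = make_exact_obs(600, seed=12, sigma=4.44)
        test = make_exact_obs(200, seed=13, sigma=4.44)
        raw_rmse = cal.evaluate(test["pa_cf1"], test["pm25_ref"]).rmse
        for sid in ("rf", "gbm", "gam"):
            fit = cal.fit_model(cal.ModelSpec.from_id(sid), train, seed=0)
            rmse = cal.evaluate(cal.predict(fit, test), test["pm25_ref"].to_numpy()).rmse
            assert rmse < raw_rmse, sid

    def test_arimax_smoke_with_small_order(self):
        train = make_exact_obs(300, seed=14, sigma=2.0)
        test = make_exact_obs(24, seed=15, sigma=2.0)
        spec = cal.ModelSpec("arimax", "arimax", hyperparams={"order": (1, 0, 1)})
        fit = cal.fit_model(spec, train, seed=0)
        if fit.converged:
            pred = cal.predict(fit, test)
            assert len(pred) == 24 and np.isfinite(pred).all()

    def test_cv_validation_rmse_tracks_noise_scale(self):
        obs = make_exact_obs(2304, seed=16, sigma=4.44)
        folds = cal.expanding_window_cv(len(obs))
        rmses = []
        for tr, va in folds:
            fit = cal.fit_model(cal.ModelSpec.from_id("lin3"), obs.iloc[list(tr)])
            pred = cal.predict(fit, obs.iloc[list(va)])
            rmses.append(cal.evaluate(pred, obs["pm25_ref"].iloc[list(va)].to_numpy()).rmse)
        assert np.mean(rmses) == pytest.approx(4.44, rel=0.10)

    def test_nuisance_covariates_stay_insignificant(self):
        hits = 0
        n_rep = 40
        for seed in range(n_rep):
            obs = make_exact_obs(400, seed=1000 + seed, sigma=4.44)
            fit = cal.fit_model(cal.ModelSpec.from_id("lin8"), obs)  # + T, P, T:P
            res = fit.handle
            hits += res.pvalues["temperature"] > 0.05
        assert hits >= 33  # ~95 % of replicates at the 5 % level


class TestImputation:
    def test_gap_free_frame_is_identity(self):
        obs = make_exact_obs(100, seed=17)
        filled, mask = cal.impute_gaps(obs)
        pd.testing.assert_frame_equal(filled, obs)
        assert not mask.to_numpy().any()

    def test_single_gap_in_constant_column(self):
        obs = make_exact_obs(100, seed=18)
        obs["pressure"] = 1013.0
        obs.loc[50, "pressure"] = np.nan
        filled, mask = cal.impute_gaps(obs)
        assert filled.loc[50, "pressure"] == pytest.approx(1013.0)
        assert int(mask.to_numpy().sum()) == 1

    def test_mcar_gaps_beat_mean_imputation(self):
        obs = make_exact_obs(400, seed=19, sigma=1.0)
        rng = np.random.default_rng(20)
        gappy = obs.copy()
        holes = rng.random(len(obs)) < 0.05
        truth = obs.loc[holes, "pm25_ref"].to_numpy()
        gappy.loc[holes, "pm25_ref"] = np.nan
        filled, _ = cal.impute_gaps(gappy, seed=0)
        rmse_model = np.sqrt(np.mean((filled.loc[holes, "pm25_ref"] - truth) ** 2))
        rmse_mean = np.sqrt(np.mean((gappy["pm25_ref"].mean() - truth) ** 2))
        assert rmse_model < rmse_mean

    def test_fully_missing_column_rejected(self):
        obs = make_exact_obs(60, seed=21)
        obs["rh"] = np.nan
        with pytest.raises(ContractError):
            cal.impute_gaps(obs)
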