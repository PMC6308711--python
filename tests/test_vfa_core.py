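"""Virtual-force state, combiners, regressors and the linear diagnostic."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vfinsole as vf

# Published worked frame for one scan-experiment instant: raw channel (ADC)
# readings, the estimated virtual forces, the fixed sensor x coordinates and
# the estimated moving x coordinates for the six areas A-F.
WORKED_ADC = np.array([55.0, 132.0, 0.0, 154.0, 0.0, 0.0])
WORKED_FORCES = np.array([23.418, 104.242, 0.0, 286.743, 0.0, 0.0])
WORKED_FIXED_X = np.array([7.0, 12.0, 12.0, 25.5, 9.25, 3.5])
WORKED_MOVING_X = np.array([5.684, 12.034, np.nan, 25.692, np.nan, np.nan])


def _state(F, xy, t=0.0):
    return vf.VirtualForceState(t=t, F=np.asarray(F, float), xy=np.asarray(xy, float))


def _random_state(rng, geometry, p_zero=0.3):
    F = rng.uniform(0, 400, 6)
    F[rng.random(6) < p_zero] = 0.0
    xy = np.full((6, 2), np.nan)
    for i in range(6):
        if F[i] > 0:
            x0, x1, y0, y1 = geometry.bounds[i]
            xy[i] = (rng.uniform(x0, x1), rng.uniform(y0, y1))
    return _state(F, xy)


class TestGeometry:
    def test_default_geometry_is_valid(self, geometry):
        assert geometry.sensor_xy.shape == (6, 2)
        np.testing.assert_array_equal(geometry.sensor_xy[:, 0], WORKED_FIXED_X)

    def test_sensor_outside_bounds_rejected(self, geometry):
        bad = geometry.sensor_xy.copy()
        bad[0] = (27.0, 10.0)
        with pytest.raises(ValueError, match="outside its area bounds"):
            vf.AreaGeometry(sensor_xy=bad)

    def test_round_trip(self, geometry):
        again = vf.AreaGeometry.from_dict(geometry.to_dict())
        np.testing.assert_array_equal(again.bounds, geometry.bounds)


class TestGrf:
    def test_zero_forces_sum_to_zero(self):
        s = _state(np.zeros(6), np.full((6, 2), np.nan))
        assert vf.grf(s) == 0.0

    def test_worked_frame_force_sum(self):
        xy = np.full((6, 2), np.nan)
        xy[WORKED_FORCES > 0] = 0.0
        s = _state(WORKED_FORCES, xy)
        assert vf.grf(s) == pytest.approx(414.403, abs=1e-9)

    def test_matches_exact_rational_summation_oracle(self, rng, geometry):
        # fsum returns the correctly rounded true sum; an exact Fraction
        # accumulation rounded back to float must agree bit for bit
        for _ in range(200):
            s = _random_state(rng, geometry)
            exact = float(sum(Fraction(v) for v in s.F))
            assert vf.grf(s) == exact


class TestWmaCop:
    def test_single_loaded_area_returns_its_coordinate(self):
        xy = np.full((6, 2), np.nan)
        xy[3] = (10.0, 4.0)
        F = np.zeros(6)
        F[3] = 100.0
        assert vf.wma_cop(_state(F, xy)) == (10.0, 4.0)

    def test_equal_forces_give_midpoint(self):
        xy = np.full((6, 2), np.nan)
        xy[0] = (5.0, 2.0)
        xy[1] = (25.0, 8.0)
        F = np.array([50.0, 50.0, 0, 0, 0, 0])
        x, y = vf.wma_cop(_state(F, xy))
        assert x == pytest.approx(15.0)
        assert y == pytest.approx(5.0)

    def test_worked_frame_moving_coordinate_cop(self):
        # weighted mean of the published moving x coordinates and forces
        xy = np.full((6, 2), np.nan)
        loaded = WORKED_FORCES > 0
        xy[loaded, 0] = WORKED_MOVING_X[loaded]
        xy[loaded, 1] = 5.0
        x, _ = vf.wma_cop(_state(WORKED_FORCES, xy))
        assert x == pytest.approx(21.13, abs=0.01)

    def test_all_zero_forces_signal_undefined(self):
        with pytest.raises(vf.CopUndefinedError):
            vf.wma_cop(_state(np.zeros(6), np.full((6, 2), np.nan)))

    def test_positive_force_with_undefined_coordinate_is_invariant_violation(self):
        F = np.array([10.0, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="undefined coordinate"):
            vf.wma_cop(_state(F, np.full((6, 2), np.nan)))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        F=st.lists(st.floats(0.0, 500.0), min_size=6, max_size=6),
        xs=st.lists(st.floats(0.0, 28.0), min_size=6, max_size=6),
        ys=st.lists(st.floats(0.0, 11.0), min_size=6, max_size=6),
    )
    def test_cop_bounded_by_defined_coordinate_extremes(self, F, xs, ys):
        # a weighted mean with non-negative weights cannot leave the
        # coordinate range of the contributing areas
        F = np.asarray(F)
        if not np.any(F > 0):
            return
        xy = np.column_stack([xs, ys]).astype(float)
        xy[F == 0] = np.nan
        x, y = vf.wma_cop(_state(F, xy))
        defined = F > 0
        assert min(xy[defined, 0]) - 1e-9 <= x <= max(xy[defined, 0]) + 1e-9
        assert min(xy[defined, 1]) - 1e-9 <= y <= max(xy[defined, 1]) + 1e-9

    def test_cop_inside_hull_of_defined_coordinates(self, rng, geometry):
        from shapely.geometry import MultiPoint, Point

        for _ in range(300):
            s = _random_state(rng, geometry, p_zero=0.4)
            if not np.any(s.F > 0):
                continue
            cop = vf.wma_cop(s)
            pts = MultiPoint([tuple(p) for p in s.xy[s.defined]])
            assert pts.convex_hull.buffer(1e-9).contains(Point(cop))


class TestFixedWma:
    def test_single_nonzero_channel_pins_cop_to_its_sensor(self, geometry):
        ch = np.zeros(6)
        ch[3] = 42.0
        assert vf.fixed_wma_cop(ch, geometry) == tuple(geometry.sensor_xy[3])

    def test_worked_frame_adc_weighted_fixed_cop(self, geometry):
        # hand arithmetic: (55*7 + 132*12 + 154*25.5) / 341 = 17.29
        x, _ = vf.fixed_wma_cop(WORKED_ADC, geometry)
        assert x == pytest.approx(17.29, abs=0.01)

    def test_zero_channel_sum_signals_undefined(self, geometry):
        with pytest.raises(vf.CopUndefinedError):
            vf.fixed_wma_cop(np.zeros(6), geometry)

    def test_reduction_from_moving_cop(self, rng, geometry):
        # moving-coordinate CoP with coordinates pinned to the fixed sensor
        # positions and forces equal to channel values IS the fixed baseline
        for _ in range(200):
            ch = rng.uniform(0, 100, 6)
            ch[rng.random(6) < 0.3] = 0.0
            if ch.sum() == 0:
                continue
            xy = np.where((ch > 0)[:, None], geometry.sensor_xy, np.nan)
            assert vf.wma_cop(_state(ch, xy)) == vf.fixed_wma_cop(ch, geometry)

    def test_series_version_matches_frame_version(self, rng, geometry):
        ch = rng.uniform(0, 100, size=(50, 6))
        series = vf.fixed_wma_cop_series(ch, geometry)
        for i in range(50):
            np.testing.assert_allclose(
                series[i], vf.fixed_wma_cop(ch[i], geometry), rtol=1e-12
            )


class TestProportionalRates:
    def test_worked_frame_adc_rates(self):
        rates = vf.proportional_rates(WORKED_ADC)
        np.testing.assert_allclose(
            np.round(rates, 2), [1.0, 2.4, 0.0, 2.8, 0.0, 0.0]
        )

    def test_worked_frame_force_rates(self):
        rates = vf.proportional_rates(WORKED_FORCES)
        np.testing.assert_allclose(
            np.round(rates, 2), [1.0, 4.45, 0.0, 12.24, 0.0, 0.0]
        )


TABLE_COEFFS = vf.LinearCoeffs(a=(79.160, 0.316, 3.155, 0.321, -0.387, -0.016, -1.253))


class TestLinearDiagnostic:
    def test_intercept_at_zero_input(self):
        assert vf.linear_force_estimate(np.zeros(6), TABLE_COEFFS) == pytest.approx(
            79.160, abs=1e-9
        )

    def test_worked_frame_estimate(self):
        est = vf.linear_force_estimate(WORKED_ADC, TABLE_COEFFS)
        assert est == pytest.approx(453.402, abs=1e-9)

    def test_zero_coefficients_map_everything_to_zero(self, rng):
        zero = vf.LinearCoeffs(a=(0.0,) * 7)
        assert vf.linear_force_estimate(rng.uniform(0, 100, 6), zero) == 0.0

    def test_exact_recovery_inside_model_class(self, rng):
        truth = np.array([12.0, 0.5, 2.0, -1.0, 0.3, -0.2, 1.5])
        ch = rng.uniform(0, 50, size=(200, 6))
        y = truth[0] + ch @ truth[1:]
        fit = vf.fit_linear_diagnostic(ch, y)
        np.testing.assert_allclose(fit.a, truth, atol=1e-6)

    def test_residuals_orthogonal_to_design(self, rng):
        ch = rng.uniform(0, 50, size=(500, 6))
        y = 5 + ch @ np.arange(1.0, 7.0) + rng.normal(0, 3, 500)
        fit = vf.fit_linear_diagnostic(ch, y)
        resid = y - np.array([vf.linear_force_estimate(c, fit) for c in ch])
        design = np.column_stack([np.ones(500), ch])
        assert np.max(np.abs(design.T @ resid)) / len(y) < 1e-6

    def test_noisy_recovery_within_sampling_error(self, rng):
        # closed-form OLS covariance oracle: each coefficient within 3 SE
        truth = np.array([10.0, 1.0, -2.0, 0.5, 3.0, -0.7, 0.1])
        n, sigma = 10_000, 4.0
        ch = rng.uniform(0, 50, size=(n, 6))
        y = truth[0] + ch @ truth[1:] + rng.normal(0, sigma, n)
        fit = vf.fit_linear_diagnostic(ch, y)
        design = np.column_stack([np.ones(n), ch])
        cov = sigma**2 * np.linalg.inv(design.T @ design)
        se = np.sqrt(np.diag(cov))
        assert np.all(np.abs(np.array(fit.a) - truth) < 3 * se)

    def test_constant_target_gives_pure_intercept(self, rng):
        ch = rng.uniform(0, 50, size=(100, 6))
        fit = vf.fit_linear_diagnostic(ch, np.full(100, 7.5))
        assert fit.a[0] == pytest.approx(7.5, abs=1e-9)
        np.testing.assert_allclose(fit.a[1:], 0.0, atol=1e-9)

    def test_rank_deficient_design_names_columns(self, rng):
        ch = rng.uniform(0, 50, size=(100, 6))
        ch[:, 2] = 2.0 * ch[:, 1]  # chC dependent on chB
        with pytest.raises(ValueError, match="dependent column"):
            vf.fit_linear_diagnostic(ch, rng.normal(size=100))


class TestTrainRegressor:
    SPEC = vf.RegressorSpec(n_hidden=5, seed=3, max_epochs=120)

    def _features(self, rng, n=400):
        return rng.uniform(-1, 1, size=(n, 18))

    def test_constant_target_warns_and_predicts_constant(self, rng):
        X = self._features(rng)
        with pytest.warns(UserWarning, match="constant"):
            net = vf.train_regressor(X, np.zeros(X.shape[0]), self.SPEC)
        assert abs(net.predict(X[0])) < 1e-3
        np.testing.assert_allclose(net.predict(X), 0.0, atol=1e-3)

    def test_nan_inputs_rejected(self, rng):
        X = self._features(rng)
        X[3, 3] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            vf.train_regressor(X, np.ones(X.shape[0]), self.SPEC)

    def test_linear_function_learned_to_sub_percent(self, rng):
        # a linear target lies inside the model class; held-out RMSE must be
        # tiny against the exact linear least-squares oracle residual (zero)
        X = self._features(rng, n=2000)
        y = 2.0 * X[:, 0]
        coef, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(len(y)), X]), y, rcond=None
        )
        oracle_resid = y - np.column_stack([np.ones(len(y)), X]) @ coef
        assert np.max(np.abs(oracle_resid)) < 1e-9
        net = vf.train_regressor(X, y, vf.RegressorSpec(n_hidden=10, seed=0))
        assert net.test_rmse < 0.01 * np.ptp(y)

    def test_training_is_seed_deterministic(self, rng):
        X = self._features(rng, n=300)
        y = np.sin(X[:, 0]) + 0.5 * X[:, 1]
        a = vf.train_regressor(X, y, self.SPEC)
        b = vf.train_regressor(X, y, self.SPEC)
        assert abs(a.test_rmse - b.test_rmse) < 1e-9
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_prediction_is_pure(self, rng):
        X = self._features(rng, n=200)
        net = vf.train_regressor(X, X[:, 0] ** 2, self.SPEC)
        p1 = net.predict(X[:10])
        p2 = net.predict(X[:10])
        np.testing.assert_array_equal(p1, p2)

    def test_too_few_frames_rejected(self, rng):
        X = self._features(rng, n=50)
        with pytest.raises(ValueError, match="at least 100"):
            vf.train_regressor(X, np.ones(50), self.SPEC)

    def test_scan_task_force_recovery(self):
        # parameter recovery against the simulator's known channel-to-force
        # mapping: area D force from scan-task data
        trial = vf.simulate_trial("scan", 60.0, seed=1)
        cond = vf.ConditioningConfig().condition(trial.t, trial.sensed)
        X = vf.build_feature_matrix(cond, 1.0 / trial.fs)
        y = trial.truth_F[:, 3]
        net = vf.train_regressor(X, y, vf.RegressorSpec(n_hidden=10, seed=1))
        assert net.test_rmse < 0.10 * np.ptp(y)

    def test_serialization_round_trip(self, rng):
        X = self._features(rng, n=200)
        net = vf.train_regressor(X, X[:, 2] + X[:, 3] ** 2, self.SPEC)
        again = vf.TrainedRegressor.from_dict(net.to_dict())
        np.testing.assert_array_equal(net.predict(X), again.predict(X))


class TestPredictState:
    def test_state_invariants_hold_for_random_inputs(self, small_model, rng):
        for _ in range(50):
            row = rng.uniform(-200, 200, 18)
            state = small_model.predict_frame(row)
            vf.validate_state(state, small_model.geometry)

    def test_zero_input_gives_all_undefined(self, noise_free_model):
        # nets trained on data where an unloaded insole has zero channels:
        # a zero feature vector must fall below the dead band everywhere
        state = noise_free_model.predict_frame(np.zeros(18))
        assert np.all(state.F == 0.0)
        assert not state.defined.any()

    def test_heel_only_load_activates_heel_area(self, small_model):
        # simulate pressure under the heel only (area F, posterior insole)
        trial = vf.simulate_trial("gait1", 12.0, seed=9)
        stance = trial.truth_F[:, 5] > 100  # heel loaded
        early = stance & (trial.truth_F[:, 3] < 1.0)  # toe not yet loaded
        idx = int(np.flatnonzero(early)[5])
        cond = small_model.conditioning.condition(trial.t, trial.sensed)
        X = vf.build_feature_matrix(cond, 1.0 / trial.fs)
        state = small_model.predict_frame(X[idx])
        assert state.F[5] > small_model.dead_band  # heel active
        assert state.F[3] < 0.25 * state.F[5]  # toe, if any, far smaller

    def test_wrong_net_count_rejected(self, small_model):
        with pytest.raises(ValueError, match="6 trained force nets"):
            vf.predict_state(
                np.zeros(18),
                small_model.force_nets[:5],
                small_model.coord_x_nets + small_model.coord_y_nets,
                small_model.geometry,
            )


class TestVfaModelBundle:
    def test_save_load_round_trip(self, small_model, tmp_path, rng):
        X = rng.uniform(0, 100, size=(20, 18))
        small_model.save(tmp_path / "bundle")
        again = vf.VfaModel.load(tmp_path / "bundle")
        a = small_model.predict_series(X)
        b = again.predict_series(X)
        np.testing.assert_array_equal(a["grf"], b["grf"])
        np.testing.assert_array_equal(a["cop"], b["cop"])

    def test_predict_series_matches_frame_prediction(self, small_model, rng):
        X = rng.uniform(0, 50, size=(10, 18))
        out = small_model.predict_series(X)
        for i in range(10):
            state = small_model.predict_frame(X[i])
            np.testing.assert_allclose(out["F"][i], state.F, rtol=1e-12)
            assert out["grf"][i] == pytest.approx(vf.grf(state), rel=1e-12)
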