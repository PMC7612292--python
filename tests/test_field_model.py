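"""Design matrix layout, pseudoinverse fitting, prediction, sliding correction."""

import warnings

import numpy as np
import pytest

import harmfield as hf
from harmfield.field_model import (
    DegenerateFitWarning,
    DynamicRangeWarning,
    FieldRecording,
    HarmonicModel,
    WindowedModelSeries,
    _window_slices,
    build_design_matrix,
    fit,
    predict,
    sliding_correct,
    stack_response,
)


def clean_system(duration=10.0, fs=60.0, n_sensors=10, seed=7, l_max=2):
    noise = hf.NoiseSpec(sensor_sigma=0.0, marker_jitter=0.0, occlusion_rate=0.0)
    sc = hf.simulate_dataset(duration=duration, fs=fs, n_sensors=n_sensors, seed=seed, noise=noise)
    pos, ori = hf.channel_world_pose(sc["array"], sc["poses"])
    X = build_design_matrix(pos, ori, l_max)
    Y = stack_response(sc["recording"].data)
    return sc, X, Y


class TestDesignMatrix:
    def test_first_order_x_channel_pattern(self):
        pos = np.array([[[0.1, 0.2, 0.3], [0.4, 0.5, 0.6]]])  # (M=1, T=2, 3)
        ori = np.tile([1.0, 0.0, 0.0], (1, 2, 1))
        X = build_design_matrix(pos, ori, 1)
        assert X.shape == (2, 1 + 3)
        np.testing.assert_allclose(X[:, 0], 1.0)  # offset column
        np.testing.assert_allclose(X[:, 1:3], 0.0, atol=1e-12)  # (1,-1), (1,0)
        np.testing.assert_allclose(X[:, 3], np.sqrt(3 / (4 * np.pi)), atol=1e-12)  # (1,1)

    def test_column_count_for_full_array(self):
        array = hf.make_head_array(n_sensors=43)
        pos = np.tile(array.positions[:, None, :], (1, 2, 1))
        ori = np.tile(array.orientations[:, None, :], (1, 2, 1))
        X = build_design_matrix(pos, ori, 2)
        assert X.shape == (86 * 2, 86 + 8)  # 94 columns

    def test_offset_block_rows_sum_to_one(self, small_clean_scenario):
        sc = small_clean_scenario
        pos, ori = hf.channel_world_pose(sc["array"], sc["poses"])
        M = sc["array"].n_channels
        X = build_design_matrix(pos[:, :5], ori[:, :5], 1)
        np.testing.assert_array_equal(X[:, :M].sum(axis=1), 1.0)
        # channel-major stacking: row k belongs to channel k // T
        T = 5
        for k in range(0, X.shape[0], 7):
            assert X[k, : M].argmax() == k // T

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_design_matrix(np.zeros((2, 3, 3)), np.zeros((3, 3, 3)), 1)


class TestFit:
    def test_noiseless_recovery(self):
        sc, X, Y = clean_system()
        model = fit(Y, X, sc["recording"].channel_ids)
        truth = sc["truth"]
        np.testing.assert_allclose(model.beta, truth["beta_static"], rtol=1e-8)
        offs = np.array([model.offsets[c] for c in sc["recording"].channel_ids])
        np.testing.assert_allclose(offs, truth["offsets"], atol=1e-8)

    def test_zero_motion_raises_degeneracy_warning(self):
        array = hf.make_head_array(n_sensors=6)
        ts = np.arange(100) / 60.0
        poses = hf.RigidPoseSeries(ts, np.tile(np.eye(3), (100, 1, 1)), np.zeros((100, 3)))
        pos, ori = hf.channel_world_pose(array, poses)
        X = build_design_matrix(pos, ori, 1)
        Y = stack_response(np.ones((array.n_channels, 100)))
        with pytest.warns(DegenerateFitWarning):
            model = fit(Y, X, array.channel_ids)
        assert np.all(np.isfinite(model.beta))  # minimum-norm solution returned

    def test_pure_offsets_give_zero_beta(self):
        sc, X, Y = clean_system()
        M = sc["array"].n_channels
        offsets = np.linspace(-1.0, 1.0, M)
        T = sc["recording"].n_samples
        Y_const = stack_response(np.tile(offsets[:, None], (1, T)))
        model = fit(Y_const, X, sc["recording"].channel_ids)
        np.testing.assert_allclose(model.beta, 0.0, atol=1e-10)
        got = np.array([model.offsets[c] for c in sc["recording"].channel_ids])
        np.testing.assert_allclose(got, offsets, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        """Pseudoinverse fit equals (XᵀX)⁻¹XᵀY on a well-conditioned instance."""
        sc, X, Y = clean_system(duration=2.0, fs=10.0, n_sensors=5)  # 200 rows? -> 5*2=10 ch * 20 = 200
        assert X.shape[0] == 200
        Y = Y + rng.normal(0, 0.05, len(Y))
        model = fit(Y, X, sc["recording"].channel_ids)
        coef_oracle = np.linalg.solve(X.T @ X, X.T @ Y)
        coef = np.concatenate([[model.offsets[c] for c in sc["recording"].channel_ids], model.beta])
        np.testing.assert_allclose(coef, coef_oracle, atol=1e-8)

    def test_non_finite_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit(np.array([np.nan, 1.0]), np.ones((2, 4)), ["a"])

    def test_nested_rss_non_increasing_in_order(self, small_noisy_scenario):
        sc = small_noisy_scenario
        pos, ori = hf.channel_world_pose(sc["array"], sc["poses"])
        Y = stack_response(sc["recording"].data)
        rss = []
        for l_max in range(1, 7):
            X = build_design_matrix(pos, ori, l_max)
            model = fit(Y, X, sc["recording"].channel_ids)
            coef = np.concatenate([[model.offsets[c] for c in sc["recording"].channel_ids], model.beta])
            rss.append(float(np.sum((Y - X @ coef) ** 2)))
        assert all(rss[i + 1] <= rss[i] + 1e-9 for i in range(len(rss) - 1))

    def test_estimate_error_shrinks_with_sample_size(self):
        """β error ~ 1/√N: two decades of N shrink the error about tenfold."""
        noise = hf.NoiseSpec(sensor_sigma=0.1, marker_jitter=0.0, occlusion_rate=0.0)
        errs = []
        for n_samples in (240, 2400, 24000):
            per_seed = []
            for seed in range(3):
                sc = hf.simulate_dataset(
                    duration=n_samples / 240.0, fs=240.0, n_sensors=4, seed=seed, noise=noise
                )
                pos, ori = hf.channel_world_pose(sc["array"], sc["poses"])
                X = build_design_matrix(pos, ori, 2)
                model = fit(stack_response(sc["recording"].data), X, sc["recording"].channel_ids)
                per_seed.append(np.linalg.norm(model.beta - sc["truth"]["beta_static"]))
            errs.append(np.mean(per_seed))
        assert errs[0] > errs[1] > errs[2]
        ratio = errs[0] / errs[2]  # expected √100 = 10
        assert 3.0 < ratio < 33.0


class TestPredict:
    def test_training_prediction_equals_design_product(self):
        sc, X, Y = clean_system()
        model = fit(Y, X, sc["recording"].channel_ids)
        pos, ori = hf.channel_world_pose(sc["array"], sc["poses"])
        pred = predict(model, pos, ori, sc["recording"].channel_ids)
        coef = np.concatenate([[model.offsets[c] for c in sc["recording"].channel_ids], model.beta])
        np.testing.assert_allclose(stack_response(pred), X @ coef, atol=1e-10)

    def test_uniform_model_is_position_independent(self):
        model = HarmonicModel(l_max=1, beta=[0.5, -0.2, 1.0], offsets={"a": 0.0})
        ori = np.tile([0.0, 0.0, 1.0], (1, 4, 1))
        pos1 = np.zeros((1, 4, 3))
        pos2 = np.random.default_rng(0).normal(size=(1, 4, 3))
        np.testing.assert_allclose(
            predict(model, pos1, ori, ["a"]), predict(model, pos2, ori, ["a"]), atol=1e-12
        )

    def test_generalizes_to_held_out_trajectory(self):
        """Order-2 truth fitted at order 2 predicts unvisited poses exactly."""
        sc, X, Y = clean_system(seed=3)
        model = fit(Y, X, sc["recording"].channel_ids)
        noise = hf.NoiseSpec(sensor_sigma=0.0, marker_jitter=0.0, occlusion_rate=0.0)
        other = hf.simulate_dataset(duration=5.0, fs=60.0, n_sensors=10, seed=99, noise=noise, room=sc["room"])
        # same room and array geometry, new trajectory; offsets differ per run
        pos, ori = hf.channel_world_pose(other["array"], other["poses"])
        pred = predict(model, pos, ori, other["recording"].channel_ids, include_offsets=False)
        truth_harm = other["recording"].data - other["truth"]["offsets"][:, None]
        np.testing.assert_allclose(pred, truth_harm, atol=1e-6)

    def test_unknown_channel_rejected(self):
        model = HarmonicModel(l_max=1, beta=np.zeros(3), offsets={"a": 0.0})
        with pytest.raises(KeyError):
            predict(model, np.zeros((1, 2, 3)), np.tile([0.0, 0, 1.0], (1, 2, 1)), ["b"])


class TestSlidingCorrect:
    def test_stationary_residual_is_sensor_noise(self, small_noisy_scenario):
        sc = small_noisy_scenario
        corrected, _ = sliding_correct(
            sc["recording"], sc["poses"], sc["array"], l_max=2, window=5.0, prediction_filter=False
        )
        resid_rms = np.sqrt(np.mean(corrected.data**2))
        assert resid_rms == pytest.approx(sc["noise"].sensor_sigma, rel=0.1)
        assert abs(np.mean(corrected.data)) < 0.01

    def test_full_window_equals_single_fit(self, small_noisy_scenario):
        sc = small_noisy_scenario
        rec = sc["recording"]
        corrected, models = sliding_correct(
            rec, sc["poses"], sc["array"], l_max=2, window=rec.duration, prediction_filter=False
        )
        assert len(models.models) == 1
        pos, ori = hf.channel_world_pose(sc["array"], sc["poses"])
        X = build_design_matrix(pos, ori, 2)
        single = fit(stack_response(rec.data), X, rec.channel_ids)
        pred = predict(single, pos, ori, rec.channel_ids)
        np.testing.assert_allclose(corrected.data, rec.data - pred, atol=1e-10)

    def test_short_windows_track_drift_better(self):
        room = hf.default_room(drift_amplitude=0.4)
        noise = hf.NoiseSpec(sensor_sigma=0.005, marker_jitter=0.0, occlusion_rate=0.0)
        sc = hf.simulate_dataset(duration=240.0, fs=10.0, n_sensors=6, seed=21, room=room, noise=noise)
        rms = {}
        for window in (5.0, 120.0):
            corrected, _ = sliding_correct(
                sc["recording"], sc["poses"], sc["array"], l_max=2, window=window, prediction_filter=False
            )
            rms[window] = np.sqrt(np.mean(corrected.data**2))
        assert rms[5.0] < rms[120.0]

    def test_window_longer_than_data_rejected(self, small_noisy_scenario):
        sc = small_noisy_scenario
        with pytest.raises(ValueError):
            sliding_correct(sc["recording"], sc["poses"], sc["array"], l_max=2, window=1e4)

    def test_trailing_partial_window_merged(self):
        slices = _window_slices(n_samples=1050, win_n=400, step_n=200)
        assert slices[-1][1] == 1050  # last window absorbs the 50-sample tail
        assert all(b - a >= 400 for a, b in slices)

    def test_overlap_mode_validation(self, small_noisy_scenario):
        sc = small_noisy_scenario
        with pytest.raises(ValueError):
            sliding_correct(sc["recording"], sc["poses"], sc["array"], l_max=2, window=5.0, overlap="blend")


class TestSerialization:
    def test_model_round_trip_bit_exact(self, tmp_path, small_noisy_scenario):
        sc = small_noisy_scenario
        _, models = sliding_correct(sc["recording"], sc["poses"], sc["array"], l_max=2, window=10.0)
        path = tmp_path / "models.json"
        models.to_json(path)
        back = WindowedModelSeries.from_json(path)
        assert back.window == models.window and back.step == models.step
        for (t0a, t1a, ma), (t0b, t1b, mb) in zip(models.models, back.models):
            assert (t0a, t1a) == (t0b, t1b)
            np.testing.assert_array_equal(ma.beta, mb.beta)
            assert ma.offsets == mb.offsets
            assert ma.condition_number == mb.condition_number


class TestFieldRecording:
    def test_dynamic_range_warning(self):
        with pytest.warns(DynamicRangeWarning):
            FieldRecording(["a"], np.array([[6.0]]), 100.0)

    def test_in_range_data_is_silent(self):
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            FieldRecording(["a"], np.array([[5.0]]), 100.0)
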