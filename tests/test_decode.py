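"""Unit tests for circular decoding, scoring, and the Haufe transform."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from streamwaves import synth
from streamwaves.decode import (
    angular_score,
    build_targets,
    crossval_decode,
    delta_score,
    encode_crossval,
    fit_spatial_filter,
    group_folds,
    haufe_pattern,
    predict_targets,
    predicted_angle,
)
from streamwaves.synth import SensorEpochs, sample_design, simulate_subject


class TestSpatialFilter:
    def test_identity_design_returns_targets(self):
        X = np.eye(2)
        Y = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        W = fit_spatial_filter(X, Y)
        assert np.allclose(W, Y)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 4))
        Y = rng.standard_normal((50, 3))
        W = fit_spatial_filter(X, Y)
        oracle = np.linalg.inv(X.T @ X) @ X.T @ Y
        assert np.allclose(W, oracle, atol=1e-10)

    def test_zero_variance_target_column_zero_filter(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 3))
        X -= X.mean(axis=0)
        Y = rng.standard_normal((40, 3))
        Y[:, 1] = 2.5  # constant column, X centred -> least-norm filter is 0
        W = fit_spatial_filter(X, Y)
        assert np.allclose(W[:, 1], 0.0, atol=1e-12)

    def test_rank_deficiency_warns(self):
        X = np.ones((10, 2))
        Y = np.ones((10, 3))
        with pytest.warns(RuntimeWarning, match="rank-deficient"):
            fit_spatial_filter(X, Y)


class TestPredict:
    def test_zero_filter_gives_zero_and_angle_convention(self):
        X = np.random.default_rng(2).standard_normal((5, 3))
        W = np.zeros((3, 3))
        Yh = predict_targets(X, W)
        assert np.all(Yh == 0.0)
        assert np.all(predicted_angle(Yh) == 0.0)

    def test_fitted_values_match_hat_matrix(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 5))
        Y = rng.standard_normal((30, 3))
        W = fit_spatial_filter(X, Y)
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        assert np.allclose(predict_targets(X, W), H @ Y, atol=1e-10)

    def test_single_sine_sensor_recovers_angle(self):
        rng = np.random.default_rng(4)
        alpha = rng.uniform(-np.pi, np.pi, 200)
        X = np.column_stack([np.sin(alpha), np.cos(alpha)])
        Y = np.column_stack([np.zeros_like(alpha), np.sin(alpha), np.cos(alpha)])
        W = fit_spatial_filter(X, Y)
        ah = predicted_angle(predict_targets(X, W))
        assert np.allclose(np.angle(np.exp(1j * (ah - alpha))), 0.0, atol=1e-8)


class TestScores:
    def test_perfect_and_opposite_angles(self):
        a = np.array([0.1, 2.0, -3.0])
        assert angular_score(a, a) == pytest.approx(np.pi / 2)
        assert angular_score(a, a + np.pi) == pytest.approx(-np.pi / 2)

    def test_chance_level_zero(self):
        rng = np.random.default_rng(5)
        n = 100_000
        a = rng.uniform(-np.pi, np.pi, n)
        b = rng.uniform(-np.pi, np.pi, n)
        sem = (np.pi / 2) / np.sqrt(3 * n)  # SD of U(-pi/2, pi/2) scores
        assert abs(angular_score(a, b)) < 3 * sem

    @given(st.floats(-10, 10))
    @settings(derandomize=True, max_examples=25)
    def test_angular_score_shift_invariant(self, shift):
        rng = np.random.default_rng(6)
        a = rng.uniform(-np.pi, np.pi, 50)
        b = a + rng.normal(0, 0.3, 50)
        assert angular_score(a + shift, b + shift) == pytest.approx(
            angular_score(a, b), abs=1e-9
        )

    def test_delta_score_limits_and_oracle(self):
        d = np.array([0.1, 0.5, 0.2, 0.9, 0.4, 0.7])
        assert delta_score(d, d) == pytest.approx(1.0)
        assert delta_score(d, -d + 1.0) == pytest.approx(-1.0)
        pred = np.array([0.2, 0.4, 0.1, 0.8, 0.6, 0.5])
        from scipy.stats import pearsonr

        assert delta_score(d, pred) == pytest.approx(pearsonr(d, pred).statistic)

    def test_delta_score_zero_variance_is_nan(self):
        assert np.isnan(delta_score(np.ones(5), np.arange(5.0)))


class TestHaufe:
    def test_white_data_identity(self):
        # orthonormal design columns: Cov(X) = I/..., patterns equal filters
        X = np.eye(4)
        Y = np.eye(4)[:, :3]
        W = fit_spatial_filter(X, Y)
        P = haufe_pattern(W, X, predict_targets(X, W))
        assert np.allclose(P, W)

    def test_equals_encoding_coefficients_against_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((100, 5))
        Y = rng.standard_normal((100, 3))
        W = fit_spatial_filter(X, Y)
        Yh = predict_targets(X, W)
        P = haufe_pattern(W, X, Yh)
        # brute-force closed form: regression of sensors on predicted targets
        oracle = X.T @ Yh @ np.linalg.inv(Yh.T @ Yh)
        assert np.allclose(P, oracle, atol=1e-8)
        # X'Y == X'Yh for OLS fits, so the encoding closed form matches too
        assert np.allclose(P, X.T @ Y @ np.linalg.inv(Yh.T @ Yh), atol=1e-8)

    def test_exact_fit_recovers_forward_model(self):
        # when X is exactly A Y, the pattern equals X'Y(Y'Y)^-1 = A up to
        # the metric of Y
        rng = np.random.default_rng(8)
        Y = rng.standard_normal((200, 3))
        A = rng.standard_normal((5, 3))
        X = Y @ A.T
        W = fit_spatial_filter(X, Y)
        P = haufe_pattern(W, X, predict_targets(X, W))
        assert np.allclose(P, X.T @ Y @ np.linalg.inv(Y.T @ Y), atol=1e-8)


class TestFolds:
    def test_partition_by_trial(self):
        trials = np.repeat(np.arange(20), 8)
        folds = group_folds(trials, 5, seed=0)
        seen = np.zeros(trials.size, dtype=int)
        for train, test in folds:
            seen[test] += 1
            assert not set(trials[train]) & set(trials[test])
        assert np.all(seen == 1)

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            group_folds(np.arange(3), 5)


@pytest.fixture(scope="module")
def noiseless_subject():
    design = sample_design(n_trials=24, n_subjects=1, seed=11)
    return simulate_subject(design, 0, noise_sd=0.0, seed=11, window=(-0.1, 0.6))


class TestCrossvalDecode:
    def test_noiseless_recovery_near_ceiling(self, noiseless_subject):
        tc = crossval_decode(noiseless_subject, n_folds=4, seed=1)
        assert tc.angle_score.max() > 1.5
        assert np.nanmax(tc.delta_r) > 0.8

    def test_shuffled_labels_score_at_chance(self, noiseless_subject):
        ep = noiseless_subject
        rng = np.random.default_rng(12)
        design = ep.design.copy()
        perm = rng.permutation(len(design))
        for col in ("alpha_rad", "theta_rad", "delta_rad"):
            design[col] = design[col].to_numpy()[perm]
        shuffled = SensorEpochs(
            data=ep.data, times=ep.times, sfreq=ep.sfreq, design=design
        )
        tc = crossval_decode(shuffled, n_folds=4, seed=1)
        n = ep.n_epochs
        sem = (np.pi / 2) / np.sqrt(3 * n)
        assert np.abs(tc.angle_score).max() < 5 * sem

    def test_score_improves_as_noise_falls(self):
        design = sample_design(n_trials=16, n_subjects=1, seed=13)
        peaks = []
        for sd in (4.0, 1.0, 0.0):
            ep = simulate_subject(design, 0, noise_sd=sd, seed=13, window=(0.0, 0.4))
            peaks.append(crossval_decode(ep, n_folds=4, seed=2).angle_score.max())
        assert peaks[0] < peaks[1] < peaks[2]


class TestEncoding:
    def test_exact_linear_channel_r_one_and_null_channel_r_zero(self):
        rng = np.random.default_rng(14)
        design = sample_design(n_trials=30, n_subjects=1, seed=14)
        targets = build_targets(design)
        q = len(design)
        data = np.zeros((q, 2, 3))
        coupled = targets.Y @ np.array([0.5, 1.0, -0.7])
        data[:, 0, :] = coupled[:, None]
        data[:, 1, :] = rng.standard_normal((q, 3))  # independent channel
        ep = SensorEpochs(
            data=data, times=np.arange(3) / 250.0, sfreq=250.0, design=design
        )
        r = encode_crossval(ep, n_folds=5, seed=3)
        assert np.all(r[0] > 0.999)
        assert np.all(np.abs(r[1]) < 3.0 / np.sqrt(q))

    def test_encoder_equals_haufe_pattern_on_exact_fit(self, noiseless_subject):
        ep = noiseless_subject
        targets = build_targets(ep.design)
        dv = targets.delta_defined
        t = int(np.argmax(np.var(ep.data.mean(axis=1), axis=0)))
        X = ep.data[dv, :, t]
        Y = targets.Y[dv]
        W = fit_spatial_filter(X, Y)
        P = haufe_pattern(W, X, predict_targets(X, W))
        encoder = (np.linalg.inv(Y.T @ Y) @ Y.T @ X).T
        assert np.allclose(P, encoder, atol=1e-8)
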