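import numpy as np
import pytest

import speechtrf as st
from speechtrf.trf import _contiguous_folds, default_lambda_grid


def _features(mat, fs=100.0, kinds=None):
    labels = tuple(f"f{i}" for i in range(np.atleast_2d(mat).shape[1]))
    return st.StimulusFeatures(mat, fs, labels, kinds or ())


def _brute_force_lag(mat, lags):
    T, F = mat.shape
    X = np.zeros((T, F * len(lags)))
    for t in range(T):
        for f in range(F):
            for i, lag in enumerate(lags):
                if 0 <= t - lag < T:
                    X[t, f * len(lags) + i] = mat[t - lag, f]
    return X


class TestLagDesignMatrix:
    def test_impulse_shifts_across_lags(self):
        x = np.zeros((20, 1))
        x[5] = 1.0
        X = st.lag_design_matrix(_features(x), 0.0, 20.0)
        assert X.shape == (20, 3)
        for i in range(3):
            assert X[5 + i, i] == 1.0
        assert X.sum() == 3.0

    def test_standard_window_has_81_lags_per_feature(self, stimulus):
        X = st.lag_design_matrix(stimulus.features.select(["env"]), -200.0, 600.0)
        assert X.shape[1] == 81

    def test_matches_double_loop_oracle(self, rng):
        mat = rng.normal(size=(40, 3))
        X = st.lag_design_matrix(_features(mat), -30.0, 50.0)
        lags = np.arange(-3, 6)
        np.testing.assert_allclose(X, _brute_force_lag(mat, lags))


class TestRidgeFit:
    def _random_problem(self, rng, n=20, p=4, channels=2):
        X = rng.normal(size=(n, p))
        Y = rng.normal(size=(channels, n))
        return X, Y

    def test_shrinkage_limit(self, rng):
        X, Y = self._random_problem(rng)
        kw = dict(fs=100.0, lag_window=(0.0, 30.0), feature_labels=("a",))
        big = st.ridge_fit(X, Y, 1e12, **kw)
        small = st.ridge_fit(X, Y, 1.0, **kw)
        assert np.linalg.norm(big.weights) < 1e-6 * np.linalg.norm(small.weights)

    def test_matches_normal_equations_oracle(self, rng):
        X, Y = self._random_problem(rng)
        lam = 1.0
        model = st.ridge_fit(X, Y, lam, fs=100.0, lag_window=(0.0, 30.0),
                             feature_labels=("a",))
        Xc = X - X.mean(0)
        for c in range(Y.shape[0]):
            yc = Y[c] - Y[c].mean()
            beta = np.linalg.solve(Xc.T @ Xc + lam * np.eye(4), Xc.T @ yc)
            got = model.weights[:, 0, c]
            assert np.linalg.norm(got - beta) <= 1e-10 * np.linalg.norm(beta)

    def test_interpolation_limit_recovers_truth(self, rng):
        X = rng.normal(size=(60, 4))
        beta_true = rng.normal(size=4)
        Y = (X @ beta_true)[None, :]
        model = st.ridge_fit(X, Y, 1e-8, fs=100.0, lag_window=(0.0, 30.0),
                             feature_labels=("a",))
        got = model.weights[:, 0, 0]
        assert np.linalg.norm(got - beta_true) <= 1e-6 * np.linalg.norm(beta_true)

    def test_monotone_shrinkage(self, rng):
        X, Y = self._random_problem(rng, n=50, p=6)
        norms = [
            np.linalg.norm(
                st.ridge_fit(X, Y, lam, fs=100.0, lag_window=(0.0, 50.0),
                             feature_labels=("a",)).weights
            )
            for lam in np.logspace(-2, 6, 9)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_scale_covariance_at_zero_lambda(self, rng):
        mat = rng.normal(size=(300, 2))
        feats = _features(mat)
        eeg = st.EEGRecording(
            rng.normal(size=(2, 300)), 100.0, ("a", "b"),
            st.default_montage()[1][:2],
        )
        X1 = st.lag_design_matrix(feats, 0.0, 30.0)
        m1 = st.ridge_fit(X1, eeg.data, 0.0, fs=100.0, lag_window=(0.0, 30.0),
                          feature_labels=feats.feature_labels)
        scaled = _features(mat * np.array([3.0, 1.0]))
        X2 = st.lag_design_matrix(scaled, 0.0, 30.0)
        m2 = st.ridge_fit(X2, eeg.data, 0.0, fs=100.0, lag_window=(0.0, 30.0),
                          feature_labels=feats.feature_labels)
        np.testing.assert_allclose(m2.weights[:, 0], m1.weights[:, 0] / 3.0,
                                   rtol=1e-8)
        np.testing.assert_allclose(m2.weights[:, 1], m1.weights[:, 1], rtol=1e-8)

    def test_negative_lambda_rejected(self, rng):
        X, Y = self._random_problem(rng)
        with pytest.raises(ValueError):
            st.ridge_fit(X, Y, -1.0, fs=100.0, lag_window=(0.0, 30.0),
                         feature_labels=("a",))


class TestCVLambdaSearch:
    def test_default_grid_spans_the_search_space(self):
        grid = default_lambda_grid()
        assert grid.size == 11
        assert grid[0] == pytest.approx(1e-2)
        assert grid[-1] == pytest.approx(1e8)

    def test_noiseless_data_predicted_almost_perfectly(self, stimulus):
        kernels = st.make_kernels(st.default_kernel_specs(), 16, seed=3)
        rec = st.simulate_eeg(stimulus.features, kernels, snr_db=300.0,
                              n_channels=16, seed=0)
        feats = stimulus.features.select(["env", "surprisal"])
        cv = st.cv_lambda_search(feats, rec, (-200.0, 700.0))
        assert cv.prediction.mean_r >= 0.99

    def test_fold_shorter_than_lag_span_rejected(self, stimulus, recording):
        feats = stimulus.features.select(["env"])
        with pytest.raises(ValueError, match="lag span"):
            st.cv_lambda_search(feats, recording, (-200.0, 600.0), n_folds=90)

    def test_chosen_lambda_near_true_held_out_optimum(self, stimulus):
        kernels = st.make_kernels(st.default_kernel_specs(), 16, seed=3)
        rec = st.simulate_eeg(stimulus.features, kernels, snr_db=5.0,
                              n_channels=16, seed=12)
        feats = stimulus.features.select(["env"])
        cv = st.cv_lambda_search(feats, rec, (-200.0, 600.0))
        # oracle: brute-force held-out r on an independent noise realization
        fresh = st.simulate_eeg(stimulus.features, kernels, snr_db=5.0,
                                n_channels=16, seed=99)
        grid = cv.lambda_grid
        oracle_r = []
        X = st.lag_design_matrix(st.scale_features(feats)[0], -200.0, 600.0)
        for lam in grid:
            model = st.ridge_fit(X, rec.data, lam, fs=100.0,
                                 lag_window=(-200.0, 600.0),
                                 feature_labels=feats.feature_labels,
                                 feature_scale=st.scale_features(feats)[1])
            pred = st.predict_and_correlate(model, feats, fresh)
            oracle_r.append(pred.mean_r)
        best = int(np.argmax(oracle_r))
        chosen = int(np.argmin(np.abs(grid - cv.best_lambda)))
        assert abs(chosen - best) <= 1


class TestPredictAndCorrelate:
    def test_perfect_model_on_training_data(self, rng):
        mat = rng.normal(size=(400, 2))
        feats = _features(mat)
        X = st.lag_design_matrix(feats, 0.0, 50.0)
        beta = rng.normal(size=X.shape[1])
        y = (X @ beta)[None, :]
        eeg = st.EEGRecording(y, 100.0, ("a",), st.default_montage()[1][:1])
        model = st.ridge_fit(X, y, 1e-10, fs=100.0, lag_window=(0.0, 50.0),
                             feature_labels=feats.feature_labels)
        pred = st.predict_and_correlate(model, feats, eeg)
        assert pred.r[0, 0] == pytest.approx(1.0, abs=1e-6)

    def test_unrelated_stimulus_gives_null_r(self, rng):
        kernels = st.make_kernels(st.default_kernel_specs(), 8, seed=3)
        rs = []
        for seed in range(6):
            stim = st.generate_stimulus(30.0, seed=100 + seed)
            rec = st.simulate_eeg(stim.features, kernels, snr_db=10.0,
                                  n_channels=8, seed=seed)
            other = st.generate_stimulus(30.0, seed=500 + seed)
            cv = st.cv_lambda_search(stim.features.select(["env"]), rec,
                                     (-200.0, 600.0))
            pred = st.predict_and_correlate(cv.model,
                                            other.features.select(["env"]), rec)
            rs.append(pred.mean_r)
        assert abs(np.mean(rs)) < 0.05

    def test_constant_channel_reports_zero_with_warning(self, rng):
        mat = rng.normal(size=(200, 1))
        feats = _features(mat)
        eeg = st.EEGRecording(np.zeros((1, 200)), 100.0, ("a",),
                              st.default_montage()[1][:1])
        X = st.lag_design_matrix(feats, 0.0, 30.0)
        model = st.ridge_fit(X, eeg.data, 1.0, fs=100.0, lag_window=(0.0, 30.0),
                             feature_labels=feats.feature_labels)
        with pytest.warns(UserWarning, match="zero-variance"):
            pred = st.predict_and_correlate(model, feats, eeg)
        assert pred.r[0, 0] == 0.0


class TestResidualR:
    def test_identical_models_give_zero(self):
        preds = [st.PredictionResult(np.full((5, 4), 0.1)) for _ in range(6)]
        res = st.residual_r(preds, preds)
        assert np.all(res.delta == 0)
        assert res.t == 0.0

    def test_participant_mismatch_rejected(self):
        a = [st.PredictionResult(np.zeros((2, 3)))]
        with pytest.raises(ValueError):
            st.residual_r(a, a * 2)

    def test_folds_partition_time(self):
        folds = _contiguous_folds(103, 5)
        assert sum(f.size for f in folds) == 103
        np.testing.assert_array_equal(np.concatenate(folds), np.arange(103))
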