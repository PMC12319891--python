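"""Temporal response function (TRF) estimation.

A forward (encoding) TRF is a lagged linear model predicting each EEG
channel from stimulus features::

    y_c(t) = sum_f sum_l  w[l, f, c] x_f(t - l) + b_c

The weights solve the Tikhonov-regularized least-squares problem with the
closed form ``beta = (X'X + lambda I)^-1 X'y`` on the lagged design matrix
``X``; the intercept is handled by column-centering and excluded from the
penalty, and the solve uses a symmetric positive-definite factorization
rather than an explicit inverse.  The regularization parameter is chosen
by leave-one-fold-out cross-validation over a logarithmic grid (default
11 values, 1e-2 to 1e8), maximizing the Pearson prediction correlation
averaged over folds and channels; the final model is refit on all data at
the chosen value.

Column ordering of the lagged design is feature-major: all lags of
feature 0 first, then all lags of feature 1, and so on, with lags
ascending from ``tmin`` to ``tmax``.  Out-of-range samples at segment
edges are zero-padded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .features import StimulusFeatures
from .preprocess import EEGRecording

__all__ = [
    "TRFModel",
    "PredictionResult",
    "CVResult",
    "ResidualRResult",
    "default_lambda_grid",
    "scale_features",
    "lag_design_matrix",
    "ridge_fit",
    "cv_lambda_search",
    "predict_and_correlate",
    "residual_r",
]


def default_lambda_grid() -> np.ndarray:
    """Log-spaced regularization grid, one value per decade, 1e-2..1e8."""
    return np.logspace(-2, 8, 11)


@dataclass(frozen=True)
class TRFModel:
    """Fitted TRF weights indexed (lag, feature, channel)."""

    weights: np.ndarray
    bias: np.ndarray
    lam: float
    lag_window: tuple[float, float]  # (tmin_ms, tmax_ms)
    fs: float
    feature_labels: tuple[str, ...]
    feature_scale: np.ndarray | None = None  # per-feature divisor used in fitting

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        tmin, tmax = self.lag_window
        n_lags = int(round((tmax - tmin) * self.fs / 1000.0)) + 1
        if w.shape[0] != n_lags or w.shape[1] != len(self.feature_labels):
            raise ValueError(
                f"weights shape {w.shape} inconsistent with {n_lags} lags x "
                f"{len(self.feature_labels)} features"
            )
        if not np.isfinite(w).all():
            raise ValueError("non-finite weights")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "feature_labels", tuple(self.feature_labels))

    @property
    def n_lags(self) -> int:
        return self.weights.shape[0]

    @property
    def n_channels(self) -> int:
        return self.weights.shape[2]

    @property
    def lags_ms(self) -> np.ndarray:
        tmin, _ = self.lag_window
        return tmin + np.arange(self.n_lags) * 1000.0 / self.fs

    def kernel(self, feature: str) -> np.ndarray:
        """Weights (n_lags, n_channels) of one feature."""
        try:
            f = self.feature_labels.index(feature)
        except ValueError:
            raise KeyError(f"model has no feature {feature!r}") from None
        return self.weights[:, f, :]


@dataclass(frozen=True)
class PredictionResult:
    """Per-fold, per-channel Pearson prediction correlations."""

    r: np.ndarray  # (n_folds, n_channels)

    def __post_init__(self) -> None:
        r = np.atleast_2d(np.asarray(self.r, float))
        if np.any(np.abs(r) > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")
        object.__setattr__(self, "r", r)

    @property
    def channel_mean(self) -> np.ndarray:
        """Fold-averaged r per channel."""
        return self.r.mean(axis=0)

    @property
    def mean_r(self) -> float:
        """Mean over folds then channels."""
        return float(self.channel_mean.mean())


@dataclass(frozen=True)
class CVResult:
    """Outcome of the cross-validated regularization search."""

    best_lambda: float
    lambda_grid: np.ndarray
    mean_r_per_lambda: np.ndarray
    model: TRFModel
    prediction: PredictionResult


@dataclass(frozen=True)
class ResidualRResult:
    """Multivariate-minus-univariate prediction-gain test across a cohort."""

    delta: np.ndarray  # (n_participants, n_channels), fold-averaged
    t: float
    df: int
    p: float

    @property
    def delta_per_participant(self) -> np.ndarray:
        return self.delta.mean(axis=1)


def scale_features(
    features: StimulusFeatures,
) -> tuple[StimulusFeatures, np.ndarray]:
    """Z-scale each regressor column; returns scaled features and divisors.

    Dense columns are divided by their standard deviation; sparse-onset
    columns by the standard deviation of their nonzero entries (zeros are
    kept, preserving sparsity).  Columns are not mean-centered here — the
    intercept handling in the ridge solve takes care of offsets.
    """
    mat = features.matrix.copy()
    scale = np.ones(features.n_features)
    for j, kind in enumerate(features.kinds):
        col = mat[:, j]
        if kind == "sparse":
            nz = col[col != 0]
            s = nz.std() if nz.size > 1 else (abs(nz[0]) if nz.size else 0.0)
        else:
            s = col.std()
        if s > 0:
            scale[j] = s
            mat[:, j] = col / s
    return (
        StimulusFeatures(mat, features.fs, features.feature_labels, features.kinds),
        scale,
    )


def _lag_samples(tmin_ms: float, tmax_ms: float, fs: float) -> np.ndarray:
    l0 = int(round(tmin_ms * fs / 1000.0))
    l1 = int(round(tmax_ms * fs / 1000.0))
    return np.arange(l0, l1 + 1)


def lag_design_matrix(
    features: StimulusFeatures, tmin_ms: float, tmax_ms: float
) -> np.ndarray:
    """Time-lagged design matrix, shape (n_times, n_features * n_lags).

    Column ``f * n_lags + i`` at row ``t`` holds feature ``f`` at time
    ``t - lag_i`` (zero outside the recording).
    """
    if tmin_ms >= tmax_ms:
        raise ValueError("tmin must be < tmax")
    lags = _lag_samples(tmin_ms, tmax_ms, features.fs)
    m = features.matrix
    T, F = m.shape
    L = lags.size
    X = np.zeros((T, F * L))
    cols = np.arange(F) * L
    for i, lag in enumerate(lags):
        if lag >= 0:
            X[lag:, cols + i] = m[: T - lag if lag else T]
        else:
            X[: T + lag, cols + i] = m[-lag:]
    return X


def _solve_ridge(
    gram: np.ndarray, xty: np.ndarray, lam: float
) -> np.ndarray:
    a = gram + lam * np.eye(gram.shape[0])
    try:
        return linalg.solve(a, xty, assume_a="pos")
    except linalg.LinAlgError:
        return linalg.solve(a, xty, assume_a="sym")


def ridge_fit(
    X: np.ndarray,
    Y: np.ndarray,
    lam: float,
    fs: float,
    lag_window: tuple[float, float],
    feature_labels: tuple[str, ...],
    feature_scale: np.ndarray | None = None,
) -> TRFModel:
    """Closed-form ridge solve of the lagged design against all channels.

    ``X`` is (n_times, n_features * n_lags) from :func:`lag_design_matrix`;
    ``Y`` is (n_channels, n_times).  Columns of ``X`` and rows of ``Y`` are
    mean-centered before the normal-equations solve; the bias reproduces
    the channel means.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape[0] != Y.shape[1]:
        raise ValueError("X rows and Y columns (time) must match")
    xm = X.mean(axis=0)
    ym = Y.mean(axis=1)
    Xc = X - xm
    gram = Xc.T @ Xc
    xty = Xc.T @ (Y - ym[:, None]).T
    beta = _solve_ridge(gram, xty, lam)
    bias = ym - beta.T @ xm
    n_lags = _lag_samples(*lag_window, fs).size
    F = len(feature_labels)
    weights = beta.reshape(F, n_lags, -1).transpose(1, 0, 2)
    return TRFModel(weights, bias, float(lam), tuple(lag_window), fs,
                    feature_labels, feature_scale)


def _flat_beta(model: TRFModel) -> np.ndarray:
    # inverse of the reshape in ridge_fit: (F*L, C)
    return model.weights.transpose(1, 0, 2).reshape(-1, model.n_channels)


def _pearson_rows(yhat: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r; degenerate (zero-variance) rows give 0."""
    yhat = yhat - yhat.mean(axis=1, keepdims=True)
    y = y - y.mean(axis=1, keepdims=True)
    num = (yhat * y).sum(axis=1)
    den = np.sqrt((yhat**2).sum(axis=1) * (y**2).sum(axis=1))
    r = np.zeros(y.shape[0])
    ok = den > 0
    if not ok.all():
        warnings.warn("zero-variance channel in correlation; r set to 0",
                      stacklevel=2)
    r[ok] = num[ok] / den[ok]
    return np.clip(r, -1.0, 1.0)


def _contiguous_folds(n_times: int, n_folds: int) -> list[np.ndarray]:
    edges = np.linspace(0, n_times, n_folds + 1).astype(int)
    return [np.arange(a, b) for a, b in zip(edges[:-1], edges[1:])]


def cv_lambda_search(
    features: StimulusFeatures,
    eeg: EEGRecording,
    lag_window: tuple[float, float],
    n_folds: int = 5,
    lambda_grid: np.ndarray | None = None,
    folds: list[np.ndarray] | None = None,
    scale: bool = True,
) -> CVResult:
    """Leave-one-fold-out search for the regularization parameter.

    The recording is split into ``n_folds`` contiguous segments (or
    explicit ``folds``); for each grid value the model is fit on the
    other folds and correlated with the held-out fold per channel.  The
    value maximizing the fold- and channel-averaged r wins, and the final
    model is refit on all data at that value.
    """
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    lambda_grid = np.asarray(lambda_grid, float)
    if lambda_grid.size == 0:
        raise ValueError("lambda grid is empty")
    if features.fs != eeg.fs:
        raise ValueError("feature and EEG sampling rates differ")
    if features.n_times != eeg.n_times:
        raise ValueError("feature and EEG lengths differ")

    feature_scale = None
    if scale:
        features, feature_scale = scale_features(features)

    X = lag_design_matrix(features, *lag_window)
    Yt = eeg.data.T  # time x channels
    T, P = X.shape
    if folds is None:
        if n_folds < 2:
            raise ValueError("need at least 2 folds")
        folds = _contiguous_folds(T, n_folds)
    n_lag_span = _lag_samples(*lag_window, features.fs).size
    if any(f.size <= n_lag_span for f in folds):
        raise ValueError("a fold is shorter than the lag span")

    # per-fold sufficient statistics; training stats are totals minus fold
    G = [X[f].T @ X[f] for f in folds]
    H = [X[f].T @ Yt[f] for f in folds]
    S = [X[f].sum(axis=0) for f in folds]
    U = [Yt[f].sum(axis=0) for f in folds]
    N = [f.size for f in folds]
    Gt, Ht = sum(G), sum(H)
    St, Ut, Nt = sum(S), sum(U), sum(N)

    n_ch = eeg.n_channels
    r_all = np.zeros((lambda_grid.size, len(folds), n_ch))
    for k, f in enumerate(folds):
        n_tr = Nt - N[k]
        s = (St - S[k]) / n_tr
        u = (Ut - U[k]) / n_tr
        gram = (Gt - G[k]) - n_tr * np.outer(s, s)
        xty = (Ht - H[k]) - n_tr * np.outer(s, u)
        Xf = X[f]
        for j, lam in enumerate(lambda_grid):
            beta = _solve_ridge(gram, xty, lam)
            yhat = Xf @ beta + (u - s @ beta)
            r_all[j, k] = _pearson_rows(yhat.T, Yt[f].T)

    mean_r = r_all.mean(axis=(1, 2))
    best_j = int(np.argmax(mean_r))
    best_lam = float(lambda_grid[best_j])

    model = ridge_fit(X, eeg.data, best_lam, features.fs, lag_window,
                      features.feature_labels, feature_scale)
    return CVResult(best_lam, lambda_grid, mean_r, model,
                    PredictionResult(r_all[best_j]))


def predict_and_correlate(
    model: TRFModel,
    features: StimulusFeatures,
    eeg: EEGRecording,
    folds: list[np.ndarray] | int | None = None,
) -> PredictionResult:
    """Predict the EEG from the model and correlate per channel.

    If ``folds`` is given (segment index lists or a fold count), the r is
    computed per fold; otherwise over the whole recording.
    """
    if tuple(features.feature_labels) != model.feature_labels:
        raise ValueError("feature labels do not match the model")
    if features.n_times != eeg.n_times:
        raise ValueError("feature and EEG lengths differ")
    mat = features.matrix
    if model.feature_scale is not None:
        mat = mat / model.feature_scale
    scaled = StimulusFeatures(mat, features.fs, features.feature_labels,
                              features.kinds)
    X = lag_design_matrix(scaled, *model.lag_window)
    yhat = (X @ _flat_beta(model) + model.bias).T  # channels x time
    if folds is None:
        return PredictionResult(_pearson_rows(yhat, eeg.data)[None, :])
    if isinstance(folds, int):
        folds = _contiguous_folds(features.n_times, folds)
    r = np.stack([_pearson_rows(yhat[:, f], eeg.data[:, f]) for f in folds])
    return PredictionResult(r)


def residual_r(
    multivariate: list[PredictionResult],
    univariate: list[PredictionResult],
) -> ResidualRResult:
    """Per-participant prediction gain of the multivariate model.

    ``delta = r_multi - r_uni`` per channel (fold-averaged); the cohort
    test averages delta over channels per participant and applies a
    one-tailed one-sample t-test of mean(delta) > 0.
    """
    if len(multivariate) != len(univariate):
        raise ValueError("participant counts differ")
    deltas = []
    for m, u in zip(multivariate, univariate):
        if m.r.shape[1] != u.r.shape[1]:
            raise ValueError("channel counts differ between models")
        deltas.append(m.channel_mean - u.channel_mean)
    delta = np.array(deltas)
    per_part = delta.mean(axis=1)
    if np.allclose(per_part, per_part[0]) and np.ptp(per_part) == 0:
        # identical models: t is 0 by definition, avoid 0/0
        return ResidualRResult(delta, 0.0, len(per_part) - 1,
                               1.0 if per_part[0] <= 0 else 0.0)
    t, p = stats.ttest_1samp(per_part, 0.0, alternative="greater")
    return ResidualRResult(delta, float(t), len(per_part) - 1, float(p))
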