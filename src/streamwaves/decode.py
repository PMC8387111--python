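"""Linear decoding and encoding of stimulus features from sensor epochs.

The backward (decoding) model is an ordinary least-squares spatial filter
fitted independently at every time sample relative to stimulus onset::

    W_t = (X_t' X_t)^-1 X_t' Y

where ``X_t`` stacks the sensor voltages of the training stimuli at time
``t`` and ``Y`` holds the three stimulus features (delta, sin alpha,
cos alpha).  Out-of-fold predictions are scored circularly for the angle
(predicted angle = arctan2(sin_hat, cos_hat); score = pi/2 minus the mean
absolute circular error, chance 0) and with Pearson's r for delta.

Filters are interpretable through the Haufe transform, which converts a
backward model into forward (encoding) patterns ``P = Cov(X) W
Cov(Y_hat)^-1``; for OLS filters this equals the coefficients of
regressing the sensors on the predicted targets, and it coincides with
the encoding coefficients ``X'Y (Y'Y)^-1`` exactly when the fit is exact.

Cross-validation is grouped by trial: all stimuli of an 8-item sequence
stay in the same fold, so temporally overlapping responses never span the
train/test split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import SensorEpochs

__all__ = [
    "TargetMatrix",
    "build_targets",
    "fit_spatial_filter",
    "predict_targets",
    "predicted_angle",
    "angular_score",
    "delta_score",
    "haufe_pattern",
    "group_folds",
    "crossval_decode",
    "encode_crossval",
]

TARGET_COLUMNS = ("delta", "sin_alpha", "cos_alpha")


@dataclass(frozen=True)
class TargetMatrix:
    """Per-stimulus regression targets, columns (delta, sin a, cos a).

    ``delta_defined`` flags the rows usable for delta fitting/scoring
    (position-1 stimuli have no preceding item, hence no delta).
    """

    Y: np.ndarray
    delta_defined: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        if self.Y.ndim != 2 or self.Y.shape[1] != 3:
            raise ValueError("Y must be (stimuli, 3)")


def build_targets(design: pd.DataFrame) -> TargetMatrix:
    """Assemble the (delta, sin alpha, cos alpha) target matrix.

    Delta is mean-centred over the rows where it is defined and set to 0
    elsewhere (those rows are excluded from fitting and delta scoring
    anyway).
    """
    alpha = design["alpha_rad"].to_numpy(dtype=float)
    delta = design["delta_rad"].to_numpy(dtype=float)
    defined = ~np.isnan(delta)
    dmean = delta[defined].mean() if defined.any() else 0.0
    dcent = np.where(defined, delta - dmean, 0.0)
    Y = np.column_stack([dcent, np.sin(alpha), np.cos(alpha)])
    return TargetMatrix(Y=Y, delta_defined=defined, alpha=alpha)


def fit_spatial_filter(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """OLS spatial filter W = (X'X)^-1 X'Y, shape (sensors, targets).

    Rank-deficient problems fall back to the minimum-norm least-squares
    solution; an all-constant channel set triggers a rank warning.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have matching rows")
    W, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn(
            f"rank-deficient design (rank {rank} < {X.shape[1]} channels); "
            "returning minimum-norm solution",
            RuntimeWarning,
            stacklevel=2,
        )
    return W


def predict_targets(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Predicted targets Y_hat = X W."""
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float)
    if X.shape[1] != W.shape[0]:
        raise ValueError("X columns must match W rows")
    return X @ W


def predicted_angle(Y_hat: np.ndarray) -> np.ndarray:
    """Angle estimate arctan2(sin_hat, cos_hat) from predicted targets.

    ``arctan2(0, 0)`` is 0 by convention (an all-zero filter predicts the
    reference angle).
    """
    return np.arctan2(Y_hat[..., 1], Y_hat[..., 2])


def _wrap(angles: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(angles, dtype=float)))


def angular_score(alpha_true: np.ndarray, alpha_pred: np.ndarray) -> float:
    """Mean circular decoding score pi/2 - |alpha - alpha_hat|, chance 0.

    Per-trial absolute circular errors lie in [0, pi], so the score lies
    in [-pi/2, pi/2]: pi/2 for perfect prediction, 0 for independent
    predictions, -pi/2 for systematically opposite ones.
    """
    a = np.asarray(alpha_true, dtype=float)
    b = np.asarray(alpha_pred, dtype=float)
    if a.size == 0 or a.shape != b.shape:
        raise ValueError("inputs must be non-empty and of equal length")
    return float(np.mean(np.pi / 2 - np.abs(_wrap(a - b))))


def delta_score(delta_true: np.ndarray, delta_pred: np.ndarray) -> float:
    """Pearson correlation between true and predicted delta, chance 0.

    Undefined (NaN) when either input has zero variance.
    """
    a = np.asarray(delta_true, dtype=float)
    b = np.asarray(delta_pred, dtype=float)
    if a.size < 2 or a.shape != b.shape:
        raise ValueError("need >= 2 paired values")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def haufe_pattern(W: np.ndarray, X: np.ndarray, Y_hat: np.ndarray) -> np.ndarray:
    """Forward patterns P = Cov(X) W Cov(Y_hat)^-1 (uncentred moments).

    With ``W`` the OLS filter fitted on ``X``, this equals the encoding
    coefficients of the sensors regressed on the predicted targets.  A
    singular predicted-target covariance falls back to the pseudo-inverse
    with a warning.
    """
    X = np.asarray(X, dtype=float)
    Y_hat = np.asarray(Y_hat, dtype=float)
    n = X.shape[0]
    cov_x = X.T @ X / n
    cov_yh = Y_hat.T @ Y_hat / n
    try:
        right = np.linalg.solve(cov_yh, (cov_x @ W).T).T
    except np.linalg.LinAlgError:
        warnings.warn(
            "singular predicted-target covariance; using pseudo-inverse",
            RuntimeWarning,
            stacklevel=2,
        )
        right = cov_x @ W @ np.linalg.pinv(cov_yh)
    return right


def group_folds(
    groups: np.ndarray, n_folds: int, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Grouped K-fold assignment: rows of one group share a fold.

    Unique groups are shuffled with ``seed`` and dealt into ``n_folds``
    nearly equal folds; returns (train_rows, test_rows) index pairs.
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if n_folds > uniq.size:
        raise ValueError(f"n_folds={n_folds} exceeds the {uniq.size} groups")
    rng = np.random.default_rng(seed)
    order = rng.permutation(uniq)
    folds = np.array_split(order, n_folds)
    out = []
    for f in folds:
        test = np.isin(groups, f)
        out.append((np.nonzero(~test)[0], np.nonzero(test)[0]))
    return out


def fit_filters_all_times(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Batched per-time OLS filters.

    ``X`` is (stimuli, sensors, times); returns W of shape
    (times, sensors, targets).  Singular normal equations at a given time
    fall back to the pseudo-inverse.
    """
    Xt = np.ascontiguousarray(np.moveaxis(X, -1, 0))  # (T, q, m)
    XtX = Xt.transpose(0, 2, 1) @ Xt  # (T, m, m)
    XtY = Xt.transpose(0, 2, 1) @ Y  # (T, m, k)
    try:
        return np.linalg.solve(XtX, XtY)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(XtX) @ XtY


@dataclass
class ScoreTimecourse:
    """Per-time decoding scores for one subject."""

    times: np.ndarray
    angle_score: np.ndarray
    delta_r: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "angle_score": self.angle_score,
                "delta_r": self.delta_r,
            }
        )


def crossval_decode(
    epochs: SensorEpochs,
    n_folds: int = 5,
    seed: int = 0,
) -> ScoreTimecourse:
    """Per-time decoding with trial-grouped cross-validation.

    Filters are fitted per time sample on the training stimuli of each
    fold (pooled over sequence positions, delta-defined rows only) and
    applied to the held-out stimuli; out-of-fold predictions are pooled
    across folds and scored per time sample — circular angle score on all
    positions, Pearson r for delta on delta-defined rows.
    """
    targets = build_targets(epochs.design)
    X = epochs.data  # (q, m, T)
    q, _, T = X.shape
    preds = np.full((q, T, 3), np.nan)
    for train, test in group_folds(epochs.design["trial"].to_numpy(), n_folds, seed):
        tr = train[targets.delta_defined[train]]
        W = fit_filters_all_times(X[tr], targets.Y[tr])  # (T, m, 3)
        # (T, q2, m) @ (T, m, 3) -> (T, q2, 3)
        Xtest = np.ascontiguousarray(np.moveaxis(X[test], -1, 0))
        preds[test] = np.moveaxis(Xtest @ W, 0, 1)
    alpha_hat = np.arctan2(preds[..., 1], preds[..., 2])  # (q, T)
    err = np.abs(_wrap(alpha_hat - targets.alpha[:, None]))
    angle = np.pi / 2 - err.mean(axis=0)
    dv = targets.delta_defined
    delta_r = np.array(
        [delta_score(targets.Y[dv, 0], preds[dv, t, 0]) for t in range(T)]
    )
    return ScoreTimecourse(times=epochs.times, angle_score=angle, delta_r=delta_r)


def encode_crossval(
    epochs: SensorEpochs,
    n_folds: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Cross-validated per-channel encoding scores.

    For each channel and time sample, an OLS regression predicts the
    voltage from the stimulus features; pooled out-of-fold predictions are
    summarized as Pearson's r with the actual voltage.  Returns an
    (n_channels, n_times) array; zero-variance channels give NaN.
    """
    targets = build_targets(epochs.design)
    dv = targets.delta_defined
    X = epochs.data[dv]  # (q, m, T)
    Y = targets.Y[dv]
    q, m, T = X.shape
    preds = np.full((q, m, T), np.nan)
    for train, test in group_folds(
        epochs.design["trial"].to_numpy()[dv], n_folds, seed
    ):
        Ytr = Y[train]
        # coefficient (3, m*T): solve the shared 3x3 normal equations once
        coef = np.linalg.solve(Ytr.T @ Ytr, Ytr.T @ X[train].reshape(len(train), -1))
        preds[test] = (Y[test] @ coef).reshape(len(test), m, T)
    xm = X.mean(axis=0)
    pm = preds.mean(axis=0)
    xc = X - xm
    pc = preds - pm
    num = np.einsum("qmt,qmt->mt", xc, pc)
    den = np.sqrt(np.einsum("qmt,qmt->mt", xc, xc) * np.einsum("qmt,qmt->mt", pc, pc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return r
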