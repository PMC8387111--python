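"""Temporal generalization (TG), per-position decoding, and the
diagonal-vs-reversal comparison.

A decoder trained at time ``t`` is scored on data from every other time
``t'``; the resulting training-time x testing-time score matrix
diagnoses the underlying dynamics.  A strictly feedforward cascade
generalizes over a constant-width band parallel to the diagonal; a chain
of negative feedback loops (updating hierarchy) generalizes over windows
that widen with training time and shows a below-chance band displaced by
the stimulus duration, where decoders meet the sign-reversed offset
response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decode import _wrap, build_targets, fit_filters_all_times, group_folds
from .stats import cluster_permutation
from .synth import SensorEpochs

__all__ = [
    "TGMatrix",
    "temporal_generalization",
    "PositionScores",
    "position_resolved_decoding",
    "diagonal_vs_reversal",
    "generalization_band",
]


@dataclass
class TGMatrix:
    """Training-time x testing-time decoding scores for one subject."""

    times: np.ndarray
    angle_score: np.ndarray  # (T_train, T_test)
    delta_r: np.ndarray  # (T_train, T_test)
    n_folds: int
    seed: int

    @property
    def diagonal_angle(self) -> np.ndarray:
        return np.diagonal(self.angle_score)

    @property
    def diagonal_delta(self) -> np.ndarray:
        return np.diagonal(self.delta_r)


def temporal_generalization(
    epochs: SensorEpochs,
    n_folds: int = 5,
    seed: int = 0,
    train_chunk: int = 32,
) -> TGMatrix:
    """Compute the full TG matrix with trial-grouped cross-validation.

    A single fold partition (keyed by ``seed``) is shared across all
    training times, so the matrix diagonal equals the plain
    cross-validated decoding timecourse.  Scores pool out-of-fold
    predictions across folds: the angle score averages per-trial circular
    scores; the delta score accumulates sufficient statistics for the
    pooled Pearson r.
    """
    targets = build_targets(epochs.design)
    X = epochs.data
    q, m, T = X.shape
    alpha = targets.alpha
    dv = targets.delta_defined
    d_true = targets.Y[:, 0]

    ang_sum = np.zeros((T, T))
    n_ang = 0
    s_p = np.zeros((T, T))
    s_pp = np.zeros((T, T))
    s_dp = np.zeros((T, T))
    n_dv = 0
    sum_d = float(d_true[dv].sum())
    sum_dd = float((d_true[dv] ** 2).sum())

    for train, test in group_folds(epochs.design["trial"].to_numpy(), n_folds, seed):
        tr = train[dv[train]]
        W = fit_filters_all_times(X[tr], targets.Y[tr])  # (T, m, 3)
        Xte = X[test]  # (q2, m, T_test)
        a_te = alpha[test]
        dv_te = dv[test]
        d_te = d_true[test][dv_te]
        flat = np.ascontiguousarray(np.moveaxis(Xte, 1, 2)).reshape(-1, m)  # (q2*T, m)
        for lo in range(0, T, train_chunk):
            hi = min(lo + train_chunk, T)
            Wc = W[lo:hi]  # (c, m, 3)
            # (q2*T_test, m) @ (m, c*3) -> (q2, T_test, c, 3)
            P = (flat @ Wc.transpose(1, 0, 2).reshape(m, -1)).reshape(
                len(test), T, hi - lo, 3
            )
            ah = np.arctan2(P[..., 1], P[..., 2])
            sc = np.pi / 2 - np.abs(_wrap(ah - a_te[:, None, None]))
            ang_sum[lo:hi] += sc.sum(axis=0).T  # (c, T_test)
            Pd = P[dv_te, :, :, 0]  # (q_dv, T_test, c)
            s_p[lo:hi] += Pd.sum(axis=0).T
            s_pp[lo:hi] += (Pd**2).sum(axis=0).T
            s_dp[lo:hi] += np.einsum("q,qtc->ct", d_te, Pd)
        n_ang += len(test)
        n_dv += int(dv_te.sum())

    angle = ang_sum / n_ang
    # pooled Pearson r from accumulated moments
    cov = s_dp / n_dv - (sum_d / n_dv) * (s_p / n_dv)
    var_d = sum_dd / n_dv - (sum_d / n_dv) ** 2
    var_p = s_pp / n_dv - (s_p / n_dv) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        delta_r = cov / np.sqrt(var_d * var_p)
    return TGMatrix(
        times=epochs.times,
        angle_score=angle,
        delta_r=delta_r,
        n_folds=n_folds,
        seed=seed,
    )


@dataclass
class PositionScores:
    """Sequence-locked decoding scores per stream position.

    ``angle_score`` and ``delta_r`` have shape (8, n_times); delta is NaN
    for position 1 (no preceding item).  ``cumulative_*`` sum the
    per-position components.
    """

    times: np.ndarray
    angle_score: np.ndarray
    delta_r: np.ndarray

    @property
    def cumulative_angle(self) -> np.ndarray:
        return self.angle_score.sum(axis=0)

    @property
    def cumulative_delta(self) -> np.ndarray:
        return np.nansum(self.delta_r, axis=0)


def position_resolved_decoding(
    seq_epochs: SensorEpochs,
    design: pd.DataFrame,
    n_folds: int = 5,
    seed: int = 0,
) -> PositionScores:
    """Decode every stream position from sequence-locked epochs.

    One decoder family per position, trained and tested on the same fold
    partition of trials across the whole sequence-locked time axis; each
    is scored against its own stimulus's features.  The cumulative curve
    is the elementwise sum over positions.
    """
    if seq_epochs.n_epochs == 0:
        raise ValueError("no sequence epochs")
    trials = seq_epochs.design["trial"].to_numpy()
    X = seq_epochs.data  # (n_trials, m, T)
    n_tr, m, T = X.shape
    positions = np.sort(design["position"].unique())
    if len(positions) < 8:
        raise ValueError("design must contain all 8 positions")
    folds = group_folds(trials, n_folds, seed)

    by_trial = design.set_index(["trial", "position"])
    angle = np.full((len(positions), T), np.nan)
    delta = np.full((len(positions), T), np.nan)
    for pi, pos in enumerate(positions):
        rows = by_trial.xs(pos, level="position").loc[trials]
        targets = build_targets(rows.reset_index())
        preds = np.full((n_tr, T, 3), np.nan)
        for train, test in folds:
            tr = train[targets.delta_defined[train]] if pos > 1 else train
            Y = targets.Y[tr] if pos > 1 else targets.Y[tr][:, 1:]
            W = fit_filters_all_times(X[tr], Y)
            Xte = np.ascontiguousarray(np.moveaxis(X[test], -1, 0))
            out = np.moveaxis(Xte @ W, 0, 1)
            preds[test] = out if pos > 1 else np.concatenate(
                [np.full((len(test), T, 1), np.nan), out], axis=2
            )
        ah = np.arctan2(preds[..., 1], preds[..., 2])
        err = np.abs(_wrap(ah - targets.alpha[:, None]))
        angle[pi] = np.pi / 2 - err.mean(axis=0)
        if pos > 1:
            d = targets.Y[:, 0]
            dm = d.mean()
            pc = preds[..., 0] - preds[..., 0].mean(axis=0)
            dc = d - dm
            num = np.einsum("q,qt->t", dc, pc)
            den = np.sqrt((dc**2).sum() * (pc**2).sum(axis=0))
            with np.errstate(invalid="ignore", divide="ignore"):
                delta[pi] = num / den
    return PositionScores(times=seq_epochs.times, angle_score=angle, delta_r=delta)


def diagonal_vs_reversal(tg: TGMatrix, soa: float, target: str = "angle") -> pd.DataFrame:
    """Diagonal decoders versus their sign-reversed counterparts.

    For every training time ``t`` with ``t + soa`` on the axis, compares
    the diagonal score(t, t) against the sign-reversed off-diagonal
    -score(t, t + soa); the returned ``difference`` column is
    score(t, t) + score(t, t + soa), positive when the diagonal decoder
    outperforms its reversal counterpart.
    """
    scores = tg.angle_score if target == "angle" else tg.delta_r
    times = tg.times
    dt = float(np.median(np.diff(times)))
    shift = int(round(soa / dt))
    if shift <= 0 or shift >= times.size:
        raise ValueError("soa outside the time axis")
    T = times.size - shift
    idx = np.arange(T)
    diff = scores[idx, idx] + scores[idx, idx + shift]
    return pd.DataFrame(
        {"time_s": times[:T], "difference": diff, "diagonal": scores[idx, idx]}
    )


def generalization_band(
    tg_stack: np.ndarray,
    times: np.ndarray,
    alpha_cluster: float = 0.05,
    n_perm: int = 511,
    seed: int = 0,
) -> pd.DataFrame:
    """Significant generalization duration per training time.

    For each training time, the subjects x testing-time scores are
    submitted to a one-sample cluster permutation test; the band width is
    the temporal extent of the significant (p < 0.05) positive cluster
    containing the diagonal sample, 0 when there is none.  Also reports
    whether a significant negative (below-chance) cluster exists and the
    testing-time lag of its mass centre.
    """
    S, T, _ = tg_stack.shape
    dt = float(np.median(np.diff(times)))
    widths = np.zeros(T)
    fwd = np.zeros(T)
    neg_lag = np.full(T, np.nan)
    for t in range(T):
        eff = tg_stack[:, t, :]  # subjects x testing time
        res = cluster_permutation(
            eff, adjacency="time", alpha_cluster=alpha_cluster, n_perm=n_perm, seed=seed
        )
        for cl in res.clusters:
            if cl.p_value >= 0.05:
                continue
            if cl.mass > 0 and t in cl.indices[0]:
                widths[t] = len(cl.indices[0]) * dt
                fwd[t] = (int(cl.indices[0].max()) - t) * dt
            elif cl.mass < 0 and np.isnan(neg_lag[t]):
                centre = np.mean(cl.indices[0])
                neg_lag[t] = (centre - t) * dt
    return pd.DataFrame(
        {
            "train_time_s": times,
            "band_width_s": widths,
            "forward_width_s": fwd,
            "neg_band_lag_s": neg_lag,
        }
    )
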