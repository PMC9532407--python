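"""Behavioral signatures: overall error, condition-wise error-vectors, and
noise-adjusted split-half consistency.

A *trial table* is the common behavioral currency for primates-like synthetic
systems and RNNs: one row per trial with columns ``condition_id``,
``repetition``, ``paddle_y`` (final paddle height, degrees). The ground truth
``y_final`` comes from the condition table.

The *error-vector* is the per-condition mean residual of the final paddle
position after a single trial-level least-squares regression of paddle on
ground truth. Residualizing (rather than subtracting) removes the component
of "error" that any system trivially shares through the ground-truth pattern
itself, so that correlating two systems' error-vectors equals the partial
correlation of their raw endpoints controlling for the ground truth.

*Consistency* between systems m and h is the split-half noise-adjusted
correlation

    rho_hat(m, h) = corr(m, h) / sqrt(corr(m, m) * corr(h, h)),

where each correlation is computed between error-vectors estimated from
random half-splits of the trials, all on equal amounts of data (no
extrapolation formulas). A replica of a system scores ~1 regardless of how
many trials were collected; unrelated error structure scores ~0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task_env import TaskCondition

__all__ = [
    "TRIAL_COLUMNS",
    "make_trial_table",
    "mean_absolute_error",
    "error_vector",
    "ConsistencyScore",
    "split_half_consistency",
]

TRIAL_COLUMNS = ["condition_id", "repetition", "paddle_y"]


def make_trial_table(
    condition_ids: np.ndarray, repetitions: np.ndarray, paddle_y: np.ndarray
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "condition_id": np.asarray(condition_ids, dtype=int),
            "repetition": np.asarray(repetitions, dtype=int),
            "paddle_y": np.asarray(paddle_y, dtype=float),
        }
    )


def _ground_truth(conds: list[TaskCondition] | pd.DataFrame) -> pd.Series:
    if isinstance(conds, pd.DataFrame):
        return pd.Series(conds["y_final"].values, index=conds["id"].values)
    return pd.Series({c.id: c.y_final for c in conds})


def _check_trials(trials: pd.DataFrame, gt: pd.Series) -> None:
    if trials.empty:
        raise ValueError("empty trial table")
    unknown = set(trials["condition_id"]) - set(gt.index)
    if unknown:
        raise KeyError(f"trials reference unknown conditions: {sorted(unknown)[:5]}")


def mean_absolute_error(
    trials: pd.DataFrame, conds: list[TaskCondition] | pd.DataFrame
) -> float:
    """Mean over trials of |final paddle height - final ball height|, degrees."""
    gt = _ground_truth(conds)
    _check_trials(trials, gt)
    z = gt.loc[trials["condition_id"]].to_numpy()
    return float(np.mean(np.abs(trials["paddle_y"].to_numpy() - z)))


def error_vector(
    trials: pd.DataFrame, conds: list[TaskCondition] | pd.DataFrame
) -> pd.Series:
    """Per-condition mean residual error (the behavioral signature).

    A single slope/intercept is fitted at the trial level across all
    conditions (paddle ~ ground truth); residuals are then averaged within
    condition. An affine distortion of perfect behavior therefore maps to the
    zero vector.
    """
    gt = _ground_truth(conds)
    _check_trials(trials, gt)
    z = gt.loc[trials["condition_id"]].to_numpy(dtype=float)
    x = trials["paddle_y"].to_numpy(dtype=float)
    if np.ptp(z) == 0:
        raise ValueError("ground truth constant across trials; regression degenerate")
    slope, intercept = np.polyfit(z, x, 1)
    resid = x - (slope * z + intercept)
    return (
        pd.Series(resid, index=trials["condition_id"].to_numpy())
        .groupby(level=0)
        .mean()
        .sort_index()
    )


@dataclass
class ConsistencyScore:
    """Noise-adjusted consistency, summarized over random trial splits."""

    rho_hat: float          # mean over splits
    dispersion: float       # SD over splits
    n_splits: int
    per_split: np.ndarray
    reliable: bool          # False if any internal reliability was <= 0
    internal_m: float       # mean split-half reliability of system m
    internal_h: float


def _split_halves(
    trials: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random half-split of trials, stratified within condition."""
    idx_a: list[np.ndarray] = []
    idx_b: list[np.ndarray] = []
    for _, grp in trials.groupby("condition_id"):
        perm = rng.permutation(grp.index.to_numpy())
        half = len(perm) // 2
        if half == 0:
            raise ValueError("need >= 2 repetitions per condition to split")
        idx_a.append(perm[:half])
        idx_b.append(perm[half : 2 * half])
    return trials.loc[np.concatenate(idx_a)], trials.loc[np.concatenate(idx_b)]


def _corr(a: pd.Series, b: pd.Series) -> float:
    joined = pd.concat([a, b], axis=1, join="inner")
    return float(np.corrcoef(joined.iloc[:, 0], joined.iloc[:, 1])[0, 1])


def split_half_consistency(
    trials_m: pd.DataFrame,
    trials_h: pd.DataFrame,
    conds: list[TaskCondition] | pd.DataFrame,
    n_splits: int = 10,
    seed: int = 0,
    m_noiseless: bool = False,
) -> ConsistencyScore:
    """Noise-adjusted split-half consistency between two systems.

    Per split, each system's trials are randomly divided into two stratified
    halves and an error-vector is computed from each half. The internal
    reliabilities are the Pearson correlations between a system's own halves;
    the cross-system term averages the four half-by-half cross correlations.
    Repeated ``n_splits`` times; the mean and SD over splits are reported.

    ``m_noiseless=True`` treats system m as deterministic with a single
    repetition (as RNNs are): its full error-vector is used on both sides and
    its internal reliability is fixed at 1.
    """
    gt_conds = conds
    rng = np.random.default_rng(seed)
    scores = np.empty(n_splits)
    rel_m = np.empty(n_splits)
    rel_h = np.empty(n_splits)
    reliable = True
    ev_m_full = error_vector(trials_m, gt_conds) if m_noiseless else None
    for s in range(n_splits):
        if m_noiseless:
            m1 = m2 = ev_m_full
            r_mm = 1.0
        else:
            a, b = _split_halves(trials_m, rng)
            m1, m2 = error_vector(a, gt_conds), error_vector(b, gt_conds)
            r_mm = _corr(m1, m2)
        a, b = _split_halves(trials_h, rng)
        h1, h2 = error_vector(a, gt_conds), error_vector(b, gt_conds)
        r_hh = _corr(h1, h2)
        r_mh = np.mean(
            [_corr(m1, h1), _corr(m1, h2), _corr(m2, h1), _corr(m2, h2)]
        )
        rel_m[s], rel_h[s] = r_mm, r_hh
        if r_mm <= 0 or r_hh <= 0:
            reliable = False
            scores[s] = np.nan
        else:
            scores[s] = r_mh / np.sqrt(r_mm * r_hh)
    valid = scores[np.isfinite(scores)]
    return ConsistencyScore(
        rho_hat=float(valid.mean()) if valid.size else float("nan"),
        dispersion=float(valid.std(ddof=1)) if valid.size > 1 else float("nan"),
        n_splits=n_splits,
        per_split=scores,
        reliable=reliable,
        internal_m=float(rel_m.mean()),
        internal_h=float(rel_h.mean()),
    )
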