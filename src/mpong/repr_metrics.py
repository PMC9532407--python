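"""Metrics on RNN internal representations.

The substrate is the hidden-state tensor X of shape
(N_trials, N_timesteps, N_units), aligned timestep-by-timestep with the ball
trajectories. The metrics:

- **ISDP** (intermediate-state decode performance): mean absolute error of a
  cross-validated linear decoder predicting the instantaneous ball (x, y)
  from hidden states, trained on visible + occluded epochs and scored on
  held-out occluded points. Lower = stronger explicit latent tracking.
- **Participation ratio**: (sum lambda)^2 / sum lambda^2 over covariance
  eigenvalues of the flattened states — an effective dimensionality.
- **Speed / curvature**: trial-averaged ratio of the time-mean norm of the
  first / second temporal difference to the time-mean activity norm.
- **Feedback control**: mean |cosine| between the movement read-out vector
  and each unit's incoming recurrent weights, across gates.
- **Velocity decoding maps**: position-binned cross-validated R^2 of ball
  velocity from hidden states, with "pixels" (decode from the encoded
  inputs) and "null" (decode from ball position alone) controls.
- **Cross-validated (partial) R^2** comparison machinery used to attribute
  consistency variance across a model zoo to competing attributes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold

__all__ = [
    "HiddenStates",
    "isdp",
    "participation_ratio",
    "speed_metric",
    "curvature_metric",
    "feedback_control",
    "velocity_decoding_map",
    "explained_variance_r2",
    "partial_r2",
]


@dataclass
class HiddenStates:
    """Padded hidden-state tensor with trajectory alignment.

    states: (N, T, U); positions/velocities: (N, T, 2) in degrees (and
    deg/timestep); visible: (N, T) bool; lengths: (N,) — entries at or beyond
    a trial's length are padding and ignored everywhere.
    """

    states: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray
    visible: np.ndarray
    lengths: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.states.shape[0]

    def valid_mask(self) -> np.ndarray:
        T = self.states.shape[1]
        return np.arange(T)[None, :] < self.lengths[:, None]

    def occluded_mask(self) -> np.ndarray:
        return self.valid_mask() & ~self.visible

    def flat_states(self) -> np.ndarray:
        """(sum of lengths, U) matrix of all valid states."""
        return self.states[self.valid_mask()]


def _fit_predict(Xtr, Ytr, Xte):
    reg = LinearRegression().fit(Xtr, Ytr)
    return reg.predict(Xte)


def isdp(hidden: HiddenStates, euclidean: bool = False) -> float:
    """Occluded-ball position decode error (degrees, lower = better).

    Two condition folds crossed with two timepoint folds; the decoder is
    fitted on (training conditions, training timepoints) over both epochs and
    scored only on (held-out conditions, held-out timepoints) restricted to
    the occluded epoch. The error averages |dx|+|dy| over the two coordinates
    (or the Euclidean distance with ``euclidean=True``).
    """
    N, T, _ = hidden.states.shape
    if N < 2:
        raise ValueError("need >= 2 conditions")
    occ = hidden.occluded_mask()
    if not occ.any():
        raise ValueError("no occluded timepoints")
    valid = hidden.valid_mask()
    cond_fold = np.arange(N) % 2
    time_fold = np.arange(T) % 2
    errs = []
    for cf in (0, 1):
        for tf in (0, 1):
            tr = (
                valid
                & (cond_fold != cf)[:, None]
                & (time_fold != tf)[None, :]
            )
            te = occ & (cond_fold == cf)[:, None] & (time_fold == tf)[None, :]
            if not te.any():
                continue
            pred = _fit_predict(
                hidden.states[tr], hidden.positions[tr], hidden.states[te]
            )
            diff = pred - hidden.positions[te]
            if euclidean:
                errs.append(np.linalg.norm(diff, axis=1).mean())
            else:
                errs.append(np.abs(diff).mean())
    return float(np.mean(errs))


def participation_ratio(states: np.ndarray | HiddenStates) -> float:
    """Effective dimensionality of the state cloud.

    PR = (sum lambda_i)^2 / sum lambda_i^2 over the eigenvalues of the
    covariance of the (samples, units) matrix; 1 for rank-1 data, U for
    isotropic data in U units.
    """
    X = states.flat_states() if isinstance(states, HiddenStates) else np.asarray(states)
    if X.ndim == 3:
        X = X.reshape(-1, X.shape[-1])
    if X.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    lam = np.linalg.eigvalsh(np.cov(X, rowvar=False))
    lam = np.clip(lam, 0.0, None)
    total = lam.sum()
    if total <= 0:
        raise ValueError("zero total variance")
    return float(total**2 / (lam**2).sum())


def _norm_ratio(hidden: HiddenStates, order: int) -> float:
    """Trial-mean of (time-mean derivative norm / time-mean activity norm)."""
    ratios = []
    for i in range(hidden.n_trials):
        L = hidden.lengths[i]
        X = hidden.states[i, :L]
        if L < order + 1:
            raise ValueError("trial too short for requested derivative")
        D = np.diff(X, n=order, axis=0)
        denom = np.linalg.norm(X, axis=1).mean()
        if denom == 0:
            raise ValueError("all-zero activity in a trial")
        ratios.append(np.linalg.norm(D, axis=1).mean() / denom)
    return float(np.mean(ratios))


def speed_metric(hidden: HiddenStates) -> float:
    """Normalized trajectory speed (first temporal difference)."""
    return _norm_ratio(hidden, 1)


def curvature_metric(hidden: HiddenStates) -> float:
    """Normalized trajectory curvature (second temporal difference)."""
    return _norm_ratio(hidden, 2)


def feedback_control(
    model,
    n_null: int = 1000,
    seed: int = 0,
    column_convention: bool = True,
) -> tuple[float, np.ndarray]:
    """Alignment of the movement read-out with the recurrent weights.

    For each gate's (H, H) recurrent block, takes each unit's incoming weight
    vector and computes |cos| with the unit-normalized movement read-out;
    averages over units and gates. With the ``h @ Wh`` storage convention,
    incoming weights are columns (``column_convention=True``); the row
    alternative is provided because the convention is arbitrary.

    Returns (score, null distribution of the same score for ``n_null``
    random unit-sphere read-out vectors).
    """
    w = model.Wout[:, 0].astype(float)
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("zero-norm movement read-out")
    w = w / nw
    mats = model.recurrent_gate_matrices()
    rng = np.random.default_rng(seed)
    H = w.shape[0]

    def score_for(vec: np.ndarray) -> float:
        vals = []
        skipped = 0
        for M in mats.values():
            V = M if column_convention else M.T  # columns = incoming weights
            norms = np.linalg.norm(V, axis=0)
            ok = norms > 0
            skipped += int((~ok).sum())
            vals.append(np.abs(vec @ V[:, ok]) / norms[ok])
        return float(np.concatenate(vals).mean())

    score = score_for(w)
    null = np.empty(n_null)
    for i in range(n_null):
        v = rng.standard_normal(H)
        null[i] = score_for(v / np.linalg.norm(v))
    return score, null


def _det_r2(pred: np.ndarray, truth: np.ndarray) -> float:
    """Held-out coefficient of determination per target dim, floored at 0.

    Unlike squared Pearson, 1 - SSE/SST is not positively biased for
    uninformative decoders on small bins: garbage predictions score <= 0.
    """
    r2s = []
    for d in range(truth.shape[1]):
        sst = ((truth[:, d] - truth[:, d].mean()) ** 2).sum()
        if sst == 0:
            r2s.append(0.0)
            continue
        sse = ((truth[:, d] - pred[:, d]) ** 2).sum()
        r2s.append(max(0.0, 1.0 - sse / sst))
    return float(np.mean(r2s))


def _cv_r2(
    X: np.ndarray, Y: np.ndarray, groups: np.ndarray, n_folds: int = 5
) -> float:
    """Cross-validated R^2 of Y from X; folds partition groups (trials)."""
    uniq = np.unique(groups)
    n_folds = min(n_folds, len(uniq))
    if n_folds < 2:
        return float("nan")
    pred = np.empty_like(Y, dtype=float)
    kf = KFold(n_splits=n_folds, shuffle=False)
    for tr_g, te_g in kf.split(uniq):
        tr = np.isin(groups, uniq[tr_g])
        te = np.isin(groups, uniq[te_g])
        pred[te] = _fit_predict(X[tr], Y[tr], X[te])
    return _det_r2(pred, Y)


def velocity_decoding_map(
    hidden: HiddenStates,
    inputs: np.ndarray | None = None,
    n_bins: int = 10,
    frame_span: float = 20.0,
    n_folds: int = 5,
    min_bin_factor: int = 2,
    global_decoder: bool = False,
) -> dict[str, np.ndarray]:
    """Position-conditioned cross-validated R^2 of ball velocity.

    Partitions the frame into ``n_bins x n_bins`` position bins; within each
    populated bin (>= ``min_bin_factor`` x n_units samples) fits a linear
    decoder hidden states -> (dx, dy) with trial-grouped cross-validation.
    Returns maps keyed ``"states"``, ``"null"`` (decode from the in-bin ball
    position — near zero by construction), and, if ``inputs`` (N, T, D
    encoded frames) is given, ``"pixels"``. Under-populated bins are NaN.
    ``global_decoder=True`` fits a single decoder on all samples and only
    *scores* per bin.
    """
    valid = hidden.valid_mask()
    S = hidden.states[valid]
    P = hidden.positions[valid]
    V = hidden.velocities[valid]
    groups = np.broadcast_to(
        np.arange(hidden.n_trials)[:, None], valid.shape
    )[valid]
    feats = {"states": S, "null": P}
    if inputs is not None:
        feats["pixels"] = inputs[valid]
    edges = np.linspace(0.0, frame_span, n_bins + 1)
    ix = np.clip(np.digitize(P[:, 0], edges) - 1, 0, n_bins - 1)
    iy = np.clip(np.digitize(P[:, 1], edges) - 1, 0, n_bins - 1)
    n_units = S.shape[1]
    maps = {k: np.full((n_bins, n_bins), np.nan) for k in feats}

    if global_decoder:
        preds = {}
        for key, X in feats.items():
            uniq = np.unique(groups)
            pred = np.empty_like(V, dtype=float)
            kf = KFold(n_splits=min(n_folds, len(uniq)), shuffle=False)
            for tr_g, te_g in kf.split(uniq):
                tr = np.isin(groups, uniq[tr_g])
                te = np.isin(groups, uniq[te_g])
                pred[te] = _fit_predict(X[tr], V[tr], X[te])
            preds[key] = pred

    for bx in range(n_bins):
        for by in range(n_bins):
            sel = (ix == bx) & (iy == by)
            if sel.sum() < min_bin_factor * n_units:
                continue
            for key, X in feats.items():
                if global_decoder:
                    maps[key][by, bx] = _det_r2(preds[key][sel], V[sel])
                else:
                    maps[key][by, bx] = _cv_r2(
                        X[sel], V[sel], groups[sel], n_folds
                    )
    return maps


def explained_variance_r2(
    X: np.ndarray, Y: np.ndarray, k_folds: int = 5, seed: int = 0
) -> float:
    """Cross-validated proportion of variance of X explained by Y.

    X is PCA-orthogonalized; each orthogonalized dimension is predicted from
    Y with k-fold cross-validated linear regression; the per-dimension
    squared Pearson r values are combined with weights proportional to the
    eigenvalues (the variance carried by each dimension).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    if Y.shape[0] == 1:
        Y = Y.T
    n = X.shape[0]
    if n <= k_folds:
        raise ValueError("need more samples than folds")
    n_comp = min(X.shape)
    pca = PCA(n_components=n_comp)
    Xp = pca.fit_transform(X)
    lam = pca.explained_variance_
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    pred = np.empty_like(Xp)
    for tr, te in kf.split(Xp):
        pred[te] = _fit_predict(Y[tr], Xp[tr], Y[te])
    r2 = np.empty(n_comp)
    for d in range(n_comp):
        if np.std(pred[:, d]) == 0 or np.std(Xp[:, d]) == 0:
            r2[d] = 0.0
        else:
            r2[d] = np.corrcoef(pred[:, d], Xp[:, d])[0, 1] ** 2
    w = lam / lam.sum()
    return float((w * r2).sum())


def partial_r2(
    attribute: np.ndarray, scores: np.ndarray, covariates: np.ndarray
) -> float:
    """Squared partial Pearson correlation of attribute and scores,
    controlling for covariates (both sides residualized by least squares)."""
    a = np.asarray(attribute, dtype=float).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != a.shape[0]:
        C = C.T
    if a.shape[0] < 3:
        raise ValueError("need >= 3 systems")
    D = np.column_stack([np.ones_like(a), C])

    def residualize(v: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(D, v, rcond=None)
        return v - D @ beta

    ra, rs = residualize(a), residualize(s)
    if np.std(ra) < 1e-10 * max(np.std(a), 1e-300) or np.std(rs) < 1e-10 * max(
        np.std(s), 1e-300
    ):
        raise ValueError("constant residuals; partial correlation undefined")
    return float(np.corrcoef(ra, rs)[0, 1] ** 2)
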