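"""Small recurrent networks (LSTM / GRU) trained to intercept the ball,
optionally with auxiliary losses that force an explicit, linearly-decodable
estimate of the latent ball position.

Every model maps a (T, 100) encoded frame sequence to 7 output channels,
each an independent linear read-out of the hidden state. Channel 0 is the
*movement* channel — the paddle position — supervised at exactly two
timepoints: trial start (central paddle) and interception (final ball
height); in between it is free-running. The remaining channels carry the
auxiliary latent-position targets depending on the optimization regime:

========== ====================================================
no_sim          movement channel only
vis_sim         + ball (x, y) while visible
all_sim         + ball (x, y) over the whole trial
all_sim2        + separate (x, y) channels for visible/occluded
simple_dynamics movement only, + slow/smooth hidden-state
                regularization (activity norm, derivative norm,
                and their ratio)
========== ====================================================

Forward passes and back-propagation-through-time are implemented directly in
numpy (the networks are tiny: 10-20 units, <= 90 timesteps); gradients are
validated against finite differences in the test suite. Training uses Adam.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .behavior_metrics import make_trial_table
from .task_env import FrameGeometry, TaskCondition

__all__ = [
    "ModelSpec",
    "RNNModel",
    "channel_layout",
    "build_model",
    "make_channel_targets",
    "compute_loss",
    "loss_and_grads",
    "train_model",
    "run_model",
    "behavior_of_model",
]

N_CHANNELS = 7
LOSS_TYPES = ("no_sim", "vis_sim", "all_sim", "all_sim2", "simple_dynamics")
RNN_TYPES = ("lstm", "gru")
REG_TYPES = ("none", "l1", "l2")


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters identifying one zoo member."""

    rnn_type: str = "gru"             # "lstm" | "gru"
    n_hidden: int = 10                # 10 | 20
    input_kind: str = "pixel_pca"     # "pixel_pca" | "gabor_pca"
    n_input: int = 100
    reg: str = "none"                 # "none" | "l1" | "l2" (read-out weights)
    reg_strength: float = 0.0         # 0.01 | 0.1 in the zoo grid
    loss_type: str = "no_sim"
    dyn_reg_weights: tuple[float, float, float] = (0.0, 0.0, 0.0)
    epochs: int = 100
    batch_size: int = 32
    lr: float = 1e-3
    init: str = "uniform"             # "uniform" | "zero"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rnn_type not in RNN_TYPES:
            raise ValueError(f"rnn_type must be one of {RNN_TYPES}")
        if self.loss_type not in LOSS_TYPES:
            raise ValueError(f"loss_type must be one of {LOSS_TYPES}")
        if self.reg not in REG_TYPES:
            raise ValueError(f"reg must be one of {REG_TYPES}")
        if self.loss_type != "simple_dynamics" and any(
            w != 0.0 for w in self.dyn_reg_weights
        ):
            raise ValueError("dyn_reg_weights only apply to simple_dynamics")

    def to_dict(self) -> dict:
        return asdict(self)


LSTM_GATES = ("input", "input_modulation", "forget", "output")
GRU_GATES = ("reset", "update")


def channel_layout(loss_type: str) -> dict[int, str]:
    """Semantic role of each contributing output channel.

    All models expose 7 channels regardless; channels absent from the layout
    exist but carry no loss.
    """
    if loss_type not in LOSS_TYPES:
        raise ValueError(f"unknown loss_type {loss_type!r}")
    layout = {0: "movement"}
    if loss_type == "vis_sim":
        layout.update({1: "vis_x", 2: "vis_y"})
    elif loss_type == "all_sim":
        layout.update({1: "x", 2: "y"})
    elif loss_type == "all_sim2":
        layout.update({1: "vis_x", 2: "vis_y", 3: "occ_x", 4: "occ_y"})
    return layout


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


@dataclass
class RNNModel:
    """Weights of one recurrent network plus its 7 linear read-outs.

    LSTM gate order along the stacked axis: input, input-modulation, forget,
    output. GRU order: reset, update, candidate (the candidate is not a gate
    but shares the stacked parameterization).
    """

    spec: ModelSpec
    Wx: np.ndarray      # (n_input, G*H)
    Wh: np.ndarray      # (H, G*H)
    b: np.ndarray       # (G*H,)
    Wout: np.ndarray    # (H, 7)
    bout: np.ndarray    # (7,)

    @property
    def n_hidden(self) -> int:
        return self.spec.n_hidden

    @property
    def gate_names(self) -> tuple[str, ...]:
        return LSTM_GATES if self.spec.rnn_type == "lstm" else GRU_GATES

    def recurrent_gate_matrices(self) -> dict[str, np.ndarray]:
        """Named (H, H) recurrent weight blocks, one per gate.

        For the GRU only the two named gates (reset, update) are returned;
        the candidate block is part of the dynamics but not a gate.
        """
        h = self.n_hidden
        return {
            name: self.Wh[:, i * h : (i + 1) * h]
            for i, name in enumerate(self.gate_names)
        }

    def params(self) -> dict[str, np.ndarray]:
        return {"Wx": self.Wx, "Wh": self.Wh, "b": self.b,
                "Wout": self.Wout, "bout": self.bout}

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params().values())


def build_model(spec: ModelSpec, seed: int | None = None) -> RNNModel:
    """Deterministically initialize a model from its spec.

    Default initialization is a small seeded uniform (scale 1/sqrt(fan-in));
    ``init="zero"`` sets every parameter to zero (which leaves hidden units
    permutation-symmetric under gradient descent and is provided for
    completeness, not as a useful default).
    """
    seed = spec.seed if seed is None else seed
    h, d = spec.n_hidden, spec.n_input
    g = 4 if spec.rnn_type == "lstm" else 3
    if spec.init == "zero":
        Wx = np.zeros((d, g * h))
        Wh = np.zeros((h, g * h))
        b = np.zeros(g * h)
        Wout = np.zeros((h, N_CHANNELS))
        bout = np.zeros(N_CHANNELS)
    else:
        rng = np.random.default_rng(seed)
        sx = 1.0 / np.sqrt(d)
        sh = 1.0 / np.sqrt(h)
        Wx = rng.uniform(-sx, sx, (d, g * h))
        Wh = rng.uniform(-sh, sh, (h, g * h))
        b = np.zeros(g * h)
        # carry-friendly gate biases so information survives the long
        # blank-input occluded epoch: LSTM forget gate and GRU update gate
        # start open (the classic forget-bias-1 initialization)
        if spec.rnn_type == "lstm":
            b[2 * h : 3 * h] = 1.0
        else:
            b[h : 2 * h] = 1.0
        Wout = rng.uniform(-sh, sh, (h, N_CHANNELS))
        bout = np.zeros(N_CHANNELS)
    return RNNModel(spec=spec, Wx=Wx, Wh=Wh, b=b, Wout=Wout, bout=bout)


# ---------------------------------------------------------------------------
# forward / backward


def _forward(model: RNNModel, X: np.ndarray) -> tuple[np.ndarray, dict]:
    """Run the recurrence over a padded batch X (B, T, D).

    Returns hidden states H (B, T, Hd) and a cache for backprop. Padded
    timesteps are run but excluded from every loss via masks.
    """
    B, T, D = X.shape
    Hd = model.n_hidden
    lstm = model.spec.rnn_type == "lstm"
    H = np.zeros((B, T, Hd))
    cache: dict = {"X": X, "lstm": lstm}
    h = np.zeros((B, Hd))
    if lstm:
        c = np.zeros((B, Hd))
        gates = np.zeros((B, T, 4 * Hd))
        C = np.zeros((B, T, Hd))
        for t in range(T):
            z = X[:, t] @ model.Wx + h @ model.Wh + model.b
            i = _sigmoid(z[:, :Hd])
            gmod = np.tanh(z[:, Hd : 2 * Hd])
            f = _sigmoid(z[:, 2 * Hd : 3 * Hd])
            o = _sigmoid(z[:, 3 * Hd :])
            c = f * c + i * gmod
            h = o * np.tanh(c)
            gates[:, t] = np.concatenate([i, gmod, f, o], axis=1)
            C[:, t] = c
            H[:, t] = h
        cache.update(gates=gates, C=C, H=H)
    else:
        R = np.zeros((B, T, Hd))
        Z = np.zeros((B, T, Hd))
        N = np.zeros((B, T, Hd))
        Q = np.zeros((B, T, Hd))  # h_{t-1} @ Wh_n (pre reset-scaling)
        for t in range(T):
            xz = X[:, t] @ model.Wx + model.b
            hz = h @ model.Wh
            r = _sigmoid(xz[:, :Hd] + hz[:, :Hd])
            zg = _sigmoid(xz[:, Hd : 2 * Hd] + hz[:, Hd : 2 * Hd])
            q = hz[:, 2 * Hd :]
            n = np.tanh(xz[:, 2 * Hd :] + r * q)
            h = (1.0 - zg) * n + zg * h
            R[:, t], Z[:, t], N[:, t], Q[:, t] = r, zg, n, q
            H[:, t] = h
        cache.update(R=R, Z=Z, N=N, Q=Q, H=H)
    return H, cache


def _backward(model: RNNModel, cache: dict, dH: np.ndarray) -> dict[str, np.ndarray]:
    """BPTT: gradient of the loss w.r.t. recurrent parameters.

    ``dH[b, t]`` is the upstream gradient on the hidden state h_t (from the
    read-outs and any state regularizers).
    """
    X = cache["X"]
    B, T, D = X.shape
    Hd = model.n_hidden
    dWx = np.zeros_like(model.Wx)
    dWh = np.zeros_like(model.Wh)
    db = np.zeros_like(model.b)
    H = cache["H"]
    if cache["lstm"]:
        gates, C = cache["gates"], cache["C"]
        dh_next = np.zeros((B, Hd))
        dc_next = np.zeros((B, Hd))
        for t in range(T - 1, -1, -1):
            dh = dH[:, t] + dh_next
            i = gates[:, t, :Hd]
            gmod = gates[:, t, Hd : 2 * Hd]
            f = gates[:, t, 2 * Hd : 3 * Hd]
            o = gates[:, t, 3 * Hd :]
            c = C[:, t]
            tc = np.tanh(c)
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc**2)
            c_prev = C[:, t - 1] if t > 0 else np.zeros((B, Hd))
            h_prev = H[:, t - 1] if t > 0 else np.zeros((B, Hd))
            di = dc * gmod
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    dg * (1.0 - gmod**2),
                    df * f * (1.0 - f),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dWx += X[:, t].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dh_next = dz @ model.Wh.T
    else:
        R, Z, N, Q = cache["R"], cache["Z"], cache["N"], cache["Q"]
        dh_next = np.zeros((B, Hd))
        for t in range(T - 1, -1, -1):
            dh = dH[:, t] + dh_next
            r, zg, n, q = R[:, t], Z[:, t], N[:, t], Q[:, t]
            h_prev = H[:, t - 1] if t > 0 else np.zeros((B, Hd))
            dn = dh * (1.0 - zg)
            dzg = dh * (h_prev - n)
            dh_prev = dh * zg
            dzn = dn * (1.0 - n**2)       # pre-tanh candidate
            dr = dzn * q
            dq = dzn * r
            dzr = dr * r * (1.0 - r)
            dzz = dzg * zg * (1.0 - zg)
            dz = np.concatenate([dzr, dzz, dzn], axis=1)
            dWx += X[:, t].T @ dz
            db += dz.sum(axis=0)
            # hidden-to-hidden: reset/update blocks see h_prev directly;
            # candidate block sees h_prev through q with reset scaling on top
            dWh[:, : 2 * Hd] += h_prev.T @ np.concatenate([dzr, dzz], axis=1)
            dWh[:, 2 * Hd :] += h_prev.T @ dq
            dh_prev = (
                dh_prev
                + np.concatenate([dzr, dzz], axis=1) @ model.Wh[:, : 2 * Hd].T
                + dq @ model.Wh[:, 2 * Hd :].T
            )
            dh_next = dh_prev
    return {"Wx": dWx, "Wh": dWh, "b": db}


# ---------------------------------------------------------------------------
# targets and loss


def make_channel_targets(
    conds: list[TaskCondition],
    geom: FrameGeometry,
    loss_type: str,
    T: int | None = None,
    normalized: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-trial, per-channel target time series with validity masks.

    Returns (targets, mask, lengths): targets and mask are (N, T, 7); the
    movement channel (0) is valid at exactly two timepoints per trial — t=0
    with the central paddle height, and t=t_end with the final ball height.
    Latent-position channels carry ball x or y over their designated epoch.

    With ``normalized=True`` (the default used for training) every target is
    mapped through (v - span/2)/(span/2) so all channels live on a ~[-1, 1]
    scale commensurate with the hidden-state range; degree-scale targets make
    the two-point movement loss land in a constant-output basin that tiny
    networks do not escape at small training scale.
    """
    from .task_env import simulate_trajectory

    layout = channel_layout(loss_type)
    if T is None:
        T = max(c.t_end for c in conds) + 1
    N = len(conds)
    targets = np.zeros((N, T, N_CHANNELS))
    mask = np.zeros((N, T, N_CHANNELS), dtype=bool)
    lengths = np.zeros(N, dtype=int)
    center = geom.frame_span / 2.0
    for n, c in enumerate(conds):
        traj = simulate_trajectory(c.x0, c.y0, c.dx0, c.dy0, geom)
        L = traj.t_end + 1
        lengths[n] = L
        targets[n, 0, 0] = center
        mask[n, 0, 0] = True
        targets[n, traj.t_end, 0] = traj.y_final
        mask[n, traj.t_end, 0] = True
        pos = traj.positions
        vis = traj.visible
        occ = ~vis
        for ch, role in layout.items():
            if role == "movement":
                continue
            axis = 0 if role.endswith("x") else 1
            if role.startswith("vis"):
                sel = vis
            elif role.startswith("occ"):
                sel = occ
            else:
                sel = np.ones(L, dtype=bool)
            targets[n, :L, ch][sel] = pos[sel, axis]
            mask[n, :L, ch][sel] = True
    if normalized:
        targets = np.where(mask, (targets - center) / center, 0.0)
    return targets, mask, lengths


def _length_mask(lengths: np.ndarray, T: int) -> np.ndarray:
    return np.arange(T)[None, :] < lengths[:, None]


def compute_loss(
    outputs: np.ndarray,
    targets: np.ndarray,
    mask: np.ndarray,
    spec: ModelSpec,
    Wout: np.ndarray | None = None,
    H: np.ndarray | None = None,
    lengths: np.ndarray | None = None,
) -> float:
    """Scalar training loss (see :func:`loss_and_grads` for the breakdown)."""
    loss, _, _ = _loss_terms(outputs, targets, mask, spec, Wout, H, lengths)
    return loss


def _loss_terms(outputs, targets, mask, spec, Wout, H, lengths):
    layout = channel_layout(spec.loss_type)
    chans = sorted(layout)
    per_channel = {}
    dout = np.zeros_like(outputs)
    for ch in chans:
        m = mask[:, :, ch]
        cnt = m.sum()
        if cnt == 0:
            raise ValueError(f"contributing channel {ch} has an empty mask")
        diff = np.where(m, outputs[:, :, ch] - targets[:, :, ch], 0.0)
        per_channel[ch] = float((diff**2).sum() / cnt)
        dout[:, :, ch] = 2.0 * diff / (cnt * len(chans))
    loss = float(np.mean([per_channel[c] for c in chans]))

    if spec.reg != "none" and Wout is not None and spec.reg_strength > 0:
        if spec.reg == "l1":
            loss += spec.reg_strength * float(np.abs(Wout).sum())
        else:
            loss += spec.reg_strength * float((Wout**2).sum())

    dH_extra = None
    if spec.loss_type == "simple_dynamics" and H is not None:
        w1, w2, w3 = spec.dyn_reg_weights
        lm = _length_mask(lengths, H.shape[1])[:, :, None]
        Hm = np.where(lm, H, 0.0)
        M = lm.sum() * 1.0
        act = float((Hm**2).sum() / M)
        dHp = np.diff(Hm, axis=1)
        # derivative valid where both t and t+1 are inside the trial
        dmask = lm[:, 1:] & lm[:, :-1]
        dHp = np.where(dmask, dHp, 0.0)
        Md = max(dmask.sum() * 1.0, 1.0)
        der = float((dHp**2).sum() / Md)
        ratio = der / act if act > 0 else 0.0
        loss += w1 * act + w2 * der + w3 * ratio
        # gradients: dL/dact and dL/dder, then distribute
        dact = w1 - w3 * der / (act**2) if act > 0 else w1
        dder = w2 + (w3 / act if act > 0 else 0.0)
        dH_extra = dact * 2.0 * Hm / M
        dd = dder * 2.0 * dHp / Md
        dH_extra[:, 1:] += dd
        dH_extra[:, :-1] -= dd
    return loss, dout, dH_extra


def loss_and_grads(
    model: RNNModel,
    X: np.ndarray,
    targets: np.ndarray,
    mask: np.ndarray,
    lengths: np.ndarray,
) -> tuple[float, dict[str, np.ndarray]]:
    """Loss and analytic gradients for a padded batch."""
    H, cache = _forward(model, X)
    outputs = H @ model.Wout + model.bout
    loss, dout, dH_extra = _loss_terms(
        outputs, targets, mask, model.spec, model.Wout, H, lengths
    )
    dWout = np.einsum("bth,btc->hc", H, dout)
    if model.spec.reg == "l1" and model.spec.reg_strength > 0:
        dWout += model.spec.reg_strength * np.sign(model.Wout)
    elif model.spec.reg == "l2" and model.spec.reg_strength > 0:
        dWout += 2.0 * model.spec.reg_strength * model.Wout
    dbout = dout.sum(axis=(0, 1))
    dH = dout @ model.Wout.T
    if dH_extra is not None:
        dH = dH + dH_extra
    grads = _backward(model, cache, dH)
    grads["Wout"] = dWout
    grads["bout"] = dbout
    return loss, grads


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainResult:
    loss_history: np.ndarray  # per-epoch mean batch loss
    diverged: bool = False


def train_model(
    model: RNNModel,
    X: np.ndarray,
    targets: np.ndarray,
    mask: np.ndarray,
    lengths: np.ndarray,
    epochs: int | None = None,
    verbose: bool = False,
) -> TrainResult:
    """Adam training with a fixed seeded batch order (fully deterministic).

    On a NaN loss the last finite parameter state is restored and training
    stops (``diverged=True``).
    """
    spec = model.spec
    epochs = spec.epochs if epochs is None else epochs
    N = X.shape[0]
    if N == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(spec.seed + 1)
    params = model.params()
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(p) for k, p in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    history = []
    for epoch in range(epochs):
        order = rng.permutation(N)
        losses = []
        for start in range(0, N, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            snapshot = {k: p.copy() for k, p in params.items()}
            loss, grads = loss_and_grads(
                model, X[idx], targets[idx], mask[idx], lengths[idx]
            )
            if not np.isfinite(loss):
                for k in params:
                    params[k][...] = snapshot[k]
                return TrainResult(np.array(history), diverged=True)
            step += 1
            for k in params:
                g = grads[k]
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g**2
                mhat = m[k] / (1 - beta1**step)
                vhat = v[k] / (1 - beta2**step)
                params[k] -= spec.lr * mhat / (np.sqrt(vhat) + eps)
            losses.append(loss)
        history.append(float(np.mean(losses)))
        if verbose and (epoch % max(1, epochs // 10) == 0):
            print(f"epoch {epoch}: loss {history[-1]:.5f}")
    return TrainResult(np.array(history))


def run_model(model: RNNModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hidden states (B, T, H) and outputs (B, T, 7) for encoded inputs."""
    H, _ = _forward(model, X)
    return H, H @ model.Wout + model.bout


def behavior_of_model(
    model: RNNModel,
    X: np.ndarray,
    conds: list[TaskCondition],
    lengths: np.ndarray,
    geom: FrameGeometry | None = None,
    normalized: bool = True,
):
    """Trial table of the model's endpoints (deterministic: one repetition).

    The final paddle position of condition i is the movement-channel output
    at that trial's interception timestep, mapped back to degrees when the
    model was trained on normalized targets.
    """
    _, out = run_model(model, X)
    paddle = out[np.arange(len(conds)), lengths - 1, 0]
    if normalized:
        geom = geom or FrameGeometry()
        center = geom.frame_span / 2.0
        paddle = paddle * center + center
    return make_trial_table(
        np.array([c.id for c in conds]), np.zeros(len(conds), dtype=int), paddle
    )
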