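"""Deterministic M-Pong world.

A ball starts at a random position with a random rightward velocity, moves at
constant speed across a 2-D frame with reflecting top/bottom walls, disappears
behind a full-height occluder covering the right part of the frame, and must be
intercepted by a paddle at the right edge. Everything here is expressed in
degrees of visual angle; the renderer converts to image pixels.

Coordinate convention: origin at the bottom-left corner of the frame, y
increases upward. One timestep is one RNN input frame (41.66 ms), not one
screen refresh (16.6 ms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FrameGeometry",
    "TaskCondition",
    "Trajectory",
    "InvalidConditionError",
    "SamplingError",
    "simulate_trajectory",
    "sample_conditions",
    "render_frames",
    "conditions_to_frame",
    "conditions_from_frame",
]

#: visible-epoch duration bounds, in timesteps
VISIBLE_RANGE = (15, 45)
#: occluded-epoch duration bounds, in timesteps
OCCLUDED_RANGE = (15, 45)
#: allowed number of wall bounces per trial
BOUNCE_RANGE = (0, 1)
#: maximum trial length in timesteps (frames)
MAX_TIMESTEPS = 90


class InvalidConditionError(ValueError):
    """Raised for physically invalid initial ball states (e.g. dx0 <= 0)."""


class SamplingError(RuntimeError):
    """Raised when rejection sampling cannot reach the requested count."""


@dataclass(frozen=True)
class FrameGeometry:
    """Geometry and timing of the task frame.

    The frame is a square of ``frame_span`` degrees of visual angle. The
    occluder is a full-height band from ``occluder_frac * frame_span`` to the
    right edge; the paddle lives on the right edge (``paddle_x``). The RNN
    timestep ``dt_ms`` is fixed so that 15 timesteps span 624.9 ms, the lower
    bound of the visible-epoch duration.
    """

    frame_span: float = 20.0
    occluder_frac: float = 0.65
    ball_radius: float = 0.25          # ball diameter 0.5 deg
    dt_ms: float = 624.9 / 15.0        # 41.66 ms per RNN timestep
    refresh_ms: float = 16.6           # screen refresh interval
    paddle_step: float = 0.17          # paddle displacement per refresh, deg
    n_pixels: int = 100                # rendered frames are n_pixels x n_pixels

    def __post_init__(self) -> None:
        if not 0.0 < self.occluder_frac < 1.0:
            raise ValueError("occluder_frac must be in (0, 1)")
        if self.frame_span <= 0 or self.ball_radius <= 0:
            raise ValueError("frame_span and ball_radius must be positive")

    @property
    def occluder_x(self) -> float:
        """Left edge of the occluder, degrees."""
        return self.occluder_frac * self.frame_span

    @property
    def paddle_x(self) -> float:
        """Interception plane (right edge of the frame), degrees."""
        return self.frame_span

    @property
    def paddle_speed(self) -> float:
        """Paddle speed in deg/ms (0.17 deg per 16.6 ms refresh ~ 0.01)."""
        return self.paddle_step / self.refresh_ms

    @property
    def px_per_deg(self) -> float:
        return self.n_pixels / self.frame_span


@dataclass(frozen=True)
class TaskCondition:
    """One unique trial condition: initial ball state plus derived epoch data."""

    id: int
    x0: float
    y0: float
    dx0: float          # deg per timestep, > 0
    dy0: float          # deg per timestep
    t_occ: int          # first occluded timestep index
    t_end: int          # interception timestep index
    n_bounces: int
    y_final: float      # ground-truth ball height at the paddle plane


@dataclass
class Trajectory:
    """Stepped ball path at RNN-timestep granularity.

    ``positions[t]`` is the ball position at timestep t (t = 0 .. t_end);
    ``velocities[t]`` is the velocity applied on the step t -> t+1 (the last
    entry repeats the final step's velocity). ``visible[t]`` is True while the
    ball center is left of the occluder.
    """

    positions: np.ndarray        # (t_end+1, 2)
    velocities: np.ndarray       # (t_end+1, 2)
    visible: np.ndarray          # (t_end+1,) bool
    n_bounces: int
    t_occ: int
    t_end: int

    @property
    def y_final(self) -> float:
        return float(self.positions[-1, 1])


def reflect_y(y: float, dy: float, span: float) -> tuple[float, float, int]:
    """Fold a y-coordinate back into [0, span], flipping dy per wall contact.

    Specular reflection: the excursion past a wall is mirrored back, so a
    sub-stepped integrator and a whole-step update agree exactly.
    """
    n = 0
    while y < 0.0 or y > span:
        if y < 0.0:
            y = -y
        else:
            y = 2.0 * span - y
        dy = -dy
        n += 1
    return y, dy, n


def simulate_trajectory(
    x0: float,
    y0: float,
    dx0: float,
    dy0: float,
    geom: FrameGeometry | None = None,
    max_steps: int = 500,
) -> Trajectory:
    """Step the ball until it reaches the paddle plane.

    Constant-velocity stepping with specular reflection at the top/bottom
    walls; the speed sqrt(dx^2 + dy^2) is conserved exactly. Raises
    :class:`InvalidConditionError` if the ball does not move rightward or
    starts outside the frame.
    """
    geom = geom or FrameGeometry()
    if dx0 <= 0.0:
        raise InvalidConditionError(f"ball must move rightward, got dx0={dx0}")
    if not (0.0 <= x0 < geom.paddle_x and 0.0 <= y0 <= geom.frame_span):
        raise InvalidConditionError(f"start ({x0}, {y0}) outside frame")

    xs = [x0]
    ys = [y0]
    pre_dy = []  # dy applied on step t -> t+1
    x, y, dy = x0, y0, dy0
    n_bounces = 0
    while x < geom.paddle_x:
        if len(xs) > max_steps:
            raise InvalidConditionError("trajectory exceeded max_steps")
        pre_dy.append(dy)
        x = x + dx0
        y, dy, nb = reflect_y(y + dy, dy, geom.frame_span)
        n_bounces += nb
        xs.append(x)
        ys.append(y)
    pre_dy.append(dy)  # final entry: velocity leaving the last point

    positions = np.column_stack([xs, ys])
    pre = np.column_stack([np.full(len(xs), dx0), pre_dy])

    visible = positions[:, 0] < geom.occluder_x
    t_end = len(xs) - 1
    t_occ = int(np.argmax(~visible)) if (~visible).any() else t_end
    return Trajectory(
        positions=positions,
        velocities=pre,
        visible=visible,
        n_bounces=n_bounces,
        t_occ=t_occ,
        t_end=t_end,
    )


def condition_from_initial_state(
    cid: int, x0: float, y0: float, dx0: float, dy0: float, geom: FrameGeometry
) -> TaskCondition:
    traj = simulate_trajectory(x0, y0, dx0, dy0, geom)
    return TaskCondition(
        id=cid,
        x0=x0,
        y0=y0,
        dx0=dx0,
        dy0=dy0,
        t_occ=traj.t_occ,
        t_end=traj.t_end,
        n_bounces=traj.n_bounces,
        y_final=traj.y_final,
    )


def condition_satisfies_constraints(cond: TaskCondition) -> bool:
    """The published acceptance constraints on a trial condition."""
    occluded = cond.t_end - cond.t_occ
    return (
        cond.dx0 > 0
        and VISIBLE_RANGE[0] <= cond.t_occ <= VISIBLE_RANGE[1]
        and OCCLUDED_RANGE[0] <= occluded <= OCCLUDED_RANGE[1]
        and BOUNCE_RANGE[0] <= cond.n_bounces <= BOUNCE_RANGE[1]
        and cond.t_end <= MAX_TIMESTEPS
    )


def sample_conditions(
    n: int,
    geom: FrameGeometry | None = None,
    seed: int = 0,
    heading_deg: float = 60.0,
    min_accept_rate: float = 1e-3,
    start_id: int = 0,
) -> list[TaskCondition]:
    """Rejection-sample ``n`` task conditions satisfying the trial constraints.

    Proposals: start position uniform over the visible region (a ball radius
    away from the walls), heading uniform in (-heading_deg, +heading_deg) from
    horizontal, speed uniform in [frame_span/90, frame_span/20] deg/timestep.
    A proposal is accepted iff the stepped trajectory satisfies: visible epoch
    in [15, 45] timesteps, occluded epoch in [15, 45] timesteps, at most one
    bounce, and trial length at most 90 timesteps. Deterministic given seed.
    """
    geom = geom or FrameGeometry()
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[TaskCondition] = []
    tried = 0
    violations = {"visible": 0, "occluded": 0, "bounces": 0, "length": 0}
    while len(out) < n:
        tried += 1
        if tried > max(1000, int(n / min_accept_rate)):
            raise SamplingError(
                f"acceptance rate below floor after {tried} proposals; "
                f"constraint violations: {violations}"
            )
        x0 = rng.uniform(geom.ball_radius, geom.occluder_x - geom.ball_radius)
        y0 = rng.uniform(geom.ball_radius, geom.frame_span - geom.ball_radius)
        theta = np.deg2rad(rng.uniform(-heading_deg, heading_deg))
        speed = rng.uniform(geom.frame_span / 90.0, geom.frame_span / 20.0)
        dx0 = speed * np.cos(theta)
        dy0 = speed * np.sin(theta)
        cond = condition_from_initial_state(start_id + len(out), x0, y0, dx0, dy0, geom)
        if not (VISIBLE_RANGE[0] <= cond.t_occ <= VISIBLE_RANGE[1]):
            violations["visible"] += 1
            continue
        occluded = cond.t_end - cond.t_occ
        if not (OCCLUDED_RANGE[0] <= occluded <= OCCLUDED_RANGE[1]):
            violations["occluded"] += 1
            continue
        if not (BOUNCE_RANGE[0] <= cond.n_bounces <= BOUNCE_RANGE[1]):
            violations["bounces"] += 1
            continue
        if cond.t_end > MAX_TIMESTEPS:
            violations["length"] += 1
            continue
        out.append(cond)
    return out


def render_frames(traj: Trajectory, geom: FrameGeometry | None = None) -> np.ndarray:
    """Render one grayscale frame per timestep (occluded frames are blank).

    Returns a float32 tensor of shape (t_end+1, n_pixels, n_pixels) with
    intensities in [0, 1]. Pixel mapping: column j covers x in
    [j, j+1) * frame_span / n_pixels; row 0 is the *top* of the frame
    (row i covers y in [span - (i+1)*res, span - i*res)). The ball is a filled
    disk with a one-pixel soft edge; the paddle is never rendered.
    """
    geom = geom or FrameGeometry()
    npx = geom.n_pixels
    res = geom.frame_span / npx
    # pixel-center coordinates in degrees
    cols = (np.arange(npx) + 0.5) * res
    rows = geom.frame_span - (np.arange(npx) + 0.5) * res
    cx = cols[None, :]
    cy = rows[:, None]
    r_px = geom.ball_radius / res
    frames = np.zeros((traj.t_end + 1, npx, npx), dtype=np.float32)
    for t in range(traj.t_end + 1):
        if not traj.visible[t]:
            continue
        x, y = traj.positions[t]
        d = np.sqrt((cx - x) ** 2 + (cy - y) ** 2) / res  # distance in pixels
        frames[t] = np.clip(r_px + 0.5 - d, 0.0, 1.0)
    return frames


_CONDITION_COLUMNS = [
    "id", "x0", "y0", "dx0", "dy0", "t_occ", "t_end", "n_bounces", "y_final",
]


def conditions_to_frame(conds: list[TaskCondition]) -> pd.DataFrame:
    """Condition table as a DataFrame (the CSV schema used on disk)."""
    return pd.DataFrame(
        [
            {k: getattr(c, k) for k in _CONDITION_COLUMNS}
            for c in conds
        ],
        columns=_CONDITION_COLUMNS,
    )


def conditions_from_frame(df: pd.DataFrame) -> list[TaskCondition]:
    missing = set(_CONDITION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"condition table missing columns: {sorted(missing)}")
    return [
        TaskCondition(
            id=int(r.id), x0=float(r.x0), y0=float(r.y0), dx0=float(r.dx0),
            dy0=float(r.dy0), t_occ=int(r.t_occ), t_end=int(r.t_end),
            n_bounces=int(r.n_bounces), y_final=float(r.y_final),
        )
        for r in df.itertuples(index=False)
    ]
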