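"""Synthetic primate-like behavioral systems.

Real interception behavior has three statistical signatures this generator
emulates: (i) a reliable condition-wise error pattern (some conditions are
systematically missed), (ii) trial-to-trial endpoint variability around each
condition's mean, and (iii) larger errors for conditions with larger occluded
vertical ball displacement — the footprint of extrapolating with a prior
toward the last visible height.

A synthetic system's mean endpoint per condition is the noisy-biased
process-model prediction (the source of signature iii) plus a system-specific
Gaussian condition bias (idiosyncrasy); each trial adds independent Gaussian
motor noise. Two *replicas* share everything at the condition level and
differ only in motor noise; *paired systems* share a controllable fraction
``rho_shared`` of their condition-bias structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior_metrics import make_trial_table
from .process_model import SimParams, simulate_endpoints
from .task_env import FrameGeometry, TaskCondition

__all__ = [
    "SyntheticSystemSpec",
    "condition_means",
    "generate_system",
    "generate_paired_systems",
]


@dataclass(frozen=True)
class SyntheticSystemSpec:
    """Defines one synthetic behavioral system.

    params
        Process-model parameters generating the condition-level endpoint
        structure; ``None`` uses the ground-truth endpoints (a system with no
        extrapolation bias, useful when condition biases should be the *only*
        error structure).
    bias_sd
        SD (deg) of the system-specific Gaussian condition bias.
    motor_sd
        SD (deg) of the independent per-trial motor noise.
    n_reps
        Trial repetitions per condition.
    seed
        Seeds the condition-level randomness (process-model draws and bias
        vector). Two tables generated from the same spec are replicas of one
        system; trial noise is seeded separately per table.
    n_mc_samples
        Monte-Carlo samples per condition for the process-model endpoint.
    """

    params: SimParams | None = field(default_factory=SimParams)
    bias_sd: float = 0.6
    motor_sd: float = 1.0
    n_reps: int = 40
    seed: int = 0
    n_mc_samples: int = 100

    def __post_init__(self) -> None:
        if self.bias_sd < 0 or self.motor_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


def condition_means(
    conds: list[TaskCondition],
    spec: SyntheticSystemSpec,
    geom: FrameGeometry | None = None,
) -> np.ndarray:
    """Condition-level mean endpoints: process-model prediction + bias."""
    geom = geom or FrameGeometry()
    if spec.params is None:
        base = np.array([c.y_final for c in conds])
    else:
        base = simulate_endpoints(
            conds, spec.params, geom, n_samples=spec.n_mc_samples, seed=spec.seed
        )
    bias_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    return base + bias_rng.normal(0.0, spec.bias_sd, len(conds))


def _trials_from_means(
    conds: list[TaskCondition],
    means: np.ndarray,
    motor_sd: float,
    n_reps: int,
    trial_seed: int,
) -> pd.DataFrame:
    rng = np.random.default_rng(trial_seed)
    n = len(conds)
    cond_ids = np.repeat([c.id for c in conds], n_reps)
    reps = np.tile(np.arange(n_reps), n)
    paddle = np.repeat(means, n_reps) + rng.normal(0.0, motor_sd, n * n_reps)
    return make_trial_table(cond_ids, reps, paddle)


def generate_system(
    conds: list[TaskCondition],
    spec: SyntheticSystemSpec,
    geom: FrameGeometry | None = None,
    trial_seed: int | None = None,
) -> pd.DataFrame:
    """Draw a trial table from one synthetic system.

    Calling twice with the same spec but different ``trial_seed`` yields two
    stochastic replicas of the same system (identical condition-level
    structure, independent motor noise).
    """
    means = condition_means(conds, spec, geom)
    if trial_seed is None:
        trial_seed = spec.seed + 10_000
    return _trials_from_means(conds, means, spec.motor_sd, spec.n_reps, trial_seed)


def generate_paired_systems(
    conds: list[TaskCondition],
    spec: SyntheticSystemSpec,
    rho_shared: float,
    geom: FrameGeometry | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two systems whose condition biases correlate at exactly ``rho_shared``.

    The pair is built on an unbiased endpoint core (the ground truth), so the
    correlated Gaussian biases are the *only* condition-level error structure
    and the true consistency between the pair equals ``rho_shared``. Motor
    noise is independent between the two tables. ``spec.params`` is ignored
    here by design: a shared biased-process core would add common error
    structure and break the equality.
    """
    if not 0.0 <= rho_shared <= 1.0:
        raise ValueError("rho_shared must be in [0, 1]")
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    n = len(conds)
    shared = rng.normal(0.0, 1.0, n)
    own_a = rng.normal(0.0, 1.0, n)
    own_b = rng.normal(0.0, 1.0, n)
    w_s, w_o = np.sqrt(rho_shared), np.sqrt(1.0 - rho_shared)
    gt = np.array([c.y_final for c in conds])
    means_a = gt + spec.bias_sd * (w_s * shared + w_o * own_a)
    means_b = gt + spec.bias_sd * (w_s * shared + w_o * own_b)
    ta = _trials_from_means(conds, means_a, spec.motor_sd, spec.n_reps, seed + 20_001)
    tb = _trials_from_means(conds, means_b, spec.motor_sd, spec.n_reps, seed + 20_002)
    return ta, tb
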