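"""End-to-end experiment runner: a desk-scale version of the full study.

The pipeline samples task conditions, fits a frame encoder, trains a small
zoo of RNNs under contrasting optimization regimes, measures each model's
behavior and internal representations, and scores behavioral consistency
against a synthetic reference system generated by the noisy-biased process
model. All randomness derives from the config seed; reruns are bit-identical.

Problem sizes here are deliberately small (hundreds of training conditions,
tens of hidden units, ~10^2 epochs); the full-scale study trains hundreds of
networks on up to 212,480 conditions. The config exposes every size knob.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .behavior_metrics import mean_absolute_error, split_half_consistency
from .encoders import FrameEncoder, fit_encoder
from .process_model import SimParams
from .repr_metrics import (
    HiddenStates,
    curvature_metric,
    feedback_control,
    isdp,
    participation_ratio,
    speed_metric,
)
from .rnn_zoo import (
    ModelSpec,
    behavior_of_model,
    build_model,
    make_channel_targets,
    run_model,
    train_model,
)
from .synthetic_behavior import SyntheticSystemSpec, generate_system
from .task_env import (
    FrameGeometry,
    TaskCondition,
    conditions_to_frame,
    render_frames,
    sample_conditions,
    simulate_trajectory,
)

__all__ = [
    "ExperimentConfig",
    "default_zoo_grid",
    "EncodedDataset",
    "prepare_dataset",
    "hidden_states_for",
    "run_pipeline",
]

MAX_T = 91  # padded sequence length (trials are at most 90 steps + t=0)


@dataclass
class ExperimentConfig:
    """Everything a pipeline run depends on, seeds included."""

    n_train: int = 300
    n_test: int = 100
    seed: int = 0
    encoder_kind: str = "pixel_pca"
    n_components: int = 100
    pca_batch_trials: int = 4
    pca_subset_trials: int = 64
    epochs: int = 200
    lr: float = 1e-2
    n_hidden: int = 10
    zoo: list[dict] = field(default_factory=list)   # ModelSpec overrides
    reference: dict = field(
        default_factory=lambda: {
            "sigma2_occ": 0.05, "sigma2_bounce": 0.1, "w_bias": 0.7,
            "bias_sd": 0.3, "motor_sd": 1.0, "n_reps": 40,
        }
    )
    n_splits: int = 10
    outdir: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)


def default_zoo_grid(
    config: ExperimentConfig, n_pairs: int = 4
) -> list[dict]:
    """Matched no_sim / all_sim2 pairs across seeds and cell types."""
    grid = []
    for k in range(n_pairs):
        rnn_type = ("gru", "lstm")[k % 2]
        for loss_type in ("no_sim", "all_sim2"):
            grid.append(
                {"rnn_type": rnn_type, "loss_type": loss_type, "seed": k}
            )
    return grid


@dataclass
class EncodedDataset:
    conds: list[TaskCondition]
    X: np.ndarray                  # (N, T, D) standardized encodings
    lengths: np.ndarray
    positions: np.ndarray          # (N, T, 2)
    velocities: np.ndarray
    visible: np.ndarray            # (N, T) bool


def _encode(
    enc: FrameEncoder,
    conds: list[TaskCondition],
    geom: FrameGeometry,
    scale: float,
    T: int = MAX_T,
) -> EncodedDataset:
    n = len(conds)
    X = np.zeros((n, T, enc.n_components))
    P = np.zeros((n, T, 2))
    V = np.zeros((n, T, 2))
    vis = np.zeros((n, T), dtype=bool)
    lengths = np.zeros(n, dtype=int)
    for i, c in enumerate(conds):
        traj = simulate_trajectory(c.x0, c.y0, c.dx0, c.dy0, geom)
        L = traj.t_end + 1
        lengths[i] = L
        X[i, :L] = enc.transform(render_frames(traj, geom)) / scale
        P[i, :L] = traj.positions
        V[i, :L] = traj.velocities
        vis[i, :L] = traj.visible
    return EncodedDataset(conds, X, lengths, P, V, vis)


def prepare_dataset(
    config: ExperimentConfig, geom: FrameGeometry | None = None
) -> tuple[EncodedDataset, EncodedDataset, FrameEncoder, float]:
    """Sample conditions, fit the encoder on training trials, encode both
    splits with a shared standardization scale."""
    geom = geom or FrameGeometry()
    train = sample_conditions(config.n_train, geom, seed=config.seed)
    test = sample_conditions(
        config.n_test, geom, seed=config.seed + 500_000, start_id=1_000_000
    )
    train_frames = [
        render_frames(simulate_trajectory(c.x0, c.y0, c.dx0, c.dy0, geom), geom)
        for c in train
    ]
    enc = fit_encoder(
        config.encoder_kind,
        train_frames,
        n_components=config.n_components,
        batch_trials=config.pca_batch_trials,
        subset_trials=config.pca_subset_trials,
        seed=config.seed,
    )
    # standardize encodings to unit global SD (computed on training trials);
    # PCA projections of mostly-blank frames are otherwise tiny and slow
    # optimization badly
    raw = np.concatenate([enc.transform(f) for f in train_frames])
    scale = float(raw.std())
    ds_train = _encode(enc, train, geom, scale)
    ds_test = _encode(enc, test, geom, scale)
    return ds_train, ds_test, enc, scale


def hidden_states_for(model, ds: EncodedDataset) -> HiddenStates:
    H, _ = run_model(model, ds.X)
    return HiddenStates(H, ds.positions, ds.velocities, ds.visible, ds.lengths)


def run_pipeline(
    config: ExperimentConfig, geom: FrameGeometry | None = None
) -> dict:
    """Execute all stages; returns (and optionally writes) the manifest.

    Stages: conditions -> encoder -> zoo training -> behavior -> metrics ->
    consistency vs. synthetic reference -> report tables. Any stage failure
    is recorded in the manifest and downstream stages are skipped.
    """
    geom = geom or FrameGeometry()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": [], "artifacts": {}}

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                fn()
                manifest["stages"].append(
                    {"name": name, "ok": True, "seconds": round(time.time() - t0, 2)}
                )
                return True
            except Exception as exc:  # noqa: BLE001 - recorded, not hidden
                manifest["stages"].append(
                    {"name": name, "ok": False, "error": f"{type(exc).__name__}: {exc}"}
                )
                return False
        return deco

    state: dict = {}

    def run_stage(name, fn):
        return stage(name)(fn)

    def _conditions():
        state["data"] = prepare_dataset(config, geom)
        if outdir:
            ds_train, ds_test, _, _ = state["data"]
            mio.write_table(
                conditions_to_frame(ds_train.conds),
                outdir / "train_conditions.csv", "conditions v1",
            )
            mio.write_table(
                conditions_to_frame(ds_test.conds),
                outdir / "test_conditions.csv", "conditions v1",
            )
            manifest["artifacts"]["train_conditions"] = "train_conditions.csv"
            manifest["artifacts"]["test_conditions"] = "test_conditions.csv"

    if not run_stage("conditions+encoder", _conditions):
        return _finish(manifest, outdir)
    ds_train, ds_test, enc, scale = state["data"]

    def _zoo():
        grid = config.zoo or default_zoo_grid(config)
        rows = []
        models = []
        for mi, overrides in enumerate(grid):
            spec_kwargs = dict(
                n_hidden=config.n_hidden,
                n_input=config.n_components,
                input_kind=config.encoder_kind,
                epochs=config.epochs,
                lr=config.lr,
            )
            spec_kwargs.update(overrides)
            spec = ModelSpec(**spec_kwargs)
            targets, mask, lengths = make_channel_targets(
                ds_train.conds, geom, spec.loss_type, MAX_T
            )
            model = build_model(spec)
            result = train_model(model, ds_train.X, targets, mask, lengths)
            models.append(model)
            rows.append(
                {
                    "model_id": mi,
                    **{k: v for k, v in spec.to_dict().items()
                       if k not in ("dyn_reg_weights",)},
                    "final_loss": result.loss_history[-1],
                    "diverged": result.diverged,
                }
            )
        state["models"] = models
        state["rows"] = rows

    if not run_stage("train_zoo", _zoo):
        return _finish(manifest, outdir)

    def _behavior_metrics():
        reference_cfg = dict(config.reference)
        params = SimParams(
            reference_cfg.pop("sigma2_occ"),
            reference_cfg.pop("sigma2_bounce"),
            reference_cfg.pop("w_bias"),
        )
        ref_spec = SyntheticSystemSpec(
            params=params, seed=config.seed + 11, **reference_cfg
        )
        ref_trials = generate_system(ds_test.conds, ref_spec, geom)
        for model, row in zip(state["models"], state["rows"]):
            trials = behavior_of_model(
                model, ds_test.X, ds_test.conds, ds_test.lengths
            )
            hs = hidden_states_for(model, ds_test)
            row["mae"] = mean_absolute_error(trials, ds_test.conds)
            row["isdp"] = isdp(hs)
            row["participation_ratio"] = participation_ratio(hs)
            row["speed"] = speed_metric(hs)
            row["curvature"] = curvature_metric(hs)
            fb, _ = feedback_control(model, n_null=100, seed=config.seed)
            row["feedback_control"] = fb
            score = split_half_consistency(
                trials, ref_trials, ds_test.conds,
                n_splits=config.n_splits, seed=config.seed, m_noiseless=True,
            )
            row["consistency"] = score.rho_hat
            row["consistency_sd"] = score.dispersion
        state["manifest_df"] = pd.DataFrame(state["rows"])

    if not run_stage("behavior+metrics+consistency", _behavior_metrics):
        return _finish(manifest, outdir)

    def _report():
        df = state["manifest_df"]
        manifest["zoo"] = df.to_dict(orient="records")
        # the consistency-vs-ISDP scatter (and vs performance) across models
        scatter = df[["model_id", "loss_type", "mae", "isdp", "consistency"]]
        manifest["scatter"] = scatter.to_dict(orient="records")
        if outdir:
            mio.write_table(df, outdir / "zoo_manifest.csv", "zoo_manifest v1")
            mio.write_table(
                scatter, outdir / "consistency_scatter.csv", "zoo_manifest v1"
            )
            manifest["artifacts"]["zoo_manifest"] = "zoo_manifest.csv"
            manifest["artifacts"]["consistency_scatter"] = "consistency_scatter.csv"

    run_stage("report", _report)
    return _finish(manifest, outdir)


def _finish(manifest: dict, outdir: Path | None) -> dict:
    if outdir:
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=float) + "\n"
        )
    return manifest
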