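"""RNN construction, losses, gradients, and training behavior."""

import numpy as np
import pytest

from mpong.rnn_zoo import (
    LSTM_GATES,
    GRU_GATES,
    ModelSpec,
    N_CHANNELS,
    behavior_of_model,
    build_model,
    channel_layout,
    compute_loss,
    loss_and_grads,
    make_channel_targets,
    run_model,
    train_model,
)


class TestBuildModel:
    def test_gru_parameter_count_matches_arithmetic(self):
        spec = ModelSpec(rnn_type="gru", n_hidden=10, n_input=100)
        model = build_model(spec)
        # 3 stacked blocks (reset, update, candidate) x (100x10 + 10x10 + 10)
        # + 7 read-outs x (10 + 1)
        expected = 3 * (100 * 10 + 10 * 10 + 10) + 7 * (10 + 1)
        assert model.n_parameters() == expected
        assert model.Wout.shape == (10, N_CHANNELS)

    def test_lstm_has_four_named_gates(self):
        model = build_model(ModelSpec(rnn_type="lstm", n_hidden=10))
        mats = model.recurrent_gate_matrices()
        assert tuple(mats) == LSTM_GATES
        assert all(m.shape == (10, 10) for m in mats.values())

    def test_gru_exposes_two_named_gates(self):
        model = build_model(ModelSpec(rnn_type="gru", n_hidden=20))
        assert tuple(model.recurrent_gate_matrices()) == GRU_GATES

    def test_same_spec_and_seed_identical_weights(self):
        spec = ModelSpec(rnn_type="lstm", n_hidden=10, seed=4)
        a, b = build_model(spec), build_model(spec)
        for k in a.params():
            assert np.array_equal(a.params()[k], b.params()[k])

    def test_zero_init_option(self):
        model = build_model(ModelSpec(init="zero"))
        assert all(np.all(p == 0) for p in model.params().values())

    def test_invalid_enums_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(rnn_type="elman")
        with pytest.raises(ValueError):
            ModelSpec(loss_type="some_sim")
        with pytest.raises(ValueError):
            ModelSpec(loss_type="no_sim", dyn_reg_weights=(0.1, 0, 0))


class TestChannelLayout:
    @pytest.mark.parametrize(
        "loss_type,n_contributing",
        [("no_sim", 1), ("vis_sim", 3), ("all_sim", 3), ("all_sim2", 5),
         ("simple_dynamics", 1)],
    )
    def test_contributing_channel_counts(self, loss_type, n_contributing):
        layout = channel_layout(loss_type)
        assert len(layout) == n_contributing
        assert layout[0] == "movement"

    def test_all_models_have_seven_channels(self):
        for lt in ("no_sim", "vis_sim", "all_sim", "all_sim2"):
            model = build_model(ModelSpec(loss_type=lt))
            assert model.Wout.shape[1] == 7


class TestTargets:
    def test_movement_mask_has_exactly_two_points_per_trial(self, geom, conds50):
        targets, mask, lengths = make_channel_targets(
            conds50, geom, "all_sim2", normalized=False
        )
        assert (mask[:, :, 0].sum(axis=1) == 2).all()
        center = geom.frame_span / 2
        for i, c in enumerate(conds50):
            assert targets[i, 0, 0] == center
            assert targets[i, c.t_end, 0] == pytest.approx(c.y_final)

    def test_normalized_targets_are_affine_rescaling(self, geom, conds50):
        raw, mask, _ = make_channel_targets(
            conds50, geom, "all_sim2", normalized=False
        )
        norm, mask2, _ = make_channel_targets(conds50, geom, "all_sim2")
        assert np.array_equal(mask, mask2)
        c = geom.frame_span / 2
        assert np.allclose(norm[mask], (raw[mask] - c) / c)
        # x can overshoot the paddle plane by at most one step (< 1 deg)
        assert np.abs(norm[mask]).max() <= 1.1

    def test_epoch_channels_cover_their_epochs(self, geom, conds50, trajs50):
        targets, mask, _ = make_channel_targets(
            conds50, geom, "all_sim2", normalized=False
        )
        for i, tr in enumerate(trajs50):
            L = tr.t_end + 1
            assert mask[i, :L, 1].sum() == tr.visible.sum()
            assert mask[i, :L, 3].sum() == (~tr.visible).sum()
            # targets equal the ball path on the valid entries
            assert np.allclose(
                targets[i, :L, 1][tr.visible], tr.positions[tr.visible, 0]
            )
            assert np.allclose(
                targets[i, :L, 4][~tr.visible], tr.positions[~tr.visible, 1]
            )


class TestLoss:
    def test_perfect_outputs_zero_loss(self):
        spec = ModelSpec(loss_type="all_sim")
        rng = np.random.default_rng(0)
        targets = rng.normal(0, 1, (2, 5, 7))
        mask = rng.random((2, 5, 7)) < 0.6
        for ch in (0, 1, 2):
            mask[0, 0, ch] = True  # nonempty
        assert compute_loss(targets.copy(), targets, mask, spec) == 0.0

    def test_hand_arithmetic_two_trials(self):
        # movement channel only; errors 1 and 2 at two valid points each ->
        # channel MSE = (1 + 0 + 4 + 0)/4
        spec = ModelSpec(loss_type="no_sim")
        outputs = np.zeros((2, 3, 7))
        targets = np.zeros((2, 3, 7))
        mask = np.zeros((2, 3, 7), dtype=bool)
        mask[0, 0, 0] = mask[0, 2, 0] = True
        mask[1, 0, 0] = mask[1, 2, 0] = True
        outputs[0, 0, 0] = 1.0
        outputs[1, 2, 0] = 2.0
        assert compute_loss(outputs, targets, mask, spec) == pytest.approx(
            (1.0 + 0.0 + 4.0 + 0.0) / 4.0, abs=1e-10
        )

    def test_channel_weighting_is_unweighted_mean(self):
        # two contributing channels with different counts still average 1:1
        spec = ModelSpec(loss_type="all_sim")
        outputs = np.zeros((1, 4, 7))
        targets = np.zeros((1, 4, 7))
        mask = np.zeros((1, 4, 7), dtype=bool)
        mask[0, :2, 0] = True          # movement: 2 points, errors 3, 0
        outputs[0, 0, 0] = 3.0
        mask[0, :4, 1] = True          # x channel: 4 points, all error 1
        outputs[0, :4, 1] = 1.0
        mask[0, 0, 2] = True           # y channel: 1 point, error 0
        expected = (9.0 / 2 + 1.0 + 0.0) / 3
        assert compute_loss(outputs, targets, mask, spec) == pytest.approx(
            expected, abs=1e-12
        )

    def test_empty_contributing_mask_raises(self):
        spec = ModelSpec(loss_type="all_sim")
        o = np.zeros((1, 3, 7))
        mask = np.zeros((1, 3, 7), dtype=bool)
        mask[0, 0, 0] = True  # movement ok, x/y empty
        with pytest.raises(ValueError):
            compute_loss(o, o, mask, spec)

    def test_constant_states_zero_dynamics_terms(self):
        spec = ModelSpec(
            loss_type="simple_dynamics", dyn_reg_weights=(0.0, 1.0, 1.0)
        )
        outputs = np.zeros((1, 4, 7))
        targets = np.zeros((1, 4, 7))
        mask = np.zeros((1, 4, 7), dtype=bool)
        mask[0, 0, 0] = mask[0, 3, 0] = True
        H = np.ones((1, 4, 3))
        lengths = np.array([4])
        # derivative and ratio terms vanish for constant hidden states
        assert compute_loss(
            outputs, targets, mask, spec, H=H, lengths=lengths
        ) == pytest.approx(0.0, abs=1e-12)

    def test_noncontributing_channel_perturbation_leaves_loss_unchanged(self):
        spec = ModelSpec(loss_type="no_sim")
        model = build_model(spec)
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (2, 6, 100)) * 0.1
        targets = np.zeros((2, 6, 7))
        mask = np.zeros((2, 6, 7), dtype=bool)
        mask[:, 0, 0] = mask[:, 5, 0] = True
        lengths = np.array([6, 6])
        l0, _ = loss_and_grads(model, X, targets, mask, lengths)
        model.Wout[:, 3] += 10.0  # unused channel
        l1, _ = loss_and_grads(model, X, targets, mask, lengths)
        assert l0 == l1

    def test_regularization_monotone_in_strength(self):
        rng = np.random.default_rng(2)
        Wout = rng.normal(0, 1, (10, 7))
        outputs = np.zeros((1, 3, 7))
        mask = np.zeros((1, 3, 7), dtype=bool)
        mask[0, 0, 0] = True
        prev = None
        for s in (0.0, 0.01, 0.1):
            spec = ModelSpec(loss_type="no_sim", reg="l1", reg_strength=s)
            val = compute_loss(outputs, outputs, mask, spec, Wout=Wout)
            if prev is not None:
                assert val >= prev
            prev = val


class TestGradients:
    @pytest.mark.parametrize("rnn_type", ["lstm", "gru"])
    @pytest.mark.parametrize("loss_type", ["all_sim2", "simple_dynamics"])
    def test_analytic_matches_finite_differences(self, rnn_type, loss_type):
        spec = ModelSpec(
            rnn_type=rnn_type,
            n_hidden=4,
            n_input=3,
            loss_type=loss_type,
            reg="l2",
            reg_strength=0.01,
            dyn_reg_weights=(0.01, 0.02, 0.005)
            if loss_type == "simple_dynamics"
            else (0.0, 0.0, 0.0),
            seed=1,
        )
        model = build_model(spec)
        rng = np.random.default_rng(0)
        B, T = 3, 6
        X = rng.standard_normal((B, T, 3)) * 0.5
        targets = rng.standard_normal((B, T, 7))
        mask = rng.random((B, T, 7)) < 0.5
        mask[:, :, 0] = False
        mask[:, 0, 0] = mask[:, T - 1, 0] = True
        for ch in channel_layout(loss_type):
            if not mask[:, :, ch].any():
                mask[0, 1, ch] = True
        lengths = np.array([6, 5, 4])
        _, grads = loss_and_grads(model, X, targets, mask, lengths)
        eps = 1e-5
        for name, P in model.params().items():
            flat_idx = rng.choice(P.size, size=min(15, P.size), replace=False)
            for fi in flat_idx:
                ij = np.unravel_index(fi, P.shape)
                orig = P[ij]
                P[ij] = orig + eps
                lp, _ = loss_and_grads(model, X, targets, mask, lengths)
                P[ij] = orig - eps
                lm, _ = loss_and_grads(model, X, targets, mask, lengths)
                P[ij] = orig
                fd = (lp - lm) / (2 * eps)
                g = grads[name][ij]
                assert abs(fd - g) <= 1e-4 * max(1.0, abs(fd), abs(g)), (
                    f"{name}{ij}: fd={fd} analytic={g}"
                )


@pytest.fixture(scope="module")
def tiny_data(geom, conds50, trajs50):
    # cheap informative inputs standing in for encoded frames: a fixed
    # random projection of the ball position while visible, zeros while
    # occluded (the encoder's blank-frame analogue)
    rng = np.random.default_rng(0)
    conds = conds50[:20]
    trajs = trajs50[:20]
    T = max(c.t_end for c in conds) + 1
    W = rng.normal(0, 0.3, (3, 12))
    X = np.zeros((len(conds), T, 12))
    for i, tr in enumerate(trajs):
        L = tr.t_end + 1
        feats = np.column_stack(
            [tr.positions / 10.0, np.ones(L)]
        ) * tr.visible[:, None]
        X[i, :L] = feats @ W
    return conds, X, T


class TestTraining:

    def test_memorizes_single_condition(self, geom, conds50, tiny_data):
        conds, X, T = tiny_data
        spec = ModelSpec(
            rnn_type="gru", n_hidden=8, n_input=12, loss_type="no_sim",
            epochs=300, lr=2e-2, seed=0,
        )
        targets, mask, lengths = make_channel_targets(conds[:1], geom, "no_sim", T)
        model = build_model(spec)
        res = train_model(model, X[:1], targets, mask, lengths)
        assert res.loss_history[-1] < 0.05 * res.loss_history[0]

    @pytest.mark.parametrize(
        "loss_type,epochs,loss_factor,movement_factor",
        [("all_sim", 150, 5.0, 2.0), ("no_sim", 200, 3.0, 3.0)],
    )
    def test_loss_and_movement_error_decrease(
        self, geom, tiny_data, loss_type, epochs, loss_factor, movement_factor
    ):
        conds, X, T = tiny_data
        spec = ModelSpec(
            rnn_type="lstm", n_hidden=8, n_input=12, loss_type=loss_type,
            epochs=epochs, lr=1e-2, seed=1,
        )
        targets, mask, lengths = make_channel_targets(conds, geom, loss_type, T)
        model = build_model(spec)

        def movement_mse(m):
            _, out = run_model(m, X)
            sel = mask[:, :, 0]
            return float(((out[:, :, 0] - targets[:, :, 0])[sel] ** 2).mean())

        before = movement_mse(model)
        res = train_model(model, X, targets, mask, lengths)
        assert res.loss_history[-1] < res.loss_history[0] / loss_factor
        assert movement_mse(model) < before / movement_factor

    def test_training_deterministic(self, geom, tiny_data):
        conds, X, T = tiny_data
        spec = ModelSpec(
            rnn_type="gru", n_hidden=6, n_input=12, loss_type="no_sim",
            epochs=5, lr=1e-2, seed=2,
        )
        targets, mask, lengths = make_channel_targets(conds, geom, "no_sim", T)
        outs = []
        for _ in range(2):
            model = build_model(spec)
            train_model(model, X, targets, mask, lengths)
            outs.append(model.Wout.copy())
        assert np.array_equal(outs[0], outs[1])

    def test_behavior_table_schema(self, geom, tiny_data):
        conds, X, T = tiny_data
        spec = ModelSpec(rnn_type="gru", n_hidden=6, n_input=12)
        model = build_model(spec)
        lengths = np.array([c.t_end + 1 for c in conds])
        tt = behavior_of_model(model, X, conds, lengths)
        assert list(tt.columns) == ["condition_id", "repetition", "paddle_y"]
        assert len(tt) == len(conds)
        assert (tt["repetition"] == 0).all()

    def test_untrained_model_not_better_than_center(self, geom, tiny_data):
        from mpong.behavior_metrics import mean_absolute_error, make_trial_table

        conds, X, T = tiny_data
        model = build_model(ModelSpec(rnn_type="gru", n_hidden=6, n_input=12))
        lengths = np.array([c.t_end + 1 for c in conds])
        tt = behavior_of_model(model, X, conds, lengths)
        center = make_trial_table(
            [c.id for c in conds], np.zeros(len(conds)),
            np.full(len(conds), geom.frame_span / 2),
        )
        mae_center = mean_absolute_error(center, conds)
        # untrained output hovers near zero -> roughly the center-or-worse
        assert mean_absolute_error(tt, conds) >= 0.8 * mae_center
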