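import numpy as np
import pytest

from swarmcast.errors import ConfigError, StratumMismatchError
from swarmcast.network import (
    HyperParams,
    ModelParams,
    attention_context,
    attention_weights,
    forecast_next,
    forward,
    init_params,
    load_model,
    lstm_step,
    output_head,
    save_model,
    train,
)
from swarmcast.panel import normalize
from swarmcast.windowing import WindowedDataset, make_windows

# ---------------------------------------------------------------- oracles
# Straight scalar transcriptions of the gate/attention/head equations,
# written independently of the vectorized implementation.


def oracle_sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def oracle_lstm_step(x, h_prev, c_prev, p):
    z = np.concatenate([h_prev, x])
    f = oracle_sigmoid(p.W_f @ z + p.b_f)
    i = oracle_sigmoid(p.W_i @ z + p.b_i)
    o = oracle_sigmoid(p.W_o @ z + p.b_o)
    c = f * c_prev + i * np.tanh(p.W_c @ z + p.b_c)
    h = o * np.tanh(c)
    return h, c


def oracle_forward(window, p):
    H = p.hidden
    h = np.zeros(H)
    c = np.zeros(H)
    states = []
    for t in range(window.shape[0]):
        h, c = oracle_lstm_step(window[t], h, c, p)
        states.append(h)
    states = np.array(states)
    if p.use_attention:
        e = np.array([p.v @ np.tanh(p.W_a @ ht + p.b_a) for ht in states])
        alpha = np.exp(e) / np.exp(e).sum()
        a = sum(al * ht for al, ht in zip(alpha, states))
    else:
        a = states[-1]
    y = p.W_y @ a + p.b_y
    return y.reshape(p.horizon, p.n_features)


def small_params(S=3, H=4, horizon=2, seed=0, scale=0.3, use_attention=True):
    return init_params(S, H, horizon, seed=seed, scale=scale,
                       use_attention=use_attention)


# --------------------------------------------------------------- lstm_step


class TestLstmStep:
    def test_zero_weights_half_gates(self):
        p = ModelParams(n_features=3, hidden=4, horizon=2)  # all zeros
        c = np.array([0.5, -1.0, 2.0, 0.0])
        h, C = lstm_step(np.ones(3), np.zeros(4), c, p)
        np.testing.assert_allclose(C, 0.5 * c)
        np.testing.assert_allclose(h, 0.5 * np.tanh(0.5 * c))

    def test_saturated_forget_gate_preserves_cell(self):
        p = ModelParams(n_features=3, hidden=4, horizon=2)
        p.b_f[:] = 20.0
        c = np.array([1.0, -2.0, 0.3, 5.0])
        _, C = lstm_step(np.zeros(3), np.zeros(4), c, p)
        np.testing.assert_allclose(C, c, rtol=1e-8)

    def test_matches_transcription_oracle(self, rng):
        p = small_params(seed=5)
        x = rng.normal(size=3)
        h0 = rng.normal(size=4) * 0.5
        c0 = rng.normal(size=4)
        h, C = lstm_step(x, h0, c0, p)
        ho, Co = oracle_lstm_step(x, h0, c0, p)
        np.testing.assert_allclose(h, ho, atol=1e-10)
        np.testing.assert_allclose(C, Co, atol=1e-10)

    def test_gate_bounds(self, rng):
        p = small_params(seed=2, scale=1.5)
        h, C = lstm_step(rng.normal(size=3), rng.normal(size=4), rng.normal(size=4), p)
        assert np.all(np.abs(h) < 1.0)

    def test_shape_mismatch(self):
        p = small_params()
        with pytest.raises(ConfigError):
            lstm_step(np.ones(7), np.zeros(4), np.zeros(4), p)


# --------------------------------------------------------------- attention


class TestAttention:
    def test_identical_states_uniform_weights(self):
        p = small_params(seed=1)
        H = np.tile(np.array([0.3, -0.2, 0.1, 0.4]), (6, 1))
        alpha = attention_weights(H, p)
        np.testing.assert_allclose(alpha, np.full(6, 1 / 6), atol=1e-12)

    def test_probability_vector(self, rng):
        p = small_params(seed=3, scale=1.0)
        alpha = attention_weights(rng.normal(size=(10, 4)), p)
        assert np.all(alpha > 0)
        assert alpha.sum() == pytest.approx(1.0, abs=1e-12)

    def test_dominant_score_saturates(self):
        # craft params so one step's score exceeds the others by ~75
        p = small_params(seed=4)
        p.v[:] = np.array([100.0, 0.0, 0.0, 0.0])
        p.W_a[:] = np.eye(4)
        p.b_a[:] = 0.0
        H = np.zeros((5, 4))
        H[2, 0] = 1.0  # e_2 = 100*tanh(1) ~ 76, others 0
        alpha = attention_weights(H, p)
        assert alpha[2] > 0.99

    def test_matches_oracle(self, rng):
        p = small_params(seed=6)
        H = rng.normal(size=(8, 4))
        e = np.array([p.v @ np.tanh(p.W_a @ h + p.b_a) for h in H])
        expected = np.exp(e) / np.exp(e).sum()
        np.testing.assert_allclose(attention_weights(H, p), expected, atol=1e-12)

    def test_context_one_hot(self, rng):
        H = rng.normal(size=(5, 4))
        alpha = np.zeros(5)
        alpha[3] = 1.0
        np.testing.assert_allclose(attention_context(H, alpha), H[3])

    def test_context_uniform_is_row_mean(self, rng):
        H = rng.normal(size=(5, 4))
        np.testing.assert_allclose(
            attention_context(H, np.full(5, 0.2)), H.mean(axis=0), atol=1e-12
        )

    def test_context_weighted_sum_oracle(self, rng):
        H = rng.normal(size=(7, 4))
        raw = rng.uniform(size=7)
        alpha = raw / raw.sum()
        expected = sum(a * h for a, h in zip(alpha, H))
        np.testing.assert_allclose(attention_context(H, alpha), expected, atol=1e-12)

    def test_context_in_convex_hull_bounds(self, rng):
        H = rng.normal(size=(6, 4))
        raw = rng.uniform(size=6)
        alpha = raw / raw.sum()
        a = attention_context(H, alpha)
        assert np.all(a <= H.max(axis=0) + 1e-12)
        assert np.all(a >= H.min(axis=0) - 1e-12)


# ------------------------------------------------------------- output head


class TestOutputHead:
    def test_zero_weights_returns_bias(self, rng):
        p = ModelParams(n_features=3, hidden=4, horizon=2)
        p.b_y[:] = rng.normal(size=6)
        out = output_head(rng.normal(size=4), p)
        np.testing.assert_array_equal(out, p.b_y.reshape(2, 3))

    def test_paper_output_node_count(self):
        p = ModelParams(n_features=24, hidden=8, horizon=5)
        out = output_head(np.zeros(8), p)
        assert out.shape == (5, 24)
        assert out.size == 120

    def test_linearity(self, rng):
        p = small_params(seed=7)
        a1, a2 = rng.normal(size=4), rng.normal(size=4)
        zero = output_head(np.zeros(4), p)
        lhs = output_head(a1 + a2, p) - zero
        rhs = (output_head(a1, p) - zero) + (output_head(a2, p) - zero)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)
        np.testing.assert_allclose(
            output_head(3.0 * a1, p) - zero, 3.0 * (output_head(a1, p) - zero),
            atol=1e-12,
        )


# ----------------------------------------------------------------- forward


class TestForward:
    def test_zero_params_gives_bias(self, rng):
        p = ModelParams(n_features=3, hidden=4, horizon=2)
        p.b_y[:] = rng.normal(size=6)
        out = forward(rng.normal(size=(6, 3)), p)
        np.testing.assert_allclose(out, p.b_y.reshape(2, 3), atol=1e-12)

    def test_inference_deterministic(self, rng):
        p = small_params(seed=8)
        window = rng.normal(size=(6, 3))
        np.testing.assert_array_equal(forward(window, p), forward(window, p))

    @pytest.mark.parametrize("use_attention", [True, False])
    def test_matches_monolithic_oracle(self, rng, use_attention):
        p = small_params(seed=9, use_attention=use_attention)
        window = rng.normal(size=(10, 3))
        np.testing.assert_allclose(
            forward(window, p), oracle_forward(window, p), atol=1e-8
        )

    def test_batched_matches_single(self, rng):
        p = small_params(seed=10)
        X = rng.normal(size=(4, 6, 3))
        batched = forward(X, p)
        for k in range(4):
            np.testing.assert_allclose(batched[k], forward(X[k], p), atol=1e-12)


# ------------------------------------------------------------------ train


def _toy_dataset(rng, n=12, w=6, h=2, S=3, target=None):
    X = rng.normal(size=(n, w, S))
    if target is None:
        Y = rng.normal(size=(n, h, S))
    else:
        Y = np.broadcast_to(target, (n, h, S)).copy()
    return WindowedDataset(
        inputs=X, targets=Y, anchor_years=tuple(range(2000, 2000 + n)), w=w, h=h
    )


class TestTrain:
    def test_constant_target_learned_by_bias(self, rng):
        c = np.array([0.7, -0.3, 1.2])
        ds = _toy_dataset(rng, target=c)
        hp = HyperParams(hidden_units=16, dropout_rate=0.0,
                         learning_rate=1e-2, batch_size=16)
        model = train(ds, None, hp, seed=0, max_epochs=100, l2=0.0)
        assert model.history["train_loss"][-1] < 1e-2
        pred = forward(ds.inputs[0], model.params)
        np.testing.assert_allclose(pred, np.broadcast_to(c, (2, 3)), atol=1e-1)

    def test_patience_rule(self, rng):
        # validation targets are pure noise at a different scale; training
        # fit improves but validation stalls quickly
        tr = _toy_dataset(rng, target=np.zeros(3))
        va = _toy_dataset(rng, n=6)
        patience = 5
        hp = HyperParams(hidden_units=16, dropout_rate=0.0,
                         learning_rate=1e-2, batch_size=16)
        model = train(tr, va, hp, seed=1, max_epochs=100, patience=patience)
        assert model.stop_epoch <= model.best_epoch + patience
        assert len(model.history["val_mse"]) == model.stop_epoch

    def test_improves_over_initialization(self, small_panel):
        z, _ = normalize(small_panel)
        ds = make_windows(z, 10, 5)
        tr = ds.subset(np.arange(len(ds) - 3))
        va = ds.subset(np.arange(len(ds) - 3, len(ds)))
        hp = HyperParams(hidden_units=32, dropout_rate=0.0,
                         learning_rate=1e-2, batch_size=16)
        model = train(tr, va, hp, seed=0, max_epochs=100)
        from swarmcast.network import _val_mse

        untrained = init_params(ds.n_strata, 32, 5, seed=0)
        assert _val_mse(model.params, va) < _val_mse(untrained, va) / 10.0

    def test_empty_training_set_rejected(self, rng):
        ds = _toy_dataset(rng).subset(np.array([], dtype=int))
        with pytest.raises(ValueError):
            train(ds, None, HyperParams(), seed=0)

    def test_seeded_reproducibility(self, rng):
        tr = _toy_dataset(rng)
        va = _toy_dataset(rng, n=4)
        hp = HyperParams(dropout_rate=0.3)
        m1 = train(tr, va, hp, seed=3, max_epochs=10)
        m2 = train(tr, va, hp, seed=3, max_epochs=10)
        assert m1.history == m2.history
        np.testing.assert_array_equal(m1.params.W_y, m2.params.W_y)

    def test_history_bounded_by_max_epochs(self, rng):
        tr = _toy_dataset(rng)
        model = train(tr, None, HyperParams(), seed=0, max_epochs=7)
        assert len(model.history["train_loss"]) == 7


class TestHyperParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"hidden_units": 8},
            {"hidden_units": 100},
            {"dropout_rate": 0.5},
            {"learning_rate": 1e-5},
            {"batch_size": 128},
        ],
    )
    def test_bounds_enforced(self, kwargs):
        with pytest.raises(ConfigError):
            HyperParams(**kwargs)

    def test_defaults_valid(self):
        hp = HyperParams()
        assert hp.hidden_units == 40


# ----------------------------------------------------------- forecast_next


class TestForecastNext:
    def test_zero_weight_model_forecasts_mean(self, small_panel):
        z, norm = normalize(small_panel)
        ds = make_windows(z, 10, 5)
        p = ModelParams(n_features=small_panel.n_strata, hidden=16, horizon=5)
        from swarmcast.network import TrainedModel

        model = TrainedModel(params=p, hyperparams=HyperParams(hidden_units=16),
                             normalization=norm, window_length=10)
        fc = forecast_next(small_panel, model, 5)
        np.testing.assert_allclose(
            fc.values, np.broadcast_to(norm.mean, fc.shape), rtol=1e-9
        )

    def test_forecast_years_follow_panel(self, small_panel):
        z, norm = normalize(small_panel)
        ds = make_windows(z, 10, 5)
        hp = HyperParams(hidden_units=16, dropout_rate=0.0,
                         learning_rate=1e-2, batch_size=16)
        model = train(ds.subset(np.arange(15)), ds.subset(np.arange(15, 18)),
                      hp, seed=0, max_epochs=20, normalization=norm)
        fc = forecast_next(small_panel, model, 5)
        assert fc.years == tuple(range(2022, 2027))
        assert fc.n_strata == small_panel.n_strata

    def test_stratum_mismatch(self, small_panel, default_panel):
        z, norm = normalize(small_panel)
        ds = make_windows(z, 10, 5)
        model = train(ds, None, HyperParams(hidden_units=16), seed=0,
                      max_epochs=2, normalization=norm)
        with pytest.raises(StratumMismatchError):
            forecast_next(default_panel, model, 5)


# ----------------------------------------------------------- save / load


class TestSaveLoad:
    def test_round_trip(self, rng, tmp_path):
        tr = _toy_dataset(rng)
        va = _toy_dataset(rng, n=4)
        model = train(tr, va, HyperParams(), seed=2, max_epochs=5)
        save_model(model, tmp_path / "bundle")
        back = load_model(tmp_path / "bundle")
        for name in ("W_f", "W_a", "v", "W_y", "b_y"):
            np.testing.assert_array_equal(
                getattr(back.params, name), getattr(model.params, name)
            )
        assert back.hyperparams == model.hyperparams
        assert back.window_length == model.window_length
        x = rng.normal(size=(6, 3))
        np.testing.assert_array_equal(forward(x, back.params), forward(x, model.params))
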