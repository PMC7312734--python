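"""Y-type model: cell equations, sharing, gradients, training, inference."""

import math

import numpy as np
import pytest

import ppiwave as pw
from ppiwave.exceptions import ConfigError, InvalidInputError
from ppiwave.model import (
    LSTMCellParams,
    ModelConfig,
    YTypeModel,
    _Direction,
    build_model,
    flatten_from_rnn,
    lstm_step,
    predict,
    relu,
    reshape_for_rnn,
    softmax,
)


def _cell(rng, input_size, hidden):
    return LSTMCellParams.init(rng, input_size, hidden)


class TestReLU:
    @pytest.mark.parametrize("x,y", [(-3.0, 0.0), (0.0, 0.0), (2.5, 2.5)])
    def test_scalar(self, x, y):
        assert relu(x) == y

    def test_elementwise(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_array_equal(relu(x), np.where(x > 0, x, 0))


class TestLSTMStep:
    def test_zero_weights_halve_everything(self, rng):
        p = _cell(rng, 4, 3)
        for f in LSTMCellParams.FIELDS:
            getattr(p, f)[...] = 0.0
        x = rng.normal(size=4)
        c_prev = rng.normal(size=3)
        h, c = lstm_step(x, rng.normal(size=3), c_prev, p)
        np.testing.assert_allclose(c, 0.5 * c_prev, atol=1e-12)
        np.testing.assert_allclose(h, 0.5 * np.tanh(0.5 * c_prev), atol=1e-12)

    def test_zero_weights_zero_state_gives_zero_output(self, rng):
        p = _cell(rng, 4, 3)
        for f in LSTMCellParams.FIELDS:
            getattr(p, f)[...] = 0.0
        h, c = lstm_step(np.ones(4), np.zeros(3), np.zeros(3), p)
        np.testing.assert_allclose(h, 0, atol=1e-12)

    def test_matches_scalar_hand_evaluation(self, rng):
        """Elementwise oracle: evaluate the gate equations with math.*"""
        H, D = 3, 2
        p = _cell(rng, D, H)
        x = rng.normal(size=D)
        h_prev = rng.normal(size=H)
        c_prev = rng.normal(size=H)
        z = list(h_prev) + list(x)
        sig = lambda v: 1.0 / (1.0 + math.exp(-v))
        h_exp, c_exp = [], []
        for k in range(H):
            a_f = sum(p.W_f[k][j] * z[j] for j in range(H + D)) + p.b_f[k]
            a_i = sum(p.W_i[k][j] * z[j] for j in range(H + D)) + p.b_i[k]
            a_c = sum(p.W_C[k][j] * z[j] for j in range(H + D)) + p.b_C[k]
            a_o = sum(p.W_o[k][j] * z[j] for j in range(H + D)) + p.b_o[k]
            c_k = sig(a_f) * c_prev[k] + sig(a_i) * math.tanh(a_c)
            c_exp.append(c_k)
            h_exp.append(sig(a_o) * math.tanh(c_k))
        h, c = lstm_step(x, h_prev, c_prev, p)
        np.testing.assert_allclose(h, h_exp, rtol=1e-12)
        np.testing.assert_allclose(c, c_exp, rtol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        p = _cell(rng, 4, 3)
        with pytest.raises(InvalidInputError):
            lstm_step(np.ones(5), np.zeros(3), np.zeros(3), p)

    def test_direction_scan_consistent_with_cell(self, rng):
        """The fast stacked-weight scan equals repeated lstm_step calls."""
        p = _cell(rng, 4, 3)
        X = rng.normal(size=(2, 6, 4))
        out, _ = _Direction(p, reverse=False).forward(X)
        h = np.zeros((2, 3))
        c = np.zeros((2, 3))
        for t in range(6):
            h, c = lstm_step(X[:, t, :], h, c, p)
            np.testing.assert_allclose(out[:, t, :], h, rtol=1e-12)


class TestGradients:
    def test_lstm_cell_gradients_match_finite_differences(self, rng):
        """BPTT gradients of a 3-unit cell vs central differences."""
        H, D, B, T = 3, 2, 2, 4
        p = _cell(rng, D, H)
        X = rng.normal(size=(B, T, D))
        dOut = rng.normal(size=(B, T, H))
        direction = _Direction(p, reverse=False)

        def objective():
            out, _ = direction.forward(X)
            return float(np.sum(out * dOut))

        out, cache = direction.forward(X)
        dX, grads = direction.backward(dOut, cache)
        eps = 1e-6
        for fname in LSTMCellParams.FIELDS:
            arr = getattr(p, fname)
            g = getattr(grads, fname)
            flat, gflat = arr.ravel(), g.ravel()
            for i in range(flat.size):
                orig = flat[i]
                flat[i] = orig + eps
                up = objective()
                flat[i] = orig - eps
                down = objective()
                flat[i] = orig
                num = (up - down) / (2 * eps)
                denom = max(abs(num), abs(gflat[i]), 1e-8)
                assert abs(num - gflat[i]) / denom < 1e-4, fname
        # input gradients too
        for b, t, d in [(0, 0, 0), (1, 3, 1), (0, 2, 1)]:
            orig = X[b, t, d]
            X[b, t, d] = orig + eps
            up = objective()
            X[b, t, d] = orig - eps
            down = objective()
            X[b, t, d] = orig
            num = (up - down) / (2 * eps)
            denom = max(abs(num), abs(dX[b, t, d]), 1e-8)
            assert abs(num - dX[b, t, d]) / denom < 1e-4

    def test_full_model_gradient_spot_check(self, rng, tiny_config):
        m = build_model(tiny_config)
        X = rng.normal(size=(3, 1200))
        Y = np.array([[1.0, 0], [0, 1], [1, 0]])
        _, cache = m.forward(X, return_cache=True)
        grads = m._backward(Y, cache)
        eps = 1e-6
        check_rng = np.random.default_rng(0)
        for name, arr in m.named_parameters().items():
            flat = arr.ravel()
            for i in check_rng.choice(flat.size, size=min(3, flat.size),
                                      replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                up = m.loss(X, Y)
                flat[i] = orig - eps
                down = m.loss(X, Y)
                flat[i] = orig
                num = (up - down) / (2 * eps)
                ana = grads[name].ravel()[i]
                assert abs(num - ana) / max(abs(num), abs(ana), 1e-6) < 1e-3, name


class TestReshape:
    def test_round_trip_identity(self, rng):
        v = rng.normal(size=600)
        np.testing.assert_array_equal(flatten_from_rnn(reshape_for_rnn(v)), v)

    def test_index_arithmetic(self, rng):
        v = rng.normal(size=600)
        steps = reshape_for_rnn(v)
        assert steps.shape == (75, 8)
        for t, j in [(0, 0), (74, 7), (10, 3), (33, 5)]:
            assert steps[t, j] == v[75 * j + t]

    def test_constant_block_fills_channel(self):
        v = np.zeros(600)
        v[75 * 2:75 * 3] = 4.5
        steps = reshape_for_rnn(v)
        np.testing.assert_array_equal(steps[:, 2], np.full(75, 4.5))

    def test_wrong_length_rejected(self):
        with pytest.raises(InvalidInputError):
            reshape_for_rnn(np.zeros(599))


class TestArchitectureAudit:
    def test_default_counts(self):
        cfg = ModelConfig()
        m = build_model(cfg)
        assert m.input_units == 1200
        assert cfg.recurrent_unit_total == 512 * 2 * 2 == 2048
        assert cfg.buffer_units == 256
        assert cfg.dense_units == (32, 8, 2)
        assert cfg.batch_size == 128
        assert cfg.learning_rate == 0.05
        assert cfg.epochs == 200
        # dense widths realized in the parameter shapes
        assert m.params.dense[0][0].shape == (256, 32)
        assert m.params.dense[1][0].shape == (32, 8)
        assert m.params.dense[2][0].shape == (8, 2)

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            ModelConfig(dense_units=(32, 8))          # must end in 2
        with pytest.raises(ConfigError):
            ModelConfig(steps_per_protein=60)         # 60*8 != 600
        with pytest.raises(ConfigError):
            ModelConfig(rnn_units=0)


class TestWeightSharing:
    def test_branches_are_same_storage(self, tiny_config):
        m = build_model(tiny_config)
        assert m.params.shared_branch is m.params.branch_b
        m.params.shared_branch[0].fwd.params.W_f[0, 0] = 123.0
        assert m.params.branch_b[0].fwd.params.W_f[0, 0] == 123.0

    def test_identical_inputs_give_identical_branch_outputs(self, rng,
                                                            tiny_config):
        m = build_model(tiny_config)
        half = rng.normal(size=(4, 600))
        X = np.concatenate([half, half], axis=1)
        _, cache = m.forward(X, return_cache=True)
        np.testing.assert_array_equal(cache["term_a"], cache["term_b"])

    def test_sharing_survives_training(self, rng, tiny_config):
        m = build_model(tiny_config)
        X = rng.normal(size=(20, 1200))
        Y = np.tile([[1.0, 0], [0, 1]], (10, 1))
        m.train((X, Y), epochs=2)
        assert m.params.shared_branch is m.params.branch_b
        half = rng.normal(size=(2, 600))
        _, cache = m.forward(np.concatenate([half, half], axis=1),
                             return_cache=True)
        np.testing.assert_array_equal(cache["term_a"], cache["term_b"])

    def test_shared_parameter_count_below_unshared_control(self, tiny_config):
        shared = build_model(tiny_config)
        control = build_model(ModelConfig(**{**tiny_config.__dict__,
                                             "shared": False}))
        assert shared.n_parameters() < control.n_parameters()
        # the recurrent + projection storage is exactly halved
        diff = control.n_parameters() - shared.n_parameters()
        branch_params = sum(
            getattr(cell, f).size
            for layer in shared.params.shared_branch
            for _, cell in layer.cells()
            for f in LSTMCellParams.FIELDS
        ) + shared.params.proj_W_a.size + shared.params.proj_b_a.size
        assert diff == branch_params


class TestTraining:
    def test_zero_epochs_leaves_params_unchanged(self, rng, tiny_config):
        m = build_model(tiny_config)
        before = {k: v.copy() for k, v in m.named_parameters().items()}
        X = rng.normal(size=(8, 1200))
        Y = np.tile([[1.0, 0]], (8, 1))
        m.train((X, Y), epochs=0)
        for k, v in m.named_parameters().items():
            np.testing.assert_array_equal(v, before[k])

    def test_zero_learning_rate_leaves_params_unchanged(self, rng, tiny_config):
        m = build_model(tiny_config)
        before = {k: v.copy() for k, v in m.named_parameters().items()}
        X = rng.normal(size=(8, 1200))
        Y = np.tile([[1.0, 0], [0, 1]], (4, 1))
        history = m.train((X, Y), epochs=1, learning_rate=0.0)
        assert len(history) == 1
        for k, v in m.named_parameters().items():
            np.testing.assert_array_equal(v, before[k])

    def test_empty_data_rejected(self, tiny_config):
        m = build_model(tiny_config)
        with pytest.raises(InvalidInputError):
            m.train((np.zeros((0, 1200)), np.zeros((0, 2))))

    def test_learns_linearly_separable_data(self, rng, learnability_config):
        """Mean-shift planted classes (linearly separable with margin,
        symmetric across the two halves): training accuracy >= 0.95
        within the epoch budget."""
        n = 500
        m600 = rng.normal(size=600)
        labels = rng.integers(0, 2, size=n)
        sign = np.where(labels == 1, 1.0, -1.0)[:, None]
        Xa = 0.5 * sign * m600 + rng.normal(size=(n, 600))
        Xb = 0.5 * sign * m600 + rng.normal(size=(n, 600))
        X = np.concatenate([Xa, Xb], axis=1)
        w = np.concatenate([m600, m600])
        assert ((X @ w > 0).astype(int) == labels).all()  # separability
        Y = np.column_stack([labels, 1 - labels]).astype(float)
        m = build_model(learnability_config, seed=0)
        m.train((X, Y), epochs=30)
        acc = (m.predict_classes(X) == labels).mean()
        assert acc >= 0.95


class TestInference:
    def test_softmax_rows_sum_to_one(self, rng, tiny_config):
        m = build_model(tiny_config)
        probs = m.forward(rng.normal(size=(5, 1200)))
        np.testing.assert_allclose(probs.sum(axis=1), 1, atol=1e-9)

    def test_zeroed_output_layer_scores_half(self, rng, tiny_config):
        m = build_model(tiny_config)
        W, b = m.params.dense[-1]
        W[...] = 0
        b[...] = 0
        scores = m.predict_proba(rng.normal(size=(4, 1200)))
        np.testing.assert_allclose(scores, 0.5, atol=1e-12)
        # exact tie resolves to non-interacting
        np.testing.assert_array_equal(
            m.predict_classes(rng.normal(size=(4, 1200))), 0)

    def test_symmetric_inference_is_order_invariant(self, rng, tiny_config):
        m = build_model(tiny_config)
        X = rng.normal(size=(6, 1200))
        Xs = np.concatenate([X[:, 600:], X[:, :600]], axis=1)
        np.testing.assert_allclose(m.predict_proba(X), m.predict_proba(Xs),
                                   atol=1e-12)

    def test_scores_bit_stable(self, rng, tiny_config):
        m = build_model(tiny_config)
        X = rng.normal(size=(3, 1200))
        np.testing.assert_array_equal(m.predict_proba(X), m.predict_proba(X))

    def test_predict_single_pair(self, rng, tiny_config):
        from ppiwave.pairs import PairFeature
        m = build_model(tiny_config)
        p = PairFeature(values=rng.normal(size=1200), label=(1, 0))
        score, label = predict(m, p)
        assert 0 <= score <= 1
        assert label in ("interacting", "non-interacting")

    def test_wrong_width_rejected(self, tiny_config):
        m = build_model(tiny_config)
        with pytest.raises(InvalidInputError):
            m.forward(np.zeros((2, 600)))


class TestPersistence:
    def test_checkpoint_round_trip(self, rng, tiny_config, tmp_path):
        m = build_model(tiny_config)
        X = rng.normal(size=(16, 1200))
        Y = np.tile([[1.0, 0], [0, 1]], (8, 1))
        m.train((X, Y), epochs=1)
        path = tmp_path / "model.ckpt.npz"
        m.save(path)
        loaded = YTypeModel.load(path)
        np.testing.assert_array_equal(loaded.predict_proba(X),
                                      m.predict_proba(X))
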