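"""LSTM core: initialization, cell equations, forward pass, training."""

import math

import numpy as np
import pytest

from iwsrisk import model as mdl
from reference_lstm import reference_logit


class TestInit:
    def test_same_seed_is_bit_identical(self):
        a = mdl.init_params(10, 8, 2, seed=5)
        b = mdl.init_params(10, 8, 2, seed=5)
        for (na, wa), (nb, wb) in zip(a.trainable(), b.trainable()):
            assert na == nb and np.array_equal(wa, wb)

    @pytest.mark.parametrize("hidden", [1, 64])
    def test_weights_within_uniform_bound(self, hidden):
        p = mdl.init_params(6, hidden, 2, seed=0)
        bound = 1.0 / math.sqrt(hidden)
        for li, lp in enumerate(p.layers):
            for g in mdl.GATES:
                assert np.abs(lp.W_ih[g]).max() <= bound
                assert np.abs(lp.W_hh[g]).max() <= bound
                assert np.abs(lp.b[g]).max() <= bound
        assert np.abs(p.w_out).max() <= bound

    def test_nonpositive_dims_rejected(self):
        with pytest.raises(ValueError):
            mdl.init_params(0, 4, 1, seed=0)


class TestCellStep:
    def _zero_layer(self, d, h):
        return mdl.LayerParams(
            W_ih={g: np.zeros((d, h)) for g in mdl.GATES},
            W_hh={g: np.zeros((h, h)) for g in mdl.GATES},
            b={g: np.zeros(h) for g in mdl.GATES},
        )

    def test_all_zero_parameters(self):
        layer = self._zero_layer(3, 2)
        h, c, tr = mdl.lstm_cell_step(np.ones(3), np.zeros(2), np.zeros(2), layer)
        assert np.allclose(tr["i"], 0.5) and np.allclose(tr["f"], 0.5)
        assert np.allclose(tr["o"], 0.5) and np.allclose(tr["g"], 0.0)
        assert np.allclose(c, 0.0) and np.allclose(h, 0.0)

    def test_memory_preservation_limit(self):
        # forget gate pinned open, input gate pinned shut -> cell unchanged
        layer = self._zero_layer(2, 2)
        layer.b["f"][:] = 20.0
        layer.b["i"][:] = -20.0
        c_prev = np.array([0.7, -1.3])
        _, c, _ = mdl.lstm_cell_step(np.ones(2), np.zeros(2), c_prev, layer)
        assert np.allclose(c, c_prev, atol=1e-8)

    def test_scalar_cell_hand_evaluated(self):
        # H = D = 1, every weight and bias 0.5, x = 1, zero states:
        # all four pre-activations are 0.5*1 + 0.5*0 + 0.5 = 1
        layer = mdl.LayerParams(
            W_ih={g: np.full((1, 1), 0.5) for g in mdl.GATES},
            W_hh={g: np.full((1, 1), 0.5) for g in mdl.GATES},
            b={g: np.full(1, 0.5) for g in mdl.GATES},
        )
        h, c, tr = mdl.lstm_cell_step(np.ones(1), np.zeros(1), np.zeros(1), layer)
        sig1 = 1 / (1 + math.exp(-1))
        c_exp = sig1 * math.tanh(1)
        h_exp = sig1 * math.tanh(c_exp)
        assert c[0] == pytest.approx(c_exp, abs=1e-12)
        assert h[0] == pytest.approx(h_exp, abs=1e-12)

    def test_nonfinite_input_rejected(self):
        layer = self._zero_layer(2, 2)
        with pytest.raises(ValueError):
            mdl.lstm_cell_step(np.array([np.nan, 0.0]), np.zeros(2), np.zeros(2), layer)


class TestForward:
    def test_eval_mode_deterministic(self, rng):
        p = mdl.init_params(5, 4, 2, seed=1)
        w = rng.random((6, 5))
        a = mdl.forward(w, p)
        b = mdl.forward(w, p)
        assert a.logit == b.logit and 0.0 < a.prob < 1.0

    def test_prob_is_sigmoid_of_logit(self, rng):
        p = mdl.init_params(5, 4, 1, seed=2)
        pred = mdl.forward(rng.random((6, 5)), p)
        assert pred.prob == pytest.approx(1 / (1 + math.exp(-pred.logit)), abs=1e-12)

    def test_trace_satisfies_output_identity_and_gate_ranges(self, rng):
        """h_t = o_t * tanh(c_t) holds on every trace entry; gates in range."""
        p = mdl.init_params(7, 6, 2, seed=3)
        tr = mdl.forward(rng.random((6, 7)), p).trace
        for l in range(2):
            assert np.all((tr.i[l] > 0) & (tr.i[l] < 1))
            assert np.all((tr.f[l] > 0) & (tr.f[l] < 1))
            assert np.all((tr.o[l] > 0) & (tr.o[l] < 1))
            assert np.all((tr.g[l] > -1) & (tr.g[l] < 1))
            assert np.allclose(tr.h[l][1:], tr.o[l] * np.tanh(tr.c[l][1:]), atol=1e-10)

    def test_matches_independent_reference(self, rng):
        for seed in range(5):
            p = mdl.init_params(9, 8, 2, seed=seed)
            p.running_mean = rng.normal(size=8) * 0.1
            p.running_var = rng.uniform(0.5, 1.5, 8)
            w = rng.random((6, 9))
            assert mdl.forward(w, p).logit == pytest.approx(
                reference_logit(p, w), abs=1e-10
            )

    def test_wrong_shape_rejected(self):
        p = mdl.init_params(5, 4, 1, seed=0)
        with pytest.raises(ValueError):
            mdl.forward(np.zeros((6, 7)), p)

    def test_batched_matches_single(self, rng):
        p = mdl.init_params(6, 5, 2, seed=4)
        X = rng.random((8, 6, 6))
        batched = mdl.predict_proba(p, X)
        singles = np.array([mdl.forward(X[i], p).prob for i in range(8)])
        assert np.allclose(batched, singles, atol=1e-6)

    def test_train_eval_agree_with_dropout_off_and_frozen_bn(self, rng):
        p = mdl.init_params(6, 5, 2, seed=5)
        X = rng.random((16, 6, 6))
        logits_tr, cache = mdl._forward_batch(p, X, train=True, dropout_rate=0.0)
        # freeze batch norm at the realized batch statistics
        p.running_mean = cache["h_last"].mean(axis=0)
        p.running_var = cache["h_last"].var(axis=0)
        logits_ev, _ = mdl._forward_batch(p, X, train=False)
        assert np.allclose(logits_tr, logits_ev, atol=1e-6)


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self, rng):
        """Central-difference check on a tiny model (D=3, H=2, L=1)."""
        p = mdl.init_params(3, 2, 1, seed=1)
        X = rng.random((5, 4, 3))
        y = np.array([0, 1, 1, 0, 1], dtype=float)
        _, grads = mdl.loss_and_grads(p, X, y, train=True)
        eps = 1e-6
        worst = 0.0
        entries = list(p.trainable())
        for name, arr in entries:
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + eps
                lp, _ = mdl.loss_and_grads(p, X, y, train=True)
                arr[idx] = orig - eps
                lm, _ = mdl.loss_and_grads(p, X, y, train=True)
                arr[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[name][idx]
                worst = max(worst, abs(num - ana) / max(1e-8, abs(num) + abs(ana)))
        assert worst < 1e-4


class TestTraining:
    def _toy_separable(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.random((n, 6, 4)) * 0.2
        y = rng.integers(0, 2, n).astype(float)
        X[y == 1, :, 0] += 0.7  # feature 0 separates the classes
        return np.clip(X, 0, 1), y

    def test_loss_decreases_on_separable_data(self):
        X, y = self._toy_separable()
        cfg = mdl.TrainConfig(hidden_dim=8, num_layers=1, dropout_rate=0.0,
                              max_epochs=40, patience=40, seed=0)
        _, hist = mdl.train(X[:90], y[:90], X[90:], y[90:], cfg)
        assert hist.train_loss[-1] < hist.train_loss[0]

    def test_fixed_seed_reproduces_loss_trajectory(self):
        X, y = self._toy_separable()
        cfg = mdl.TrainConfig(hidden_dim=6, num_layers=1, max_epochs=8,
                              patience=8, seed=3)
        _, h1 = mdl.train(X[:90], y[:90], X[90:], y[90:], cfg)
        _, h2 = mdl.train(X[:90], y[:90], X[90:], y[90:], cfg)
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss

    def test_single_class_labels_rejected(self):
        X, _ = self._toy_separable()
        with pytest.raises(ValueError):
            mdl.train(X[:50], np.zeros(50), X[50:60], np.ones(10), mdl.TrainConfig())

    def test_empty_split_rejected(self):
        X, y = self._toy_separable()
        with pytest.raises(ValueError):
            mdl.train(X[:0], y[:0], X, y, mdl.TrainConfig())


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path, rng):
        p = mdl.init_params(6, 5, 2, seed=9)
        p.running_mean = rng.normal(size=5)
        p.running_var = rng.uniform(0.5, 2.0, 5)
        mdl.save_model(p, tmp_path / "m")
        q = mdl.load_model(tmp_path / "m")
        w = rng.random((6, 6))
        assert mdl.forward(w, p).logit == pytest.approx(mdl.forward(w, q).logit, abs=1e-15)
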