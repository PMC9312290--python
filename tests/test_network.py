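"""CNN-GRU contracts: scalar oracles, gate ranges, gradients, training."""

import numpy as np
import pytest

from ecgfusion.network import (Conv1D, Dense, FusionGC, GRU, MaxPool1D,
                               NetworkConfig, TrainConfig, bce_loss, _sigmoid)


def naive_conv(x, W, b, stride=1):
    """Scalar-loop valid cross-correlation oracle: x (L, Cin), W (k, Cin, Cout)."""
    k, cin, cout = W.shape
    L = x.shape[0]
    n = (L - k) // stride + 1
    out = np.zeros((n, cout))
    for i in range(n):
        for o in range(cout):
            acc = b[o]
            for j in range(k):
                for c in range(cin):
                    acc += x[i * stride + j, c] * W[j, c, o]
            out[i, o] = acc
    return out


def naive_gru_step(f, h, p):
    """Scalar-loop oracle for one GRU cell update."""
    H = h.size
    z = np.empty(H)
    r = np.empty(H)
    hc = np.empty(H)
    hn = np.empty(H)
    for i in range(H):
        az = p["bz"][i] + p["Wz"][i] @ f + p["Uz"][i] @ h
        ar = p["br"][i] + p["Wr"][i] @ f + p["Ur"][i] @ h
        z[i] = 1 / (1 + np.exp(-az))
        r[i] = 1 / (1 + np.exp(-ar))
    for i in range(H):
        ac = p["bc"][i] + p["Wc"][i] @ f + p["Uc"][i] @ (r * h)
        hc[i] = np.tanh(ac)
        hn[i] = z[i] * h[i] + (1 - z[i]) * hc[i]
    return hn


class TestConv:
    def test_hand_cross_correlation(self):
        conv = Conv1D(3, 1, 1, padding="valid", activation="linear")
        conv.params["W"][:, 0, 0] = [1.0, 0.0, -1.0]
        conv.params["b"][:] = 0.0
        x = np.array([1.0, 2, 3, 4, 5])[None, :, None]
        out = conv.forward(x)
        np.testing.assert_allclose(out[0, :, 0], [-2, -2, -2])

    def test_zero_input_zero_bias_gives_zero(self):
        conv = Conv1D(4, 2, 3, padding="same")
        conv.params["b"][:] = 0.0
        out = conv.forward(np.zeros((2, 9, 2)))
        np.testing.assert_array_equal(out, 0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k, cin, cout = rng.integers(1, 5), rng.integers(1, 4), rng.integers(1, 4)
        L = int(rng.integers(k, k + 8))
        conv = Conv1D(int(k), int(cin), int(cout), padding="valid",
                      rng=rng, activation="linear")
        x = rng.standard_normal((3, L, cin))
        out = conv.forward(x)
        for t in range(3):
            np.testing.assert_allclose(
                out[t], naive_conv(x[t], conv.params["W"], conv.params["b"]),
                atol=1e-6)

    def test_kernel_longer_than_input_rejected(self):
        conv = Conv1D(8, 1, 1, padding="valid")
        with pytest.raises(ValueError):
            conv.forward(np.zeros((1, 4, 1)))


class TestPool:
    def test_hand_example(self):
        pool = MaxPool1D(2, 2)
        out = pool.forward(np.array([1.0, 3, 2, 5])[None, :, None])
        np.testing.assert_allclose(out[0, :, 0], [3, 5])

    def test_constant_map_halves(self):
        pool = MaxPool1D(2, 2)
        out = pool.forward(np.full((2, 10, 3), 7.0))
        assert out.shape == (2, 5, 3)
        assert np.all(out == 7.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((2, 11, 3))
        out = MaxPool1D(2, 2).forward(x)
        for t in range(2):
            for i in range(5):
                for c in range(3):
                    assert out[t, i, c] == max(x[t, 2 * i, c], x[t, 2 * i + 1, c])


class TestGRU:
    def test_update_gate_one_holds_state(self):
        gru = GRU(3, 4, rng=np.random.default_rng(0))
        gru.params["Wz"][:] = 0.0
        gru.params["Uz"][:] = 0.0
        gru.params["bz"][:] = 50.0  # z ~ 1
        h_prev = np.array([0.3, -0.2, 0.9, 0.0])
        h, _ = gru.step(np.ones(3), h_prev)
        np.testing.assert_allclose(h, h_prev, atol=1e-12)

    def test_gates_zero_give_fresh_candidate(self):
        gru = GRU(3, 4, rng=np.random.default_rng(0))
        for g in ("z", "r"):
            gru.params[f"W{g}"][:] = 0.0
            gru.params[f"U{g}"][:] = 0.0
            gru.params[f"b{g}"][:] = -50.0  # gate ~ 0
        f = np.array([0.5, -1.0, 2.0])
        h, _ = gru.step(f, np.array([5.0, 5.0, 5.0, 5.0]))
        expected = np.tanh(gru.params["Wc"] @ f + gru.params["bc"])
        np.testing.assert_allclose(h, expected, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scalar_oracle(self, seed):
        rng = np.random.default_rng(seed)
        gru = GRU(4, 5, rng=rng)
        f = rng.standard_normal(4)
        h = rng.standard_normal(5)
        out, (_, _, z, r, _) = gru.step(f, h)
        np.testing.assert_allclose(out, naive_gru_step(f, h, gru.params),
                                   atol=1e-7)
        assert np.all((z > 0) & (z < 1))
        assert np.all((r > 0) & (r < 1))


class TestForward:
    def test_zero_input_gives_half_probabilities(self):
        net = FusionGC(n_cols=21, seed=0)
        p = net.forward(np.zeros((5, 21)))
        np.testing.assert_allclose(p, 0.5, atol=1e-12)

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        M = rng.standard_normal((6, 21))
        a = FusionGC(n_cols=21, seed=3).forward(M)
        b = FusionGC(n_cols=21, seed=3).forward(M)
        np.testing.assert_array_equal(a, b)

    def test_outputs_in_open_unit_interval(self):
        net = FusionGC(n_cols=21, seed=0)
        rng = np.random.default_rng(2)
        for _ in range(200):
            p = net.forward(rng.standard_normal((4, 21)) * 5)
            assert np.all((p > 0) & (p < 1))

    def test_wrong_column_count_rejected(self):
        net = FusionGC(n_cols=21, seed=0)
        with pytest.raises(ValueError):
            net.forward(np.zeros((5, 20)))


class TestLoss:
    def test_perfect_prediction_near_zero(self):
        Y = np.array([[1.0, 0.0, 1.0]])
        assert bce_loss(Y, Y) < 1e-9

    def test_half_probability_single_label(self):
        assert bce_loss(np.array([[1.0]]), np.array([[0.5]])) == pytest.approx(
            np.log(2), rel=1e-9)

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(4)
        Y = (rng.random((8, 6)) < 0.4).astype(float)
        P = rng.uniform(0.01, 0.99, (8, 6))
        expected = np.mean([
            sum(-Y[i, j] * np.log(P[i, j]) - (1 - Y[i, j]) * np.log(1 - P[i, j])
                for j in range(6))
            for i in range(8)])
        assert bce_loss(Y, P) == pytest.approx(expected, abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bce_loss(np.zeros((2, 3)), np.full((3, 2), 0.5))


class TestGradients:
    def test_micro_network_matches_finite_differences(self):
        cfg = NetworkConfig(conv_blocks=[(3, 2, 1)], dense_sizes=[],
                            gru_hidden=4, n_labels=2)
        net = FusionGC(n_cols=8, config=cfg, seed=1)
        rng = np.random.default_rng(2)
        M = rng.standard_normal((4, 8))
        Y = np.array([[1.0, 0.0]])
        net.loss_and_grad([M], Y)
        h = 1e-5
        for layer in net._layers():
            for name, P in layer.params.items():
                G = layer.grads[name]
                it = np.nditer(P, flags=["multi_index"])
                for _ in range(min(P.size, 15)):
                    idx = it.multi_index
                    old = P[idx]
                    P[idx] = old + h
                    lp = bce_loss(Y, net.forward(M)[None, :])
                    P[idx] = old - h
                    lm = bce_loss(Y, net.forward(M)[None, :])
                    P[idx] = old
                    fd = (lp - lm) / (2 * h)
                    denom = max(abs(fd), abs(G[idx]), 1e-6)
                    assert abs(fd - G[idx]) / denom < 1e-4, (name, idx)
                    it.iternext()


class TestTraining:
    @staticmethod
    def _separable_dataset(n=40, seed=3):
        rng = np.random.default_rng(seed)
        mats, Y = [], []
        for _ in range(n):
            lab = rng.integers(0, 2, 2)
            lab[0] = max(lab[0], 1 - lab[1])  # no empty label sets
            M = rng.standard_normal((5, 21)) * 0.1
            M[:, :5] += 2.0 * lab[0]
            M[:, 5:10] += 2.0 * lab[1]
            mats.append(M)
            Y.append(lab)
        return mats, np.array(Y, dtype=float)

    def test_learns_separable_data(self):
        mats, Y = self._separable_dataset()
        net = FusionGC(n_cols=21, config=NetworkConfig(n_labels=2), seed=0)
        net.train(mats, Y, TrainConfig(epochs=150, batch_size=10,
                                       learning_rate=0.2, seed=0))
        acc = np.mean(net.predict(mats) == Y)
        assert acc >= 0.95

    def test_zero_learning_rate_freezes_weights(self):
        mats, Y = self._separable_dataset(n=8)
        net = FusionGC(n_cols=21, config=NetworkConfig(n_labels=2), seed=0)
        before = [p.copy() for lay in net._layers() for p in lay.params.values()]
        hist = net.train(mats, Y, TrainConfig(epochs=3, learning_rate=0.0,
                                              batch_size=4, seed=0))
        after = [p for lay in net._layers() for p in lay.params.values()]
        for b, a in zip(before, after):
            np.testing.assert_array_equal(b, a)
        assert np.ptp(hist["loss"]) < 1e-12

    def test_same_seed_identical_traces(self):
        mats, Y = self._separable_dataset(n=12)
        traces = []
        for _ in range(2):
            net = FusionGC(n_cols=21, config=NetworkConfig(n_labels=2), seed=5)
            h = net.train(mats, Y, TrainConfig(epochs=5, batch_size=4,
                                               learning_rate=0.1, seed=5))
            traces.append(h["loss"])
        np.testing.assert_array_equal(traces[0], traces[1])


class TestPredict:
    def test_threshold_rule(self):
        net = FusionGC(n_cols=21, config=NetworkConfig(n_labels=3), seed=0)
        net.predict_proba = lambda mats: np.array([[0.9, 0.1, 0.5]])
        np.testing.assert_array_equal(net.predict([None]), [[1, 0, 1]])
        np.testing.assert_array_equal(net.predict([None], threshold=1.0 + 1e-9),
                                      [[0, 0, 0]])

    def test_threshold_monotonicity(self):
        net = FusionGC(n_cols=21, seed=0)
        rng = np.random.default_rng(7)
        mats = [rng.standard_normal((4, 21)) for _ in range(5)]
        prev = None
        for thr in (0.9, 0.7, 0.5, 0.3, 0.1):
            pred = net.predict(mats, threshold=thr)
            if prev is not None:
                assert np.all(pred >= prev)  # lowering never removes positives
            prev = pred


def test_sigmoid_stable_at_extremes():
    x = np.array([-800.0, 0.0, 800.0])
    s = _sigmoid(x)
    assert np.all(np.isfinite(s))
    np.testing.assert_allclose(s, [0.0, 0.5, 1.0], atol=1e-12)
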