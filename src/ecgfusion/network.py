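"""The CNN-GRU fusion classifier for multi-label ECG windows.

Input is one sliding-window feature matrix per record (timestamps x
attributes).  Each timestamp's attribute row is passed through a stack of
1-D convolution + ReLU + max-pooling blocks (spatial feature fusion);
the per-timestamp feature vectors are then consumed by a gated recurrent
unit (temporal fusion) whose final hidden state feeds a small dense head
ending in m independent sigmoid outputs, one per label.  Training
minimizes the per-label binary cross-entropy (summed over labels, meaned
over instances) by minibatch stochastic gradient descent.

Default topology: three convolution blocks with kernel sizes 20/10/5 and
3/6/6 filters (stride 1, 'same' padding, 2x2 max-pooling after each),
GRU hidden width 20, dense sizes 20 -> 10 -> m.  Everything is plain
NumPy with hand-derived backward passes, so forward outputs and analytic
gradients can be verified against scalar oracles and finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EPS = 1e-12  # probability clamp in the cross-entropy


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class NetworkConfig:
    conv_blocks: list = field(default_factory=lambda: [(20, 3, 1), (10, 6, 1), (5, 6, 1)])
    padding: str = "same"  # 'same' or 'valid'
    pool_size: int = 2
    pool_stride: int = 2
    gru_hidden: int = 20
    dense_sizes: list = field(default_factory=lambda: [20, 10])
    n_labels: int = 6

    def __post_init__(self):
        if any(k < 1 for k, _, _ in self.conv_blocks):
            raise ValueError("kernel sizes must be >= 1")
        if self.gru_hidden < 1:
            raise ValueError("gru_hidden must be >= 1")
        if self.padding not in ("same", "valid"):
            raise ValueError("padding must be 'same' or 'valid'")


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 150
    epochs: int = 100
    seed: int = 0
    patience: int = 10  # early stopping on validation loss; None disables
    lr_schedule: str = "constant"  # 'constant' or 'cosine' (anneal to ~0)

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError("lr_schedule must be 'constant' or 'cosine'")

    def lr_at(self, epoch: int) -> float:
        if self.lr_schedule == "cosine":
            frac = epoch / max(self.epochs - 1, 1)
            return self.learning_rate * 0.5 * (1.0 + np.cos(np.pi * frac))
        return self.learning_rate


class Conv1D:
    """Valid/same cross-correlation over the attribute axis, per timestamp.

    Input (T, L, Cin) -> output (T, L_out, Cout), followed by ReLU.
    """

    def __init__(self, kernel, c_in, c_out, stride=1, padding="same",
                 rng=None, activation="relu"):
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.activation = activation
        lim = np.sqrt(1.0 / (kernel * c_in))
        rng = rng or np.random.default_rng()
        self.params = {
            "W": rng.uniform(-lim, lim, size=(kernel, c_in, c_out)),
            "b": np.zeros(c_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def _pad_amount(self, L):
        if self.padding == "valid":
            return 0, 0
        L_out = -(-L // self.stride)  # ceil
        total = max(0, (L_out - 1) * self.stride + self.kernel - L)
        return total // 2, total - total // 2

    def out_length(self, L):
        pl, pr = self._pad_amount(L)
        return (L + pl + pr - self.kernel) // self.stride + 1

    def forward(self, x):
        T, L, Cin = x.shape
        pl, pr = self._pad_amount(L)
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        if xp.shape[1] < self.kernel:
            raise ValueError("kernel longer than padded input")
        # win axes: (T, position, Cin, k)
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=1)
        win = win[:, ::self.stride]
        a = np.einsum("tpik,kio->tpo", win, self.params["W"], optimize=True)
        a = a + self.params["b"][None, None, :]
        self._cache = (xp, win, pl, L, a)
        if self.activation == "relu":
            out = np.maximum(a, 0.0)
        else:
            out = a
        self._out = out
        return out

    def backward(self, dout):
        xp, win, pl, L, a = self._cache
        if self.activation == "relu":
            dout = dout * (a > 0)
        # dW[k, ci, co] = sum_{t,pos} win[t, pos, ci, k] * dout[t, pos, co]
        self.grads["W"] += np.einsum("tpik,tpo->kio", win, dout, optimize=True)
        self.grads["b"] += dout.sum(axis=(0, 1))
        dxp = np.zeros_like(xp)
        W = self.params["W"]  # (k, Cin, Cout)
        for j in range(self.kernel):
            # positions i map to padded index i*stride + j
            contrib = np.einsum("tpo,io->tpi", dout, W[j], optimize=True)
            idx = np.arange(dout.shape[1]) * self.stride + j
            np.add.at(dxp, (slice(None), idx, slice(None)), contrib)
        return dxp[:, pl:pl + L, :]


class MaxPool1D:
    """Windowed maximum over the attribute axis (trailing partial window
    dropped); depth unchanged."""

    def __init__(self, size=2, stride=2):
        self.size, self.stride = size, stride
        self.params, self.grads = {}, {}

    def out_length(self, L):
        if L < self.size:
            return 0
        return (L - self.size) // self.stride + 1

    def forward(self, x):
        T, L, C = x.shape
        n = self.out_length(L)
        if n == 0:
            raise ValueError("input shorter than pool window")
        starts = np.arange(n) * self.stride
        win = np.stack([x[:, s:s + self.size, :] for s in starts], axis=1)
        arg = np.argmax(win, axis=2)  # (T, n, C)
        out = np.take_along_axis(win, arg[:, :, None, :], axis=2)[:, :, 0, :]
        self._cache = (x.shape, starts, arg)
        return out

    def backward(self, dout):
        shape, starts, arg = self._cache
        dx = np.zeros(shape)
        T, n, C = dout.shape
        t_idx = np.repeat(np.arange(T), n * C)
        p_idx = np.tile(np.repeat(np.arange(n), C), T)
        c_idx = np.tile(np.arange(C), T * n)
        l_idx = starts[p_idx] + arg[t_idx, p_idx, c_idx]
        np.add.at(dx, (t_idx, l_idx, c_idx), dout[t_idx, p_idx, c_idx])
        return dx


class GRU:
    """Gated recurrent unit over the timestamp axis.

    z_t = sigmoid(Wz f_t + Uz h_{t-1} + bz)
    r_t = sigmoid(Wr f_t + Ur h_{t-1} + br)
    hcand_t = tanh(Wc f_t + Uc (r_t * h_{t-1}) + bc)
    h_t = z_t * h_{t-1} + (1 - z_t) * hcand_t

    (update gate z = 1 holds the previous state.)  Returns the final
    hidden state.
    """

    def __init__(self, d_in, hidden, rng=None):
        rng = rng or np.random.default_rng()
        lim_w = np.sqrt(1.0 / d_in)
        lim_u = np.sqrt(1.0 / hidden)
        self.hidden = hidden
        self.params = {}
        for g in ("z", "r", "c"):
            self.params[f"W{g}"] = rng.uniform(-lim_w, lim_w, size=(hidden, d_in))
            self.params[f"U{g}"] = rng.uniform(-lim_u, lim_u, size=(hidden, hidden))
            self.params[f"b{g}"] = np.zeros(hidden)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def step(self, f_t, h_prev):
        """One cell update (used directly by tests and oracles)."""
        p = self.params
        z = _sigmoid(p["Wz"] @ f_t + p["Uz"] @ h_prev + p["bz"])
        r = _sigmoid(p["Wr"] @ f_t + p["Ur"] @ h_prev + p["br"])
        hc = np.tanh(p["Wc"] @ f_t + p["Uc"] @ (r * h_prev) + p["bc"])
        h = z * h_prev + (1.0 - z) * hc
        return h, (f_t, h_prev, z, r, hc)

    def forward(self, F):
        """F: (T, d_in) -> final hidden state (hidden,)."""
        h = np.zeros(self.hidden)
        self._cache = []
        for t in range(F.shape[0]):
            h, cache = self.step(F[t], h)
            self._cache.append(cache)
        return h

    def backward(self, dh):
        p, g = self.params, self.grads
        dF = np.zeros((len(self._cache), p["Wz"].shape[1]))
        for t in range(len(self._cache) - 1, -1, -1):
            f_t, h_prev, z, r, hc = self._cache[t]
            dz = dh * (h_prev - hc)
            dhc = dh * (1.0 - z)
            dh_prev = dh * z

            dac = dhc * (1.0 - hc ** 2)
            g["Wc"] += np.outer(dac, f_t)
            g["Uc"] += np.outer(dac, r * h_prev)
            g["bc"] += dac
            drh = p["Uc"].T @ dac
            dr = drh * h_prev
            dh_prev = dh_prev + drh * r
            dF[t] += p["Wc"].T @ dac

            daz = dz * z * (1.0 - z)
            g["Wz"] += np.outer(daz, f_t)
            g["Uz"] += np.outer(daz, h_prev)
            g["bz"] += daz
            dh_prev = dh_prev + p["Uz"].T @ daz
            dF[t] += p["Wz"].T @ daz

            dar = dr * r * (1.0 - r)
            g["Wr"] += np.outer(dar, f_t)
            g["Ur"] += np.outer(dar, h_prev)
            g["br"] += dar
            dh_prev = dh_prev + p["Ur"].T @ dar
            dF[t] += p["Wr"].T @ dar

            dh = dh_prev
        return dF


class Dense:
    """Fully connected layer on a vector, optional ReLU."""

    def __init__(self, d_in, d_out, rng=None, activation="relu"):
        rng = rng or np.random.default_rng()
        lim = np.sqrt(1.0 / d_in)
        self.activation = activation
        self.params = {"W": rng.uniform(-lim, lim, size=(d_out, d_in)),
                       "b": np.zeros(d_out)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x):
        a = self.params["W"] @ x + self.params["b"]
        self._cache = (x, a)
        return np.maximum(a, 0.0) if self.activation == "relu" else a

    def backward(self, dout):
        x, a = self._cache
        if self.activation == "relu":
            dout = dout * (a > 0)
        self.grads["W"] += np.outer(dout, x)
        self.grads["b"] += dout
        return self.params["W"].T @ dout


def bce_loss(Y, P):
    """Eq.-style cross-entropy: mean over instances of the per-label
    binary cross-entropy summed over labels; P clamped to [EPS, 1-EPS]."""
    Y = np.asarray(Y, dtype=float)
    P = np.clip(np.asarray(P, dtype=float), EPS, 1.0 - EPS)
    if Y.shape != P.shape:
        raise ValueError("shape mismatch")
    return float(np.mean(np.sum(-Y * np.log(P) - (1 - Y) * np.log(1 - P), axis=-1)))


class FusionGC:
    """CNN + GRU fusion classifier (see module docstring)."""

    def __init__(self, n_cols: int, config: NetworkConfig | None = None,
                 seed: int = 0):
        self.config = config or NetworkConfig()
        self.n_cols = n_cols
        rng = np.random.default_rng(seed)
        cfg = self.config

        self.conv_stack = []
        L, C = n_cols, 1
        for kernel, filters, stride in cfg.conv_blocks:
            conv = Conv1D(kernel, C, filters, stride=stride,
                          padding=cfg.padding, rng=rng)
            L = conv.out_length(L)
            pool = MaxPool1D(cfg.pool_size, cfg.pool_stride)
            Lp = pool.out_length(L)
            if L < 1 or Lp < 1:
                raise ValueError(
                    f"conv/pool stack exhausts the {n_cols}-column input; "
                    "use 'same' padding or fewer blocks")
            self.conv_stack.append((conv, pool))
            L, C = Lp, filters
        self.flat_dim = L * C

        self.gru = GRU(self.flat_dim, cfg.gru_hidden, rng=rng)
        self.dense_stack = []
        d = cfg.gru_hidden
        for size in cfg.dense_sizes:
            self.dense_stack.append(Dense(d, size, rng=rng, activation="relu"))
            d = size
        self.head = Dense(d, cfg.n_labels, rng=rng, activation="linear")

    # -- parameter plumbing -------------------------------------------------
    def _layers(self):
        for conv, pool in self.conv_stack:
            yield conv
        yield self.gru
        yield from self.dense_stack
        yield self.head

    def parameters(self):
        return [(layer, name) for layer in self._layers()
                for name in layer.params]

    def zero_grads(self):
        for layer in self._layers():
            for k in layer.grads:
                layer.grads[k][...] = 0.0

    # -- forward / backward -------------------------------------------------
    def forward(self, M: np.ndarray) -> np.ndarray:
        """One record's window matrix (T, n_cols) -> m label probabilities."""
        M = np.asarray(M, dtype=float)
        if M.ndim != 2 or M.shape[0] < 1:
            raise ValueError("expected a (timestamps, attributes) matrix")
        if M.shape[1] != self.n_cols:
            raise ValueError(f"expected {self.n_cols} columns, got {M.shape[1]}")
        x = M[:, :, None]  # (T, L, 1)
        for conv, pool in self.conv_stack:
            x = pool.forward(conv.forward(x))
        T = x.shape[0]
        F = x.reshape(T, self.flat_dim)
        self._conv_out_shape = x.shape
        h = self.gru.forward(F)
        for dense in self.dense_stack:
            h = dense.forward(h)
        logits = self.head.forward(h)
        self._probs = _sigmoid(logits)
        return self._probs

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients given dLoss/dlogits."""
        dh = self.head.backward(dlogits)
        for dense in reversed(self.dense_stack):
            dh = dense.backward(dh)
        dF = self.gru.backward(dh)
        dx = dF.reshape(self._conv_out_shape)
        for conv, pool in reversed(self.conv_stack):
            dx = conv.backward(pool.backward(dx))

    def loss_and_grad(self, matrices, Y, accumulate=False):
        """Mean summed-BCE loss over the batch; gradients accumulated."""
        if not accumulate:
            self.zero_grads()
        n = len(matrices)
        P = np.empty((n, self.config.n_labels))
        for i, M in enumerate(matrices):
            P[i] = self.forward(M)
            # d(summed BCE)/dlogits with the sigmoid folded in
            self.backward((P[i] - Y[i]) / n)
        return bce_loss(Y, P), P

    # -- training / inference -----------------------------------------------
    def train(self, matrices, Y, train_config: TrainConfig | None = None,
              val_matrices=None, val_Y=None, verbose=False):
        """Minibatch SGD on the cross-entropy.  Returns the per-epoch loss
        trace (and the validation trace when validation data is given).

        Raises ``FloatingPointError`` if the loss diverges to a non-finite
        value.  Deterministic for a fixed ``train_config.seed``.
        """
        tc = train_config or TrainConfig()
        Y = np.asarray(Y, dtype=float)
        rng = np.random.default_rng(tc.seed)
        n = len(matrices)
        trace, val_trace = [], []
        best_val, best_state, wait = np.inf, None, 0
        for epoch in range(tc.epochs):
            lr = tc.lr_at(epoch)
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, tc.batch_size):
                idx = order[start:start + tc.batch_size]
                batch = [matrices[i] for i in idx]
                loss, _ = self.loss_and_grad(batch, Y[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged at epoch {epoch} (loss={loss})")
                epoch_loss += loss * len(idx)
                for layer in self._layers():
                    for k in layer.params:
                        layer.params[k] -= lr * layer.grads[k]
            trace.append(epoch_loss / n)
            if val_matrices is not None:
                P = self.predict_proba(val_matrices)
                vl = bce_loss(val_Y, P)
                val_trace.append(vl)
                if vl < best_val - 1e-6:
                    best_val, wait = vl, 0
                    best_state = [{k: v.copy() for k, v in lay.params.items()}
                                  for lay in self._layers()]
                elif tc.patience is not None:
                    wait += 1
                    if wait >= tc.patience:
                        break
            if verbose:
                print(f"epoch {epoch}: loss {trace[-1]:.4f}")
        if best_state is not None:
            for lay, st in zip(self._layers(), best_state):
                for k in st:
                    lay.params[k][...] = st[k]
        return {"loss": trace, "val_loss": val_trace}

    def predict_proba(self, matrices) -> np.ndarray:
        return np.stack([self.forward(M) for M in matrices])

    def predict(self, matrices, threshold: float = 0.5) -> np.ndarray:
        """Binarize probabilities: label assigned iff p >= threshold."""
        return (self.predict_proba(matrices) >= threshold).astype(int)
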