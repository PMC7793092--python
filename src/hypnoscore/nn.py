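"""Minimal dense/convolutional/recurrent network core in pure numpy.

Implements exactly the layers the DeepConvLSTM sleep scorer needs — 1-D
convolution along the epoch axis, batch normalization, ReLU, LSTM, dense —
with manual backpropagation, Adam, L2 kernel regularization and cross-entropy
heads.  Everything is float64 and driven by explicit RNGs, so training runs
are bit-reproducible.  Gradients are verified against central finite
differences in the test suite.

Shapes: inputs are ``(batch, time, channels)``; recurrent layers may return
the full sequence or only the final hidden state.
"""

from __future__ import annotations

import copy

import numpy as np


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base layer: ``params``/``grads`` are parallel lists of arrays."""

    params: list
    grads: list

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x, train: bool):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError

    def reg_loss(self) -> float:
        return 0.0


class Conv1D(Layer):
    """Same-padded 1-D convolution along the time axis, stride 1, odd kernel.

    Optional L2 penalty ``l2 * sum(W**2)`` on the kernel (not the bias).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng, l2: float = 0.0):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        scale = np.sqrt(2.0 / (kernel * c_in))  # He init for the ReLU stack
        self.W = rng.normal(0.0, scale, size=(kernel, c_in, c_out))
        self.b = np.zeros(c_out)
        self.kernel = kernel
        self.l2 = l2
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train: bool):
        k, p = self.kernel, self.kernel // 2
        self._xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        T = x.shape[1]
        y = np.tile(self.b, (x.shape[0], T, 1))
        for j in range(k):
            y += self._xp[:, j : j + T, :] @ self.W[j]
        self._T = T
        return y

    def backward(self, dy):
        k, p, T = self.kernel, self.kernel // 2, self._T
        dW, db = self.grads
        db[...] = dy.sum(axis=(0, 1))
        dxp = np.zeros_like(self._xp)
        for j in range(k):
            dW[j] = np.tensordot(self._xp[:, j : j + T, :], dy, axes=([0, 1], [0, 1]))
            dxp[:, j : j + T, :] += dy @ self.W[j].T
        if self.l2:
            dW += 2.0 * self.l2 * self.W
        return dxp[:, p : p + T, :]

    def reg_loss(self) -> float:
        return float(self.l2 * np.sum(self.W**2))


class BatchNorm(Layer):
    """Per-channel batch normalization over the (batch, time) axes."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def forward(self, x, train: bool):
        if train:
            mu = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean *= self.momentum
            self.running_mean += (1 - self.momentum) * mu
            self.running_var *= self.momentum
            self.running_var += (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv_std
        self._m = x.shape[0] * x.shape[1]
        self._train = train
        return self.gamma * self._xhat + self.beta

    def backward(self, dy):
        dgamma, dbeta = self.grads
        dgamma[...] = np.sum(dy * self._xhat, axis=(0, 1))
        dbeta[...] = dy.sum(axis=(0, 1))
        dxhat = dy * self.gamma
        if not self._train:
            return dxhat * self._inv_std
        m = self._m
        # standard batch-norm gradient with batch statistics
        return (
            self._inv_std
            / m
            * (m * dxhat - dxhat.sum(axis=(0, 1)) - self._xhat * (dxhat * self._xhat).sum(axis=(0, 1)))
        )


class ReLU(Layer):
    def forward(self, x, train: bool):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class LSTM(Layer):
    """Single LSTM layer; gate order (i, f, g, o), forget bias 1."""

    def __init__(self, c_in: int, units: int, rng, return_sequences: bool = True):
        super().__init__()
        s_in = np.sqrt(1.0 / c_in)
        s_h = np.sqrt(1.0 / units)
        self.Wx = rng.normal(0.0, s_in, size=(c_in, 4 * units))
        self.Wh = rng.normal(0.0, s_h, size=(units, 4 * units))
        self.b = np.zeros(4 * units)
        self.b[units : 2 * units] = 1.0
        self.units = units
        self.return_sequences = return_sequences
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train: bool):
        B, T, _ = x.shape
        H = self.units
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._x = x
        self._cache = []
        hs = np.empty((B, T, H))
        for t in range(T):
            a = x[:, t, :] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            hs[:, t, :] = h
            self._cache.append((i, f, g, o, c_prev, tc, h_prev))
        self._hs = hs
        return hs if self.return_sequences else h

    def backward(self, dy):
        x = self._x
        B, T, _ = x.shape
        H = self.units
        dWx, dWh, db = self.grads
        dWx[...] = 0.0
        dWh[...] = 0.0
        db[...] = 0.0
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, tc, h_prev = self._cache[t]
            dh = dh_next.copy()
            if self.return_sequences:
                dh += dy[:, t, :]
            elif t == T - 1:
                dh += dy
            dc = dc_next + dh * o * (1.0 - tc**2)
            da = np.empty((B, 4 * H))
            da[:, :H] = dc * g * i * (1.0 - i)  # input gate
            da[:, H : 2 * H] = dc * c_prev * f * (1.0 - f)  # forget gate
            da[:, 2 * H : 3 * H] = dc * i * (1.0 - g**2)  # candidate
            da[:, 3 * H :] = dh * tc * o * (1.0 - o)  # output gate
            dWx += x[:, t, :].T @ da
            dWh += h_prev.T @ da
            db += da.sum(axis=0)
            dx[:, t, :] = da @ self.Wx.T
            dh_next = da @ self.Wh.T
            dc_next = dc * f
        return dx


class LastStep(Layer):
    """Select the final timestep of a sequence."""

    def forward(self, x, train: bool):
        self._shape = x.shape
        return x[:, -1, :]

    def backward(self, dy):
        dx = np.zeros(self._shape)
        dx[:, -1, :] = dy
        return dx


class Dense(Layer):
    def __init__(self, c_in: int, c_out: int, rng):
        super().__init__()
        scale = np.sqrt(1.0 / c_in)
        self.W = rng.normal(0.0, scale, size=(c_in, c_out))
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train: bool):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


class Network:
    """A plain sequential stack with a classification head.

    ``n_classes == 2`` uses a single sigmoid logit with binary cross-entropy;
    ``n_classes >= 3`` a softmax with categorical cross-entropy.  Per-class
    weights rebalance the loss.
    """

    def __init__(self, layers: list[Layer], n_classes: int):
        self.layers = layers
        self.n_classes = n_classes

    # -- plumbing ----------------------------------------------------------
    @property
    def params(self):
        return [p for lyr in self.layers for p in lyr.params]

    @property
    def grads(self):
        return [g for lyr in self.layers for g in lyr.grads]

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))

    def get_weights(self):
        return [p.copy() for p in self.params]

    def set_weights(self, weights):
        for p, w in zip(self.params, weights, strict=True):
            p[...] = w

    def get_state(self):
        """Weights plus non-trainable state (batch-norm running stats)."""
        state = {"weights": self.get_weights(), "bn": []}
        for lyr in self.layers:
            if isinstance(lyr, BatchNorm):
                state["bn"].append((lyr.running_mean.copy(), lyr.running_var.copy()))
        return state

    def set_state(self, state):
        self.set_weights(state["weights"])
        bn = iter(state["bn"])
        for lyr in self.layers:
            if isinstance(lyr, BatchNorm):
                m, v = next(bn)
                lyr.running_mean[...] = m
                lyr.running_var[...] = v

    # -- forward / loss ----------------------------------------------------
    def forward(self, x, train: bool = False):
        for lyr in self.layers:
            x = lyr.forward(x, train)
        return x

    def predict_proba(self, x, batch_size: int = 256):
        outs = []
        for i in range(0, x.shape[0], batch_size):
            logits = self.forward(x[i : i + batch_size], train=False)
            outs.append(self._probs(logits))
        return np.concatenate(outs, axis=0)

    def _probs(self, logits):
        if self.n_classes == 2:
            p = _sigmoid(logits[:, 0])
            return np.column_stack([1.0 - p, p])
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def loss_and_grad(self, logits, y, class_weight=None):
        """Mean weighted cross-entropy and its gradient w.r.t. the logits."""
        n = logits.shape[0]
        w = np.ones(n) if class_weight is None else np.asarray(class_weight)[y]
        wsum = w.sum()
        probs = self._probs(logits)
        eps = 1e-12
        loss = float(-(w * np.log(probs[np.arange(n), y] + eps)).sum() / wsum)
        if self.n_classes == 2:
            dlogits = ((probs[:, 1] - y) * w / wsum)[:, None]
        else:
            onehot = np.zeros_like(probs)
            onehot[np.arange(n), y] = 1.0
            dlogits = (probs - onehot) * (w / wsum)[:, None]
        return loss, dlogits

    def reg_loss(self) -> float:
        return float(sum(lyr.reg_loss() for lyr in self.layers))

    def backward(self, dlogits):
        g = dlogits
        for lyr in reversed(self.layers):
            g = lyr.backward(g)
        return g

    def data_loss(self, x, y, class_weight=None, batch_size: int = 256) -> float:
        """Unregularized cross-entropy in inference mode (running BN stats)."""
        total, wtot = 0.0, 0.0
        y = np.asarray(y)
        for i in range(0, x.shape[0], batch_size):
            logits = self.forward(x[i : i + batch_size], train=False)
            yi = y[i : i + batch_size]
            w = np.ones(yi.size) if class_weight is None else np.asarray(class_weight)[yi]
            probs = self._probs(logits)
            total += float(-(w * np.log(probs[np.arange(yi.size), yi] + 1e-12)).sum())
            wtot += w.sum()
        return total / wtot


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g**2
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def fit(
    net: Network,
    x_train,
    y_train,
    x_val,
    y_val,
    *,
    lr: float = 1e-3,
    batch_size: int = 64,
    max_epochs: int = 30,
    patience: int = 5,
    class_weight=None,
    seed: int = 0,
    shuffle: bool = True,
):
    """Mini-batch Adam training with min-validation-loss checkpointing.

    Returns ``(history, best_state)`` where history is a list of
    ``(train_loss, val_loss)`` per epoch and the network is left holding the
    weights (and batch-norm statistics) of the epoch with the lowest
    validation loss.
    """
    rng = np.random.default_rng(seed)
    opt = Adam(net.params, lr=lr)
    y_train = np.asarray(y_train)
    history = []
    best_loss = np.inf
    best_state = net.get_state()
    since_best = 0
    n = x_train.shape[0]
    for _epoch in range(max_epochs):
        idx = rng.permutation(n) if shuffle else np.arange(n)
        ep_loss, ep_w = 0.0, 0.0
        for i in range(0, n, batch_size):
            b = idx[i : i + batch_size]
            logits = net.forward(x_train[b], train=True)
            loss, dlogits = net.loss_and_grad(logits, y_train[b], class_weight)
            net.backward(dlogits)
            opt.step(net.grads)
            ep_loss += loss * b.size
            ep_w += b.size
        val_loss = net.data_loss(x_val, y_val, class_weight)
        history.append((ep_loss / ep_w, val_loss))
        if val_loss < best_loss - 1e-12:
            best_loss = val_loss
            best_state = net.get_state()
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    net.set_state(copy.deepcopy(best_state))
    return history, best_state
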