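"""Minimal neural-network layers with exact backpropagation, in numpy.

Implements exactly what the activity classifier needs: 2-D convolution with
TensorFlow-style "same" padding, batch normalization, ReLU, inverted
dropout, an LSTM (run forward or backward in time, combined into a BiLSTM),
a dense layer, softmax cross-entropy, and the Adam optimizer. Gradients are
hand-derived and checked against numerical differentiation in the test
suite. float32 is the default compute precision; float64 is available for
gradient checking.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


def glorot_uniform(rng, shape, fan_in, fan_out, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    def params(self) -> list:
        return []

    def state(self) -> dict:
        return {}

    def set_state(self, state: dict) -> None:
        pass


class Conv2D(Layer):
    """2-D convolution, NHWC layout, "same" padding (TF convention: output
    size ceil(in/stride), extra padding goes after)."""

    def __init__(self, c_in, c_out, kernel, stride, rng, dtype=np.float32, name="conv"):
        kh, kw = kernel
        self.stride = (stride, stride) if np.isscalar(stride) else tuple(stride)
        fan_in = kh * kw * c_in
        fan_out = kh * kw * c_out
        self.w = Param(glorot_uniform(rng, (kh, kw, c_in, c_out), fan_in, fan_out, dtype),
                       f"{name}.w")
        self.b = Param(np.zeros(c_out, dtype=dtype), f"{name}.b")
        self.kernel = (kh, kw)
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def _geometry(self, h, w):
        kh, kw = self.kernel
        sh, sw = self.stride
        ho = -(-h // sh)
        wo = -(-w // sw)
        pad_h = max((ho - 1) * sh + kh - h, 0)
        pad_w = max((wo - 1) * sw + kw - w, 0)
        return ho, wo, (pad_h // 2, pad_h - pad_h // 2), (pad_w // 2, pad_w - pad_w // 2)

    def forward(self, x, training=False):
        b, h, w, _ = x.shape
        kh, kw = self.kernel
        sh, sw = self.stride
        ho, wo, ph, pw = self._geometry(h, w)
        xp = np.pad(x, ((0, 0), ph, pw, (0, 0)))
        y = np.tile(self.b.value, (b, ho, wo, 1)).astype(x.dtype)
        for di in range(kh):
            for dj in range(kw):
                xs = xp[:, di:di + (ho - 1) * sh + 1:sh, dj:dj + (wo - 1) * sw + 1:sw, :]
                y += np.tensordot(xs, self.w.value[di, dj], axes=([3], [0]))
        self._cache = (xp, x.shape)
        return y

    def backward(self, dy):
        xp, x_shape = self._cache
        b, h, w, _ = x_shape
        kh, kw = self.kernel
        sh, sw = self.stride
        ho, wo, ph, pw = self._geometry(h, w)
        dxp = np.zeros_like(xp)
        for di in range(kh):
            for dj in range(kw):
                sl_h = slice(di, di + (ho - 1) * sh + 1, sh)
                sl_w = slice(dj, dj + (wo - 1) * sw + 1, sw)
                xs = xp[:, sl_h, sl_w, :]
                self.w.grad[di, dj] += np.tensordot(xs, dy, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, sl_h, sl_w, :] += np.tensordot(dy, self.w.value[di, dj],
                                                      axes=([3], [1]))
        self.b.grad += dy.sum(axis=(0, 1, 2))
        return dxp[:, ph[0]:ph[0] + h, pw[0]:pw[0] + w, :]


class BatchNorm(Layer):
    """Batch normalization over all axes but the last (channel) axis."""

    def __init__(self, channels, momentum=0.9, eps=1e-5, dtype=np.float32, name="bn"):
        self.gamma = Param(np.ones(channels, dtype=dtype), f"{name}.gamma")
        self.beta = Param(np.zeros(channels, dtype=dtype), f"{name}.beta")
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def state(self):
        return {"running_mean": self.running_mean.copy(),
                "running_var": self.running_var.copy()}

    def set_state(self, state):
        self.running_mean = state["running_mean"].copy()
        self.running_var = state["running_var"].copy()

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mu).astype(
                self.running_mean.dtype)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(
                self.running_var.dtype)
        else:
            mu, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * ivar
        self._cache = (xhat, ivar.astype(x.dtype), axes, training)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy):
        xhat, ivar, axes, training = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        dxhat = dy * self.gamma.value
        if not training:
            return dxhat * ivar
        m = np.prod([xhat.shape[a] for a in axes])
        return (ivar / m) * (
            m * dxhat
            - dxhat.sum(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True)
        )


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate, rng):
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Dense(Layer):
    def __init__(self, n_in, n_out, rng, dtype=np.float32, name="dense"):
        self.w = Param(glorot_uniform(rng, (n_in, n_out), n_in, n_out, dtype),
                       f"{name}.w")
        self.b = Param(np.zeros(n_out, dtype=dtype), f"{name}.b")

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class LSTM(Layer):
    """Single-direction LSTM returning the final hidden state.

    Gate order i, f, g, o; forget-gate bias initialized to 1. With
    ``go_backwards`` the sequence is processed in reverse time order.
    """

    def __init__(self, n_in, n_hidden, rng, dtype=np.float32,
                 go_backwards=False, name="lstm"):
        h = n_hidden
        self.wx = Param(glorot_uniform(rng, (n_in, 4 * h), n_in, 4 * h, dtype),
                        f"{name}.wx")
        self.wh = Param(glorot_uniform(rng, (h, 4 * h), h, 4 * h, dtype),
                        f"{name}.wh")
        b = np.zeros(4 * h, dtype=dtype)
        b[h:2 * h] = 1.0
        self.b = Param(b, f"{name}.b")
        self.n_hidden = h
        self.go_backwards = go_backwards

    def params(self):
        return [self.wx, self.wh, self.b]

    def forward(self, x, training=False):
        if self.go_backwards:
            x = x[:, ::-1]
        bsz, t_len, _ = x.shape
        h = self.n_hidden
        xw = x.reshape(bsz * t_len, -1) @ self.wx.value
        xw = xw.reshape(bsz, t_len, 4 * h)
        gates = np.empty((bsz, t_len, 4 * h), dtype=x.dtype)
        cs = np.empty((bsz, t_len, h), dtype=x.dtype)
        hs = np.empty((bsz, t_len, h), dtype=x.dtype)
        hprev = np.zeros((bsz, h), dtype=x.dtype)
        cprev = np.zeros((bsz, h), dtype=x.dtype)
        for t in range(t_len):
            z = xw[:, t] + hprev @ self.wh.value + self.b.value
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h:2 * h])
            g = np.tanh(z[:, 2 * h:3 * h])
            o = _sigmoid(z[:, 3 * h:])
            cprev = f * cprev + i * g
            hprev = o * np.tanh(cprev)
            gates[:, t, :h] = i
            gates[:, t, h:2 * h] = f
            gates[:, t, 2 * h:3 * h] = g
            gates[:, t, 3 * h:] = o
            cs[:, t] = cprev
            hs[:, t] = hprev
        self._cache = (x, gates, cs, hs)
        return hprev

    def backward(self, dh_last):
        x, gates, cs, hs = self._cache
        bsz, t_len, _ = x.shape
        h = self.n_hidden
        dz = np.empty((bsz, t_len, 4 * h), dtype=x.dtype)
        dh = dh_last.astype(x.dtype)
        dc = np.zeros((bsz, h), dtype=x.dtype)
        for t in range(t_len - 1, -1, -1):
            i = gates[:, t, :h]
            f = gates[:, t, h:2 * h]
            g = gates[:, t, 2 * h:3 * h]
            o = gates[:, t, 3 * h:]
            c = cs[:, t]
            tc = np.tanh(c)
            c_prev = cs[:, t - 1] if t > 0 else np.zeros_like(c)
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g * i * (1.0 - i)
            df = dc * c_prev * f * (1.0 - f)
            dg = dc * i * (1.0 - g * g)
            do = dh * tc * o * (1.0 - o)
            dz[:, t, :h] = di
            dz[:, t, h:2 * h] = df
            dz[:, t, 2 * h:3 * h] = dg
            dz[:, t, 3 * h:] = do
            h_prev = hs[:, t - 1] if t > 0 else np.zeros_like(dh)
            self.wh.grad += h_prev.T @ dz[:, t]
            dh = dz[:, t] @ self.wh.value.T
            dc = dc * f
        self.wx.grad += np.tensordot(x, dz, axes=([0, 1], [0, 1]))
        self.b.grad += dz.sum(axis=(0, 1))
        dx = dz.reshape(bsz * t_len, -1) @ self.wx.value.T
        dx = dx.reshape(x.shape)
        if self.go_backwards:
            dx = dx[:, ::-1]
        return dx


class BiLSTM(Layer):
    """Forward and backward LSTM; output is the concatenated final states."""

    def __init__(self, n_in, n_hidden, rng, dtype=np.float32, name="bilstm"):
        self.fwd = LSTM(n_in, n_hidden, rng, dtype, False, f"{name}.fwd")
        self.bwd = LSTM(n_in, n_hidden, rng, dtype, True, f"{name}.bwd")
        self.n_hidden = n_hidden

    def params(self):
        return self.fwd.params() + self.bwd.params()

    def forward(self, x, training=False):
        return np.concatenate([self.fwd.forward(x, training),
                               self.bwd.forward(x, training)], axis=1)

    def backward(self, dy):
        h = self.n_hidden
        return self.fwd.backward(dy[:, :h]) + self.bwd.backward(dy[:, h:])


def softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits, labels):
    """Mean sparse categorical cross-entropy and its gradient w.r.t. logits."""
    probs = softmax(logits.astype(np.float64))
    n = len(labels)
    eps = 1e-12
    loss = float(-np.mean(np.log(probs[np.arange(n), labels] + eps)))
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(logits.dtype), probs


class Adam:
    """Adam with bias-corrected first/second moments."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                p.value.dtype)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0
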