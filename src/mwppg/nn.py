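"""Minimal numpy layer library with hand-written backpropagation.

Provides exactly the pieces the blood-pressure regressor needs: 2-D
convolution (same padding, stride 1), batch normalisation, the
self-normalising SELU activation, squeeze-and-excitation channel
attention, 2x2 average pooling, dense layers, a bidirectional LSTM, the
mean-absolute-error loss and the Adam optimiser.  Every layer caches its
forward activations and implements ``backward`` returning the gradient
with respect to its input while accumulating parameter gradients.

Conventions: feature maps are ``(B, C, H, W)``; sequences are
``(B, T, D)``.  All parameters are float64 for reproducibility.
"""

from __future__ import annotations

import numpy as np

from .errors import ShapeError

# SELU constants (self-normalising activation).
SELU_ALPHA = 1.6732632423543772
SELU_SCALE = 1.0507009873554805


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    """Base layer: ``forward(x, train)`` then ``backward(grad)``."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _lecun_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    # LeCun-normal initialisation keeps SELU in its self-normalising regime.
    return rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=shape)


class Conv2d(Layer):
    """3x3 (configurable) convolution, stride 1, zero 'same' padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ShapeError("kernel size must be odd for same padding")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        self.w = Param(_lecun_normal(rng, (out_ch, in_ch, kernel, kernel), fan_in), "conv.w")
        self.b = Param(np.zeros(out_ch), "conv.b")
        self._cols = None
        self._xshape = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        B, C, H, W = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (B, C, H, W, k, k) sliding view -> columns (B*H*W, C*k*k)
        view = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * W, C * k * k)
        wmat = self.w.value.reshape(self.out_ch, -1)
        out = cols @ wmat.T + self.b.value
        if train:
            self._cols, self._xshape = cols, x.shape
        return out.reshape(B, H, W, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, grad):
        B, C, H, W = self._xshape
        k, p = self.k, self.k // 2
        gout = grad.transpose(0, 2, 3, 1).reshape(B * H * W, self.out_ch)
        wmat = self.w.value.reshape(self.out_ch, -1)
        self.w.grad += (gout.T @ self._cols).reshape(self.w.value.shape)
        self.b.grad += gout.sum(axis=0)
        gcols = (gout @ wmat).reshape(B, H, W, C, k, k)
        gx = np.zeros((B, C, H + 2 * p, W + 2 * p))
        for ki in range(k):
            for kj in range(k):
                gx[:, :, ki : ki + H, kj : kj + W] += gcols[:, :, :, :, ki, kj].transpose(
                    0, 3, 1, 2
                )
        return gx[:, :, p : p + H, p : p + W]


class BatchNorm2d(Layer):
    """Per-channel batch normalisation over (B, H, W)."""

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_ch), "bn.gamma")
        self.beta = Param(np.zeros(n_ch), "bn.beta")
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_sd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_sd[None, :, None, None]
        if train:
            self._cache = (xhat, inv_sd, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad):
        xhat, inv_sd, shape = self._cache
        B, C, H, W = shape
        m = B * H * W
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.value[None, :, None, None]
        gsum = g.sum(axis=(0, 2, 3)).reshape(1, C, 1, 1)
        gxhat_sum = (g * xhat).sum(axis=(0, 2, 3)).reshape(1, C, 1, 1)
        return (
            inv_sd[None, :, None, None]
            * (g - gsum / m - xhat * gxhat_sum / m)
        )


class SELU(Layer):
    def __init__(self):
        self._x = None

    def forward(self, x, train):
        out = SELU_SCALE * np.where(x > 0, x, SELU_ALPHA * np.expm1(x))
        if train:
            self._x = x
        return out

    def backward(self, grad):
        x = self._x
        deriv = SELU_SCALE * np.where(x > 0, 1.0, SELU_ALPHA * np.exp(x))
        return grad * deriv


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class SEAttention(Layer):
    """Squeeze-and-excitation channel attention.

    Global average pool -> bottleneck dense (ratio ``reduction``) -> ReLU
    -> dense -> sigmoid; the resulting per-channel weights (strictly in
    (0, 1)) rescale the feature map.
    """

    def __init__(self, n_ch: int, reduction: int, rng: np.random.Generator):
        hidden = max(1, n_ch // max(1, reduction))
        self.w1 = Param(_lecun_normal(rng, (n_ch, hidden), n_ch), "se.w1")
        self.b1 = Param(np.zeros(hidden), "se.b1")
        self.w2 = Param(_lecun_normal(rng, (hidden, n_ch), hidden), "se.w2")
        self.b2 = Param(np.zeros(n_ch), "se.b2")
        self._cache = None

    def params(self):
        return [self.w1, self.b1, self.w2, self.b2]

    def channel_weights(self, x: np.ndarray) -> np.ndarray:
        """Attention weights (B, C) for a feature map, no caching."""
        s = x.mean(axis=(2, 3))
        h = np.maximum(s @ self.w1.value + self.b1.value, 0.0)
        return _sigmoid(h @ self.w2.value + self.b2.value)

    def forward(self, x, train):
        s = x.mean(axis=(2, 3))                        # (B, C) squeeze
        z1 = s @ self.w1.value + self.b1.value
        h = np.maximum(z1, 0.0)
        z2 = h @ self.w2.value + self.b2.value
        a = _sigmoid(z2)                               # (B, C) in (0,1)
        out = x * a[:, :, None, None]
        if train:
            self._cache = (x, s, z1, h, a)
        return out

    def backward(self, grad):
        x, s, z1, h, a = self._cache
        B, C, H, W = x.shape
        gx = grad * a[:, :, None, None]
        ga = (grad * x).sum(axis=(2, 3))               # (B, C)
        gz2 = ga * a * (1.0 - a)
        self.w2.grad += h.T @ gz2
        self.b2.grad += gz2.sum(axis=0)
        gh = gz2 @ self.w2.value.T
        gz1 = gh * (z1 > 0)
        self.w1.grad += s.T @ gz1
        self.b1.grad += gz1.sum(axis=0)
        gs = gz1 @ self.w1.value.T                     # (B, C)
        gx += gs[:, :, None, None] / (H * W)
        return gx


class AvgPool2(Layer):
    """2x2 average pooling, stride 2 (spatial dims must be even)."""

    def __init__(self):
        self._shape = None

    def forward(self, x, train):
        B, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ShapeError(f"AvgPool2 needs even spatial dims; got {x.shape}")
        out = x.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))
        if train:
            self._shape = x.shape
        return out

    def backward(self, grad):
        B, C, H, W = self._shape
        g = np.repeat(np.repeat(grad, 2, axis=2), 2, axis=3) / 4.0
        return g


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Param(_lecun_normal(rng, (n_in, n_out), n_in), "dense.w")
        self.b = Param(np.zeros(n_out), "dense.b")
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad):
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T


class _LSTMDirection:
    """One direction of one LSTM layer (gate order i, f, g, o)."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(hidden)
        self.wx = Param(rng.uniform(-bound, bound, (n_in, 4 * hidden)), "lstm.wx")
        self.wh = Param(rng.uniform(-bound, bound, (hidden, 4 * hidden)), "lstm.wh")
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.b = Param(b, "lstm.b")
        self.hidden = hidden
        self._cache = None

    def params(self):
        return [self.wx, self.wh, self.b]

    def forward(self, x, train):
        B, T, D = x.shape
        Hn = self.hidden
        h = np.zeros((B, Hn))
        c = np.zeros((B, Hn))
        hs = np.empty((B, T, Hn))
        cache = [] if train else None
        for t in range(T):
            z = x[:, t] @ self.wx.value + h @ self.wh.value + self.b.value
            i = _sigmoid(z[:, :Hn])
            f = _sigmoid(z[:, Hn : 2 * Hn])
            g = np.tanh(z[:, 2 * Hn : 3 * Hn])
            o = _sigmoid(z[:, 3 * Hn :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            if train:
                cache.append((x[:, t], h, c, i, f, g, o, c_new, tc))
            h, c = h_new, c_new
            hs[:, t] = h
        if train:
            self._cache = (cache, x.shape)
        return hs

    def backward(self, grad):
        cache, (B, T, D) = self._cache
        Hn = self.hidden
        gx = np.zeros((B, T, D))
        gh_next = np.zeros((B, Hn))
        gc_next = np.zeros((B, Hn))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, c_new, tc = cache[t]
            gh = grad[:, t] + gh_next
            go = gh * tc
            gc = gh * o * (1.0 - tc**2) + gc_next
            gi = gc * g
            gf = gc * c_prev
            gg = gc * i
            gz = np.concatenate(
                [
                    gi * i * (1.0 - i),
                    gf * f * (1.0 - f),
                    gg * (1.0 - g**2),
                    go * o * (1.0 - o),
                ],
                axis=1,
            )
            self.wx.grad += x_t.T @ gz
            self.wh.grad += h_prev.T @ gz
            self.b.grad += gz.sum(axis=0)
            gx[:, t] = gz @ self.wx.value.T
            gh_next = gz @ self.wh.value.T
            gc_next = gc * f
        return gx


class BiLSTM(Layer):
    """Stacked bidirectional LSTM; output is (B, T, 2*hidden)."""

    def __init__(self, n_in: int, hidden: int, n_layers: int, rng: np.random.Generator):
        self.layers: list[tuple[_LSTMDirection, _LSTMDirection]] = []
        d = n_in
        for _ in range(n_layers):
            fwd = _LSTMDirection(d, hidden, rng)
            bwd = _LSTMDirection(d, hidden, rng)
            self.layers.append((fwd, bwd))
            d = 2 * hidden
        self.out_dim = d

    def params(self):
        out = []
        for fwd, bwd in self.layers:
            out.extend(fwd.params())
            out.extend(bwd.params())
        return out

    def forward(self, x, train):
        for fwd, bwd in self.layers:
            hf = fwd.forward(x, train)
            hb = bwd.forward(x[:, ::-1], train)[:, ::-1]
            x = np.concatenate([hf, hb], axis=2)
        return x

    def backward(self, grad):
        for fwd, bwd in reversed(self.layers):
            Hn = fwd.hidden
            gf = fwd.backward(grad[:, :, :Hn])
            gb = bwd.backward(grad[:, ::-1, Hn:])[:, ::-1]
            grad = gf + gb
        return grad


class TemporalMean(Layer):
    """(B, T, D) -> (B, D) mean over time."""

    def __init__(self):
        self._T = None

    def forward(self, x, train):
        if train:
            self._T = x.shape[1]
        return x.mean(axis=1)

    def backward(self, grad):
        return np.repeat(grad[:, None, :], self._T, axis=1) / self._T


class HeightPoolToSequence(Layer):
    """(B, C, H, W) -> (B, T=W, D=C): average over height, width as time.

    Scalogram columns are time steps, so the feature-map width axis is read
    as the recurrent sequence after collapsing height by average pooling.
    """

    def __init__(self):
        self._shape = None

    def forward(self, x, train):
        if train:
            self._shape = x.shape
        return x.mean(axis=2).transpose(0, 2, 1)

    def backward(self, grad):
        B, C, H, W = self._shape
        g = grad.transpose(0, 2, 1)[:, :, None, :]  # (B, C, 1, W)
        return np.broadcast_to(g, (B, C, H, W)) / H


def mae_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error over all elements and its subgradient."""
    if pred.shape != target.shape:
        raise ShapeError(f"pred {pred.shape} vs target {target.shape}")
    diff = pred - target
    loss = float(np.mean(np.abs(diff)))
    grad = np.sign(diff) / diff.size
    return loss, grad


class Adam:
    """Adam optimiser (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
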