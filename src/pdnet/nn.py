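"""A compact, deterministic CNN framework on numpy.

Implements exactly the layer inventory the classifier needs — 2-D
convolution (im2col), ReLU, max pooling, dropout, flatten, dense, sigmoid
— with reverse-mode gradients and an Adam optimizer.  Everything is
float32 and driven by an explicit ``numpy.random.Generator``, so a fixed
seed reproduces training bit-for-bit on a single thread.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "ReLU", "MaxPool2D", "Dropout", "Flatten", "Dense", "Sigmoid",
           "Sequential", "Adam", "bce_loss"]

F32 = np.float32


class Layer:
    def forward(self, x, training=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError

    def params(self):
        return []

    def grads(self):
        return []


def _im2col(x, kh, kw, ph, pw):
    """(N, C, H, W) -> (N, H, W, C*kh*kw) patches with zero same-padding."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    out = np.empty((n, h, w, c * kh * kw), dtype=x.dtype)
    col = 0
    for ci in range(c):
        for i in range(kh):
            for j in range(kw):
                out[..., col] = xp[:, ci, i : i + h, j : j + w]
                col += 1
    return out


class Conv2D(Layer):
    """Same-padded stride-1 convolution, He-initialized."""

    def __init__(self, in_ch, out_ch, kernel, rng):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        self.w = (rng.standard_normal((fan_in, out_ch)) * np.sqrt(2.0 / fan_in)).astype(F32)
        self.b = np.zeros(out_ch, dtype=F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training=False):
        self._shape = x.shape
        p = self.k // 2
        self._cols = _im2col(x, self.k, self.k, p, p)
        n, _, h, w = x.shape
        out = self._cols.reshape(-1, self.w.shape[0]) @ self.w + self.b
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, _, h, w = self._shape
        g = grad.transpose(0, 2, 3, 1).reshape(-1, self.out_ch)
        cols = self._cols.reshape(-1, self.w.shape[0])
        self.dw[...] = cols.T @ g
        self.db[...] = g.sum(axis=0)
        dcols = (g @ self.w.T).reshape(n, h, w, -1)
        # scatter patches back (col2im)
        p = self.k // 2
        dxp = np.zeros((n, self.in_ch, h + 2 * p, w + 2 * p), dtype=F32)
        col = 0
        for ci in range(self.in_ch):
            for i in range(self.k):
                for j in range(self.k):
                    dxp[:, ci, i : i + h, j : j + w] += dcols[..., col]
                    col += 1
        return dxp[:, :, p : p + h, p : p + w] if p else dxp

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2D(Layer):
    """Non-overlapping pooling; size 1 is the identity (the '1x1 pooling' variant)."""

    def __init__(self, size):
        self.size = size

    def forward(self, x, training=False):
        if self.size == 1:
            return x
        n, c, h, w = x.shape
        s = self.size
        if h % s or w % s:
            raise ValueError(f"spatial dims ({h},{w}) not divisible by pool size {s}")
        xr = x.reshape(n, c, h // s, s, w // s, s)
        self._x = xr
        out = xr.max(axis=(3, 5))
        self._out = out
        return out

    def backward(self, grad):
        if self.size == 1:
            return grad
        mask = self._x == self._out[:, :, :, None, :, None]
        counts = mask.sum(axis=(3, 5), keepdims=True)  # ties share the gradient
        g = mask * grad[:, :, :, None, :, None] / counts
        n, c, hs, s, ws, s2 = g.shape
        return g.reshape(n, c, hs * s, ws * s2)


class Dropout(Layer):
    def __init__(self, rate, rng):
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in, n_out, rng):
        self.w = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(F32)
        self.b = np.zeros(n_out, dtype=F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.dw[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class Sigmoid(Layer):
    def forward(self, x, training=False):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Sequential:
    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params()))

    def state(self):
        return [p.copy() for p in self.params()]

    def load_state(self, state):
        for p, s in zip(self.params(), state):
            p[...] = s


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


def bce_loss(prob, y):
    """Binary cross-entropy and its gradient w.r.t. the probability."""
    prob = np.clip(prob, 1e-7, 1 - 1e-7)
    loss = -np.mean(y * np.log(prob) + (1 - y) * np.log(1 - prob))
    grad = (prob - y) / (prob * (1 - prob)) / prob.shape[0]
    return float(loss), grad.astype(F32)


def bce_with_logits(z, y):
    """Numerically stable fused sigmoid + BCE.

    Returns (loss, prob, grad_z) with grad_z = (prob - y)/N: saturating
    outputs keep bounded gradients, unlike clipping the probability.
    """
    z = z.astype(np.float64)
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    prob = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
    grad = ((prob - y) / z.shape[0]).astype(F32)
    return loss, prob, grad
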