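"""NumPy layers with explicit forward/backward passes.

Conventions: activations are float64 arrays in NCHW layout; every
layer caches what its backward pass needs during forward and exposes
``parameters()`` as a list of dicts ``{"name", "value", "grad",
"l2"}`` whose ``value`` arrays are updated in place by the optimizer.
Gradients accumulate into ``grad`` between ``zero_grad()`` calls, so
weight sharing and residual fan-out compose correctly.
"""

from __future__ import annotations

import numpy as np

from ..errors import ConfigurationError


class Layer:
    """Base class: stateless layers override forward/backward only."""

    def parameters(self) -> list[dict]:
        return []

    def zero_grad(self) -> None:
        for p in self.parameters():
            p["grad"][...] = 0.0

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...],
             fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2D(Layer):
    """2-D convolution with TF-style 'same' padding, via im2col."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None, l2: float = 0.0):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.w = _he_init(rng, (cout, cin * k * k), cin * k * k)
        self.b = np.zeros(cout)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.l2 = l2
        self._idx_cache: dict = {}

    def parameters(self):
        return [{"name": "conv.w", "value": self.w, "grad": self.gw,
                 "l2": self.l2},
                {"name": "conv.b", "value": self.b, "grad": self.gb,
                 "l2": 0.0}]

    def _geometry(self, h: int, w: int):
        key = (h, w)
        if key in self._idx_cache:
            return self._idx_cache[key]
        s, k = self.stride, self.k
        oh = -(-h // s)
        ow = -(-w // s)
        pad_h = max((oh - 1) * s + k - h, 0)
        pad_w = max((ow - 1) * s + k - w, 0)
        pads = (pad_h // 2, pad_h - pad_h // 2, pad_w // 2, pad_w - pad_w // 2)
        geom = (oh, ow, pads, h + pad_h, w + pad_w)
        self._idx_cache[key] = geom
        return geom

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ConfigurationError(f"expected {self.cin} channels, got {c}")
        if self.k == 1 and self.stride == 1:
            # pointwise fast path: plain channel mixing
            xl = x.reshape(n, c, h * w)
            y = np.matmul(self.w[None], xl) + self.b[None, :, None]
            self._cache = (xl, (n, c, h, w))
            return y.reshape(n, self.cout, h, w)
        oh, ow, pads, hp, wp = self._geometry(h, w)
        xp = np.pad(x, ((0, 0), (0, 0), (pads[0], pads[1]),
                        (pads[2], pads[3])))
        k, s = self.k, self.stride
        # im2col by k*k shifted slabs into the (n, cin*k*k, L) layout
        cols = np.empty((n, c, k, k, oh, ow))
        for ky in range(k):
            for kx in range(k):
                cols[:, :, ky, kx] = xp[:, :, ky:ky + (oh - 1) * s + 1:s,
                                        kx:kx + (ow - 1) * s + 1:s]
        cols = cols.reshape(n, c * k * k, oh * ow)
        y = np.matmul(self.w[None], cols) + self.b[None, :, None]
        self._cache = (cols, (n, c, h, w))
        return y.reshape(n, self.cout, oh, ow)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, (n, c, h, w) = self._cache
        if self.k == 1 and self.stride == 1:
            dyl = dy.reshape(n, self.cout, h * w)
            self.gw += np.matmul(dyl, cols.transpose(0, 2, 1)).sum(axis=0)
            self.gb += dyl.sum(axis=(0, 2))
            dx = np.matmul(self.w.T[None], dyl)
            return dx.reshape(n, c, h, w)
        oh, ow, pads, hp, wp = self._geometry(h, w)
        k, s = self.k, self.stride
        dyl = dy.reshape(n, self.cout, oh * ow)
        self.gw += np.matmul(dyl, cols.transpose(0, 2, 1)).sum(axis=0)
        self.gb += dyl.sum(axis=(0, 2))
        dcols = np.matmul(self.w.T[None], dyl).reshape(n, c, k, k, oh, ow)
        # col2im: accumulate the k*k shifted slabs (fast vs scatter-add)
        dxp = np.zeros((n, c, hp, wp))
        for ky in range(k):
            for kx in range(k):
                dxp[:, :, ky:ky + (oh - 1) * s + 1:s,
                    kx:kx + (ow - 1) * s + 1:s] += dcols[:, :, ky, kx]
        return dxp[:, :, pads[0]:hp - pads[1], pads[2]:wp - pads[3]]


class Dense(Layer):
    def __init__(self, din: int, dout: int,
                 rng: np.random.Generator | None = None, l2: float = 0.0):
        rng = rng or np.random.default_rng(0)
        self.w = _he_init(rng, (din, dout), din)
        self.b = np.zeros(dout)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.l2 = l2

    def parameters(self):
        return [{"name": "dense.w", "value": self.w, "grad": self.gw,
                 "l2": self.l2},
                {"name": "dense.b", "value": self.b, "grad": self.gb,
                 "l2": 0.0}]

    def forward(self, x, train: bool = True):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.gw += self._x.T @ dy
        self.gb += dy.sum(axis=0)
        return dy @ self.w.T


class BatchNorm(Layer):
    """Batch normalization over all axes except the channel axis.

    Works for NCHW activations (``axis=1``) and dense features
    (``axis=1`` of an (N, C) array).
    """

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.ggamma = np.zeros(c)
        self.gbeta = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps

    def parameters(self):
        return [{"name": "bn.gamma", "value": self.gamma, "grad": self.ggamma,
                 "l2": 0.0},
                {"name": "bn.beta", "value": self.beta, "grad": self.gbeta,
                 "l2": 0.0}]

    def _axes(self, x):
        return (0,) if x.ndim == 2 else (0, 2, 3)

    def _shape(self, x):
        return (1, -1) if x.ndim == 2 else (1, -1, 1, 1)

    def forward(self, x, train: bool = True):
        axes, shape = self._axes(x), self._shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) / std.reshape(shape)
        self._cache = (xhat, std, axes, shape, train)
        return self.gamma.reshape(shape) * xhat + self.beta.reshape(shape)

    def backward(self, dy):
        xhat, std, axes, shape, train = self._cache
        self.ggamma += (dy * xhat).sum(axis=axes)
        self.gbeta += dy.sum(axis=axes)
        g = self.gamma.reshape(shape) / std.reshape(shape)
        if not train:
            return g * dy
        m = dy.size // dy.shape[1] if dy.ndim == 4 else dy.shape[0]
        mean_dy = dy.mean(axis=axes).reshape(shape)
        mean_dyx = (dy * xhat).mean(axis=axes).reshape(shape)
        return g * (dy - mean_dy - xhat * mean_dyx)


class ReLU(Layer):
    def forward(self, x, train: bool = True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2(Layer):
    """2x2 max pooling with stride 2 (requires even spatial dims)."""

    def forward(self, x, train: bool = True):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ConfigurationError(f"MaxPool2 needs even dims, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._arg = xr.argmax(axis=-1)
        self._shape = (n, c, h, w)
        return xr.max(axis=-1)

    def backward(self, dy):
        n, c, h, w = self._shape
        d = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(d, self._arg[..., None], dy[..., None], axis=-1)
        d = d.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return d.reshape(n, c, h, w)


class Upsample2(Layer):
    """Nearest-neighbor 2x upsampling."""

    def forward(self, x, train: bool = True):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class GlobalAvgPool(Layer):
    def forward(self, x, train: bool = True):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None] / (h * w),
                               self._shape).copy()


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time or with rate 0."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ConfigurationError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train: bool = True):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y_index: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.log(np.clip(p[np.arange(n), y_index], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), y_index] -= 1.0
    return loss, grad / n


class Adam:
    """Adam optimizer with optional per-parameter L2 weight decay."""

    def __init__(self, params: list[dict], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p["value"]) for p in params]
        self.v = [np.zeros_like(p["value"]) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p["grad"]
            if p.get("l2"):
                g = g + p["l2"] * p["value"]
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p["value"] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
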