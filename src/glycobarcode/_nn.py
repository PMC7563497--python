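"""A compact CPU neural-network engine for small barcode classifiers.

Implements exactly the layer inventory the barcode networks need — strided and
grouped convolution, cross-channel (local response) normalization, overlapping
max pooling, fully connected layers, dropout, and a softmax cross-entropy head
— with explicit backward passes, plus SGD-with-momentum and Adam optimizers.
All randomness (initialization, batch order, dropout masks) flows from a
single numpy Generator so training is bit-reproducible given a seed.

Tensors are NCHW float32. Convolution and pooling use im2col with small
kernel-offset loops; this is deliberately simple and fast enough for the
grid-raster image sizes used here.
"""

from __future__ import annotations

import numpy as np


def _pair(v):
    return (v, v) if np.isscalar(v) else tuple(v)


def im2col(x: np.ndarray, kh: int, kw: int, stride: tuple[int, int]) -> np.ndarray:
    """(N, C, H, W) -> (N, C, kh, kw, OH, OW) view-copies for convolution."""
    n, c, h, w = x.shape
    sh, sw = stride
    oh = (h - kh) // sh + 1
    ow = (w - kw) // sw + 1
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i : i + sh * oh : sh, j : j + sw * ow : sw]
    return cols


def col2im(
    dcols: np.ndarray, x_shape: tuple, kh: int, kw: int, stride: tuple[int, int]
) -> np.ndarray:
    """Scatter-add the adjoint of :func:`im2col`."""
    n, c, h, w = x_shape
    sh, sw = stride
    oh, ow = dcols.shape[4], dcols.shape[5]
    dx = np.zeros(x_shape, dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + sh * oh : sh, j : j + sw * ow : sw] += dcols[:, :, i, j]
    return dx


class Layer:
    trainable = True

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """Convolution with stride, symmetric zero padding and channel groups."""

    def __init__(self, in_channels, out_channels, kernel, stride=1, pad=0, groups=1):
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must divide evenly into groups")
        self.ci, self.co, self.g = in_channels, out_channels, groups
        self.kh, self.kw = _pair(kernel)
        self.stride = _pair(stride)
        self.pad = _pair(pad)
        self.W = np.zeros((out_channels, in_channels // groups, self.kh, self.kw), np.float32)
        self.b = np.zeros(out_channels, np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def init(self, rng: np.random.Generator) -> None:
        fan_in = (self.ci // self.g) * self.kh * self.kw
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), self.W.shape).astype(np.float32)
        self.b = np.zeros(self.co, np.float32)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def out_shape(self, in_shape):
        c, h, w = in_shape
        ph, pw = self.pad
        oh = (h + 2 * ph - self.kh) // self.stride[0] + 1
        ow = (w + 2 * pw - self.kw) // self.stride[1] + 1
        return (self.co, oh, ow)

    def n_params(self):
        return self.W.size + self.b.size

    def forward(self, x, training):
        ph, pw = self.pad
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        self._x_shape = x.shape
        cols = im2col(x, self.kh, self.kw, self.stride)  # (N,C,kh,kw,OH,OW)
        n, _, _, _, oh, ow = cols.shape
        cg = self.ci // self.g
        fg = self.co // self.g
        self._cols = cols
        out = np.empty((n, self.co, oh, ow), dtype=np.float32)
        for g in range(self.g):
            colg = cols[:, g * cg : (g + 1) * cg].reshape(n, cg * self.kh * self.kw, oh * ow)
            wg = self.W[g * fg : (g + 1) * fg].reshape(fg, cg * self.kh * self.kw)
            out[:, g * fg : (g + 1) * fg] = (wg @ colg).reshape(n, fg, oh, ow)
        out += self.b[None, :, None, None]
        return out

    def backward(self, dy):
        n, _, oh, ow = dy.shape
        cg = self.ci // self.g
        fg = self.co // self.g
        dcols = np.empty_like(self._cols)
        for g in range(self.g):
            colg = self._cols[:, g * cg : (g + 1) * cg].reshape(n, cg * self.kh * self.kw, oh * ow)
            dyg = dy[:, g * fg : (g + 1) * fg].reshape(n, fg, oh * ow)
            wg = self.W[g * fg : (g + 1) * fg].reshape(fg, cg * self.kh * self.kw)
            self.dW[g * fg : (g + 1) * fg] = (
                np.einsum("nfl,nkl->fk", dyg, colg).reshape(fg, cg, self.kh, self.kw)
            )
            dcolg = np.einsum("fk,nfl->nkl", wg, dyg)
            dcols[:, g * cg : (g + 1) * cg] = dcolg.reshape(n, cg, self.kh, self.kw, oh, ow)
        self.db[...] = dy.sum(axis=(0, 2, 3))
        dx = col2im(dcols, self._x_shape, self.kh, self.kw, self.stride)
        ph, pw = self.pad
        if ph or pw:
            dx = dx[:, :, ph : dx.shape[2] - ph, pw : dx.shape[3] - pw]
        return dx


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class CrossChannelNorm(Layer):
    """Local response normalization across channels.

    b_i = a_i / (k + (alpha/n) * sum_{j in window(i)} a_j^2)^beta with a
    symmetric window of ``n`` channels, matching the convention in which the
    sum of squares is divided by the window size.
    """

    def __init__(self, n=5, alpha=1e-4, beta=0.75, k=2.0):
        self.n, self.alpha, self.beta, self.k = n, alpha, beta, k

    def _window_sum(self, t):
        c = t.shape[1]
        half = self.n // 2
        out = np.zeros_like(t)
        for off in range(-half, half + 1):
            lo, hi = max(0, -off), min(c, c - off)
            out[:, lo:hi] += t[:, lo + off : hi + off]
        return out

    def forward(self, x, training):
        s = self._window_sum(x * x)
        self._x = x
        self._d = self.k + (self.alpha / self.n) * s
        self._y = x * self._d ** (-self.beta)
        return self._y

    def backward(self, dy):
        t = dy * self._x * self._d ** (-self.beta - 1.0)
        return dy * self._d ** (-self.beta) - (
            2.0 * self.alpha * self.beta / self.n
        ) * self._x * self._window_sum(t)


class MaxPool(Layer):
    def __init__(self, kernel=3, stride=2):
        self.kh, self.kw = _pair(kernel)
        self.stride = _pair(stride)

    def out_shape(self, in_shape):
        c, h, w = in_shape
        oh = (h - self.kh) // self.stride[0] + 1
        ow = (w - self.kw) // self.stride[1] + 1
        return (c, oh, ow)

    def forward(self, x, training):
        self._x_shape = x.shape
        cols = im2col(x, self.kh, self.kw, self.stride)
        n, c, kh, kw, oh, ow = cols.shape
        flat = cols.reshape(n, c, kh * kw, oh, ow)
        self._arg = flat.argmax(axis=2)
        return np.take_along_axis(flat, self._arg[:, :, None], axis=2)[:, :, 0]

    def backward(self, dy):
        n, c, oh, ow = dy.shape
        dflat = np.zeros((n, c, self.kh * self.kw, oh, ow), dtype=dy.dtype)
        np.put_along_axis(dflat, self._arg[:, :, None], dy[:, :, None], axis=2)
        dcols = dflat.reshape(n, c, self.kh, self.kw, oh, ow)
        return col2im(dcols, self._x_shape, self.kh, self.kw, self.stride)


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_units, units):
        self.in_units, self.units = in_units, units
        self.W = np.zeros((in_units, units), np.float32)
        self.b = np.zeros(units, np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def init(self, rng):
        self.W = rng.normal(0.0, np.sqrt(2.0 / self.in_units), self.W.shape).astype(np.float32)
        self.b = np.zeros(self.units, np.float32)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def n_params(self):
        return self.W.size + self.b.size

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T


class Dropout(Layer):
    def __init__(self, p=0.5, rng: np.random.Generator | None = None):
        self.p = p
        self.rng = rng

    def forward(self, x, training):
        if not training or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(x.dtype) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss over integer labels, and d(loss)/d(logits)."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(np.maximum(p[np.arange(n), y], 1e-12)).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


class SGDM:
    """Stochastic gradient descent with (classical) momentum."""

    def __init__(self, lr=1e-4, momentum=0.9):
        self.lr, self.momentum = lr, momentum
        self._v: dict[int, dict[str, np.ndarray]] = {}

    def step(self, layers):
        for li, layer in enumerate(layers):
            if not layer.trainable:
                continue
            ps, gs = layer.params(), layer.grads()
            if not ps:
                continue
            state = self._v.setdefault(li, {k: np.zeros_like(v) for k, v in ps.items()})
            for k in ps:
                state[k] = self.momentum * state[k] - self.lr * gs[k]
                ps[k] += state[k]


class Adam:
    def __init__(self, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._m: dict[int, dict[str, np.ndarray]] = {}
        self._v: dict[int, dict[str, np.ndarray]] = {}
        self._t = 0

    def step(self, layers):
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for li, layer in enumerate(layers):
            if not layer.trainable:
                continue
            ps, gs = layer.params(), layer.grads()
            if not ps:
                continue
            m = self._m.setdefault(li, {k: np.zeros_like(v) for k, v in ps.items()})
            v = self._v.setdefault(li, {k: np.zeros_like(p) for k, p in ps.items()})
            for k in ps:
                m[k] = b1 * m[k] + (1 - b1) * gs[k]
                v[k] = b2 * v[k] + (1 - b2) * gs[k] ** 2
                mhat = m[k] / (1 - b1 ** self._t)
                vhat = v[k] / (1 - b2 ** self._t)
                ps[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Network:
    """A simple sequential network over the layers above."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def param_layers(self) -> list[Layer]:
        return [l for l in self.layers if l.params()]

    def state(self) -> dict[str, np.ndarray]:
        out = {}
        for li, layer in enumerate(self.layers):
            for k, v in layer.params().items():
                out[f"{li}.{k}"] = v.copy()
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for li, layer in enumerate(self.layers):
            for k, v in layer.params().items():
                key = f"{li}.{k}"
                if key not in state:
                    raise ValueError(f"missing parameter {key} in state")
                if state[key].shape != v.shape:
                    raise ValueError(f"shape mismatch for {key}")
                v[...] = state[key]
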