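"""Convolutional building blocks in numpy with explicit backward passes.

These are the primitives the multi-branch network is assembled from: 2-D
convolution (arbitrary odd kernel, stride), transposed convolution realised
as zero-insertion upsampling followed by a stride-1 convolution, batch
normalization, ReLU, and Adam.  All arithmetic is float32; convolutions are
evaluated as k*k batched matrix products (one BLAS call per kernel tap),
which keeps memory linear in the feature-map size.

Padding is "same" for odd kernels.  ``pad_mode`` selects the boundary rule:
``reflect`` (default), ``wrap`` (periodic; makes the network exactly
translation-equivariant at the common stride), or ``constant`` (zeros).
Gradients fold the padded borders back onto their source pixels, so the
backward pass is exact for every mode.
"""

from __future__ import annotations

import numpy as np

_F32 = np.float32


class Param:
    """A learnable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(_F32)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


def _pad2d(x: np.ndarray, p: int, mode: str) -> np.ndarray:
    if p == 0:
        return x
    np_mode = {"reflect": "reflect", "wrap": "wrap", "constant": "constant"}[mode]
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), mode=np_mode)


def _fold_axis(d: np.ndarray, p: int, mode: str, axis: int) -> np.ndarray:
    """Fold gradient of a padded axis back onto the unpadded array."""
    n = d.shape[axis] - 2 * p
    sl = [slice(None)] * d.ndim

    def take(a, b):
        sl2 = list(sl)
        sl2[axis] = slice(a, b)
        return d[tuple(sl2)]

    core = take(p, p + n).copy()
    if p == 0 or mode == "constant":
        return core
    top, bottom = take(0, p), take(p + n, n + 2 * p)
    flip = [slice(None)] * d.ndim
    flip[axis] = slice(None, None, -1)
    sl_core = lambda a, b: tuple(sl[:axis] + [slice(a, b)] + sl[axis + 1 :])
    if mode == "wrap":
        core[sl_core(n - p, n)] += top
        core[sl_core(0, p)] += bottom
    elif mode == "reflect":
        core[sl_core(1, p + 1)] += top[tuple(flip)]
        core[sl_core(n - p - 1, n - 1)] += bottom[tuple(flip)]
    return core


class Conv2d:
    """Same-padded 2-D convolution, odd kernel, integer stride."""

    def __init__(self, cin, cout, kernel, stride=1, pad_mode="reflect", rng=None, bias=True):
        assert kernel % 2 == 1, "kernel must be odd"
        self.cin, self.cout, self.k, self.stride = cin, cout, kernel, stride
        self.pad_mode = pad_mode
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (cin * kernel * kernel))
        self.W = Param(rng.normal(0.0, std, size=(cout, cin, kernel, kernel)))
        self.b = Param(np.zeros(cout)) if bias else None
        self._cache = None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, cin, hh, ww = x.shape
        k, s, p = self.k, self.stride, self.k // 2
        ho = (hh + 2 * p - k) // s + 1
        wo = (ww + 2 * p - k) // s + 1
        xp = _pad2d(x, p, self.pad_mode)
        out = np.zeros((n, self.cout, ho * wo), dtype=_F32)
        wmat = self.W.value
        for i in range(k):
            for j in range(k):
                xs = np.ascontiguousarray(
                    xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
                ).reshape(n, cin, ho * wo)
                out += np.matmul(wmat[:, :, i, j], xs)
        out = out.reshape(n, self.cout, ho, wo)
        if self.b is not None:
            out += self.b.value[None, :, None, None]
        if train:
            self._cache = (xp, x.shape, (ho, wo))
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, xshape, (ho, wo) = self._cache
        n, cin, hh, ww = xshape
        k, s, p = self.k, self.stride, self.k // 2
        dyf = dy.reshape(n, self.cout, ho * wo)
        if self.b is not None:
            self.b.grad += dy.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(xp)
        wmat = self.W.value
        for i in range(k):
            for j in range(k):
                xs = np.ascontiguousarray(
                    xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
                ).reshape(n, cin, ho * wo)
                # (cout, cin) gradient for this tap, summed over batch+space
                self.W.grad[:, :, i, j] += np.einsum(
                    "nop,ncp->oc", dyf, xs, optimize=True
                )
                dxs = np.matmul(wmat[:, :, i, j].T, dyf)  # (n, cin, ho*wo)
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dxs.reshape(
                    n, cin, ho, wo
                )
        dx = _fold_axis(dxp, p, self.pad_mode, axis=2)
        dx = _fold_axis(dx, p, self.pad_mode, axis=3)
        return dx


class ConvTranspose2d:
    """2x learnable upsampling: zero-insertion followed by a 3x3 convolution."""

    def __init__(self, cin, cout, kernel=3, pad_mode="reflect", rng=None):
        self.conv = Conv2d(cin, cout, kernel, stride=1, pad_mode=pad_mode, rng=rng)

    def params(self):
        return self.conv.params()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, hh, ww = x.shape
        z = np.zeros((n, c, 2 * hh, 2 * ww), dtype=_F32)
        z[:, :, ::2, ::2] = x
        return self.conv.forward(z, train=train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dz = self.conv.backward(dy)
        return np.ascontiguousarray(dz[:, :, ::2, ::2])


class BatchNorm2d:
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels, momentum=0.1, eps=1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels, dtype=_F32)
        self.running_var = np.ones(channels, dtype=_F32)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[
            None, :, None, None
        ]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dg = (dy * xhat).sum(axis=(0, 2, 3))
        db = dy.sum(axis=(0, 2, 3))
        self.gamma.grad += dg
        self.beta.grad += db
        g = self.gamma.value[None, :, None, None] * inv[None, :, None, None]
        return g * (dy - (db / m)[None, :, None, None] - xhat * (dg / m)[None, :, None, None])


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mask = x > 0
        if train:
            self._mask = mask
        return np.where(mask, x, 0.0).astype(_F32, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(_F32, copy=False)


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    """Adaptive-moment gradient descent over a parameter list."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad * p.grad - v)
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Softmax over axis 1, numerically stable."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
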