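"""Minimal 3D convolutional network framework in numpy.

Implements exactly the pieces the SFCN classifier needs — 3D convolution
(im2col + BLAS matmul), batch normalization, ReLU, 2x max pooling, global
average pooling, dropout, a linear head, softmax cross-entropy, and
SGD/AdamW optimizers — with explicit forward/backward passes.  Gradients
with respect to intermediate activations are exposed so Grad-CAM can pull
the gradient of a class score at any named layer.

Data layout is (N, C, D, H, W), float32 throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

try:  # numba accelerates the 3x3x3 convolutions ~10x; numpy path is the
    import numba  # reference implementation and fallback

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

if HAVE_NUMBA:

    @numba.njit(fastmath=True, cache=False)
    def _conv3_fwd(xp, w):
        """Valid 3^3 correlation of padded input: (N,C,D+2,H+2,W+2) x
        (F,C,3,3,3) -> (N,F,D,H,W)."""
        n_, c_, dp, hp, wp = xp.shape
        f_ = w.shape[0]
        d, h, w2 = dp - 2, hp - 2, wp - 2
        out = np.zeros((n_, f_, d, h, w2), dtype=np.float32)
        for n in range(n_):
            for f in range(f_):
                for c in range(c_):
                    for i in range(3):
                        for j in range(3):
                            for l in range(3):
                                wv = w[f, c, i, j, l]
                                for dd in range(d):
                                    for hh in range(h):
                                        for ww in range(w2):
                                            out[n, f, dd, hh, ww] += (
                                                wv * xp[n, c, dd + i,
                                                        hh + j, ww + l])
        return out

    @numba.njit(fastmath=True, cache=False)
    def _maxpool_fwd(x):
        n_, c_, d, h, w_ = x.shape
        d2, h2, w2 = d // 2, h // 2, w_ // 2
        out = np.empty((n_, c_, d2, h2, w2), dtype=np.float32)
        arg = np.empty((n_, c_, d2, h2, w2), dtype=np.uint8)
        for n in range(n_):
            for c in range(c_):
                for dd in range(d2):
                    for hh in range(h2):
                        for ww in range(w2):
                            best = np.float32(-np.inf)
                            bidx = np.uint8(0)
                            k = np.uint8(0)
                            for i in range(2):
                                for j in range(2):
                                    for l in range(2):
                                        v = x[n, c, 2 * dd + i,
                                              2 * hh + j, 2 * ww + l]
                                        if v > best:
                                            best = v
                                            bidx = k
                                        k += np.uint8(1)
                            out[n, c, dd, hh, ww] = best
                            arg[n, c, dd, hh, ww] = bidx
        return out, arg

    @numba.njit(fastmath=True, cache=False)
    def _maxpool_bwd(dout, arg, d, h, w_):
        n_, c_, d2, h2, w2 = dout.shape
        dx = np.zeros((n_, c_, d, h, w_), dtype=np.float32)
        for n in range(n_):
            for c in range(c_):
                for dd in range(d2):
                    for hh in range(h2):
                        for ww in range(w2):
                            k = arg[n, c, dd, hh, ww]
                            i, rem = k // 4, k % 4
                            j, l = rem // 2, rem % 2
                            dx[n, c, 2 * dd + i, 2 * hh + j, 2 * ww + l] = \
                                dout[n, c, dd, hh, ww]
        return dx

    @numba.njit(fastmath=True, cache=False)
    def _chan_affine2(dout, x, a1, a2, a3):
        """Fused per-channel dx = a1*dout + a2*x + a3."""
        n_, c_, d, h, w_ = x.shape
        out = np.empty_like(x)
        for n in range(n_):
            for c in range(c_):
                v1, v2, v3 = a1[c], a2[c], a3[c]
                for dd in range(d):
                    for hh in range(h):
                        for ww in range(w_):
                            out[n, c, dd, hh, ww] = (
                                v1 * dout[n, c, dd, hh, ww]
                                + v2 * x[n, c, dd, hh, ww] + v3)
        return out

    @numba.njit(fastmath=True, cache=False)
    def _conv3_dw(xp, dout):
        """Weight gradient: (N,C,D+2,H+2,W+2), (N,F,D,H,W) -> (F,C,3,3,3)."""
        n_, c_, dp, hp, wp = xp.shape
        f_ = dout.shape[1]
        d, h, w2 = dp - 2, hp - 2, wp - 2
        dw = np.zeros((f_, c_, 3, 3, 3), dtype=np.float32)
        for n in range(n_):
            for f in range(f_):
                for c in range(c_):
                    for i in range(3):
                        for j in range(3):
                            for l in range(3):
                                acc = np.float32(0.0)
                                for dd in range(d):
                                    for hh in range(h):
                                        for ww in range(w2):
                                            acc += (dout[n, f, dd, hh, ww]
                                                    * xp[n, c, dd + i,
                                                         hh + j, ww + l])
                                dw[f, c, i, j, l] += acc
        return dw


class Parameter:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("name", "data", "grad")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size


class Layer:
    """Base class: stateless unless it has parameters or caches."""

    name: str = ""

    def params(self) -> list:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray, need_dx: bool = True):
        raise NotImplementedError


def _he_init(rng, shape, fan_in):
    return rng.standard_normal(shape).astype(np.float32) * np.sqrt(2.0 / fan_in)


class Conv3d(Layer):
    """3D convolution, stride 1, 'same' zero padding for odd kernels.

    Weight shape (out, in, k, k, k).  For k = 1 the op is a channel mix;
    for k = 3 an im2col view feeds a single matmul.
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3, bias: bool = True,
                 rng=None, name: str = "conv"):
        if k % 2 != 1:
            raise ValueError("only odd kernel sizes supported")
        rng = np.random.default_rng(0) if rng is None else rng
        self.name = name
        self.k = k
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * k ** 3
        self.w = Parameter(f"{name}.w", _he_init(rng, (c_out, c_in, k, k, k),
                                                 fan_in))
        self.b = Parameter(f"{name}.b", np.zeros(c_out)) if bias else None
        self._cache = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    @property
    def _wmat(self):
        # (c_in * k^3, c_out)
        return self.w.data.transpose(1, 2, 3, 4, 0).reshape(-1, self.c_out)

    @staticmethod
    def _im2col(x, k):
        """(N, C, D, H, W) zero-padded -> (N, D*H*W, C*k^3)."""
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
        n, c, d, h, w_ = x.shape
        cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(
            n, d * h * w_, c * k ** 3)
        return np.ascontiguousarray(cols, dtype=np.float32)

    @staticmethod
    def _pad1(x):
        return np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))

    def _conv_same(self, x, w):
        """'same' 3^3 correlation of x with w (F, C, 3, 3, 3)."""
        if HAVE_NUMBA:
            return _conv3_fwd(self._pad1(x),
                              np.ascontiguousarray(w, dtype=np.float32))
        n, c, d, h, w_ = x.shape
        cols = self._im2col(x, 3)
        wmat = w.transpose(1, 2, 3, 4, 0).reshape(-1, w.shape[0])
        out = cols @ wmat
        return np.ascontiguousarray(
            out.transpose(0, 2, 1).reshape(n, w.shape[0], d, h, w_),
            dtype=np.float32)

    def forward(self, x, train=False):
        n, c, d, h, w_ = x.shape
        if c != self.c_in:
            raise ValueError(f"{self.name}: expected {self.c_in} channels, "
                             f"got {c}")
        x = np.ascontiguousarray(x, dtype=np.float32)
        self._cache = x
        if self.k == 1:
            out = np.tensordot(x, self.w.data[:, :, 0, 0, 0],
                               axes=([1], [1]))          # (N,D,H,W,F)
            out = np.ascontiguousarray(np.moveaxis(out, -1, 1),
                                       dtype=np.float32)
        else:
            out = self._conv_same(x, self.w.data)
        if self.b is not None:
            out += self.b.data[None, :, None, None, None]
        return out

    def backward(self, dout, need_dx=True):
        x = self._cache
        n, c, d, h, w_ = x.shape
        dout = np.ascontiguousarray(dout, dtype=np.float32)
        if self.b is not None:
            self.b.grad += dout.sum(axis=(0, 2, 3, 4))
        if self.k == 1:
            dw = np.tensordot(dout, x, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
            self.w.grad += dw[:, :, None, None, None]
            if not need_dx:
                return None
            dx = np.tensordot(dout, self.w.data[:, :, 0, 0, 0],
                              axes=([1], [0]))
            return np.ascontiguousarray(np.moveaxis(dx, -1, 1),
                                        dtype=np.float32)
        if HAVE_NUMBA:
            self.w.grad += _conv3_dw(self._pad1(x), dout)
        else:
            cols = self._im2col(x, 3)
            dout2 = dout.reshape(n, self.c_out, -1).transpose(0, 2, 1)
            dwmat = np.tensordot(cols, dout2, axes=([0, 1], [0, 1]))
            self.w.grad += dwmat.reshape(
                self.c_in, 3, 3, 3, self.c_out).transpose(4, 0, 1, 2, 3)
        if not need_dx:
            return None
        # dx = conv(dout, spatially flipped W with in/out channels swapped)
        wb = self.w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        return self._conv_same(dout, np.ascontiguousarray(wb))


class BatchNorm3d(Layer):
    """Per-channel batch normalization over (N, D, H, W)."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn"):
        self.name = name
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(f"{name}.gamma", np.ones(c))
        self.beta = Parameter(f"{name}.beta", np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    @staticmethod
    def _chan_stats(x):
        """Per-channel mean and variance over (N, D, H, W), single pass,
        no transposed copy."""
        s1 = np.einsum("ncdhw->c", x, dtype=np.float64)
        s2 = np.einsum("ncdhw,ncdhw->c", x, x, dtype=np.float64)
        m = x.shape[0] * x.shape[2] * x.shape[3] * x.shape[4]
        mean = s1 / m
        var = np.maximum(s2 / m - mean ** 2, 0.0)
        return mean.astype(np.float32), var.astype(np.float32)

    def forward(self, x, train=False):
        if train:
            mean, var = self._chan_stats(x)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        self._cache = (x, mean, inv, train)
        # fused channel affine: out = a * x + b
        a = self.gamma.data * inv
        b = self.beta.data - a * mean
        return (x * a[None, :, None, None, None]
                + b[None, :, None, None, None]).astype(np.float32)

    def backward(self, dout, need_dx=True):
        x, mean, inv, train = self._cache
        s_d = np.einsum("ncdhw->c", dout, dtype=np.float64)
        s_dx = np.einsum("ncdhw,ncdhw->c", dout, x, dtype=np.float64)
        # sum of dout * xhat, without materializing xhat
        s_dxhat = (inv * (s_dx - mean * s_d)).astype(np.float32)
        self.gamma.grad += s_dxhat
        self.beta.grad += s_d.astype(np.float32)
        if not need_dx:
            return None
        g = self.gamma.data
        if not train:
            a = g * inv
            return (dout * a[None, :, None, None, None]).astype(np.float32)
        m = x.shape[0] * x.shape[2] * x.shape[3] * x.shape[4]
        # dx = a1*dout + a2*x + a3 per channel (xhat re-expressed through x)
        a1 = g * inv
        a2 = (-g * inv ** 2 * s_dxhat / m).astype(np.float32)
        a3 = (-g * inv * s_d.astype(np.float32) / m - a2 * mean)
        if HAVE_NUMBA:
            return _chan_affine2(
                np.ascontiguousarray(dout, dtype=np.float32), x, a1, a2, a3)
        return (dout * a1[None, :, None, None, None]
                + x * a2[None, :, None, None, None]
                + a3[None, :, None, None, None]).astype(np.float32)


class ReLU(Layer):
    def __init__(self, name: str = "relu"):
        self.name = name
        self._mask = None

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dout, need_dx=True):
        return (dout * self._mask).astype(np.float32) if need_dx else None


class MaxPool3d(Layer):
    """2x2x2 max pooling, stride 2.  Requires even spatial extents; on ties
    the gradient goes to the first (lowest-offset) maximum."""

    def __init__(self, name: str = "pool"):
        self.name = name
        self._cache = None

    def forward(self, x, train=False):
        n, c, d, h, w_ = x.shape
        if d < 2 or h < 2 or w_ < 2 or d % 2 or h % 2 or w_ % 2:
            raise ValueError(
                f"{self.name}: spatial extents {(d, h, w_)} must be even and "
                ">= 2; use fewer pooling blocks or a larger grid")
        x = np.ascontiguousarray(x, dtype=np.float32)
        if HAVE_NUMBA:
            out, arg = _maxpool_fwd(x)
        else:
            xt = x.reshape(n, c, d // 2, 2, h // 2, 2, w_ // 2, 2)
            xt = np.ascontiguousarray(xt.transpose(0, 1, 2, 4, 6, 3, 5, 7))
            xt = xt.reshape(n, c, d // 2, h // 2, w_ // 2, 8)
            arg = xt.argmax(axis=-1).astype(np.uint8)
            out = np.take_along_axis(xt, arg[..., None], axis=-1)[..., 0]
        self._cache = (arg, (d, h, w_))
        return out

    def backward(self, dout, need_dx=True):
        if not need_dx:
            return None
        arg, (d, h, w_) = self._cache
        dout = np.ascontiguousarray(dout, dtype=np.float32)
        if HAVE_NUMBA:
            return _maxpool_bwd(dout, arg, d, h, w_)
        n, c = dout.shape[:2]
        dxt = np.zeros(dout.shape + (8,), dtype=np.float32)
        np.put_along_axis(dxt, arg[..., None].astype(int), dout[..., None],
                          axis=-1)
        dxt = dxt.reshape(n, c, d // 2, h // 2, w_ // 2, 2, 2, 2)
        dxt = dxt.transpose(0, 1, 2, 5, 3, 6, 4, 7)
        return np.ascontiguousarray(dxt.reshape(n, c, d, h, w_))


class GlobalAvgPool(Layer):
    """(N, C, D, H, W) -> (N, C) spatial mean."""

    def __init__(self, name: str = "gap"):
        self.name = name
        self._shape = None

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4)).astype(np.float32)

    def backward(self, dout, need_dx=True):
        if not need_dx:
            return None
        n, c, d, h, w_ = self._shape
        dx = np.broadcast_to(dout[:, :, None, None, None] / (d * h * w_),
                             self._shape)
        return np.ascontiguousarray(dx, dtype=np.float32)


class Dropout(Layer):
    """Inverted dropout; identity in eval mode or at p = 0."""

    def __init__(self, p: float = 0.0, rng=None, name: str = "drop"):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.name = name
        self.p = p
        self.rng = np.random.default_rng(0) if rng is None else rng
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return (x * self._mask).astype(np.float32)

    def backward(self, dout, need_dx=True):
        if not need_dx:
            return None
        if self._mask is None:
            return dout
        return (dout * self._mask).astype(np.float32)


class Linear(Layer):
    def __init__(self, c_in: int, c_out: int, rng=None, name: str = "fc"):
        rng = np.random.default_rng(0) if rng is None else rng
        self.name = name
        self.w = Parameter(f"{name}.w", _he_init(rng, (c_out, c_in), c_in))
        self.b = Parameter(f"{name}.b", np.zeros(c_out))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        self._x = x
        return (x @ self.w.data.T + self.b.data).astype(np.float32)

    def backward(self, dout, need_dx=True):
        self.w.grad += dout.T @ self._x
        self.b.grad += dout.sum(axis=0)
        if not need_dx:
            return None
        return (dout @ self.w.data).astype(np.float32)


class Sequential(Layer):
    """Ordered layer container with named-activation capture for saliency."""

    def __init__(self, layers, name: str = "seq"):
        self.name = name
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def layer_names(self):
        return [layer.name for layer in self.layers]

    def forward(self, x, train=False, capture: str | None = None):
        captured = None
        for layer in self.layers:
            x = layer.forward(x, train=train)
            if capture is not None and layer.name == capture:
                captured = x
        if capture is not None:
            if captured is None:
                raise KeyError(
                    f"unknown layer {capture!r}; available: "
                    f"{self.layer_names()}")
            return x, captured
        return x

    def backward(self, dout, need_dx=True, stop_at: str | None = None):
        """Backpropagate; if ``stop_at`` names a layer, return the gradient
        with respect to that layer's *output* and do not descend further."""
        for i in reversed(range(len(self.layers))):
            if stop_at is not None and self.layers[i].name == stop_at:
                return dout
            # inter-layer gradients always flow; only the first layer's
            # input gradient is optional
            dout = self.layers[i].backward(dout, need_dx=need_dx or i > 0)
        if stop_at is not None:
            raise KeyError(f"unknown layer {stop_at!r}")
        return dout


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean softmax cross-entropy; returns (loss, dlogits)."""
    n = len(labels)
    p = softmax(logits.astype(np.float64))
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    d = p.copy()
    d[np.arange(n), labels] -= 1.0
    return float(loss), (d / n).astype(np.float32)


def count_parameters(module) -> int:
    """Exact count of trainable scalars in any Layer or model exposing
    ``params()``."""
    return int(sum(p.size for p in module.params()))


def zero_grads(module) -> None:
    for p in module.params():
        p.grad[...] = 0.0


def get_state(module) -> dict:
    """Snapshot of all trainable parameters (copies)."""
    return {p.name: p.data.copy() for p in module.params()}


def set_state(module, state: dict) -> None:
    for p in module.params():
        p.data[...] = state[p.name]


class AdamW:
    """Adam with decoupled weight decay (the decay multiplies the weight
    directly by lr * wd, independent of the gradient moments)."""

    def __init__(self, params, lr: float = 3e-4, weight_decay: float = 0.0,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 decay_norm_params: bool = False):
        self.params = list(params)
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.decay_norm = decay_norm_params
        self.t = 0
        self.m = {p.name: np.zeros_like(p.data) for p in self.params}
        self.v = {p.name: np.zeros_like(p.data) for p in self.params}

    def step(self):
        self.t += 1
        for p in self.params:
            m = self.m[p.name]
            v = self.v[p.name]
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            if self.wd and (self.decay_norm or p.data.ndim > 1):
                p.data *= (1.0 - self.lr * self.wd)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)
                       ).astype(np.float32)


class SGDW:
    """Momentum SGD with decoupled weight decay."""

    def __init__(self, params, lr: float = 1e-2, weight_decay: float = 0.0,
                 momentum: float = 0.9):
        self.params = list(params)
        self.lr = lr
        self.wd = weight_decay
        self.mu = momentum
        self.vel = {p.name: np.zeros_like(p.data) for p in self.params}

    def step(self):
        for p in self.params:
            v = self.vel[p.name]
            v *= self.mu
            v -= self.lr * p.grad
            if self.wd and p.data.ndim > 1:
                p.data *= (1.0 - self.lr * self.wd)
            p.data += v
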