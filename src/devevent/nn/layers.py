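"""Layers with explicit forward/backward passes.

Convolutions use TensorFlow-style ``same`` padding: the output extent along
a strided axis is ``ceil(n / s)`` and the required padding is split with the
extra pixel on the right.  All convolutions carry a bias term; batch
normalisation follows with learned scale/offset and running statistics for
evaluation mode.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _same_pad(n: int, k: int, s: int) -> tuple[int, int, int]:
    """Output length and (left, right) padding for TF-style same padding."""
    out = -(-n // s)
    pad = max((out - 1) * s + k - n, 0)
    return out, pad // 2, pad - pad // 2


def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class _ConvNd(Layer):
    """Generic correlation over the innermost window axes via im2col."""

    def __init__(self, rng, k: int, cin: int, cout: int, stride: int):
        self.k, self.cin, self.cout, self.stride = k, cin, cout, stride
        fan_in = k * cin
        self.w = Param(he_normal(rng, (k * cin, cout), fan_in))
        self.b = Param(np.zeros(cout, dtype=np.float32))

    def params(self):
        return [self.w, self.b]

    def _forward_1axis(self, x: np.ndarray) -> np.ndarray:
        """x: (M, n, cin) -> (M, out, cout), conv along axis 1."""
        m, n, cin = x.shape
        out, pl, pr = _same_pad(n, self.k, self.stride)
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        win = sliding_window_view(xp, self.k, axis=1)[:, :: self.stride]
        # win: (M, out, cin, k) -> cols (M*out, k*cin)
        cols = win.transpose(0, 1, 3, 2).reshape(m * out, self.k * cin)
        y = cols @ self.w.value + self.b.value
        self._cache = (cols, x.shape, pl, out)
        return y.reshape(m, out, self.cout)

    def _backward_1axis(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape, pl, out = self._cache
        m, n, cin = xshape
        dflat = dout.reshape(m * out, self.cout)
        self.w.grad += cols.T @ dflat
        self.b.grad += dflat.sum(axis=0)
        dcols = (dflat @ self.w.value.T).reshape(m, out, self.k, cin)
        _, pleft, pright = _same_pad(n, self.k, self.stride)
        dxp = np.zeros((m, n + pleft + pright, cin), dtype=np.float32)
        s = self.stride
        for i in range(self.k):
            dxp[:, i : i + s * out : s, :] += dcols[:, :, i, :]
        return dxp[:, pleft : pleft + n, :]


class Conv2D(Layer):
    """2D convolution on (N, H, W, C), kernel kh x kw, same padding."""

    def __init__(self, rng, kernel: int, cin: int, cout: int, stride: int = 1):
        self.k, self.cin, self.cout, self.stride = kernel, cin, cout, stride
        fan_in = kernel * kernel * cin
        self.w = Param(he_normal(rng, (kernel * kernel * cin, cout), fan_in))
        self.b = Param(np.zeros(cout, dtype=np.float32))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        k, s = self.k, self.stride
        ho, pt, pb = _same_pad(h, k, s)
        wo, plft, prgt = _same_pad(w, k, s)
        xp = np.pad(x, ((0, 0), (pt, pb), (plft, prgt), (0, 0)))
        win = sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::s, ::s]
        # win: (N, ho, wo, C, k, k) -> (N*ho*wo, k*k*C)
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * ho * wo, k * k * c)
        y = cols @ self.w.value + self.b.value
        self._cache = (cols, x.shape, (pt, plft), (ho, wo))
        return y.reshape(n, ho, wo, self.cout)

    def backward(self, dout):
        cols, xshape, (pt, plft), (ho, wo) = self._cache
        n, h, w, c = xshape
        k, s = self.k, self.stride
        dflat = dout.reshape(n * ho * wo, self.cout)
        self.w.grad += cols.T @ dflat
        self.b.grad += dflat.sum(axis=0)
        dcols = (dflat @ self.w.value.T).reshape(n, ho, wo, k, k, c)
        _, _, pb = _same_pad(h, k, s)
        _, _, prgt = _same_pad(w, k, s)
        dxp = np.zeros((n, h + pt + pb, w + plft + prgt, c), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + s * ho : s, j : j + s * wo : s, :] += dcols[:, :, :, i, j, :]
        return dxp[:, pt : pt + h, plft : plft + w, :]


class SpatialConv3D(Layer):
    """(2+1)D spatial half: kernel 1 x k x k on (N, L, H, W, C).

    ``t_stride`` subsamples frames before the 2D convolution; with a
    temporal kernel extent of 1 this is exactly a strided convolution
    along the frame axis.
    """

    def __init__(self, rng, kernel: int, cin: int, cout: int, stride: int = 1, t_stride: int = 1):
        self.conv = Conv2D(rng, kernel, cin, cout, stride)
        self.t_stride = t_stride

    def params(self):
        return self.conv.params()

    def forward(self, x, training=False):
        self._l_in = x.shape[1]
        if self.t_stride > 1:
            x = x[:, :: self.t_stride]
        n, l, h, w, c = x.shape
        self._nl = (n, l)
        y = self.conv.forward(x.reshape(n * l, h, w, c), training)
        _, ho, wo, f = y.shape
        return y.reshape(n, l, ho, wo, f)

    def backward(self, dout):
        n, l = self._nl
        _, _, ho, wo, f = dout.shape
        dx = self.conv.backward(dout.reshape(n * l, ho, wo, f))
        _, h, w, c = dx.shape
        dx = dx.reshape(n, l, h, w, c)
        if self.t_stride > 1:
            full = np.zeros((n, self._l_in, h, w, c), dtype=np.float32)
            full[:, :: self.t_stride] = dx
            dx = full
        return dx


class TemporalConv3D(_ConvNd):
    """(2+1)D temporal half: kernel k x 1 x 1 along the frame axis."""

    def forward(self, x, training=False):
        n, l, h, w, c = x.shape
        self._shape = (n, l, h, w, c)
        # (N, L, H, W, C) -> (N*H*W, L, C)
        xt = x.transpose(0, 2, 3, 1, 4).reshape(n * h * w, l, c)
        y = self._forward_1axis(xt)
        lo = y.shape[1]
        return y.reshape(n, h, w, lo, self.cout).transpose(0, 3, 1, 2, 4)

    def backward(self, dout):
        n, l, h, w, c = self._shape
        lo = dout.shape[1]
        dt = dout.transpose(0, 2, 3, 1, 4).reshape(n * h * w, lo, self.cout)
        dx = self._backward_1axis(dt)
        return dx.reshape(n, h, w, l, c).transpose(0, 3, 1, 2, 4)


class PointwiseConv3D(Layer):
    """1x1x1 projection with optional (t, s, s) stride, used for shortcuts."""

    def __init__(self, rng, cin: int, cout: int, stride: tuple[int, int, int] = (1, 1, 1)):
        self.cin, self.cout, self.stride = cin, cout, stride
        self.w = Param(he_normal(rng, (cin, cout), cin))
        self.b = Param(np.zeros(cout, dtype=np.float32))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False):
        st, sh, sw = self.stride
        xs = x[:, ::st, ::sh, ::sw, :]
        self._cache = (xs, x.shape)
        return xs @ self.w.value + self.b.value

    def backward(self, dout):
        xs, xshape = self._cache
        st, sh, sw = self.stride
        self.w.grad += xs.reshape(-1, self.cin).T @ dout.reshape(-1, self.cout)
        self.b.grad += dout.reshape(-1, self.cout).sum(axis=0)
        dx = np.zeros(xshape, dtype=np.float32)
        dx[:, ::st, ::sh, ::sw, :] = dout @ self.w.value.T
        return dx


class BatchNorm(Layer):
    """Batch normalisation over every axis except the last (channels)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels, dtype=np.float32))
        self.beta = Param(np.zeros(channels, dtype=np.float32))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._n_updates = 0

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            # first batch seeds the running statistics outright
            if self._n_updates == 0:
                self.running_mean, self.running_var = mean.copy(), var.copy()
            else:
                m = self.momentum
                self.running_mean = m * self.running_mean + (1 - m) * mean
                self.running_var = m * self.running_var + (1 - m) * var
            self._n_updates += 1
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean) / std
        self._cache = (xhat, std, axes, x.size // x.shape[-1], training)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dout):
        xhat, std, axes, m, training = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.value
        if not training:
            return dxhat / std
        return (dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).mean(axis=axes)) / std


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class MaxPool3D(Layer):
    """Non-overlapping max pooling on (N, L, H, W, C); kernel == stride.

    Right-pads with -inf so partial windows are kept (ceil semantics).
    """

    def __init__(self, kernel: tuple[int, int, int]):
        self.kernel = kernel

    def forward(self, x, training=False):
        kl, kh, kw = self.kernel
        n, l, h, w, c = x.shape
        lo, ho, wo = -(-l // kl), -(-h // kh), -(-w // kw)
        xp = np.full((n, lo * kl, ho * kh, wo * kw, c), -np.inf, dtype=np.float32)
        xp[:, :l, :h, :w, :] = x
        win = xp.reshape(n, lo, kl, ho, kh, wo, kw, c)
        flat = win.transpose(0, 1, 3, 5, 2, 4, 6, 7).reshape(n, lo, ho, wo, kl * kh * kw, c)
        idx = flat.argmax(axis=4)
        self._cache = (idx, (n, l, h, w, c), (lo, ho, wo))
        return np.take_along_axis(flat, idx[:, :, :, :, None, :], axis=4)[:, :, :, :, 0, :]

    def backward(self, dout):
        idx, (n, l, h, w, c), (lo, ho, wo) = self._cache
        kl, kh, kw = self.kernel
        dflat = np.zeros((n, lo, ho, wo, kl * kh * kw, c), dtype=np.float32)
        np.put_along_axis(dflat, idx[:, :, :, :, None, :], dout[:, :, :, :, None, :], axis=4)
        dxp = dflat.reshape(n, lo, ho, wo, kl, kh, kw, c).transpose(0, 1, 4, 2, 5, 3, 6, 7)
        dxp = dxp.reshape(n, lo * kl, ho * kh, wo * kw, c)
        return dxp[:, :l, :h, :w, :]


class MaxPool2D(Layer):
    """Non-overlapping max pooling on (N, H, W, C) via the 3D kernel."""

    def __init__(self, kernel: tuple[int, int]):
        self._pool = MaxPool3D((1, *kernel))

    def forward(self, x, training=False):
        y = self._pool.forward(x[:, None], training)
        return y[:, 0]

    def backward(self, dout):
        return self._pool.backward(dout[:, None])[:, 0]


class GlobalAvgPool(Layer):
    """Mean over all axes between batch and channels."""

    def forward(self, x, training=False):
        self._shape = x.shape
        axes = tuple(range(1, x.ndim - 1))
        return x.mean(axis=axes)

    def backward(self, dout):
        shape = self._shape
        m = int(np.prod(shape[1:-1]))
        expand = (slice(None),) + (None,) * (len(shape) - 2) + (slice(None),)
        return np.broadcast_to(dout[expand] / m, shape).astype(np.float32)


class Dense(Layer):
    def __init__(self, rng, cin: int, cout: int):
        self.cin, self.cout = cin, cout
        self.w = Param(he_normal(rng, (cin, cout), cin))
        self.b = Param(np.zeros(cout, dtype=np.float32))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout):
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value.T


class L2Normalize(Layer):
    """Project row vectors onto the unit sphere."""

    def __init__(self, eps: float = 1e-12):
        self.eps = eps

    def forward(self, x, training=False):
        norm = np.sqrt((x * x).sum(axis=1, keepdims=True) + self.eps)
        y = x / norm
        self._cache = (y, norm)
        return y

    def backward(self, dout):
        y, norm = self._cache
        return (dout - y * (dout * y).sum(axis=1, keepdims=True)) / norm
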