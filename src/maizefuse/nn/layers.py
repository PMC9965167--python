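"""Minimal CNN building blocks on numpy with explicit backpropagation.

Layers follow a tiny common protocol: ``forward(x, train)`` caches whatever
the backward pass needs, ``backward(dy)`` returns the gradient with respect
to the input and fills ``grads`` aligned with ``params``.  Convolutions are
im2col + BLAS matmul; the col2im scatter in the backward pass loops over the
(small) kernel support rather than materializing an index map.

Array layout: 3-D convolution consumes (N, D, H, W, C) with D the spectral
axis; 2-D convolution consumes (N, H, W, C).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _pad_same(x: np.ndarray, kernel: tuple[int, ...], spatial_axes: tuple[int, ...]) -> np.ndarray:
    pad = [(0, 0)] * x.ndim
    for k, ax in zip(kernel, spatial_axes):
        lo = (k - 1) // 2
        pad[ax] = (lo, k - 1 - lo)
    return np.pad(x, pad)


class ConvND(Layer):
    """N-dimensional (2 or 3) valid/same convolution, stride 1.

    Weights are stored flattened as (C_in * prod(kernel), C_out); bias is
    initialized to zero and weights from the Glorot uniform distribution.
    """

    def __init__(self, ndim: int, in_channels: int, out_channels: int,
                 kernel: tuple[int, ...], padding: str, rng: np.random.Generator):
        super().__init__()
        if ndim not in (2, 3) or len(kernel) != ndim:
            raise ValueError("ndim must be 2 or 3 and match the kernel")
        if padding not in ("same", "valid"):
            raise ValueError("padding must be 'same' or 'valid'")
        self.ndim = ndim
        self.kernel = tuple(int(k) for k in kernel)
        self.padding = padding
        self.in_channels = in_channels
        self.out_channels = out_channels
        ksize = int(np.prod(self.kernel))
        fan_in = in_channels * ksize
        fan_out = out_channels * ksize
        self.W = glorot_uniform(rng, (in_channels * ksize, out_channels), fan_in, fan_out)
        self.b = np.zeros(out_channels)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _spatial_axes(self) -> tuple[int, ...]:
        return tuple(range(1, 1 + self.ndim))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[-1] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {x.shape[-1]}")
        xp = _pad_same(x, self.kernel, self._spatial_axes()) if self.padding == "same" else x
        for k, ax in zip(self.kernel, self._spatial_axes()):
            if xp.shape[ax] < k:
                raise ValueError(
                    f"spatial extent {xp.shape[ax]} smaller than kernel {k} (axis {ax})"
                )
        # windows: (N, *out_spatial, C, *kernel)
        win = sliding_window_view(xp, self.kernel, axis=self._spatial_axes())
        out_spatial = win.shape[1 : 1 + self.ndim]
        n = x.shape[0]
        cols = win.reshape(n * int(np.prod(out_spatial)), -1)
        y = cols @ self.W + self.b
        self._cache = (xp.shape, cols, out_spatial, n)
        return y.reshape(n, *out_spatial, self.out_channels)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp_shape, cols, out_spatial, n = self._cache
        dy_flat = dy.reshape(-1, self.out_channels)
        self.grads[0][...] = cols.T @ dy_flat
        self.grads[1][...] = dy_flat.sum(axis=0)
        dcols = dy_flat @ self.W.T
        dcols = dcols.reshape(n, *out_spatial, self.in_channels, *self.kernel)
        dxp = np.zeros(xp_shape)
        if self.ndim == 3:
            kd, kh, kw = self.kernel
            od, oh, ow = out_spatial
            for i in range(kd):
                for j in range(kh):
                    for k in range(kw):
                        dxp[:, i : i + od, j : j + oh, k : k + ow, :] += dcols[..., i, j, k]
        else:
            kh, kw = self.kernel
            oh, ow = out_spatial
            for j in range(kh):
                for k in range(kw):
                    dxp[:, j : j + oh, k : k + ow, :] += dcols[..., j, k]
        if self.padding == "same":
            slices = [slice(None)]
            for k, ax in zip(self.kernel, self._spatial_axes()):
                lo = (k - 1) // 2
                hi = dxp.shape[ax] - (k - 1 - lo)
                slices.append(slice(lo, hi))
            slices.append(slice(None))
            return dxp[tuple(slices)]
        return dxp


class MaxPoolND(Layer):
    """Non-overlapping max pooling; a window is clipped to the remaining
    extent when an axis is smaller than the pool size, and trailing
    remainders are dropped (floor division)."""

    def __init__(self, ndim: int, pool: tuple[int, ...]):
        super().__init__()
        if len(pool) != ndim:
            raise ValueError("pool size must match ndim")
        self.ndim = ndim
        self.pool = tuple(int(p) for p in pool)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        spatial = x.shape[1 : 1 + self.ndim]
        eff = tuple(min(p, s) for p, s in zip(self.pool, spatial))
        out_spatial = tuple(s // p for s, p in zip(spatial, eff))
        crop = [slice(None)]
        crop += [slice(0, o * p) for o, p in zip(out_spatial, eff)]
        crop.append(slice(None))
        xc = x[tuple(crop)]
        n, c = x.shape[0], x.shape[-1]
        shape = [n]
        for o, p in zip(out_spatial, eff):
            shape += [o, p]
        shape.append(c)
        xr = xc.reshape(shape)
        pool_axes = tuple(2 + 2 * i for i in range(self.ndim))
        y = xr.max(axis=pool_axes)
        # broadcast max back over pooled axes to build the gradient mask
        expand = y.reshape([n] + [s for o in out_spatial for s in (o, 1)] + [c])
        mask = xr == expand
        counts = mask.sum(axis=pool_axes, keepdims=True)
        self._cache = (x.shape, xc.shape, mask, counts, eff, out_spatial)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape, xc_shape, mask, counts, eff, out_spatial = self._cache
        n, c = x_shape[0], x_shape[-1]
        dyr = dy.reshape([n] + [s for o in out_spatial for s in (o, 1)] + [c])
        dxr = mask * (dyr / counts)
        dxc = dxr.reshape(xc_shape)
        dx = np.zeros(x_shape)
        crop = [slice(None)]
        crop += [slice(0, o * p) for o, p in zip(out_spatial, eff)]
        crop.append(slice(None))
        dx[tuple(crop)] = dxc
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class GlobalAvgPool(Layer):
    """Average over all non-batch, non-channel axes -> (N, C)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        axes = tuple(range(1, x.ndim - 1))
        self._count = int(np.prod([x.shape[a] for a in axes]))
        return x.mean(axis=axes)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c = dy.shape
        shape = (n,) + (1,) * (len(self._shape) - 2) + (c,)
        return np.broadcast_to(dy.reshape(shape), self._shape) / self._count


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.W = glorot_uniform(rng, (in_features, out_features), in_features, out_features)
        self.b = np.zeros(out_features)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Adam:
    """Adaptive-moment optimizer over a flat parameter list."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray], lr: float | None = None) -> None:
        rate = self.lr if lr is None else lr
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            p -= rate * mhat / (np.sqrt(vhat) + self.eps)
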