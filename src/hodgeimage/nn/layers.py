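"""Layers with explicit forward/backward passes (NumPy, float32).

Shapes follow the channels-first convention (N, C, *spatial) with 2 or 3
spatial dims.  Each layer caches what its backward pass needs; training
is fully deterministic given the initialization RNG.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param", "Module", "Sequential", "ConvNd", "BatchNormNd", "ReLU",
    "MaxPoolHalf", "GlobalAvgPool", "Linear", "ResidualNorm",
]


class Param:
    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.decay = decay  # AdamW weight decay applies only where True


class Module:
    def parameters(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def parameters(self):
        return [p for m in self.modules for p in m.parameters()]

    def forward(self, x, training):
        for m in self.modules:
            x = m.forward(x, training)
        return x

    def backward(self, dout):
        for m in reversed(self.modules):
            dout = m.backward(dout)
        return dout


class ConvNd(Module):
    """Grouped N-d convolution, stride 1, odd kernel, same-size padding.

    kernel_size 1 uses a pure matmul fast path; kernel_size 3 pads by 1
    so spatial extents are preserved.
    """

    def __init__(self, ndim: int, in_channels: int, out_channels: int,
                 kernel_size: int, groups: int, rng: np.random.Generator,
                 bias: bool = True):
        if in_channels % groups or out_channels % groups:
            raise ValueError(
                f"channels ({in_channels}->{out_channels}) not divisible by "
                f"groups={groups}"
            )
        if kernel_size % 2 == 0:
            raise ValueError("only odd kernels supported")
        self.ndim = ndim
        self.cin, self.cout, self.k, self.g = in_channels, out_channels, kernel_size, groups
        self.pad = (kernel_size - 1) // 2
        fan_in = (in_channels // groups) * kernel_size**ndim
        bound = float(1.0 / np.sqrt(fan_in))
        wshape = (out_channels, in_channels // groups) + (kernel_size,) * ndim
        self.w = Param(rng.uniform(-bound, bound, size=wshape))
        self.b = Param(rng.uniform(-bound, bound, size=out_channels), decay=False) if bias else None

    def parameters(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def _cols(self, x):
        """im2col: (N, g, P, (cin/g)*k^d) from (N, cin, *S)."""
        n = x.shape[0]
        spatial = x.shape[2:]
        if self.pad:
            pad = [(0, 0), (0, 0)] + [(self.pad, self.pad)] * self.ndim
            x = np.pad(x, pad)
        win = sliding_window_view(x, (self.k,) * self.ndim,
                                  axis=tuple(range(2, 2 + self.ndim)))
        # win: (N, cin, *S, *k)
        P = int(np.prod(spatial))
        kd = self.k**self.ndim
        cg = self.cin // self.g
        win = win.reshape(n, self.g, cg, P, kd)
        cols = np.ascontiguousarray(np.moveaxis(win, 2, 3)).reshape(
            n, self.g, P, cg * kd
        )
        return cols, spatial

    def forward(self, x, training):
        x = np.ascontiguousarray(x, dtype=np.float32)
        cols, spatial = self._cols(x)
        og = self.cout // self.g
        w2 = self.w.value.reshape(self.g, og, -1)        # (g, og, cg*kd)
        out = cols @ np.swapaxes(w2, 1, 2)               # (N, g, P, og)
        out = np.moveaxis(out, 3, 2).reshape((x.shape[0], self.cout) + spatial)
        if self.b is not None:
            out += self.b.value.reshape((1, -1) + (1,) * self.ndim)
        self._cache = (cols, x.shape)
        return out

    def backward(self, dout):
        cols, xshape = self._cache
        n = dout.shape[0]
        spatial = dout.shape[2:]
        P = int(np.prod(spatial))
        og = self.cout // self.g
        cg = self.cin // self.g
        kd = self.k**self.ndim
        d2 = dout.reshape(n, self.g, og, P)
        d2 = np.ascontiguousarray(np.moveaxis(d2, 2, 3))  # (N, g, P, og)
        if self.b is not None:
            self.b.grad += d2.sum(axis=(0, 2)).reshape(-1)
        # dW: sum_n cols^T @ d2 -> (g, cg*kd, og)
        dw = np.einsum("ngpc,ngpo->gco", cols, d2, optimize=True)
        self.w.grad += np.moveaxis(dw, 1, 2).reshape(self.w.value.shape)
        # dX: scatter d2 @ w back through the windows
        w2 = self.w.value.reshape(self.g, og, cg * kd)
        dcols = d2 @ w2                                   # (N, g, P, cg*kd)
        dcols = dcols.reshape(n, self.g, P, cg, kd)
        dcols = np.moveaxis(dcols, 3, 2)                  # (N, g, cg, P, kd)
        dcols = dcols.reshape((n, self.cin) + spatial + (self.k,) * self.ndim)
        padded_shape = (n, self.cin) + tuple(s + 2 * self.pad for s in spatial)
        dxp = np.zeros(padded_shape, dtype=np.float32)
        for flat in range(kd):
            offs = np.unravel_index(flat, (self.k,) * self.ndim)
            sl = (slice(None), slice(None)) + tuple(
                slice(o, o + s) for o, s in zip(offs, spatial)
            )
            kidx = (Ellipsis,) + offs
            dxp[sl] += dcols[kidx]
        if self.pad:
            core = (slice(None), slice(None)) + tuple(
                slice(self.pad, self.pad + s) for s in spatial
            )
            return dxp[core]
        return dxp


class BatchNormNd(Module):
    """Batch normalization over (N, *spatial) per channel, affine."""

    def __init__(self, channels: int, ndim: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.ndim = ndim
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(channels), decay=False)
        self.beta = Param(np.zeros(channels), decay=False)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def parameters(self):
        return [self.gamma, self.beta]

    def _bshape(self, c):
        return (1, c) + (1,) * self.ndim

    def forward(self, x, training):
        c = x.shape[1]
        axes = (0,) + tuple(range(2, 2 + self.ndim))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = x.shape[0] * int(np.prod(x.shape[2:]))
            unbiased = var * (m / max(m - 1, 1))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(self._bshape(c))) * inv.reshape(self._bshape(c))
        self._cache = (xhat, inv, axes)
        return self.gamma.value.reshape(self._bshape(c)) * xhat + \
            self.beta.value.reshape(self._bshape(c))

    def backward(self, dout):
        xhat, inv, axes = self._cache
        c = dout.shape[1]
        m = dout.shape[0] * int(np.prod(dout.shape[2:]))
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        g = self.gamma.value.reshape(self._bshape(c))
        dxhat = dout * g
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
        ) * inv.reshape(self._bshape(c))
        return dx.astype(np.float32)


class ReLU(Module):
    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0).astype(np.float32)


class MaxPoolHalf(Module):
    """Max pooling with kernel 2 and stride 2 (halves every spatial axis)."""

    def __init__(self, ndim: int):
        self.ndim = ndim

    def forward(self, x, training):
        n, c = x.shape[:2]
        spatial = x.shape[2:]
        if any(s % 2 for s in spatial):
            raise ValueError(f"spatial extents must be even, got {spatial}")
        halves = tuple(s // 2 for s in spatial)
        shape = (n, c)
        for h in halves:
            shape += (h, 2)
        xr = x.reshape(shape)
        # bring the 2-extent window axes to the back
        win_axes = tuple(3 + 2 * i for i in range(self.ndim))
        keep_axes = (0, 1) + tuple(2 + 2 * i for i in range(self.ndim))
        xr = np.transpose(xr, keep_axes + win_axes)
        xr = xr.reshape((n, c) + halves + (2**self.ndim,))
        idx = np.argmax(xr, axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape)
        return np.ascontiguousarray(out)

    def backward(self, dout):
        idx, xshape = self._cache
        n, c = xshape[:2]
        spatial = xshape[2:]
        halves = tuple(s // 2 for s in spatial)
        dxr = np.zeros((n, c) + halves + (2**self.ndim,), dtype=np.float32)
        np.put_along_axis(dxr, idx[..., None], dout[..., None].astype(np.float32), axis=-1)
        # invert the transpose/reshape of forward
        dxr = dxr.reshape((n, c) + halves + (2,) * self.ndim)
        perm = (0, 1) + tuple(2 + 2 * i for i in range(self.ndim)) + tuple(
            3 + 2 * i for i in range(self.ndim)
        )
        dxr = np.transpose(dxr, np.argsort(perm))
        return np.ascontiguousarray(dxr.reshape(xshape))


class GlobalAvgPool(Module):
    """Mean over all spatial axes: (N, C, *S) -> (N, C)."""

    def forward(self, x, training):
        self._shape = x.shape
        axes = tuple(range(2, x.ndim))
        return x.mean(axis=axes)

    def backward(self, dout):
        shape = self._shape
        m = int(np.prod(shape[2:]))
        return (
            np.broadcast_to(
                dout.reshape(shape[:2] + (1,) * (len(shape) - 2)), shape
            )
            / m
        ).astype(np.float32)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = float(1.0 / np.sqrt(n_in))
        self.w = Param(rng.uniform(-bound, bound, size=(n_in, n_out)))
        self.b = Param(rng.uniform(-bound, bound, size=n_out), decay=False)

    def parameters(self):
        return [self.w, self.b]

    def forward(self, x, training):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout):
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return (dout @ self.w.value.T).astype(np.float32)


class ResidualNorm(Module):
    """Post-norm residual sublayer: y = Norm(x + block(x))."""

    def __init__(self, block: Module, norm: BatchNormNd):
        self.block = block
        self.norm = norm

    def parameters(self):
        return self.block.parameters() + self.norm.parameters()

    def forward(self, x, training):
        return self.norm.forward(x + self.block.forward(x, training), training)

    def backward(self, dout):
        d = self.norm.backward(dout)
        return d + self.block.backward(d)
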