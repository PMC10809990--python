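"""Minimal NumPy neural-network engine for 3D volumetric models.

Implements exactly the layers the Siamese collateral-scoring backbone needs
(3D convolution, instance normalization, ReLU, nearest-neighbour upsampling,
fully connected layer) with explicit forward/backward passes and an Adam
optimizer.  All tensors are ``float32`` with layout ``(N, C, D, H, W)``.

The backward pass of every layer is verified against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv3d",
    "InstanceNorm3d",
    "ReLU",
    "UpsampleNearest",
    "Linear",
    "Adam",
    "softmax",
]

_F32 = np.float32


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=_F32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base class: stateless API contract for forward/backward."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(_F32)


class Conv3d(Layer):
    """3D convolution, kernel ``k`` cubed, stride 1 or 2, 'same' zero padding.

    With k odd and padding k//2, stride 1 preserves the grid and stride 2
    produces ``ceil(n/2)`` along each spatial axis (exactly half for even
    inputs).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride: int = 1,
        *,
        rng: np.random.Generator,
        name: str = "conv",
        input_grad: bool = True,
    ) -> None:
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        self.cin = in_channels
        self.cout = out_channels
        self.k = kernel_size
        self.stride = stride
        # first layers of a network do not need a gradient w.r.t. the input
        self.input_grad = input_grad
        fan_in = in_channels * kernel_size**3
        self.weight = Param(
            _he_init(rng, (out_channels, in_channels, kernel_size, kernel_size, kernel_size), fan_in),
            name=f"{name}.weight",
        )
        self.bias = Param(np.zeros(out_channels, dtype=_F32), name=f"{name}.bias")
        self._xp: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def _out_shape(self, spatial: tuple[int, int, int]) -> tuple[int, int, int]:
        p, s = self.k // 2, self.stride
        return tuple((n + 2 * p - self.k) // s + 1 for n in spatial)  # type: ignore[return-value]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, cin, d, h, w = x.shape
        if cin != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {cin}")
        p, s, k = self.k // 2, self.stride, self.k
        do, ho, wo = self._out_shape((d, h, w))
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        self._xp = xp
        self._xshape = x.shape
        m = do * ho * wo
        out = np.broadcast_to(
            self.bias.value[None, :, None], (n, self.cout, m)
        ).copy()
        wmat = self.weight.value  # (cout, cin, k, k, k)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    xs = xp[:, :, i : i + s * do : s, j : j + s * ho : s, l : l + s * wo : s]
                    xs = np.ascontiguousarray(xs).reshape(n, cin, m)
                    # (1, cout, cin) @ (n, cin, m) -> (n, cout, m)
                    out += np.matmul(wmat[None, :, :, i, j, l], xs)
        return out.reshape(n, self.cout, do, ho, wo)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._xp is not None and self._xshape is not None
        n, cin, d, h, w = self._xshape
        p, s, k = self.k // 2, self.stride, self.k
        do, ho, wo = dy.shape[2:]
        m = do * ho * wo
        dyf = np.ascontiguousarray(dy, dtype=_F32).reshape(n, self.cout, m)
        self.bias.grad += dyf.sum(axis=(0, 2))
        dxp = np.zeros_like(self._xp) if self.input_grad else None
        wmat = self.weight.value
        dw = self.weight.grad
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    sl = (
                        slice(None),
                        slice(None),
                        slice(i, i + s * do, s),
                        slice(j, j + s * ho, s),
                        slice(l, l + s * wo, s),
                    )
                    xs = np.ascontiguousarray(self._xp[sl]).reshape(n, cin, m)
                    # dW: sum_n dy (cout, m) @ xs.T (m, cin)
                    dw[:, :, i, j, l] += np.einsum("ncm,nim->ci", dyf, xs, optimize=True)
                    if dxp is not None:
                        # dx: (1, cin, cout) @ (n, cout, m)
                        dxs = np.matmul(wmat[None, :, :, i, j, l].transpose(0, 2, 1), dyf)
                        dxp[sl] += dxs.reshape(n, cin, do, ho, wo)
        self._xp = None
        if dxp is None:
            return np.zeros(self._xshape, dtype=_F32)
        if p == 0:
            return dxp
        return dxp[:, :, p : p + d, p : p + h, p : p + w]


class InstanceNorm3d(Layer):
    """Per-sample, per-channel normalization over the spatial axes.

    Learnable affine scale/shift; ``eps`` guards the degenerate constant-input
    case (variance zero) so outputs stay finite.
    """

    def __init__(self, channels: int, eps: float = 1e-5, name: str = "inorm") -> None:
        self.c = channels
        self.eps = eps
        self.gamma = Param(np.ones(channels, dtype=_F32), name=f"{name}.gamma")
        self.beta = Param(np.zeros(channels, dtype=_F32), name=f"{name}.beta")
        self._cache: tuple[np.ndarray, np.ndarray] | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        ax = (2, 3, 4)
        mu = x.mean(axis=ax, keepdims=True)
        var = x.var(axis=ax, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv.astype(_F32))
        g = self.gamma.value[None, :, None, None, None]
        b = self.beta.value[None, :, None, None, None]
        return (g * xhat + b).astype(_F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        xhat, inv = self._cache
        ax = (2, 3, 4)
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3, 4))
        self.beta.grad += dy.sum(axis=(0, 2, 3, 4))
        dxhat = dy * self.gamma.value[None, :, None, None, None]
        m1 = dxhat.mean(axis=ax, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=ax, keepdims=True)
        dx = inv * (dxhat - m1 - xhat * m2)
        self._cache = None
        return dx.astype(_F32)


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(_F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        dx = np.where(self._mask, dy, 0).astype(_F32)
        self._mask = None
        return dx


class UpsampleNearest(Layer):
    """Nearest-neighbour upsampling by an integer factor along each spatial axis."""

    def __init__(self, factor: int = 2) -> None:
        self.f = factor

    def forward(self, x: np.ndarray) -> np.ndarray:
        f = self.f
        return np.repeat(np.repeat(np.repeat(x, f, axis=2), f, axis=3), f, axis=4)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        f = self.f
        n, c, d, h, w = dy.shape
        return (
            dy.reshape(n, c, d // f, f, h // f, f, w // f, f)
            .sum(axis=(3, 5, 7))
            .astype(_F32)
        )


class Linear(Layer):
    def __init__(
        self, in_features: int, out_features: int, *, rng: np.random.Generator, name: str = "fc"
    ) -> None:
        self.weight = Param(
            (rng.standard_normal((out_features, in_features)) / np.sqrt(in_features)).astype(_F32),
            name=f"{name}.weight",
        )
        self.bias = Param(np.zeros(out_features, dtype=_F32), name=f"{name}.bias")
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._x is not None
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        dx = dy @ self.weight.value
        self._x = None
        return dx.astype(_F32)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
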