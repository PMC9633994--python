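"""Minimal NumPy layers for 3D segmentation networks.

Each layer implements ``forward(x)`` and ``backward(grad_out)``; parameters
are :class:`Param` objects whose gradients accumulate during backward.
Convolutions use im2col + BLAS matmul; transposed convolutions restrict to
kernel == stride (non-overlapping block upsampling), which is all the U-Net
decoder needs. Arrays are (N, C, D, H, W) float32 throughout.
"""

from __future__ import annotations

import numpy as np

Triple = tuple[int, int, int]


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv3d(Layer):
    """3D convolution, kernel k (1 or 3), 'same'-style padding (k-1)//2, arbitrary stride."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride: Triple = (1, 1, 1),
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ):
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        fan_in = in_channels * k**3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, in_channels, k, k, k))
        self.weight = Param(w.astype(np.float32), f"{name}.weight")
        self.bias = Param(np.zeros(out_channels, dtype=np.float32), f"{name}.bias")
        self.k = k
        self.pad = (k - 1) // 2
        self.stride = tuple(stride)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def _im2col(self, xp: np.ndarray) -> np.ndarray:
        k, (s0, s1, s2) = self.k, self.stride
        view = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
        view = view[:, :, ::s0, ::s1, ::s2]  # (N, C, Do, Ho, Wo, k, k, k)
        n, c, do, ho, wo = view.shape[:5]
        col = view.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n * do * ho * wo, c * k**3)
        return np.ascontiguousarray(col), (n, do, ho, wo)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}"
            )
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        col, (n, do, ho, wo) = self._im2col(xp)
        wmat = self.weight.value.reshape(self.out_channels, -1)
        y = col @ wmat.T + self.bias.value
        self._cache = (col, x.shape, xp.shape, (n, do, ho, wo))
        return y.reshape(n, do, ho, wo, self.out_channels).transpose(0, 4, 1, 2, 3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        col, x_shape, xp_shape, (n, do, ho, wo) = self._cache
        k, (s0, s1, s2), p = self.k, self.stride, self.pad
        gmat = grad.transpose(0, 2, 3, 4, 1).reshape(-1, self.out_channels)
        self.weight.grad += (gmat.T @ col).reshape(self.weight.value.shape)
        self.bias.grad += gmat.sum(axis=0)
        dcol = gmat @ self.weight.value.reshape(self.out_channels, -1)
        dcol = dcol.reshape(n, do, ho, wo, x_shape[1], k, k, k)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        for kd in range(k):
            for kh in range(k):
                for kw in range(k):
                    dxp[
                        :, :, kd : kd + s0 * do : s0, kh : kh + s1 * ho : s1,
                        kw : kw + s2 * wo : s2,
                    ] += dcol[:, :, :, :, :, kd, kh, kw].transpose(0, 4, 1, 2, 3)
        self._cache = None
        if p:
            return dxp[:, :, p:-p, p:-p, p:-p]
        return dxp


class ConvTranspose3d(Layer):
    """Transposed convolution with kernel == stride: non-overlapping upsampling."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        stride: Triple,
        rng: np.random.Generator | None = None,
        name: str = "up",
    ):
        rng = rng or np.random.default_rng(0)
        k0, k1, k2 = stride
        fan_in = in_channels  # each output voxel sees one input voxel per channel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (in_channels, out_channels, k0, k1, k2))
        self.weight = Param(w.astype(np.float32), f"{name}.weight")
        self.bias = Param(np.zeros(out_channels, dtype=np.float32), f"{name}.bias")
        self.stride = tuple(stride)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, d, h, w_ = x.shape
        k0, k1, k2 = self.stride
        xmat = x.transpose(0, 2, 3, 4, 1).reshape(-1, c)
        wmat = self.weight.value.reshape(c, -1)  # (C_in, C_out*k0*k1*k2)
        y = xmat @ wmat
        y = y.reshape(n, d, h, w_, self.out_channels, k0, k1, k2)
        y = y.transpose(0, 4, 1, 5, 2, 6, 3, 7).reshape(
            n, self.out_channels, d * k0, h * k1, w_ * k2
        )
        y += self.bias.value[None, :, None, None, None]
        self._cache = (x, (n, c, d, h, w_))
        return np.ascontiguousarray(y)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, (n, c, d, h, w_) = self._cache
        k0, k1, k2 = self.stride
        g = grad.reshape(n, self.out_channels, d, k0, h, k1, w_, k2)
        g = g.transpose(0, 2, 4, 6, 1, 3, 5, 7).reshape(-1, self.out_channels * k0 * k1 * k2)
        xmat = x.transpose(0, 2, 3, 4, 1).reshape(-1, c)
        self.weight.grad += (xmat.T @ g).reshape(self.weight.value.shape)
        self.bias.grad += grad.sum(axis=(0, 2, 3, 4))
        dx = g @ self.weight.value.reshape(c, -1).T
        self._cache = None
        return np.ascontiguousarray(
            dx.reshape(n, d, h, w_, c).transpose(0, 4, 1, 2, 3)
        )


class InstanceNorm3d(Layer):
    """Per-sample, per-channel normalization over the spatial axes, with affine."""

    def __init__(self, channels: int, eps: float = 1e-5, name: str = "norm"):
        self.gamma = Param(np.ones(channels, dtype=np.float32), f"{name}.gamma")
        self.beta = Param(np.zeros(channels, dtype=np.float32), f"{name}.beta")
        self.eps = eps
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = (2, 3, 4)
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        std = np.sqrt(var + self.eps)
        xhat = (x - mu) / std
        self._cache = (xhat, std)
        return self.gamma.value[None, :, None, None, None] * xhat + self.beta.value[
            None, :, None, None, None
        ]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, std = self._cache
        axes = (2, 3, 4)
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3, 4))
        self.beta.grad += grad.sum(axis=(0, 2, 3, 4))
        dxhat = grad * self.gamma.value[None, :, None, None, None]
        m1 = dxhat.mean(axis=axes, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=axes, keepdims=True)
        self._cache = None
        return (dxhat - m1 - xhat * m2) / std


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = np.where(self._mask, grad, self.slope * grad)
        self._mask = None
        return out


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Softmax over axis 1 (classes), numerically stabilised."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
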