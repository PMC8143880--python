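"""Layer primitives: conv, depthwise conv, transposed conv, instance norm,
ReLU, max-pool, fixed bilinear upsampling and channel softmax.

Conventions
-----------
* tensors are ``float32`` arrays shaped ``(N, C, H, W)``
* ``forward(x)`` caches intermediates on the instance; ``backward(dy)``
  consumes that cache, accumulates parameter gradients in ``Parameter.grad``
  and returns the gradient w.r.t. the layer input
* parameter gradients accumulate across backward calls until
  ``zero_grad()`` — this is what lets the supervised and consistency terms
  of a training step share one optimizer update
"""

from __future__ import annotations

import numpy as np

from . import _kernels

__all__ = [
    "Parameter",
    "Module",
    "Conv2d",
    "DepthwiseConv2d",
    "ConvTranspose2d",
    "InstanceNorm2d",
    "ReLU",
    "MaxPool2d",
    "BilinearUp2d",
    "Softmax2d",
    "Sequential",
]


class Parameter:
    """A trainable array plus its accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base class; submodules and parameters are discovered by attribute walk."""

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix=full + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")

    def modules(self):
        yield self
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield from item.modules()

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def num_params(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data[...] = arr

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    """3x3 (pad 1) or 1x1 convolution, stride 1."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 bias: bool = True, rng: np.random.Generator | None = None):
        if kernel_size not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are supported")
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(
            _he_init(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in)
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        if C != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {C}")
        O = self.out_channels
        if self.kernel_size == 1:
            wmat = self.weight.data.reshape(O, C)
            y = np.matmul(wmat, x.reshape(N, C, H * W))
            self._cache = ("1x1", x.reshape(N, C, H * W), (N, C, H, W))
        else:
            cols = _kernels.im2col3(np.ascontiguousarray(x))
            wmat = self.weight.data.reshape(O, C * 9)
            y = np.matmul(wmat, cols)
            self._cache = ("3x3", cols, (N, C, H, W))
        if self.bias is not None:
            y += self.bias.data[None, :, None]
        return y.reshape(N, O, H, W)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        kind, cols, (N, C, H, W) = self._cache
        O = self.out_channels
        dyf = dy.reshape(N, O, H * W)
        if self.bias is not None:
            self.bias.grad += dyf.sum(axis=(0, 2))
        # dW = sum_n dY[n] @ cols[n]^T as one batched GEMM
        dw = np.matmul(dyf, cols.transpose(0, 2, 1)).sum(axis=0)
        if kind == "1x1":
            # cols here is x reshaped (N, C, HW)
            self.weight.grad += dw.reshape(self.weight.data.shape)
            wmat = self.weight.data.reshape(O, C)
            dx = np.matmul(wmat.T, dyf)
            return dx.reshape(N, C, H, W)
        self.weight.grad += dw.reshape(self.weight.data.shape)
        wmat = self.weight.data.reshape(O, C * 9)
        dcols = np.matmul(wmat.T, dyf)
        return _kernels.col2im3(dcols, H, W)


class DepthwiseConv2d(Module):
    """Per-channel 3x3 convolution (pad 1, stride 1) — the Ghost cheap transform."""

    def __init__(self, channels: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.channels = channels
        self.weight = Parameter(_he_init(rng, (channels, 3, 3), 9))
        self.bias = Parameter(np.zeros(channels)) if bias else None
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        if C != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {C}")
        x = np.ascontiguousarray(x)
        y = _kernels.depthwise_fwd(x, self.weight.data)
        if self.bias is not None:
            y += self.bias.data[None, :, None, None]
        self._cache = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        dx, dw = _kernels.depthwise_bwd(x, self.weight.data, np.ascontiguousarray(dy))
        self.weight.grad += dw
        return dx


class ConvTranspose2d(Module):
    """2x2 stride-2 transposed convolution (learnable upsampling)."""

    def __init__(self, in_channels: int, out_channels: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.weight = Parameter(
            _he_init(rng, (in_channels, out_channels, 2, 2), in_channels)
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        if C != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {C}")
        O = self.out_channels
        y = np.empty((N, O, 2 * H, 2 * W), dtype=x.dtype)
        xf = x.reshape(N, C, H * W)
        for i in range(2):
            for j in range(2):
                out = np.matmul(self.weight.data[:, :, i, j].T, xf).reshape(N, O, H, W)
                y[:, :, i::2, j::2] = out
        if self.bias is not None:
            y += self.bias.data[None, :, None, None]
        self._cache = (xf, (N, C, H, W))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xf, (N, C, H, W) = self._cache
        O = self.out_channels
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        dx = np.zeros((N, C, H * W), dtype=dy.dtype)
        for i in range(2):
            for j in range(2):
                dyf = np.ascontiguousarray(dy[:, :, i::2, j::2]).reshape(N, O, H * W)
                self.weight.grad[:, :, i, j] += np.matmul(
                    xf, dyf.transpose(0, 2, 1)
                ).sum(axis=0)
                dx += np.matmul(self.weight.data[:, :, i, j], dyf)
        return dx.reshape(N, C, H, W)


class InstanceNorm2d(Module):
    """Affine instance normalization (statistics per sample and channel)."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.channels = channels
        self.eps = eps
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.data[None, :, None, None]
        m1 = dxhat.mean(axis=(2, 3), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
        return inv * (dxhat - m1 - xhat * m2)


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class MaxPool2d(Module):
    """2x2 max pooling, stride 2."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError("spatial size must be even for 2x2 pooling")
        xr = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(N, C, H // 2, W // 2, 4)
        self._argmax = xr.argmax(axis=-1)
        self._shape = (N, C, H, W)
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, C, H, W = self._shape
        flat = np.zeros((N, C, H // 2, W // 2, 4), dtype=dy.dtype)
        np.put_along_axis(flat, self._argmax[..., None], dy[..., None], axis=-1)
        flat = flat.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return flat.reshape(N, C, H, W)


_BILINEAR_TAPS = np.array([0.25, 0.75, 0.75, 0.25], dtype=np.float32)


class BilinearUp2d(Module):
    """Fixed x2 bilinear upsampling (no trainable parameters).

    Realized as a depthwise transposed convolution with the separable kernel
    ``outer([1,3,3,1]/4)``, stride 2, crop 1 — the usual half-pixel-aligned
    bilinear interpolant away from the border.
    """

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        full = np.zeros((N, C, 2 * H + 2, 2 * W + 2), dtype=x.dtype)
        for i in range(4):
            for j in range(4):
                full[:, :, i : i + 2 * H : 2, j : j + 2 * W : 2] += (
                    x * (_BILINEAR_TAPS[i] * _BILINEAR_TAPS[j])
                )
        self._shape = (N, C, H, W)
        return full[:, :, 1 : 1 + 2 * H, 1 : 1 + 2 * W]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, C, H, W = self._shape
        dyp = np.pad(dy, ((0, 0), (0, 0), (1, 1), (1, 1)))
        dx = np.zeros((N, C, H, W), dtype=dy.dtype)
        for i in range(4):
            for j in range(4):
                dx += dyp[:, :, i : i + 2 * H : 2, j : j + 2 * W : 2] * (
                    _BILINEAR_TAPS[i] * _BILINEAR_TAPS[j]
                )
        return dx


class Softmax2d(Module):
    """Channel-wise softmax, turning logits into a per-pixel probability map."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=1, keepdims=True)
        self._p = p
        return p

    def backward(self, dp: np.ndarray) -> np.ndarray:
        p = self._p
        inner = (dp * p).sum(axis=1, keepdims=True)
        return p * (dp - inner)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy
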