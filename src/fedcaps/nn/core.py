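"""Minimal deterministic neural-network stack on numpy.

Layers implement explicit ``forward``/``backward`` passes; a :class:`Module`
aggregates layers and exposes its parameters as one canonically ordered flat
float64 vector plus a shape registry (the serialization the model ledger
digests).  Everything is seeded and single-threaded-deterministic: the same
seed and inputs reproduce the same weights bit for bit.

Array layout is (batch, channels, height, width) for images.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "MaxPool2",
    "Linear",
    "Module",
    "Adam",
]


class Layer:
    """Base class: parameters and their gradients live in parallel dicts."""

    def __init__(self) -> None:
        self.params: "OrderedDict[str, np.ndarray]" = OrderedDict()
        self.grads: "OrderedDict[str, np.ndarray]" = OrderedDict()

    def init(self, rng: np.random.Generator) -> None:  # pragma: no cover
        pass

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


class Conv2d(Layer):
    """Same-padding 2D convolution (stride 1) via im2col."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3):
        super().__init__()
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        self.pad = kernel // 2
        self.params["W"] = np.zeros((out_ch, in_ch * kernel * kernel))
        self.params["b"] = np.zeros(out_ch)

    def init(self, rng: np.random.Generator) -> None:
        fan_in = self.in_ch * self.k * self.k
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=self.params["W"].shape
        )
        self.params["b"] = np.zeros(self.out_ch)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        # (B, C, H, W, k, k) -> (B*H*W, C*k*k)
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * W, C * self.k * self.k)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, C, H, W = x.shape
        cols = self._im2col(x)
        out = cols @ self.params["W"].T + self.params["b"]
        if train:
            self._cache = (cols, x.shape)
        return out.reshape(B, H, W, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, (B, C, H, W) = self._cache
        dmat = dout.transpose(0, 2, 3, 1).reshape(B * H * W, self.out_ch)
        self.grads["W"] = dmat.T @ cols
        self.grads["b"] = dmat.sum(axis=0)
        dcols = dmat @ self.params["W"]  # (B*H*W, C*k*k)
        dcols = dcols.reshape(B, H, W, C, self.k, self.k)
        dxp = np.zeros((B, C, H + 2 * self.pad, W + 2 * self.pad))
        for di in range(self.k):
            for dj in range(self.k):
                dxp[:, :, di : di + H, dj : dj + W] += dcols[:, :, :, :, di, dj].transpose(
                    0, 3, 1, 2
                )
        if self.pad:
            return dxp[:, :, self.pad : -self.pad, self.pad : -self.pad]
        return dxp


class ConvTranspose2d(Layer):
    """Kernel-2 stride-2 transposed convolution (exact 2x upsampling)."""

    def __init__(self, in_ch: int, out_ch: int):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.params["W"] = np.zeros((in_ch, out_ch, 2, 2))
        self.params["b"] = np.zeros(out_ch)

    def init(self, rng: np.random.Generator) -> None:
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / self.in_ch), size=self.params["W"].shape
        )
        self.params["b"] = np.zeros(self.out_ch)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, C, H, W = x.shape
        if train:
            self._cache = x
        y = np.einsum("bchw,codk->bohdwk", x, self.params["W"])
        y = y.reshape(B, self.out_ch, 2 * H, 2 * W)
        return y + self.params["b"][None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        B, C, H, W = x.shape
        d = dout.reshape(B, self.out_ch, H, 2, W, 2)
        self.grads["W"] = np.einsum("bchw,bohdwk->codk", x, d)
        self.grads["b"] = dout.sum(axis=(0, 2, 3))
        return np.einsum("bohdwk,codk->bchw", d, self.params["W"])


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics for eval."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv, x.shape)
        return (
            self.params["gamma"][None, :, None, None] * xhat
            + self.params["beta"][None, :, None, None]
        )

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        n = shape[0] * shape[2] * shape[3]
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dout.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        dxhat = dout * g
        term = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / n
        )
        return term * inv[None, :, None, None]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = 1.0 / (1.0 + np.exp(-np.clip(x, -50, 50)))
        if train:
            self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._out * (1.0 - self._out)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; spatial dims must be even."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, C, H, W = x.shape
        win = x.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = win.reshape(B, C, H // 2, W // 2, 4)
        out = flat.max(axis=-1)
        if train:
            is_max = flat == out[..., None]
            first = np.cumsum(is_max, axis=-1) == 1   # first max wins ties
            self._mask = is_max & first
            self._shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, H, W = self._shape
        d = dout[..., None] * self._mask                       # (B,C,H2,W2,4)
        d = d.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return d.reshape(B, C, H, W)


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int):
        super().__init__()
        self.in_dim, self.out_dim = in_dim, out_dim
        self.params["W"] = np.zeros((out_dim, in_dim))
        self.params["b"] = np.zeros(out_dim)

    def init(self, rng: np.random.Generator) -> None:
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / self.in_dim), size=self.params["W"].shape
        )
        self.params["b"] = np.zeros(self.out_dim)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = dout.T @ self._x
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"]


class Module:
    """A named, ordered collection of layers (and sub-modules).

    The parameter registry is the flattened, registration-ordered list of
    ``(qualified_name, shape)`` pairs; ``get_flat``/``set_flat`` round-trip
    all parameters through one float64 vector in registry order.
    """

    def __init__(self) -> None:
        self._children: "OrderedDict[str, Layer | Module]" = OrderedDict()

    def add(self, name: str, child: "Layer | Module"):
        self._children[name] = child
        return child

    def named_layers(self, prefix: str = ""):
        for name, child in self._children.items():
            qual = f"{prefix}{name}"
            if isinstance(child, Module):
                yield from child.named_layers(qual + ".")
            else:
                yield qual, child

    def named_parameters(self):
        for lname, layer in self.named_layers():
            for pname, arr in layer.params.items():
                yield f"{lname}.{pname}", layer, pname, arr

    def shape_registry(self) -> list[tuple[str, tuple[int, ...]]]:
        return [(name, arr.shape) for name, _, _, arr in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(arr.size for _, _, _, arr in self.named_parameters())

    def get_flat(self) -> np.ndarray:
        parts = [arr.ravel() for _, _, _, arr in self.named_parameters()]
        if not parts:
            return np.zeros(0)
        return np.concatenate(parts).astype(np.float64)

    def set_flat(self, vec: np.ndarray) -> None:
        vec = np.asarray(vec, dtype=np.float64)
        if vec.size != self.n_parameters():
            raise ValueError(
                f"flat vector length {vec.size} != parameter count {self.n_parameters()}"
            )
        offset = 0
        for _, layer, pname, arr in self.named_parameters():
            layer.params[pname] = vec[offset : offset + arr.size].reshape(arr.shape).copy()
            offset += arr.size

    def grad_flat(self) -> np.ndarray:
        parts = []
        for _, layer, pname, arr in self.named_parameters():
            g = layer.grads.get(pname)
            parts.append((g if g is not None else np.zeros_like(arr)).ravel())
        return np.concatenate(parts) if parts else np.zeros(0)

    def zero_grad(self) -> None:
        for _, layer in self.named_layers():
            layer.zero_grad()

    def init_params(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        for _, layer in self.named_layers():
            layer.init(rng)


class Adam:
    """Adaptive-moment optimizer over a module's flat parameter vector."""

    def __init__(self, module: Module, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.module = module
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        n = module.n_parameters()
        self.m = np.zeros(n)
        self.v = np.zeros(n)
        self.t = 0

    def step(self) -> None:
        g = self.module.grad_flat()
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * g
        self.v = self.beta2 * self.v + (1 - self.beta2) * g * g
        mhat = self.m / (1 - self.beta1**self.t)
        vhat = self.v / (1 - self.beta2**self.t)
        w = self.module.get_flat()
        self.module.set_flat(w - self.lr * mhat / (np.sqrt(vhat) + self.eps))
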