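"""Differentiable layers with hand-written backward passes.

Layers operate on ``(N, C, H, W)`` float64 batches. Each trainable layer
exposes ``params`` / ``grads`` as parallel lists so the SGD loop can update
in place. ``backward`` consumes the gradient of the loss w.r.t. the layer
output and returns the gradient w.r.t. its input.
"""

from __future__ import annotations

import numpy as np

from .ops import im2col, output_size, relu, relu_deriv, sigmoid

__all__ = [
    "Layer",
    "Conv2D",
    "MaxPool2",
    "BilinearUpsample",
    "Flatten",
    "Dense",
    "apply_activation",
]


def apply_activation(z: np.ndarray, activation: str | None):
    if activation is None or activation == "none":
        return z
    if activation == "relu":
        return relu(z)
    if activation == "sigmoid":
        return sigmoid(z)
    raise ValueError(f"unknown activation {activation!r}")


def _activation_grad(grad: np.ndarray, z: np.ndarray, out: np.ndarray, activation):
    if activation is None or activation == "none":
        return grad
    if activation == "relu":
        return grad * relu_deriv(z)
    if activation == "sigmoid":
        return grad * out * (1.0 - out)
    raise ValueError(f"unknown activation {activation!r}")


class Layer:
    """Base class: parameter-free identity."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def init_weights(self, rng: np.random.Generator) -> None:  # pragma: no cover
        pass

    def forward(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """2-D cross-correlation with stride/padding/dilation and fused activation."""

    def __init__(
        self,
        in_maps: int,
        out_maps: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        dilation: int = 1,
        activation: str | None = "relu",
    ) -> None:
        super().__init__()
        self.in_maps = in_maps
        self.out_maps = out_maps
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.dilation = dilation
        self.activation = activation
        self.weight = np.zeros(
            (out_maps, in_maps, kernel_size, kernel_size), dtype=np.float64
        )
        self.bias = np.zeros(out_maps, dtype=np.float64)
        self.params = [self.weight, self.bias]
        self.grads = [np.zeros_like(self.weight), np.zeros_like(self.bias)]

    def init_weights(self, rng: np.random.Generator) -> None:
        # He-style uniform bound: keeps activation variance stable under ReLU
        fan_in = self.in_maps * self.kernel_size**2
        a = np.sqrt(6.0 / fan_in)
        self.weight[...] = rng.uniform(-a, a, size=self.weight.shape)
        self.bias[...] = 0.0

    def out_size(self, i: int) -> int:
        return output_size(i, self.kernel_size, self.padding, self.stride, self.dilation)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n = x.shape[0]
        cols, ho, wo = im2col(x, self.kernel_size, self.stride, self.padding, self.dilation)
        z = cols @ self.weight.reshape(self.out_maps, -1).T + self.bias
        z = z.reshape(n, ho, wo, self.out_maps).transpose(0, 3, 1, 2)
        self._x_shape = x.shape
        self._cols = cols
        self._z = z
        self._out = apply_activation(z, self.activation)
        return self._out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = _activation_grad(grad, self._z, self._out, self.activation)
        n, _, ho, wo = grad.shape
        gr = grad.transpose(0, 2, 3, 1).reshape(-1, self.out_maps)
        self.grads[0][...] = (gr.T @ self._cols).reshape(self.weight.shape)
        self.grads[1][...] = gr.sum(axis=0)
        dcols = gr @ self.weight.reshape(self.out_maps, -1)
        # col2im: scatter patch-row gradients back onto the padded input grid
        _, c, h, w = self._x_shape
        p, s, d, q = self.padding, self.stride, self.dilation, self.kernel_size
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float64)
        dpatch = dcols.reshape(n, ho, wo, c, q, q).transpose(0, 3, 4, 5, 1, 2)
        for a in range(q):
            for b in range(q):
                dxp[
                    :,
                    :,
                    a * d : a * d + s * ho : s,
                    b * d : b * d + s * wo : s,
                ] += dpatch[:, :, a, b]
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        return dxp


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; odd trailing rows/cols are dropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        ho, wo = h // 2, w // 2
        self._x_shape = x.shape
        xr = x[:, :, : 2 * ho, : 2 * wo]
        blocks = xr.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5)
        blocks = blocks.reshape(n, c, ho, wo, 4)
        self._argmax = blocks.argmax(axis=-1)
        return np.take_along_axis(blocks, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, ho, wo = grad.shape
        dblocks = np.zeros((n, c, ho, wo, 4), dtype=np.float64)
        np.put_along_axis(dblocks, self._argmax[..., None], grad[..., None], axis=-1)
        dx = np.zeros(self._x_shape, dtype=np.float64)
        dxr = dblocks.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx[:, :, : 2 * ho, : 2 * wo] = dxr.reshape(n, c, 2 * ho, 2 * wo)
        return dx


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic linear-interpolation matrix, corners aligned."""
    mat = np.zeros((n_out, n_in), dtype=np.float64)
    if n_in == 1 or n_out == 1:
        mat[:, 0] = 1.0
        return mat
    src = np.arange(n_out) * (n_in - 1) / (n_out - 1)
    i0 = np.minimum(src.astype(int), n_in - 2)
    frac = src - i0
    mat[np.arange(n_out), i0] += 1.0 - frac
    mat[np.arange(n_out), i0 + 1] += frac
    return mat


class BilinearUpsample(Layer):
    """Bilinear interpolation to a target spatial size (a fixed linear map)."""

    def __init__(self, target: tuple[int, int] | None = None) -> None:
        super().__init__()
        self.target = target
        self._cache: dict[tuple[int, int, int, int], tuple[np.ndarray, np.ndarray]] = {}

    def set_target(self, target: tuple[int, int]) -> None:
        self.target = (int(target[0]), int(target[1]))

    def _matrices(self, h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
        key = (h, w, *self.target)
        if key not in self._cache:
            self._cache[key] = (
                _interp_matrix(h, self.target[0]),
                _interp_matrix(w, self.target[1]),
            )
        return self._cache[key]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.target is None:
            raise RuntimeError("upsample target not set")
        a, b = self._matrices(x.shape[2], x.shape[3])
        self._ab = (a, b)
        return a @ x @ b.T

    def backward(self, grad: np.ndarray) -> np.ndarray:
        a, b = self._ab
        return a.T @ grad @ b


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._x_shape)


class Dense(Layer):
    """Fully connected layer on flattened features, with fused activation."""

    def __init__(self, in_features: int, out_features: int, activation: str | None = None):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.activation = activation
        self.weight = np.zeros((out_features, in_features), dtype=np.float64)
        self.bias = np.zeros(out_features, dtype=np.float64)
        self.params = [self.weight, self.bias]
        self.grads = [np.zeros_like(self.weight), np.zeros_like(self.bias)]

    def init_weights(self, rng: np.random.Generator) -> None:
        a = 1.0 / np.sqrt(self.in_features)
        self.weight[...] = rng.uniform(-a, a, size=self.weight.shape)
        self.bias[...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._z = x @ self.weight.T + self.bias
        self._out = apply_activation(self._z, self.activation)
        return self._out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = _activation_grad(grad, self._z, self._out, self.activation)
        self.grads[0][...] = grad.T @ self._x
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.weight
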