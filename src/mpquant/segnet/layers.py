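"""Minimal convolutional layers with hand-written backpropagation.

Everything operates on float32 arrays in NCHW layout.  Each layer caches
what its backward pass needs during forward; ``backward`` consumes the
gradient of the loss w.r.t. its output and returns the gradient w.r.t. its
input, accumulating parameter gradients in ``grads``.  Gradients are
verified against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2d", "ReLU", "MaxPool2", "UpsampleNearest2", "Layer"]


class Layer:
    """Base class: parameter-free layers inherit the empty containers."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0


class Conv2d(Layer):
    """k x k convolution, stride 1, same padding, via im2col matmul."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        if k % 2 != 1:
            raise ValueError("kernel size must be odd (same padding)")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k * k
        # He initialization, suited to the ReLU nonlinearity
        w = rng.standard_normal((c_out, fan_in)) * np.sqrt(2.0 / fan_in)
        self.params = {
            "w": w.astype(np.float32),
            "b": np.zeros(c_out, dtype=np.float32),
        }
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # n,c,h,w,k,k
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
        self._cols = cols
        self._xshape = x.shape
        y = cols @ self.params["w"].T + self.params["b"]
        return y.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        k, p = self.k, self.k // 2
        dyf = dy.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.grads["w"] += (dyf.T @ self._cols).astype(np.float32)
        self.grads["b"] += dyf.sum(axis=0).astype(np.float32)
        dcols = dyf @ self.params["w"]  # (n*h*w, c*k*k)
        dcols = dcols.reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, p : p + h, p : p + w]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; spatial dims must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2 needs even spatial dimensions")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._argmax = xr.argmax(axis=-1)
        self._inshape = x.shape
        return xr.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._inshape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dxr, self._argmax[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)


class UpsampleNearest2(Layer):
    """Nearest-neighbour 2x upsampling; backward sums each 2x2 block."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return (
            dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5)).astype(np.float32)
        )
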