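"""Minimal NumPy layers with explicit backpropagation for 3D segmentation.

No deep-learning framework is assumed: convolutions are lowered to matrix
multiplies (im2col) so BLAS does the heavy lifting, and every layer
implements ``forward``/``backward`` by hand. This is deliberately a small,
CPU-only engine sized for desk-scale volumes (tens of voxels per side); it
trades generality (no strides, no dilation, single sample at a time) for
being auditable and dependency-free.

Tensors are channel-first: inputs are (C, D, H, W) float32 arrays.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv3d",
    "InstanceNorm3d",
    "ReLU",
    "Sigmoid",
    "MaxPool3d",
    "Upsample3d",
    "Adam",
    "gradient_check",
]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(C, D, H, W) -> (D*H*W, C*k^3) patch matrix with 'same' zero padding."""
    if k == 1:
        c = x.shape[0]
        return np.ascontiguousarray(x.reshape(c, -1).T)
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))  # (C, D, H, W, k, k, k)
    d, h, w = x.shape[1:]
    cols = win.transpose(1, 2, 3, 0, 4, 5, 6).reshape(d * h * w, x.shape[0] * k**3)
    return np.ascontiguousarray(cols)


class Layer:
    """Base: forward caches what backward needs; params() yields state dicts."""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[dict]:
        return []


class Conv3d(Layer):
    """k×k×k convolution, stride 1, 'same' zero padding, He-initialized."""

    def __init__(self, cin: int, cout: int, k: int = 3, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = cin * k**3
        self.W = (rng.standard_normal((fan_in, cout)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        d, h, w = x.shape[1:]
        cols = _im2col(x, self.k)
        y = cols @ self.W + self.b
        return np.ascontiguousarray(y.T.reshape(self.cout, d, h, w))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        assert x is not None, "forward() must run before backward()"
        d, h, w = x.shape[1:]
        gmat = grad.reshape(self.cout, -1).T  # (DHW, cout)
        cols = _im2col(x, self.k)  # recomputed: trades FLOPs for memory
        self.dW += cols.T @ gmat
        self.db += gmat.sum(axis=0)
        # dL/dx = 'same' correlation of grad with the spatially flipped,
        # channel-transposed kernel (stride 1, odd k, symmetric padding)
        Wk = self.W.reshape(self.cin, self.k, self.k, self.k, self.cout)
        Wb = Wk[:, ::-1, ::-1, ::-1, :].transpose(4, 1, 2, 3, 0).reshape(
            self.cout * self.k**3, self.cin
        )
        dx = _im2col(grad, self.k) @ np.ascontiguousarray(Wb)
        return np.ascontiguousarray(dx.T.reshape(self.cin, d, h, w))

    def params(self) -> list[dict]:
        return [
            {"value": self.W, "grad": self.dW},
            {"value": self.b, "grad": self.db},
        ]


class InstanceNorm3d(Layer):
    """Per-channel normalization over the spatial volume, with affine."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.eps = eps
        self._xhat: np.ndarray | None = None
        self._inv_sd: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        var = x.var(axis=(1, 2, 3), keepdims=True)
        inv_sd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_sd
        self._xhat, self._inv_sd = xhat, inv_sd
        return (self.gamma[:, None, None, None] * xhat + self.beta[:, None, None, None]).astype(
            np.float32
        )

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_sd = self._xhat, self._inv_sd
        assert xhat is not None
        self.dgamma += (grad * xhat).sum(axis=(1, 2, 3))
        self.dbeta += grad.sum(axis=(1, 2, 3))
        g = grad * self.gamma[:, None, None, None]
        m = g.mean(axis=(1, 2, 3), keepdims=True)
        mx = (g * xhat).mean(axis=(1, 2, 3), keepdims=True)
        return ((g - m - xhat * mx) * inv_sd).astype(np.float32)

    def params(self) -> list[dict]:
        return [
            {"value": self.gamma, "grad": self.dgamma},
            {"value": self.beta, "grad": self.dbeta},
        ]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._y * (1.0 - self._y)


class MaxPool3d(Layer):
    """2×2×2 max pooling; spatial dims must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        assert d % 2 == 0 and h % 2 == 0 and w % 2 == 0, "pooling needs even dims"
        blocks = (
            x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 3, 5, 2, 4, 6)
            .reshape(c, d // 2, h // 2, w // 2, 8)
        )
        self._idx = blocks.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(blocks, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        c, d, h, w = self._in_shape
        blocks = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=grad.dtype)
        np.put_along_axis(blocks, self._idx[..., None], grad[..., None], axis=-1)
        return (
            blocks.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3, 6)
            .reshape(c, d, h, w)
        )


class Upsample3d(Layer):
    """Nearest-neighbour ×2 upsampling; backward sums each 2×2×2 block."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        c, d, h, w = grad.shape
        return grad.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(2, 4, 6))


class Adam:
    """Adam over the parameter dicts exposed by ``Layer.params()``."""

    def __init__(self, params: list[dict], lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p["value"]) for p in params]
        self._v = [np.zeros_like(p["value"]) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p["grad"][...] = 0.0

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            g = p["grad"]
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p["value"] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def gradient_check(layer: Layer, x: np.ndarray, eps: float = 1e-3) -> float:
    """Max relative error between analytic and central-difference input
    gradients of sum(layer(x)**2)/2 — a development/testing aid."""
    y = layer.forward(x)
    analytic = layer.backward(y.copy())
    num = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        yp = float((layer.forward(x) ** 2).sum()) / 2
        x[i] = orig - eps
        ym = float((layer.forward(x) ** 2).sum()) / 2
        x[i] = orig
        num[i] = (yp - ym) / (2 * eps)
    layer.forward(x)  # restore caches
    denom = np.maximum(np.abs(analytic) + np.abs(num), 1e-8)
    return float((np.abs(analytic - num) / denom).max())
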