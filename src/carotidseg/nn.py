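"""Minimal CPU neural-network layer library (numpy, NCHW, float64).

Implements exactly the operations the residual U-net needs — padded 3×3 and
1×1 convolutions (im2col), batch normalization, PReLU, 2×2 average pooling,
nearest-neighbour 2× upsampling, channel (2D) dropout, channel concatenation
— each as a layer object with an explicit ``forward``/``backward`` pair, plus
the Adam optimizer.  Layers cache what their backward pass needs on forward,
so the usage pattern is forward → loss gradient → backward, every step.

Everything is pure numpy, hence bit-deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Layer", "Conv2d", "BatchNorm2d", "PReLU", "AvgPool2x2",
    "UpsampleNearest2x", "Dropout2d", "Adam",
]


class Param:
    """A learnable tensor and its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    def parameters(self) -> list:
        return []


class Conv2d(Layer):
    """k×k convolution, stride 1, 'same' zero padding, via im2col."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 name: str = "conv"):
        fan_in = cin * k * k
        # He initialization, appropriate for rectifier activations
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k))
        self.W = Param(w, f"{name}.W")
        self.b = Param(np.zeros(cout), f"{name}.b")
        self.k, self.cin, self.cout = k, cin, cout
        self.pad = (k - 1) // 2
        self._cache = None

    def parameters(self):
        return [self.W, self.b]

    def _wmat(self) -> np.ndarray:
        # (k*k*cin, cout), row order matching the im2col layout below
        return self.W.value.transpose(2, 3, 1, 0).reshape(self.k * self.k * self.cin,
                                                          self.cout)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.k, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = np.empty((n, k * k * c, h * w), dtype=x.dtype)
        for di in range(k):
            for dj in range(k):
                block = x[:, :, di:di + h, dj:dj + w].reshape(n, c, h * w)
                cols[:, (di * k + dj) * c:(di * k + dj + 1) * c, :] = block
        return cols

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        cols = self._im2col(x)
        wm = self._wmat()
        y = np.matmul(wm.T[None], cols)          # (n, cout, h*w)
        y += self.b.value[None, :, None]
        if train:
            self._cache = (cols, x.shape)
        return y.reshape(n, self.cout, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, c, h, w = xshape
        k, p = self.k, self.pad
        dyf = dy.reshape(n, self.cout, h * w)
        dwm = np.einsum("nkp,nop->ko", cols, dyf)
        self.W.grad += dwm.reshape(k, k, c, self.cout).transpose(3, 2, 0, 1)
        self.b.grad += dyf.sum(axis=(0, 2))
        dcols = np.matmul(self._wmat()[None], dyf)  # (n, k*k*c, h*w)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dy.dtype)
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di:di + h, dj:dj + w] += (
                    dcols[:, (di * k + dj) * c:(di * k + dj + 1) * c, :]
                    .reshape(n, c, h, w))
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics for eval."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5,
                 name: str = "bn"):
        self.gamma = Param(np.ones(c), f"{name}.gamma")
        self.beta = Param(np.zeros(c), f"{name}.beta")
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        if train:
            self._cache = (xhat, invstd, x.shape)
        return self.gamma.value[None, :, None, None] * xhat \
            + self.beta.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd, xshape = self._cache
        n, c, h, w = xshape
        m = n * h * w
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        dxhat = dy * g
        # standard batch-norm backward over the (N, H, W) reduction axes
        sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (invstd[None, :, None, None] / m) * (
            m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)
        return dx


class PReLU(Layer):
    """Parametric ReLU with one learned negative slope per channel."""

    def __init__(self, c: int, init: float = 0.25, name: str = "prelu"):
        self.a = Param(np.full(c, init), f"{name}.a")
        self._cache = None

    def parameters(self):
        return [self.a]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._cache = x
        a = self.a.value[None, :, None, None]
        return np.where(x > 0, x, a * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        neg = x <= 0
        self.a.grad += (dy * np.where(neg, x, 0.0)).sum(axis=(0, 2, 3))
        a = self.a.value[None, :, None, None]
        return dy * np.where(neg, a, 1.0)


class AvgPool2x2(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) / 4.0


class UpsampleNearest2x(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Dropout2d(Layer):
    """Channel dropout: whole feature maps are zeroed with probability p."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout p must be in [0,1), got {p}")
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape[:2]) < keep) / keep
        self._mask = mask[:, :, None, None]
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class Adam:
    """Adam optimizer with an externally supplied per-step learning rate."""

    def __init__(self, params: list, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
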