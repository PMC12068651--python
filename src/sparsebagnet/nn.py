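"""Minimal convolutional-network engine (forward + backprop) on numpy.

Only what a bag-of-local-features classifier needs: valid (unpadded) 2-D
convolutions via im2col, ReLU, residual blocks of 1x1 convolutions, and
SGD with momentum.  Arrays are NCHW float32 throughout.  Everything is
seeded explicitly; there is no global random state.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "BatchNorm2d", "ReLU", "Residual", "Sequential", "SGD"]


def _im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*k*k, L) column view of all valid kxk windows."""
    n, c, h, w = x.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, ho, wo, k, k)
    col = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo)
    return np.ascontiguousarray(col)


class Conv2d:
    """Valid convolution, optional ReLU fused for brevity elsewhere."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 use_bias: bool = True):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride = kernel, stride
        self.use_bias = use_bias
        self.weight = np.zeros((out_ch, in_ch, kernel, kernel), np.float32)
        self.bias = np.zeros(out_ch, np.float32)
        self._cache = None

    def init_params(self, rng: np.random.Generator) -> None:
        fan_in = self.in_ch * self.kernel * self.kernel
        scale = np.sqrt(2.0 / fan_in)
        self.weight = rng.normal(0.0, scale, self.weight.shape).astype(np.float32)
        self.bias = np.zeros(self.out_ch, np.float32)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        k, s = self.kernel, self.stride
        if h < k or w < k:
            raise ValueError(f"input {h}x{w} smaller than kernel {k}")
        ho = (h - k) // s + 1
        wo = (w - k) // s + 1
        col = _im2col(x, k, s)  # (N, C*k*k, L)
        wmat = self.weight.reshape(self.out_ch, -1)
        out = np.matmul(wmat[None], col) + self.bias[None, :, None]
        if train:
            self._cache = (x.shape, col)
        return out.reshape(n, self.out_ch, ho, wo)

    def backward(self, dout: np.ndarray):
        x_shape, col = self._cache
        n, c, h, w = x_shape
        k, s = self.kernel, self.stride
        no, co, ho, wo = dout.shape
        dflat = dout.reshape(n, co, ho * wo)
        wmat = self.weight.reshape(co, -1)
        self.dweight = np.einsum("ncl,nkl->ck", dflat, col).reshape(self.weight.shape)
        self.dbias = dflat.sum(axis=(0, 2)) if self.use_bias else np.zeros_like(self.bias)
        dcol = np.matmul(wmat.T[None], dflat)  # (N, C*k*k, L)
        dcol = dcol.reshape(n, c, k, k, ho, wo)
        dx = np.zeros(x_shape, np.float32)
        for ki in range(k):
            for kj in range(k):
                dx[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += dcol[:, :, ki, kj]
        self._cache = None
        return dx

    def params(self):
        if not self.use_bias:
            return [(self, "weight")]
        return [(self, "weight"), (self, "bias")]


class BatchNorm2d:
    """Per-channel batch normalization with learned affine and running stats.

    Training uses batch statistics; inference uses the running averages, so
    evaluation stays a per-pixel affine map (patchwise locality preserved).
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = np.ones(channels, np.float32)
        self.beta = np.zeros(channels, np.float32)
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)
        self._cache = None

    def forward(self, x, train: bool = False):
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean + self.momentum * mu).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var + self.momentum * var).astype(np.float32)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        out = self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return out.astype(np.float32)

    def backward(self, dout):
        xhat, inv = self._cache
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dgamma = (dout * xhat).sum(axis=(0, 2, 3))
        self.dbeta = dout.sum(axis=(0, 2, 3))
        g = (self.gamma * inv)[None, :, None, None]
        dx = g * (
            dout
            - (self.dbeta / m)[None, :, None, None]
            - xhat * (self.dgamma / m)[None, :, None, None]
        )
        self._cache = None
        return dx.astype(np.float32)

    def params(self):
        return [(self, "gamma"), (self, "beta")]

    def extra_state(self):
        return [self.running_mean, self.running_var]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x, train: bool = False):
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout):
        dx = dout * self._mask
        self._mask = None
        return dx

    def params(self):
        return []


class Residual:
    """y = relu(x + branch(x)); branch layers must preserve shape (1x1, s=1)."""

    def __init__(self, branch: list):
        self.branch = branch
        self._relu = ReLU()

    def forward(self, x, train: bool = False):
        y = x
        for layer in self.branch:
            y = layer.forward(y, train=train)
        if y.shape != x.shape:
            raise ValueError("residual branch must preserve tensor shape")
        return self._relu.forward(x + y, train=train)

    def backward(self, dout):
        d = self._relu.backward(dout)
        dy = d
        for layer in reversed(self.branch):
            dy = layer.backward(dy)
        return d + dy

    def params(self):
        out = []
        for layer in self.branch:
            out.extend(layer.params())
        return out


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x, train: bool = False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def init_params(self, rng: np.random.Generator):
        for layer in self.layers:
            if isinstance(layer, Conv2d):
                layer.init_params(rng)
            elif isinstance(layer, Residual):
                for sub in layer.branch:
                    if isinstance(sub, Conv2d):
                        sub.init_params(rng)

    def _flat_layers(self):
        for layer in self.layers:
            if isinstance(layer, Residual):
                yield from layer.branch
            else:
                yield layer

    def state(self) -> list[np.ndarray]:
        out = [getattr(obj, name).copy() for obj, name in self.params()]
        for layer in self._flat_layers():
            if isinstance(layer, BatchNorm2d):
                out.append(layer.running_mean.copy())
                out.append(layer.running_var.copy())
        return out

    def load_state(self, state: list[np.ndarray]) -> None:
        n_params = len(self.params())
        for (obj, name), arr in zip(self.params(), state[:n_params], strict=True):
            setattr(obj, name, arr.copy())
        rest = iter(state[n_params:])
        for layer in self._flat_layers():
            if isinstance(layer, BatchNorm2d):
                layer.running_mean = next(rest).copy()
                layer.running_var = next(rest).copy()


class SGD:
    """Plain SGD with classical momentum."""

    def __init__(self, params, lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(getattr(o, n)) for o, n in params]

    def step(self):
        for (obj, name), vel in zip(self.params, self.velocity):
            grad = getattr(obj, "d" + name)
            vel *= self.momentum
            vel -= self.lr * grad
            setattr(obj, name, getattr(obj, name) + vel)
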