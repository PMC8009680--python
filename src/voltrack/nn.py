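"""Minimal neural-network building blocks in numpy.

The pipeline needs two small trainable networks: a fully connected
similarity network for point matching and a reduced 3D U-Net voxel
classifier.  Both are desk-scale (CPU, seconds-to-minutes of training), so
the layers here implement forward and backward passes directly in numpy
(float32) with an Adam optimizer.  Batch-normalization layers keep running
statistics that are frozen at inference.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


# ---------------------------------------------------------------------------
# dense blocks


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He initialization, suitable for the ReLU units used throughout
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(F32)
        self.b = np.zeros(n_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class BatchNorm:
    """Batch normalization over axis 0 with running statistics."""

    def __init__(self, n: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n, dtype=F32)
        self.beta = np.zeros(n, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(n, dtype=F32)
        self.run_var = np.ones(n, dtype=F32)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self._inv_sd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_sd
        return self.gamma * self._xhat + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_sd = self._xhat, self._inv_sd
        n = dy.shape[0]
        self.dgamma = (dy * xhat).sum(axis=0)
        self.dbeta = dy.sum(axis=0)
        dxhat = dy * self.gamma
        # standard batchnorm backward (training-mode statistics)
        return (
            inv_sd
            / n
            * (n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
        )

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0)


def drelu(x: np.ndarray, dy: np.ndarray) -> np.ndarray:
    return dy * (x > 0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dz)."""
    z = z.astype(np.float64)
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    dz = ((sigmoid(z) - y) / z.size).astype(F32)
    return loss, dz


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = params  # list of layers exposing .params()
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for lay in params for p, _ in lay.params()]
        self.v = [np.zeros_like(p) for lay in params for p, _ in lay.params()]

    def step(self) -> None:
        self.t += 1
        i = 0
        for lay in self.layers:
            for p, g in lay.params():
                self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
                self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
                mhat = self.m[i] / (1 - self.b1**self.t)
                vhat = self.v[i] / (1 - self.b2**self.t)
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
                i += 1


# ---------------------------------------------------------------------------
# 3D convolution blocks (im2col based, kernel 3x3x3, same padding, stride 1)


def _im2col(x: np.ndarray, k: int = 3) -> np.ndarray:
    """(N, C, D, H, W) -> (N, D*H*W, C*k^3) with zero 'same' padding."""
    n, c, d, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    # win: (N, C, D, H, W, k, k, k) -> (N, D*H*W, C*k^3)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
        n, d * h * w, c * k**3
    )


class Conv3D:
    """3x3x3 convolution with same padding; weights (C_in*27, C_out)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * 27
        self.c_in, self.c_out = c_in, c_out
        self.W = (rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)).astype(
            F32
        )
        self.b = np.zeros(c_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._cols = _im2col(x)
        n, _, d, h, w = x.shape
        y = self._cols @ self.W + self.b
        return y.reshape(n, d, h, w, self.c_out).transpose(0, 4, 1, 2, 3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, _, d, h, w = self._shape
        dyf = dy.transpose(0, 2, 3, 4, 1).reshape(n, d * h * w, self.c_out)
        self.dW = np.tensordot(self._cols, dyf, axes=([0, 1], [0, 1]))
        self.db = dyf.sum(axis=(0, 1))
        # dx = correlation of dy with spatially flipped, channel-swapped kernel
        wk = self.W.reshape(self.c_in, 3, 3, 3, self.c_out)
        wflip = wk[:, ::-1, ::-1, ::-1, :]  # flip spatial taps
        wback = (
            np.ascontiguousarray(wflip.transpose(4, 1, 2, 3, 0)).reshape(
                self.c_out * 27, self.c_in
            )
        )
        cols = _im2col(dy)
        dx = cols @ wback
        return dx.reshape(n, d, h, w, self.c_in).transpose(0, 4, 1, 2, 3)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class MaxPool3D:
    """Non-overlapping max pooling; pool dims must divide the input dims."""

    def __init__(self, pool: tuple[int, int, int]):
        self.pool = pool

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, d, h, w = x.shape
        pz, py, px = self.pool
        xr = x.reshape(n, c, d // pz, pz, h // py, py, w // px, px)
        xr = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            n, c, d // pz, h // py, w // px, pz * py * px
        )
        self._arg = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, d, h, w = self._shape
        pz, py, px = self.pool
        out = np.zeros(
            (n, c, d // pz, h // py, w // px, pz * py * px), dtype=dy.dtype
        )
        np.put_along_axis(out, self._arg[..., None], dy[..., None], axis=-1)
        out = out.reshape(n, c, d // pz, h // py, w // px, pz, py, px)
        out = out.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(n, c, d, h, w)
        return out

    def params(self):
        return []


class Upsample3D:
    """Nearest-neighbour upsampling by integer factors."""

    def __init__(self, factors: tuple[int, int, int]):
        self.factors = factors

    def forward(self, x: np.ndarray) -> np.ndarray:
        fz, fy, fx = self.factors
        y = np.repeat(np.repeat(np.repeat(x, fz, axis=2), fy, axis=3), fx, axis=4)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, d, h, w = dy.shape
        fz, fy, fx = self.factors
        return (
            dy.reshape(n, c, d // fz, fz, h // fy, fy, w // fx, fx)
            .sum(axis=(3, 5, 7))
        )

    def params(self):
        return []
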