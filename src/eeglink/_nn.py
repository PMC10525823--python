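"""Minimal numpy neural-network primitives shared by the two deep models.

Parameters live in flat ``{name: ndarray}`` dicts so one Adam instance can
drive a whole model; every layer implements ``forward`` and ``backward`` with
explicit caches.  Convolution is im2col-based; all math is float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Adam",
    "softmax",
    "cross_entropy",
    "one_hot",
    "clip_gradients",
    "Dense",
    "Conv1d",
    "BatchNorm1d",
    "MaxPool1d",
    "ReLU",
    "Dropout",
]


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax (max-subtraction)."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((y.size, n_classes))
    out[np.arange(y.size), y] = 1.0
    return out


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    """Mean negative log-likelihood; y holds 0-based class indices."""
    eps = 1e-12
    return float(-np.log(probs[np.arange(y.size), y] + eps).mean())


def clip_gradients(grads: dict[str, np.ndarray], max_norm: float) -> float:
    """Scale all gradients in place so their global L2 norm <= max_norm."""
    total = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
    if total > max_norm > 0:
        scale = max_norm / total
        for g in grads.values():
            g *= scale
    return total


class Adam:
    """Adaptive moment estimation over a flat parameter dict.

    Defaults are stepsize 1e-3, decay rates (0.9, 0.999) and eps 1e-8.
    """

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        if not (0 < beta1 < 1 and 0 < beta2 < 1):
            raise ValueError("decay rates must lie in (0, 1)")
        if eps <= 0:
            raise ValueError("eps must be positive")
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            p = self.params[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """Uniform init scaled by fan-in."""
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Dense:
    """Affine layer y = x @ W + b on (..., in) arrays."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, prefix: str) -> None:
        self.prefix = prefix
        self.params = {
            f"{prefix}.W": glorot(rng, (n_in, n_out), n_in),
            f"{prefix}.b": np.zeros(n_out),
        }
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params[f"{self.prefix}.W"] + self.params[f"{self.prefix}.b"]

    def backward(self, dout: np.ndarray, grads: dict[str, np.ndarray]) -> np.ndarray:
        x = self._x
        grads[f"{self.prefix}.W"] = x.reshape(-1, x.shape[-1]).T @ dout.reshape(-1, dout.shape[-1])
        grads[f"{self.prefix}.b"] = dout.reshape(-1, dout.shape[-1]).sum(axis=0)
        return dout @ self.params[f"{self.prefix}.W"].T


class Conv1d:
    """Same-padding 1-D convolution, stride 1, on (B, C, L) arrays."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        prefix: str,
    ) -> None:
        if kernel % 2 != 1:
            raise ValueError("same padding needs an odd kernel")
        self.kernel, self.c_in, self.c_out, self.prefix = kernel, c_in, c_out, prefix
        fan_in = c_in * kernel
        self.params = {
            f"{prefix}.W": glorot(rng, (c_in * kernel, c_out), fan_in),
            f"{prefix}.b": np.zeros(c_out),
        }
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        B, C, L = x.shape
        k = self.kernel
        pad = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        # windows: (B, C, L, k) -> (B, L, C*k)
        s0, s1, s2 = xp.strides
        win = np.lib.stride_tricks.as_strided(
            xp, shape=(B, C, L, k), strides=(s0, s1, s2, s2), writeable=False
        )
        return win.transpose(0, 2, 1, 3).reshape(B, L, C * k)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        cols = self._im2col(x)
        self._cols = cols
        out = cols @ self.params[f"{self.prefix}.W"] + self.params[f"{self.prefix}.b"]
        return out.transpose(0, 2, 1)  # (B, c_out, L)

    def backward(self, dout: np.ndarray, grads: dict[str, np.ndarray]) -> np.ndarray:
        B, C, L = self._shape
        k = self.kernel
        pad = k // 2
        d = dout.transpose(0, 2, 1).reshape(-1, self.c_out)  # (B*L, c_out)
        cols = self._cols.reshape(-1, C * k)
        grads[f"{self.prefix}.W"] = cols.T @ d
        grads[f"{self.prefix}.b"] = d.sum(axis=0)
        dcols = (d @ self.params[f"{self.prefix}.W"].T).reshape(B, L, C, k)
        dxp = np.zeros((B, C, L + 2 * pad))
        for j in range(k):
            dxp[:, :, j:j + L] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dxp[:, :, pad:pad + L]


class BatchNorm1d:
    """Per-channel batch normalization over (B, C, L); running stats for eval."""

    def __init__(self, c: int, prefix: str, momentum: float = 0.9, eps: float = 1e-5) -> None:
        self.prefix, self.momentum, self.eps = prefix, momentum, eps
        self.params = {
            f"{prefix}.gamma": np.ones(c),
            f"{prefix}.beta": np.zeros(c),
        }
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        g = self.params[f"{self.prefix}.gamma"][None, :, None]
        b = self.params[f"{self.prefix}.beta"][None, :, None]
        if training:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv, x.shape)
        return g * xhat + b

    def backward(self, dout: np.ndarray, grads: dict[str, np.ndarray]) -> np.ndarray:
        xhat, inv, shape = self._cache
        B, C, L = shape
        n = B * L
        g = self.params[f"{self.prefix}.gamma"]
        grads[f"{self.prefix}.gamma"] = (dout * xhat).sum(axis=(0, 2))
        grads[f"{self.prefix}.beta"] = dout.sum(axis=(0, 2))
        dxhat = dout * g[None, :, None]
        # standard batch-norm backward, reduced over batch and time
        term1 = dxhat
        term2 = dxhat.mean(axis=(0, 2), keepdims=True)
        term3 = xhat * (dxhat * xhat).mean(axis=(0, 2), keepdims=True)
        return inv[None, :, None] * (term1 - term2 - term3)


class MaxPool1d:
    """Max pooling with window 2, stride 2 along the time axis."""

    def __init__(self, size: int = 2) -> None:
        self.size = size
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, L = x.shape
        s = self.size
        Lp = L // s
        xv = x[:, :, : Lp * s].reshape(B, C, Lp, s)
        arg = xv.argmax(axis=3)
        self._cache = (arg, x.shape)
        return xv.max(axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        arg, (B, C, L) = self._cache
        s = self.size
        Lp = L // s
        dx = np.zeros((B, C, Lp, s))
        b, c, l = np.ogrid[:B, :C, :Lp]
        dx[b, c, l, arg] = dout
        dx = dx.reshape(B, C, Lp * s)
        if Lp * s < L:
            dx = np.pad(dx, ((0, 0), (0, 0), (0, L - Lp * s)))
        return dx


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dropout:
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float) -> None:
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask
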