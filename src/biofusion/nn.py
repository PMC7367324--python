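"""Minimal neural-network layers with explicit numpy backpropagation.

Every layer implements ``forward(x, training)`` and ``backward(grad)``;
``backward`` must be called with the gradient of the loss w.r.t. the layer
output for the most recent forward pass, and returns the gradient w.r.t.
the input.  Parameters are :class:`Param` objects accumulated through
``params()`` and updated by :class:`Adam`.

The stack is deliberately small: dense layers, a per-timestep 1-D
convolution, a 3x3-style 2-D convolution via im2col, fixed average
pooling, masked batch normalisation (samples flagged absent contribute
neither to batch statistics nor to running-statistic updates, and their
outputs are forced to zero), and the usual ReLU / softmax / sigmoid
pieces.  Correctness is pinned by finite-difference gradient tests.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    """Affine map ``x @ W + b`` with He-scaled initialisation."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=True):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class ReLU(Layer):
    def forward(self, x, training=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Conv1DSame(Layer):
    """Shared 1-D convolution applied independently to each timestep.

    Input shape (B, T, L); a single length-``k`` kernel (odd ``k``) with
    zero 'same' padding maps each length-L row to a length-L row, so the
    output shape equals the input shape.
    """

    def __init__(self, kernel_size: int, rng: np.random.Generator):
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd for same-padding")
        self.k = kernel_size
        w = rng.normal(0.0, 1.0 / np.sqrt(kernel_size), size=kernel_size)
        # bias towards pass-through at init: helps early training keep beat shape
        w[kernel_size // 2] += 1.0
        self.w = Param(w)
        self.b = Param(np.zeros(1))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=True):
        B, T, L = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        self._xp = xp
        self._L = L
        y = np.zeros_like(x)
        for j in range(self.k):
            y += self.w.value[j] * xp[:, :, j : j + L]
        return y + self.b.value[0]

    def backward(self, grad):
        L = self._L
        p = self.k // 2
        for j in range(self.k):
            self.w.grad[j] += np.sum(grad * self._xp[:, :, j : j + L])
        self.b.grad[0] += grad.sum()
        gxp = np.zeros_like(self._xp)
        for j in range(self.k):
            gxp[:, :, j : j + L] += self.w.value[j] * grad
        return gxp[:, :, p:-p] if p else gxp


class TimestepMax(Layer):
    """Element-wise max over the timestep axis: (B, T, L) -> (B, L)."""

    def forward(self, x, training=True):
        self._x_shape = x.shape
        self._arg = np.argmax(x, axis=1)
        return np.max(x, axis=1)

    def backward(self, grad):
        B, T, L = self._x_shape
        gx = np.zeros(self._x_shape)
        b_idx = np.arange(B)[:, None]
        l_idx = np.arange(L)[None, :]
        gx[b_idx, self._arg, l_idx] = grad
        return gx


class AvgPool2D(Layer):
    """Non-overlapping average pooling with a fixed integer factor."""

    def __init__(self, factor: int):
        self.f = factor

    def forward(self, x, training=True):
        B, H, W = x.shape
        f = self.f
        if H % f or W % f:
            raise ValueError(f"pool factor {f} must divide image dims {(H, W)}")
        self._shape = (B, H, W)
        return x.reshape(B, H // f, f, W // f, f).mean(axis=(2, 4))

    def backward(self, grad):
        B, H, W = self._shape
        f = self.f
        g = np.repeat(np.repeat(grad, f, axis=1), f, axis=2) / (f * f)
        return g


class Conv2DSame(Layer):
    """2-D convolution, single input channel -> ``n_filters``, 'same' padding.

    Input (B, H, W), output (B, n_filters, H, W).  Implemented with im2col;
    sizes used here (post-pooling thumbnails) keep this cheap.
    """

    def __init__(self, n_filters: int, kernel_size: int, rng: np.random.Generator):
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        self.k = kernel_size
        self.n_filters = n_filters
        scale = np.sqrt(2.0 / (kernel_size * kernel_size))
        self.W = Param(rng.normal(0.0, scale, size=(n_filters, kernel_size * kernel_size)))
        self.b = Param(np.zeros(n_filters))

    def params(self):
        return [self.W, self.b]

    def _im2col(self, xp, H, W):
        k = self.k
        B = xp.shape[0]
        cols = np.empty((B, k * k, H * W))
        idx = 0
        for i in range(k):
            for j in range(k):
                cols[:, idx, :] = xp[:, i : i + H, j : j + W].reshape(B, -1)
                idx += 1
        return cols

    def forward(self, x, training=True):
        B, H, W = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p)))
        cols = self._im2col(xp, H, W)  # (B, k*k, H*W)
        self._cols = cols
        self._hw = (H, W)
        y = np.einsum("fk,bkp->bfp", self.W.value, cols)
        y += self.b.value[None, :, None]
        return y.reshape(B, self.n_filters, H, W)

    def backward(self, grad):
        B = grad.shape[0]
        H, W = self._hw
        g = grad.reshape(B, self.n_filters, H * W)
        self.W.grad += np.einsum("bfp,bkp->fk", g, self._cols)
        self.b.grad += g.sum(axis=(0, 2))
        gcols = np.einsum("fk,bfp->bkp", self.W.value, g)
        p = self.k // 2
        gxp = np.zeros((B, H + 2 * p, W + 2 * p))
        idx = 0
        for i in range(self.k):
            for j in range(self.k):
                gxp[:, i : i + H, j : j + W] += gcols[:, idx, :].reshape(B, H, W)
                idx += 1
        return gxp[:, p:-p, p:-p] if p else gxp


class Flatten(Layer):
    def forward(self, x, training=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class MaskedBatchNorm(Layer):
    """Batch normalisation that ignores absent-modality samples.

    ``set_mask`` installs a per-sample boolean presence vector before each
    forward pass.  Batch statistics (and running-statistic updates) are
    computed over present samples only; outputs of absent samples are
    forced to zero, so a zero-filled placeholder block stays exactly zero
    and never distorts the statistics of real samples.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(dim))
        self.beta = Param(np.zeros(dim))
        # exponential moving averages, zero-initialised and bias-corrected at
        # read time (few-update regimes would otherwise be pulled toward the
        # initial values)
        self._ema_mean = np.zeros(dim)
        self._ema_var = np.zeros(dim)
        self._updates = 0
        self.momentum = momentum
        self.eps = eps
        self._mask: np.ndarray | None = None

    @property
    def running_mean(self) -> np.ndarray:
        if self._updates == 0:
            return np.zeros_like(self._ema_mean)
        return self._ema_mean / (1.0 - (1.0 - self.momentum) ** self._updates)

    @running_mean.setter
    def running_mean(self, value):
        self._ema_mean = np.array(value, dtype=np.float64)
        self._updates = max(self._updates, 1)
        self._ema_mean *= 1.0 - (1.0 - self.momentum) ** self._updates

    @property
    def running_var(self) -> np.ndarray:
        if self._updates == 0:
            return np.ones_like(self._ema_var)
        return self._ema_var / (1.0 - (1.0 - self.momentum) ** self._updates)

    @running_var.setter
    def running_var(self, value):
        self._ema_var = np.array(value, dtype=np.float64)
        self._updates = max(self._updates, 1)
        self._ema_var *= 1.0 - (1.0 - self.momentum) ** self._updates

    def params(self):
        return [self.gamma, self.beta]

    def set_mask(self, mask: np.ndarray | None):
        self._mask = None if mask is None else np.asarray(mask, dtype=bool)

    def forward(self, x, training=True):
        B = x.shape[0]
        mask = self._mask if self._mask is not None else np.ones(B, dtype=bool)
        if mask.shape != (B,):
            raise ValueError("presence mask must have one entry per sample")
        n = int(mask.sum())
        self._fmask = mask
        if training and n > 0:
            xm = x[mask]
            mean = xm.mean(axis=0)
            var = xm.var(axis=0)
            self._ema_mean = (1 - self.momentum) * self._ema_mean + self.momentum * mean
            self._ema_var = (1 - self.momentum) * self._ema_var + self.momentum * var
            self._updates += 1
        else:
            mean = self.running_mean
            var = self.running_var
        self._n = n
        self._training_stats = training and n > 0
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._xhat = xhat
        self._inv = inv
        out = self.gamma.value * xhat + self.beta.value
        out[~mask] = 0.0
        return out

    def backward(self, grad):
        mask = self._fmask
        grad = grad.copy()
        grad[~mask] = 0.0
        self.gamma.grad += np.sum(grad * self._xhat, axis=0)
        self.beta.grad += grad.sum(axis=0)
        gxhat = grad * self.gamma.value
        if not self._training_stats:
            return gxhat * self._inv
        n = self._n
        xhat_m = self._xhat[mask]
        gxhat_m = gxhat[mask]
        # standard batch-norm backward restricted to present rows
        gx = np.zeros_like(grad)
        gx[mask] = (
            self._inv
            / n
            * (n * gxhat_m - gxhat_m.sum(axis=0) - xhat_m * np.sum(gxhat_m * xhat_m, axis=0))
        )
        # absent rows: output was forcibly zeroed, so no gradient flows back
        return gx


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, training=True):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax (max-subtraction)."""
    z = logits - np.max(logits, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Adam:
    """Adaptive-moment optimizer over a flat parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def count_params(layers_or_params) -> int:
    """Total scalar parameter count of a layer, iterable of layers, or Param list."""
    if isinstance(layers_or_params, Layer):
        return sum(p.size for p in layers_or_params.params())
    total = 0
    for item in layers_or_params:
        if isinstance(item, Param):
            total += item.size
        else:
            total += count_params(item)
    return total
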