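"""Minimal seeded neural-network core used by the twin metric-learning models.

Implements exactly the pieces the twin encoders need — linear and 1-D
convolutional layers, batch normalization, ReLU, average pooling, dense-block
concatenation and an Adam optimizer — with hand-derived reverse-mode
gradients on numpy arrays.  Everything is deterministic given the
``numpy.random.Generator`` handed to the constructors.

Conventions: fully connected tensors are ``(batch, features)``; convolutional
tensors are ``(batch, channels, length)``.  Weight decay is added to the
gradient inside Adam (the decoupled L2-in-gradient form).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Linear",
    "BatchNorm1d",
    "ReLU",
    "Conv1d",
    "AvgPool1d",
    "GlobalAvgPool1d",
    "Reshape1d",
    "DenseBlock1d",
    "Transition1d",
    "Sequential",
    "Adam",
]


class Layer:
    """Base layer: ``forward`` caches what ``backward`` needs."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(param, grad) pairs; grads are accumulated in-place by backward."""
        return []

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Arrays to serialize beyond parameters (e.g. BN running stats)."""
        return {}


def _kaiming_uniform(rng: np.random.Generator, shape, fan_in: int, dtype):
    bound = float(np.sqrt(1.0 / fan_in))
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        self.W = _kaiming_uniform(rng, (n_in, n_out), n_in, dtype)
        self.b = _kaiming_uniform(rng, (n_out,), n_in, dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW += self._x.T @ dy
        self.db += dy.sum(axis=0)
        return dy @ self.W.T

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]


class BatchNorm1d(Layer):
    """Batch normalization over the batch axis (and length axis for 3-D input).

    2-D input normalizes each feature; 3-D input normalizes each channel.
    """

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = np.ones(n_features, dtype=dtype)
        self.beta = np.zeros(n_features, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n_features, dtype=dtype)
        self.running_var = np.ones(n_features, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def _axes_and_shape(self, x):
        if x.ndim == 2:
            return (0,), (1, -1)
        return (0, 2), (1, -1, 1)

    def forward(self, x, train=True):
        axes, shape = self._axes_and_shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            n = x.size // mean.size
            self.running_mean += self.momentum * (mean - self.running_mean)
            # unbiased variance for the running estimate, as torch does
            unbiased = var * (n / max(n - 1, 1))
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mean = self.running_mean
            var = self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv_std.reshape(shape)
        self._cache = (xhat, inv_std, axes, shape)
        return self.gamma.reshape(shape) * xhat + self.beta.reshape(shape)

    def backward(self, dy):
        xhat, inv_std, axes, shape = self._cache
        n = dy.size // self.gamma.size
        self.dgamma += (dy * xhat).sum(axis=axes)
        self.dbeta += dy.sum(axis=axes)
        g = self.gamma.reshape(shape)
        dxhat = dy * g
        mean_dxhat = dxhat.mean(axis=axes).reshape(shape)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=axes).reshape(shape)
        return inv_std.reshape(shape) * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)

    def parameters(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def state_arrays(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Conv1d(Layer):
    """Same-padded 1-D convolution via sliding-window + einsum."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        fan_in = c_in * kernel
        self.W = _kaiming_uniform(rng, (c_out, c_in, kernel), fan_in, dtype)
        self.b = _kaiming_uniform(rng, (c_out,), fan_in, dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.kernel = kernel
        self.pad = kernel // 2

    def forward(self, x, train=True):
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p))) if p else x
        patches = sliding_window_view(xp, self.kernel, axis=2)  # (B, C, L, K)
        self._patches = patches
        self._in_len = x.shape[2]
        y = np.einsum("ock,bclk->bol", self.W, patches, optimize=True)
        return y + self.b[None, :, None]

    def backward(self, dy):
        self.dW += np.einsum("bol,bclk->ock", dy, self._patches, optimize=True)
        self.db += dy.sum(axis=(0, 2))
        dpatch = np.einsum("ock,bol->bclk", self.W, dy, optimize=True)
        B, C, L, K = dpatch.shape
        p = self.pad
        dxp = np.zeros((B, C, L + 2 * p), dtype=dy.dtype)
        for k in range(K):
            dxp[:, :, k:k + L] += dpatch[:, :, :, k]
        return dxp[:, :, p:p + self._in_len] if p else dxp

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]


class AvgPool1d(Layer):
    """Non-overlapping average pooling; trailing remainder frames dropped."""

    def __init__(self, kernel: int = 2):
        self.kernel = kernel

    def forward(self, x, train=True):
        k = self.kernel
        L = (x.shape[2] // k) * k
        self._in_len = x.shape[2]
        self._pooled_len = L
        return x[:, :, :L].reshape(x.shape[0], x.shape[1], L // k, k).mean(axis=3)

    def backward(self, dy):
        k = self.kernel
        dx = np.zeros((dy.shape[0], dy.shape[1], self._in_len), dtype=dy.dtype)
        dx[:, :, :self._pooled_len] = np.repeat(dy / k, k, axis=2)
        return dx


class GlobalAvgPool1d(Layer):
    def forward(self, x, train=True):
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy):
        return np.repeat(dy[:, :, None], self._L, axis=2) / self._L


class Reshape1d(Layer):
    """(B, L) <-> (B, 1, L) adapter for the convolutional encoder."""

    def forward(self, x, train=True):
        return x[:, None, :]

    def backward(self, dy):
        return dy[:, 0, :]


class DenseBlock1d(Layer):
    """DenseNet-style block: each BN-ReLU-Conv layer consumes the channel
    concatenation of the block input and all previous layer outputs."""

    def __init__(self, c_in: int, growth: int, n_layers: int, kernel: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.sublayers: list[list[Layer]] = []
        c = c_in
        for _ in range(n_layers):
            self.sublayers.append([
                BatchNorm1d(c, dtype=dtype),
                ReLU(),
                Conv1d(c, growth, kernel, rng, dtype=dtype),
            ])
            c += growth
        self.c_out = c

    def forward(self, x, train=True):
        feats = [x]
        self._widths = []
        for bn, relu, conv in self.sublayers:
            cat = np.concatenate(feats, axis=1) if len(feats) > 1 else feats[0]
            self._widths.append([f.shape[1] for f in feats])
            h = conv.forward(relu.forward(bn.forward(cat, train), train), train)
            feats.append(h)
        self._n_feats = len(feats)
        return np.concatenate(feats, axis=1)

    def backward(self, dy):
        # split the gradient of the final concatenation back onto each feature
        widths = self._widths[-1] + [self.sublayers[-1][2].W.shape[0]]
        grads = list(np.split(dy, np.cumsum(widths)[:-1], axis=1))
        for i in range(len(self.sublayers) - 1, -1, -1):
            bn, relu, conv = self.sublayers[i]
            dcat = bn.backward(relu.backward(conv.backward(grads.pop())))
            w = self._widths[i]
            for j, piece in enumerate(np.split(dcat, np.cumsum(w)[:-1], axis=1)):
                grads[j] = grads[j] + piece
        return grads[0]

    def parameters(self):
        return [p for sub in self.sublayers for lay in sub for p in lay.parameters()]

    def state_arrays(self):
        out = {}
        for i, sub in enumerate(self.sublayers):
            for name, arr in sub[0].state_arrays().items():
                out[f"layer{i}.{name}"] = arr
        return out


class Transition1d(Layer):
    """BN-ReLU-Conv(1x1)-AvgPool(2) channel/length reduction between blocks."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float32):
        self.bn = BatchNorm1d(c_in, dtype=dtype)
        self.relu = ReLU()
        self.conv = Conv1d(c_in, c_out, 1, rng, dtype=dtype)
        self.pool = AvgPool1d(2)
        self.c_out = c_out

    def forward(self, x, train=True):
        h = self.conv.forward(self.relu.forward(self.bn.forward(x, train), train), train)
        return self.pool.forward(h, train)

    def backward(self, dy):
        return self.bn.backward(self.relu.backward(self.conv.backward(self.pool.backward(dy))))

    def parameters(self):
        return self.bn.parameters() + self.conv.parameters()

    def state_arrays(self):
        return {f"bn.{k}": v for k, v in self.bn.state_arrays().items()}


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def state_arrays(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.state_arrays().items():
                out[f"{i}.{name}"] = arr
        return out

    def zero_grad(self):
        for _, g in self.parameters():
            g[...] = 0.0


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params: list[tuple[np.ndarray, np.ndarray]],
                 lr: float = 5e-4, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-6):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            grad = g + self.weight_decay * p
            m += (1.0 - self.b1) * (grad - m)
            v += (1.0 - self.b2) * (grad * grad - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
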