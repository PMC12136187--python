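"""A small seeded neural-network engine for 1-D convolutional models.

Implements exactly the pieces the fingerprint GANs need — dense and 1-D
convolutional layers, max pooling, nearest-neighbour upsampling, batch
normalization, the usual activations, a softmax/cross-entropy head, and an
Adam optimizer with optional L2 weight penalty.  Everything is plain NumPy
(float32) with explicit seeding, so training runs are bit-reproducible and
parameter freezing can be verified by checksum.

Tensor convention: feature maps are channels-last, (batch, length,
channels); dense activations are (batch, features).  Convolution is
evaluated as ``kernel`` accumulated matrix products over shifted views of
the padded input, which keeps the whole engine GEMM-bound without im2col
copies.
"""

from __future__ import annotations

import hashlib
from typing import Sequence

import numpy as np

DTYPE = np.float32


class Layer:
    """Base layer: forward/backward plus named trainable parameters."""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 init: str = "he"):
        scale = np.sqrt(2.0 / n_in) if init == "he" else np.sqrt(1.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T


class Conv1D(Layer):
    """1-D convolution, stride 1, 'same' zero padding (odd kernel).

    Weights have shape (kernel, c_in, c_out); the output is accumulated as
    one (B, L, c_in) @ (c_in, c_out) product per kernel offset, evaluated
    on shifted views of the padded input.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.W = rng.normal(0.0, scale, size=(kernel, c_in, c_out)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x, training=False):
        B, L, C = x.shape
        k, pad = self.kernel, self.kernel // 2
        xp = np.zeros((B, L + 2 * pad, C), dtype=DTYPE)
        xp[:, pad:pad + L, :] = x
        # im2col: windows over the padded signal -> one (B*L, k*C) GEMM
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
        cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B * L, k * C)
        self._cols, self._shape = cols, (B, L, C)
        out = cols @ self.W.reshape(k * C, self.c_out) + self.b
        return out.reshape(B, L, self.c_out)

    def backward(self, dout):
        B, L, C = self._shape
        k, pad = self.kernel, self.kernel // 2
        F = self.c_out
        dflat = dout.reshape(B * L, F)
        self.db = dflat.sum(axis=0)
        self.dW = (self._cols.T @ dflat).reshape(k, C, F)
        # input gradient: k shifted GEMMs into the padded buffer
        dxp = np.zeros((B, L + 2 * pad, C), dtype=DTYPE)
        for j in range(k):
            dxp[:, j:j + L, :] += (dflat @ self.W[j].T).reshape(B, L, C)
        return dxp[:, pad:pad + L, :]


class MaxPool1D(Layer):
    """Non-overlapping max pooling along length; remainder positions dropped."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, training=False):
        B, L, C = x.shape
        Lo = L // self.size
        self._in_shape = (B, L, C)
        if self.size == 2:  # fast path: compare the two lanes directly
            a, b = x[:, 0:2 * Lo:2, :], x[:, 1:2 * Lo:2, :]
            self._right = b > a
            return np.where(self._right, b, a)
        xv = x[:, : Lo * self.size, :].reshape(B, Lo, self.size, C)
        self._argmax = xv.argmax(axis=2)
        return xv.max(axis=2)

    def backward(self, dout):
        B, L, C = self._in_shape
        Lo = dout.shape[1]
        full = np.zeros((B, L, C), dtype=dout.dtype)
        if self.size == 2:
            z = dout.dtype.type(0)
            full[:, 0:2 * Lo:2, :] = np.where(self._right, z, dout)
            full[:, 1:2 * Lo:2, :] = np.where(self._right, dout, z)
            return full
        dx = np.zeros((B, Lo, self.size, C), dtype=dout.dtype)
        np.put_along_axis(dx, self._argmax[:, :, None, :],
                          dout[:, :, None, :], axis=2)
        full[:, : Lo * self.size, :] = dx.reshape(B, Lo * self.size, C)
        return full


class Upsample1D(Layer):
    """Nearest-neighbour upsampling along length by an integer factor."""

    def __init__(self, factor: int = 2):
        self.factor = factor

    def forward(self, x, training=False):
        return np.repeat(x, self.factor, axis=1)

    def backward(self, dout):
        B, L, C = dout.shape
        return dout.reshape(B, L // self.factor, self.factor, C).sum(axis=2)


class BatchNorm1D(Layer):
    """Per-channel batch normalization over (batch, length).

    Uses batch statistics in training mode (running buffers updated with
    momentum 0.9) and the running estimates at inference.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.9):
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(channels, dtype=DTYPE)
        self.run_var = np.ones(channels, dtype=DTYPE)
        self.eps, self.momentum = eps, momentum

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.run_mean = (self.momentum * self.run_mean
                             + (1 - self.momentum) * mean).astype(DTYPE)
            self.run_var = (self.momentum * self.run_var
                            + (1 - self.momentum) * var).astype(DTYPE)
        else:
            mean, var = self.run_mean, self.run_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._training = training
        return self.gamma * self._xhat + self.beta

    def backward(self, dout):
        xhat, std = self._xhat, self._std
        self.dgamma = (dout * xhat).sum(axis=(0, 1))
        self.dbeta = dout.sum(axis=(0, 1))
        if not self._training:
            return dout * (self.gamma / std)
        dxhat = dout * self.gamma
        return (dxhat - dxhat.mean(axis=(0, 1), keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=(0, 1), keepdims=True)) / std


class Activation(Layer):
    def __init__(self, kind: str, alpha: float = 0.2):
        if kind not in {"relu", "leaky_relu", "tanh", "sigmoid"}:
            raise ValueError(f"unknown activation: {kind}")
        self.kind, self.alpha = kind, alpha

    def forward(self, x, training=False):
        if self.kind == "relu":
            self._mask = x > 0
            return np.where(self._mask, x, x.dtype.type(0))
        if self.kind == "leaky_relu":
            self._mask = x > 0
            return np.where(self._mask, x, x.dtype.type(self.alpha) * x)
        if self.kind == "tanh":
            self._y = np.tanh(x)
            return self._y
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, dout):
        if self.kind == "relu":
            return np.where(self._mask, dout, dout.dtype.type(0))
        if self.kind == "leaky_relu":
            return np.where(self._mask, dout, dout.dtype.type(self.alpha) * dout)
        if self.kind == "tanh":
            return dout * (1.0 - self._y**2)
        return dout * self._y * (1.0 - self._y)


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Reshape(Layer):
    """(batch, features) -> (batch, length, channels)."""

    def __init__(self, length: int, channels: int):
        self.length, self.channels = length, channels

    def forward(self, x, training=False):
        return x.reshape(x.shape[0], self.length, self.channels)

    def backward(self, dout):
        return dout.reshape(dout.shape[0], -1)


class MaskLayer(Layer):
    """Substructure-preserving lambda layer: y = x * unmask + mask.

    Positions where ``mask`` is 1 are forced to exactly 1; other positions
    pass through.  Gradients flow only through unmasked positions, so the
    generator never wastes capacity on constrained bits.
    """

    def __init__(self, mask: np.ndarray):
        mask = np.asarray(mask, dtype=DTYPE)
        if not np.isin(mask, (0.0, 1.0)).all():
            raise ValueError("mask must be binary")
        self.mask = mask
        self.unmask = (1.0 - mask).astype(DTYPE)

    def forward(self, x, training=False):
        if x.shape[-1] != self.mask.size:
            raise ValueError(
                f"mask length {self.mask.size} does not match input {x.shape[-1]}"
            )
        return x * self.unmask + self.mask

    def backward(self, dout):
        return dout * self.unmask


class Sequential:
    """An ordered layer stack with cached-forward backprop."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    __call__ = forward

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = np.asarray(dout, dtype=DTYPE)
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self) -> list[tuple[str, np.ndarray]]:
        out = []
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params().items():
                out.append((f"{i}.{layer.__class__.__name__}.{name}", arr))
        return out

    def gradients(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend(layer.grads().values())
        return out

    def n_parameters(self) -> int:
        return int(sum(arr.size for _, arr in self.parameters()))

    def checksum(self) -> str:
        """SHA-256 over all trainable parameters (buffers excluded)."""
        h = hashlib.sha256()
        for name, arr in self.parameters():
            h.update(name.encode())
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()

    def get_weights(self) -> dict[str, np.ndarray]:
        state = {name: arr.copy() for name, arr in self.parameters()}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm1D):
                state[f"{i}.BatchNorm1D.run_mean"] = layer.run_mean.copy()
                state[f"{i}.BatchNorm1D.run_var"] = layer.run_var.copy()
        return state

    def set_weights(self, state: dict[str, np.ndarray]) -> None:
        for name, arr in self.parameters():
            arr[...] = state[name]
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm1D):
                layer.run_mean[...] = state[f"{i}.BatchNorm1D.run_mean"]
                layer.run_var[...] = state[f"{i}.BatchNorm1D.run_var"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def categorical_cross_entropy(
    logits: np.ndarray, onehot: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean 2-class (or k-class) cross-entropy and its gradient wrt logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-(onehot * np.log(np.clip(p, 1e-12, None))).sum() / n)
    return loss, ((p - onehot) / n).astype(DTYPE)


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size and (labels.min() < 0 or labels.max() >= n_classes):
        raise ValueError("label out of range")
    out = np.zeros((labels.size, n_classes), dtype=DTYPE)
    out[np.arange(labels.size), labels] = 1.0
    return out


class Adam:
    """Adam with optional L2 penalty on matrix-shaped parameters."""

    def __init__(self, model: Sequential, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, l2: float = 0.0):
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps, self.l2 = lr, beta1, beta2, eps, l2
        self.t = 0
        self._m = [np.zeros_like(arr) for _, arr in model.parameters()]
        self._v = [np.zeros_like(arr) for _, arr in model.parameters()]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 / (1.0 - b1**self.t)
        c2 = 1.0 / (1.0 - b2**self.t)
        params = self.model.parameters()
        grads = self.model.gradients()
        for (name, p), g, m, v in zip(params, grads, self._m, self._v):
            if self.l2 and p.ndim >= 2:  # penalize kernels, not biases/gains
                g = g + DTYPE(self.l2) * p
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m * c1) / (np.sqrt(v * c2) + self.eps)
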