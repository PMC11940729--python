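"""Minimal feed-forward neural-network core (numpy, explicit backprop).

Implements exactly the pieces the classifiers need: 1D convolution with
same-length (end-padded) output, max pooling, fully connected layers, ReLU,
inverted dropout, softmax cross-entropy, the Adam optimizer and a step
learning-rate schedule.  All randomness (initialisation, shuffling,
dropout) flows from one ``numpy.random.Generator``, so training is
bit-reproducible under a fixed seed on a given platform.  Gradients are
validated against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


class Layer:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(value, gradient) pairs; gradients are filled by backward()."""
        return []


class Conv1d(Layer):
    """kernel-size-2, stride-1 convolution with one zero padded at the end,
    so the output length equals the input length."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, dtype=np.float64):
        if kernel_size != 2:
            raise ValueError("only kernel_size=2 is supported")
        bound = 1.0 / np.sqrt(in_channels * kernel_size)
        self.W = rng.uniform(-bound, bound,
                             (out_channels, in_channels, kernel_size)).astype(dtype)
        self.b = rng.uniform(-bound, bound, out_channels).astype(dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train):
        # x: (B, C_in, L) -> (B, C_out, L)
        self._x = x
        x1 = np.concatenate([x[:, :, 1:], np.zeros_like(x[:, :, :1])], axis=2)
        self._x1 = x1
        y = (np.einsum("oc,bcl->bol", self.W[:, :, 0], x)
             + np.einsum("oc,bcl->bol", self.W[:, :, 1], x1))
        return y + self.b[None, :, None]

    def backward(self, grad):
        self.dW[:, :, 0] = np.einsum("bol,bcl->oc", grad, self._x)
        self.dW[:, :, 1] = np.einsum("bol,bcl->oc", grad, self._x1)
        self.db[:] = grad.sum(axis=(0, 2))
        gx = np.einsum("oc,bol->bcl", self.W[:, :, 0], grad)
        # contribution through the shifted tap: x[l+1] received W[...,1]*grad[l]
        gx[:, :, 1:] += np.einsum("oc,bol->bcl", self.W[:, :, 1], grad)[:, :, :-1]
        return gx

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]


class MaxPool1d(Layer):
    """Non-overlapping max pooling, size = stride = 2 (floor length)."""

    def forward(self, x, train):
        B, C, L = x.shape
        Lo = L // 2
        xv = x[:, :, :2 * Lo].reshape(B, C, Lo, 2)
        self._arg = xv.argmax(axis=3)
        self._shape = x.shape
        return xv.max(axis=3)

    def backward(self, grad):
        B, C, Lo = grad.shape
        gx = np.zeros(self._shape, dtype=grad.dtype)
        gv = gx[:, :, :2 * Lo].reshape(B, C, Lo, 2)
        np.put_along_axis(gv, self._arg[..., None], grad[..., None], axis=3)
        return gx


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time or when p == 0."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x, train):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = ((self.rng.random(x.shape) >= self.p)
                      .astype(x.dtype) / (1.0 - self.p))
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, dtype=np.float64):
        bound = 1.0 / np.sqrt(in_features)
        self.W = rng.uniform(-bound, bound, (in_features, out_features)).astype(dtype)
        self.b = rng.uniform(-bound, bound, out_features).astype(dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[:] = self._x.T @ grad
        self.db[:] = grad.sum(axis=0)
        return grad @ self.W.T

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Network:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        return [pg for layer in self.layers for pg in layer.parameters()]

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.parameters())


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_loss(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    probs = softmax(logits)
    n = len(y)
    eps = 1e-12
    loss = float(-np.log(probs[np.arange(n), y] + eps).mean())
    grad = probs.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self._buf = [np.empty_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        # bias correction folded into the step size (standard reformulation)
        alpha = self.lr * np.sqrt(1.0 - b2 ** self.t) / (1.0 - b1 ** self.t)
        eps_hat = self.eps * np.sqrt(1.0 - b2 ** self.t)
        for (p, g), m, v, buf in zip(self.params, self.m, self.v, self._buf):
            m *= b1
            m += (1 - b1) * g
            np.multiply(g, g, out=buf)
            v *= b2
            buf *= (1 - b2)
            v += buf
            np.sqrt(v, out=buf)
            buf += eps_hat
            np.divide(m, buf, out=buf)
            buf *= alpha
            p -= buf


def step_lr(base_lr: float, epoch: int, step: int = 10,
            gamma: float = 0.9) -> float:
    """Learning rate of a 1-indexed epoch: multiplied by ``gamma`` after
    every ``step`` epochs (epochs 1..10 at base, 11..20 at 0.9x, ...)."""
    return base_lr * gamma ** ((epoch - 1) // step)
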