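"""Minimal NumPy neural-network primitives: 1-D convolution, dense layers,
inverted dropout and the Adamax optimizer.

Everything is float64 and single-threaded BLAS underneath, so a fixed seed
reproduces training bit-for-bit. Layers own their parameters and gradients;
``params()`` exposes named arrays for the optimizer and for serialization.
"""

from __future__ import annotations

import numpy as np


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def glorot_uniform(shape: tuple[int, ...], fan_in: int, fan_out: int, rng: np.random.Generator) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Conv1D:
    """Valid (unpadded) 1-D convolution with ReLU activation.

    Input (B, L, C_in) -> output (B, (L-k)//stride + 1, C_out).
    """

    def __init__(self, kernel: int, c_in: int, c_out: int, stride: int, rng: np.random.Generator, name: str):
        if kernel < 1 or stride < 1:
            raise ValueError("kernel and stride must be >= 1")
        self.kernel, self.stride, self.name = kernel, stride, name
        fan_in, fan_out = kernel * c_in, kernel * c_out
        self.W = glorot_uniform((kernel, c_in, c_out), fan_in, fan_out, rng)
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def out_len(self, length: int) -> int:
        if length < self.kernel:
            raise ValueError(f"input length {length} shorter than kernel {self.kernel}")
        return (length - self.kernel) // self.stride + 1

    def forward(self, X: np.ndarray) -> np.ndarray:
        k, s = self.kernel, self.stride
        L_out = self.out_len(X.shape[1])
        Z = np.tile(self.b, (X.shape[0], L_out, 1))
        for t in range(k):
            Z += X[:, t : t + s * L_out : s, :] @ self.W[t]
        self._X, self._Z = X, Z
        return relu(Z)

    def backward(self, dA: np.ndarray) -> np.ndarray:
        k, s = self.kernel, self.stride
        X, Z = self._X, self._Z
        L_out = dA.shape[1]
        dZ = dA * (Z > 0)
        self.db += dZ.sum(axis=(0, 1))
        dX = np.zeros_like(X)
        for t in range(k):
            Xw = X[:, t : t + s * L_out : s, :]
            self.dW[t] += np.tensordot(Xw, dZ, axes=([0, 1], [0, 1]))
            dX[:, t : t + s * L_out : s, :] += dZ @ self.W[t].T
        return dX

    def params(self):
        return {f"{self.name}.W": (self.W, self.dW), f"{self.name}.b": (self.b, self.db)}


class Dense:
    """Fully connected layer with ReLU, sigmoid or linear activation."""

    def __init__(self, n_in: int, n_out: int, activation: str, rng: np.random.Generator, name: str):
        self.activation, self.name = activation, name
        self.W = glorot_uniform((n_in, n_out), n_in, n_out, rng)
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, X: np.ndarray) -> np.ndarray:
        Z = X @ self.W + self.b
        if self.activation == "relu":
            A = relu(Z)
        elif self.activation == "sigmoid":
            A = sigmoid(Z)
        else:
            A = Z
        self._X, self._A, self._Z = X, A, Z
        return A

    def backward(self, dA: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            dZ = dA * (self._Z > 0)
        elif self.activation == "sigmoid":
            dZ = dA * self._A * (1.0 - self._A)
        else:
            dZ = dA
        self.dW += self._X.T @ dZ
        self.db += dZ.sum(axis=0)
        return dZ @ self.W.T

    def params(self):
        return {f"{self.name}.W": (self.W, self.dW), f"{self.name}.b": (self.b, self.db)}


class Dropout:
    """Inverted dropout: identity at inference, rescaled mask in training."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, X: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return X
        keep = 1.0 - self.rate
        self._mask = (rng.random(X.shape) < keep) / keep
        return X * self._mask

    def backward(self, dA: np.ndarray) -> np.ndarray:
        return dA if self._mask is None else dA * self._mask


class Adamax:
    """Adamax optimizer with the defaults of its original formulation:
    lr=0.002, beta1=0.9, beta2=0.999, eps=1e-8."""

    def __init__(self, params: dict[str, tuple[np.ndarray, np.ndarray]],
                 lr: float = 0.002, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(w) for k, (w, _) in params.items()}
        self.u = {k: np.zeros_like(w) for k, (w, _) in params.items()}

    def step(self) -> None:
        self.t += 1
        bias_corr = 1.0 - self.beta1**self.t
        for key, (w, g) in self.params.items():
            m = self.m[key]
            u = self.u[key]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            np.maximum(self.beta2 * u, np.abs(g), out=u)
            w -= (self.lr / bias_corr) * m / (u + self.eps)

    def zero_grad(self) -> None:
        for _, (_, g) in self.params.items():
            g[...] = 0.0
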