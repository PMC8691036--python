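"""Baseline plain CNN on the same 84 features, for comparison harnesses.

The baseline shares the feature representation and the dense-layer
variants of the class-similarity network but classifies the input vector
directly: one conv stack on x (no reference channels, no similarity
subtraction) followed by a dense head with two sigmoid output nodes,
trained with the same MSE objective and Adamax settings.
"""

from __future__ import annotations

import numpy as np

from ._nn import Adamax, Dense, Dropout
from .network import NetworkConfig, _ConvStack, _targets


class BaselineCNN:
    """Plain conv + dense classifier with dense variant z2, z3 or z2+z3."""

    def __init__(self, config: NetworkConfig, n_features: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(config.seed)
        self.config = config
        self.n_features = n_features
        self.stack = _ConvStack(config, n_features, rng, "stack")
        flat = self.stack.out_shape[0] * self.stack.out_shape[1]
        self.variant = config.dense_variant
        self.drop1 = Dropout(config.dropout_r1)
        self.drop2 = Dropout(config.dropout_r2)
        if self.variant in ("z2", "z2+z3"):
            self.dense1 = Dense(flat, config.hidden_units, "relu", rng, "dense1")
            self.dense2 = Dense(config.hidden_units, 2, "sigmoid", rng, "dense2")
        if self.variant in ("z3", "z2+z3"):
            self.dense3 = Dense(flat, 2, "sigmoid", rng, "dense3")
        self.history: list[float] = []

    def forward(self, X: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        f = self.stack.forward(X[:, :, None]).reshape(X.shape[0], -1)
        self._f_shape = (X.shape[0], *self.stack.out_shape)
        y = 0.0
        if self.variant in ("z2", "z2+z3"):
            y = y + self.dense2.forward(self.dense1.forward(self.drop1.forward(f, train, rng)))
        if self.variant in ("z3", "z2+z3"):
            y = y + self.dense3.forward(self.drop2.forward(f, train, rng))
        return y

    def backward(self, dY: np.ndarray) -> None:
        df = 0.0
        if self.variant in ("z2", "z2+z3"):
            df = df + self.drop1.backward(self.dense1.backward(self.dense2.backward(dY)))
        if self.variant in ("z3", "z2+z3"):
            df = df + self.drop2.backward(self.dense3.backward(dY))
        self.stack.backward(np.asarray(df).reshape(self._f_shape))

    def params(self):
        out = dict(self.stack.params())
        if self.variant in ("z2", "z2+z3"):
            out.update(self.dense1.params())
            out.update(self.dense2.params())
        if self.variant in ("z3", "z2+z3"):
            out.update(self.dense3.params())
        return out


def train_baseline(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    config: NetworkConfig,
    seed: int | None = None,
) -> BaselineCNN:
    """Train the baseline CNN with the shared MSE/Adamax protocol."""
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("training data must contain both classes")
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    init_rng, drop_rng, shuffle_rng = (np.random.default_rng(c) for c in ss.spawn(3))
    model = BaselineCNN(config, X.shape[1], init_rng)
    opt = Adamax(model.params(), lr=config.learning_rate)
    Y = _targets(y, config.target_convention)
    n = X.shape[0]
    for _ in range(config.epochs):
        perm = shuffle_rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            idx = perm[lo : lo + config.batch_size]
            yhat = model.forward(X[idx], train=True, rng=drop_rng)
            err = yhat - Y[idx]
            losses.append(float((err**2).mean()))
            model.backward(2.0 * err / err.size)
            opt.step()
            opt.zero_grad()
        model.history.append(float(np.mean(losses)))
    return model


def predict_baseline(model: BaselineCNN, X_scaled: np.ndarray) -> np.ndarray:
    """Binary predictions (1 = positive class) for pre-scaled features."""
    out = model.forward(X_scaled, train=False)
    if model.config.target_convention == "[1,0]":
        return (out[:, 0] >= out[:, 1]).astype(int)
    return (out[:, 1] >= out[:, 0]).astype(int)
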