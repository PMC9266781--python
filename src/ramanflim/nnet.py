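"""Minimal dense feed-forward classifier on numpy.

Only what the selection network and the small rhomboidal classifier need:
fully-connected layers, ReLU hidden activations, a probabilistic 3-way output
(softmax, or per-node sigmoid with argmax decision), categorical
cross-entropy, and the Adam update rule.  Initialization and mini-batch
shuffling are seeded, so training is bit-reproducible.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


class MLP:
    """Feed-forward network ``n_inputs -> hidden widths -> n_outputs``."""

    def __init__(self, n_inputs: int, hidden: tuple[int, ...], n_outputs: int,
                 output: str = "softmax", learning_rate: float = 0.005,
                 seed: int = 0) -> None:
        if n_inputs < 1:
            raise ValueError("n_inputs must be >= 1")
        if len(hidden) == 0:
            raise ValueError("at least one hidden layer is required")
        if output not in ("softmax", "sigmoid"):
            raise ValueError("output must be 'softmax' or 'sigmoid'")
        self.output = output
        self.learning_rate = learning_rate
        self.rng = np.random.default_rng(seed)
        sizes = (n_inputs, *hidden, n_outputs)
        self.weights = [self.rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                        size=(fan_in, fan_out))
                        for fan_in, fan_out in zip(sizes[:-1], sizes[1:])]
        self.biases = [np.zeros(fan_out) for fan_out in sizes[1:]]
        # Adam state
        self._m = [np.zeros_like(w) for w in self.weights + self.biases]
        self._v = [np.zeros_like(w) for w in self.weights + self.biases]
        self._t = 0

    # -- forward ---------------------------------------------------------
    def _forward(self, X: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        acts = [X]
        h = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ W + b, 0.0)
            acts.append(h)
        z = h @ self.weights[-1] + self.biases[-1]
        if self.output == "softmax":
            z = z - z.max(axis=1, keepdims=True)
            e = np.exp(z)
            probs = e / e.sum(axis=1, keepdims=True)
        else:
            probs = 1.0 / (1.0 + np.exp(-z))
        return acts, probs

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(X, dtype=float))[1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    def accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        """Mean categorical cross-entropy ``-log p[true class]`` of the
        (sum-normalized) class probabilities."""
        probs = self.predict_proba(X)
        probs = probs / (probs.sum(axis=1, keepdims=True) + _EPS)
        return float(-np.mean(np.log(probs[np.arange(len(y)), y] + _EPS)))

    # -- training --------------------------------------------------------
    def train_epoch(self, X: np.ndarray, y: np.ndarray, batch_size: int = 128) -> None:
        n = X.shape[0]
        order = self.rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            self._step(X[idx], y[idx])

    def _step(self, X: np.ndarray, y: np.ndarray) -> None:
        acts, probs = self._forward(X)
        n = X.shape[0]
        onehot = np.zeros_like(probs)
        onehot[np.arange(n), y] = 1.0
        # softmax: categorical cross-entropy; sigmoid: per-node binary
        # cross-entropy (one-vs-rest targets) -- both give dz = p - y
        dz = (probs - onehot) / n
        grads_w: list[np.ndarray] = []
        grads_b: list[np.ndarray] = []
        for layer in range(len(self.weights) - 1, -1, -1):
            grads_w.insert(0, acts[layer].T @ dz)
            grads_b.insert(0, dz.sum(axis=0))
            if layer > 0:
                dz = (dz @ self.weights[layer].T) * (acts[layer] > 0)
        self._adam(grads_w + grads_b)

    def _adam(self, grads: list[np.ndarray], beta1: float = 0.9,
              beta2: float = 0.999, eps: float = 1e-8) -> None:
        self._t += 1
        params = self.weights + self.biases
        for i, (p, g) in enumerate(zip(params, grads)):
            self._m[i] = beta1 * self._m[i] + (1 - beta1) * g
            self._v[i] = beta2 * self._v[i] + (1 - beta2) * g * g
            mhat = self._m[i] / (1 - beta1 ** self._t)
            vhat = self._v[i] / (1 - beta2 ** self._t)
            p -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)
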