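"""Compact numpy implementation of a 1-D convolutional binary classifier.

Architecture (fixed topology, sizes configurable): each input row is treated as a
length-F single-channel sequence in schema column order, passed through

    Conv1D(filters, kernel, ReLU) -> MaxPool1D(pool) -> Dropout(rate)
    -> Flatten -> Dense(units, ReLU) -> Dense(1, sigmoid)

trained with binary cross-entropy and the Adam optimizer (beta1=0.9, beta2=0.999,
eps=1e-8) on shuffled mini-batches. Inputs are standardized with training-set
means/sds. At roughly 40 input features the network has ~4e4 parameters, small
enough for CPU training.
"""

from __future__ import annotations

import numpy as np

ADAM_B1, ADAM_B2, ADAM_EPS = 0.9, 0.999, 1e-8


class Conv1DNet:
    def __init__(self, n_features: int, filters: int = 64, kernel: int = 3, pool: int = 2,
                 dropout: float = 0.5, dense_units: int = 50, batch_size: int = 16,
                 learning_rate: float = 1e-3, seed: int = 0):
        if n_features < kernel:
            raise ValueError("input length shorter than kernel")
        self.F = n_features
        self.filters = filters
        self.kernel = kernel
        self.pool = pool
        self.dropout = dropout
        self.dense_units = dense_units
        self.batch_size = batch_size
        self.lr = learning_rate
        self.rng = np.random.default_rng(seed)
        self.L = n_features - kernel + 1          # conv output length (valid padding)
        self.Lp = self.L // pool                  # pooled length
        self.flat = self.Lp * filters
        r = self.rng
        # He initialization for ReLU layers, Glorot for the sigmoid output
        self.params = {
            "Wc": r.normal(0, np.sqrt(2.0 / kernel), (kernel, filters)),
            "bc": np.zeros(filters),
            "W1": r.normal(0, np.sqrt(2.0 / self.flat), (self.flat, dense_units)),
            "b1": np.zeros(dense_units),
            "W2": r.normal(0, np.sqrt(1.0 / dense_units), (dense_units, 1)),
            "b2": np.zeros(1),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0
        self._mu = np.zeros(n_features)
        self._sigma = np.ones(n_features)

    # ------------------------------------------------------------------ forward

    def _windows(self, X: np.ndarray) -> np.ndarray:
        """(n, L, kernel) sliding windows of the standardized input."""
        n = X.shape[0]
        idx = np.arange(self.L)[:, None] + np.arange(self.kernel)[None, :]
        return X[:, idx]

    def _forward(self, X: np.ndarray, train: bool = False):
        cache = {}
        W = self._windows(X)                                  # (n, L, k)
        Z = W @ self.params["Wc"] + self.params["bc"]         # (n, L, filters)
        H = np.maximum(Z, 0.0)
        Hc = H[:, : self.Lp * self.pool, :].reshape(X.shape[0], self.Lp, self.pool, self.filters)
        P = Hc.max(axis=2)                                    # (n, Lp, filters)
        if train and self.dropout > 0:
            mask = (self.rng.random(P.shape) >= self.dropout) / (1.0 - self.dropout)
            D = P * mask
            cache["mask"] = mask
        else:
            D = P
        A = D.reshape(X.shape[0], self.flat)
        Z1 = A @ self.params["W1"] + self.params["b1"]
        A1 = np.maximum(Z1, 0.0)
        Z2 = A1 @ self.params["W2"] + self.params["b2"]
        out = 1.0 / (1.0 + np.exp(-Z2[:, 0]))
        cache.update(W=W, Z=Z, Hc=Hc, P=P, A=A, Z1=Z1, A1=A1, out=out)
        return out, cache

    # ----------------------------------------------------------------- backward

    def _backward(self, X: np.ndarray, y: np.ndarray, cache) -> dict:
        n = X.shape[0]
        dZ2 = (cache["out"] - y)[:, None] / n                 # BCE + sigmoid
        g = {
            "W2": cache["A1"].T @ dZ2,
            "b2": dZ2.sum(axis=0),
        }
        dA1 = dZ2 @ self.params["W2"].T
        dZ1 = dA1 * (cache["Z1"] > 0)
        g["W1"] = cache["A"].T @ dZ1
        g["b1"] = dZ1.sum(axis=0)
        dA = (dZ1 @ self.params["W1"].T).reshape(n, self.Lp, self.filters)
        if "mask" in cache:
            dA = dA * cache["mask"]
        # route gradient through the max-pool argmax
        Hc = cache["Hc"]                                      # (n, Lp, pool, filters)
        winner = Hc == Hc.max(axis=2, keepdims=True)
        winner = winner / winner.sum(axis=2, keepdims=True)   # split ties evenly
        dHc = winner * dA[:, :, None, :]
        dH = np.zeros((n, self.L, self.filters))
        dH[:, : self.Lp * self.pool, :] = dHc.reshape(n, self.Lp * self.pool, self.filters)
        dZ = dH * (cache["Z"] > 0)
        g["Wc"] = np.einsum("nlk,nlf->kf", cache["W"], dZ)
        g["bc"] = dZ.sum(axis=(0, 1))
        return g

    def _adam_step(self, grads: dict) -> None:
        self._adam_t += 1
        t = self._adam_t
        for k, gk in grads.items():
            m = self._adam_m[k] = ADAM_B1 * self._adam_m[k] + (1 - ADAM_B1) * gk
            v = self._adam_v[k] = ADAM_B2 * self._adam_v[k] + (1 - ADAM_B2) * gk**2
            mhat = m / (1 - ADAM_B1**t)
            vhat = v / (1 - ADAM_B2**t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + ADAM_EPS)

    # ------------------------------------------------------------------- public

    def set_normalization(self, X_train: np.ndarray) -> None:
        self._mu = X_train.mean(axis=0)
        sd = X_train.std(axis=0)
        self._sigma = np.where(sd > 0, sd, 1.0)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self._mu) / self._sigma

    def train_epoch(self, X: np.ndarray, y: np.ndarray) -> float:
        """One pass over shuffled mini-batches; returns the mean training loss."""
        Xs = self._standardize(X)
        y = np.asarray(y, dtype=float)
        order = self.rng.permutation(len(y))
        losses = []
        for start in range(0, len(y), self.batch_size):
            idx = order[start: start + self.batch_size]
            out, cache = self._forward(Xs[idx], train=True)
            p = np.clip(out, 1e-12, 1 - 1e-12)
            losses.append(float(-np.mean(y[idx] * np.log(p) + (1 - y[idx]) * np.log(1 - p))))
            self._adam_step(self._backward(Xs[idx], y[idx], cache))
        return float(np.mean(losses))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        out, _ = self._forward(self._standardize(X), train=False)
        return out

    def get_weights(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict) -> None:
        for k, v in weights.items():
            self.params[k] = v.copy()
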