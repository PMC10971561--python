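"""A small 1-D convolutional network over ordered feature vectors.

Architecture: input (length m) -> 1-D convolution (``filters`` kernels of
width ``kernel``, zero-padded "same") -> ReLU -> max-pool (width 2) ->
dense ReLU layer -> softmax over the damage levels. Trained by
mini-batch Adam on the cross-entropy; all randomness (weight init, batch
shuffling) flows from one seed, so a fixed seed gives bit-identical
weights and predictions.

Implemented directly in numpy with explicit backpropagation: the feature
vectors here are short (a handful to a few dozen features), so the
network is tiny and single-threaded training on hundreds of trees takes
seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CNNTrainingError", "Conv1DNet"]


class CNNTrainingError(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class Conv1DNet:
    filters: int = 16
    kernel: int = 3
    pool: int = 2
    dense: int = 32
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("filters", "kernel", "pool", "dense", "epochs",
                     "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    # -- forward pieces -----------------------------------------------------
    def _conv_patches(self, X: np.ndarray) -> np.ndarray:
        """(n, m) -> (n, m, kernel) zero-padded sliding windows."""
        n, m = X.shape
        p = self.kernel // 2
        Xp = np.pad(X, ((0, 0), (p, p + (self.kernel - 1) - p)))
        idx = np.arange(m)[:, None] + np.arange(self.kernel)[None, :]
        return Xp[:, idx]

    def _forward(self, X: np.ndarray) -> dict:
        patches = self._conv_patches(X)                       # (n, m, K)
        conv = patches @ self.Wc + self.bc                    # (n, m, F)
        relu1 = np.maximum(conv, 0.0)
        n, m, F = relu1.shape
        L = m // self.pool
        if L >= 1:
            pooled_in = relu1[:, : L * self.pool].reshape(n, L, self.pool, F)
            argmax = pooled_in.argmax(axis=2)
            pooled = np.take_along_axis(pooled_in, argmax[:, :, None],
                                        axis=2)[:, :, 0]      # (n, L, F)
        else:  # input shorter than the pool: pass through
            pooled_in, argmax, pooled, L = None, None, relu1, m
        flat = pooled.reshape(n, -1)
        h = np.maximum(flat @ self.W1 + self.b1, 0.0)
        logits = h @ self.W2 + self.b2
        return {"patches": patches, "conv": conv, "relu1": relu1,
                "pooled_in": pooled_in, "argmax": argmax, "L": L,
                "flat": flat, "h": h, "logits": logits,
                "proba": _softmax(logits)}

    def _init(self, m: int, n_classes: int, rng: np.random.Generator) -> None:
        F, K = self.filters, self.kernel
        L = max(1, m // self.pool) if m >= self.pool else m
        flat_dim = L * F
        self.Wc = rng.normal(0, np.sqrt(2.0 / K), (K, F))
        self.bc = np.zeros(F)
        self.W1 = rng.normal(0, np.sqrt(2.0 / flat_dim), (flat_dim, self.dense))
        self.b1 = np.zeros(self.dense)
        self.W2 = rng.normal(0, np.sqrt(2.0 / self.dense),
                             (self.dense, n_classes))
        self.b2 = np.zeros(n_classes)
        self._params = ["Wc", "bc", "W1", "b1", "W2", "b2"]
        self._adam_m = {p: np.zeros_like(getattr(self, p)) for p in self._params}
        self._adam_v = {p: np.zeros_like(getattr(self, p)) for p in self._params}
        self._adam_t = 0

    # -- backward -----------------------------------------------------------
    def _backward(self, cache: dict, y_onehot: np.ndarray,
                  to_input: bool = False) -> dict:
        n = y_onehot.shape[0]
        d_logits = (cache["proba"] - y_onehot) / n
        grads = {
            "W2": cache["h"].T @ d_logits,
            "b2": d_logits.sum(axis=0),
        }
        dh = (d_logits @ self.W2.T) * (cache["h"] > 0)
        grads["W1"] = cache["flat"].T @ dh
        grads["b1"] = dh.sum(axis=0)
        dflat = dh @ self.W1.T
        F = self.filters
        if cache["pooled_in"] is not None:
            L = cache["L"]
            dpooled = dflat.reshape(n, L, F)
            dpool_in = np.zeros_like(cache["pooled_in"])
            np.put_along_axis(dpool_in, cache["argmax"][:, :, None],
                              dpooled[:, :, None, :], axis=2)
            m = cache["relu1"].shape[1]
            drelu1 = np.zeros_like(cache["relu1"])
            drelu1[:, : L * self.pool] = dpool_in.reshape(n, L * self.pool, F)
        else:
            drelu1 = dflat.reshape(cache["relu1"].shape)
        dconv = drelu1 * (cache["conv"] > 0)
        grads["Wc"] = np.einsum("nmk,nmf->kf", cache["patches"], dconv)
        grads["bc"] = dconv.sum(axis=(0, 1))
        if to_input:
            dpatches = np.einsum("nmf,kf->nmk", dconv, self.Wc)
            n_, m_, K = dpatches.shape
            p = K // 2
            dXp = np.zeros((n_, m_ + K - 1))
            for k in range(K):  # scatter-add the overlapping windows
                dXp[:, k:k + m_] += dpatches[:, :, k]
            grads["input"] = dXp[:, p:p + m_]
        return grads

    def _adam_step(self, grads: dict) -> None:
        b1, b2, eps = 0.9, 0.999, 1e-8
        self._adam_t += 1
        t = self._adam_t
        for p in self._params:
            g = grads[p]
            self._adam_m[p] = b1 * self._adam_m[p] + (1 - b1) * g
            self._adam_v[p] = b2 * self._adam_v[p] + (1 - b2) * g * g
            mhat = self._adam_m[p] / (1 - b1**t)
            vhat = self._adam_v[p] / (1 - b2**t)
            setattr(self, p, getattr(self, p)
                    - self.learning_rate * mhat / (np.sqrt(vhat) + eps))

    # -- public API ---------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "Conv1DNet":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("X must be (n, m) with m >= 2 features")
        self.classes_ = np.unique(y)
        onehot = (y[:, None] == self.classes_[None, :]).astype(float)
        rng = np.random.default_rng(self.seed)
        self._init(X.shape[1], self.classes_.size, rng)
        n = X.shape[0]
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            for s in range(0, n, self.batch_size):
                idx = order[s:s + self.batch_size]
                cache = self._forward(X[idx])
                if not np.all(np.isfinite(cache["logits"])):
                    raise CNNTrainingError(
                        f"non-finite logits at epoch {epoch}, batch {s // self.batch_size}; "
                        f"try a lower learning rate (current {self.learning_rate})")
                self._adam_step(self._backward(cache, onehot[idx]))
        self._X_train = X
        self._y_onehot = onehot
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(X, dtype=float))["proba"]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def input_gradient_importances(self) -> np.ndarray:
        """Mean |d loss / d input_j| over the training set, summing to 1."""
        cache = self._forward(self._X_train)
        grads = self._backward(cache, self._y_onehot, to_input=True)
        imp = np.abs(grads["input"] * self._X_train.shape[0]).mean(axis=0)
        total = imp.sum()
        return imp / total if total > 0 else np.full_like(imp, 1 / imp.size)
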