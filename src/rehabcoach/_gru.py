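"""Minimal NumPy gated-recurrent-unit sequence classifier.

Architecture: integer pose-class labels -> learned embedding -> single GRU
layer -> dense softmax over exercise classes.  Trained with categorical
cross-entropy (log loss) and Adam; gradients are computed by manual
backpropagation through time.  Padding label 0 carries no information: its
embedding row is pinned at zero and the hidden state is frozen across
padded timesteps, so trailing padding never alters the prediction.

Everything is deterministic given the seed: parameter initialisation and
the per-epoch shuffle both draw from one ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["GRUClassifier"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-limit, limit, size=shape)


class GRUClassifier:
    """GRU + softmax classifier over fixed-length integer label sequences.

    Parameters
    ----------
    n_classes : number of output classes.
    vocab_size : highest input label value (labels are 0..vocab_size,
        0 being padding).
    units : GRU hidden width.
    embed_dim : embedding dimension for the input labels.
    seed : seed for initialisation and shuffling.
    """

    def __init__(
        self,
        n_classes: int,
        vocab_size: int,
        units: int = 32,
        embed_dim: int = 8,
        seed: int = 0,
    ) -> None:
        self.n_classes = int(n_classes)
        self.vocab_size = int(vocab_size)
        self.units = int(units)
        self.embed_dim = int(embed_dim)
        self.seed = int(seed)
        self._rng = np.random.default_rng(seed)
        rng, h, d, c, v = self._rng, self.units, self.embed_dim, self.n_classes, self.vocab_size

        self.params: dict[str, np.ndarray] = {
            "E": np.vstack([np.zeros((1, d)), _glorot(rng, (v, d))]),
            "Wz": _glorot(rng, (d, h)), "Uz": _glorot(rng, (h, h)), "bz": np.zeros(h),
            "Wr": _glorot(rng, (d, h)), "Ur": _glorot(rng, (h, h)), "br": np.zeros(h),
            "Wh": _glorot(rng, (d, h)), "Uh": _glorot(rng, (h, h)), "bh": np.zeros(h),
            "Wo": _glorot(rng, (h, c)), "bo": np.zeros(c),
        }
        self._adam_m = {k: np.zeros_like(p) for k, p in self.params.items()}
        self._adam_v = {k: np.zeros_like(p) for k, p in self.params.items()}
        self._adam_t = 0
        self.history: dict[str, list[float]] = {"loss": [], "accuracy": []}

    # -- forward -----------------------------------------------------------

    def _forward(self, X: np.ndarray, keep_cache: bool = False):
        """Run the GRU over a batch ``X`` (N, T) of int labels; return final h."""
        p = self.params
        n, T = X.shape
        h = np.zeros((n, self.units))
        cache = []
        for t in range(T):
            ids = X[:, t]
            x = p["E"][ids]
            mask = (ids != 0).astype(x.dtype)[:, None]
            z = _sigmoid(x @ p["Wz"] + h @ p["Uz"] + p["bz"])
            r = _sigmoid(x @ p["Wr"] + h @ p["Ur"] + p["br"])
            hc = np.tanh(x @ p["Wh"] + (r * h) @ p["Uh"] + p["bh"])
            h_new = (1.0 - z) * h + z * hc
            h_next = mask * h_new + (1.0 - mask) * h
            if keep_cache:
                cache.append((ids, x, mask, z, r, hc, h))
            h = h_next
        return h, cache

    def predict_proba(self, X: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        """Class posteriors (N, n_classes); rows sum to 1."""
        X = np.asarray(X, dtype=np.int64)
        out = np.empty((X.shape[0], self.n_classes))
        for start in range(0, X.shape[0], batch_size):
            h, _ = self._forward(X[start : start + batch_size])
            logits = h @ self.params["Wo"] + self.params["bo"]
            logits -= logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            out[start : start + batch_size] = e / e.sum(axis=1, keepdims=True)
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    # -- backward ----------------------------------------------------------

    def _batch_grads(self, X: np.ndarray, y: np.ndarray):
        p = self.params
        n = X.shape[0]
        h_final, cache = self._forward(X, keep_cache=True)
        logits = h_final @ p["Wo"] + p["bo"]
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        loss = -np.mean(np.log(probs[np.arange(n), y] + 1e-12))

        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n

        g = {k: np.zeros_like(v) for k, v in p.items()}
        g["Wo"] = h_final.T @ dlogits
        g["bo"] = dlogits.sum(axis=0)
        dh = dlogits @ p["Wo"].T

        for ids, x, mask, z, r, hc, h_prev in reversed(cache):
            dh_new = dh * mask
            dh_prev = dh * (1.0 - mask)
            dz = dh_new * (hc - h_prev)
            dhc = dh_new * z
            dh_prev += dh_new * (1.0 - z)

            dhc_pre = dhc * (1.0 - hc * hc)
            g["Wh"] += x.T @ dhc_pre
            g["Uh"] += (r * h_prev).T @ dhc_pre
            g["bh"] += dhc_pre.sum(axis=0)
            drh = dhc_pre @ p["Uh"].T
            dr = drh * h_prev
            dh_prev += drh * r

            dz_pre = dz * z * (1.0 - z)
            dr_pre = dr * r * (1.0 - r)
            g["Wz"] += x.T @ dz_pre
            g["Uz"] += h_prev.T @ dz_pre
            g["bz"] += dz_pre.sum(axis=0)
            g["Wr"] += x.T @ dr_pre
            g["Ur"] += h_prev.T @ dr_pre
            g["br"] += dr_pre.sum(axis=0)

            dx = dhc_pre @ p["Wh"].T + dz_pre @ p["Wz"].T + dr_pre @ p["Wr"].T
            np.add.at(g["E"], ids, dx)
            dh = dh_prev + dz_pre @ p["Uz"].T + dr_pre @ p["Ur"].T
        g["E"][0] = 0.0  # padding embedding stays pinned at zero
        return loss, g, probs

    def _adam_step(self, grads, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7) -> None:
        self._adam_t += 1
        t = self._adam_t
        for k, p in self.params.items():
            gk = grads[k]
            m = self._adam_m[k]
            v = self._adam_v[k]
            m *= beta1
            m += (1 - beta1) * gk
            v *= beta2
            v += (1 - beta2) * gk * gk
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)
        self.params["E"][0] = 0.0

    # -- training ----------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int = 10,
        batch_size: int = 128,
        lr: float = 1e-3,
    ) -> "GRUClassifier":
        """Train with Adam on shuffled mini-batches; records loss/accuracy."""
        X = np.asarray(X, dtype=np.int64)
        y = np.asarray(y, dtype=np.int64)
        if np.unique(y).size < 2:
            raise ValueError("training data must contain at least 2 classes")
        n = X.shape[0]
        for _ in range(epochs):
            order = self._rng.permutation(n)
            total_loss = 0.0
            correct = 0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                loss, grads, probs = self._batch_grads(X[idx], y[idx])
                self._adam_step(grads, lr=lr)
                total_loss += loss * idx.size
                correct += int((probs.argmax(axis=1) == y[idx]).sum())
            self.history["loss"].append(total_loss / n)
            self.history["accuracy"].append(correct / n)
        return self

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        meta = np.array(
            [self.n_classes, self.vocab_size, self.units, self.embed_dim, self.seed],
            dtype=np.int64,
        )
        np.savez(path, __meta__=meta, **self.params)

    @classmethod
    def load(cls, path) -> "GRUClassifier":
        data = np.load(path)
        meta = data["__meta__"]
        model = cls(*(int(v) for v in meta))
        for k in model.params:
            model.params[k] = data[k]
        return model
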