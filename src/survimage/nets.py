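"""A compact convolutional network in pure numpy.

This is the package's desk-scale image classifier: two 3×3 convolution +
ReLU + 2×2 max-pool stages, dropout before a final linear layer, softmax
cross-entropy loss, trained with Adam. It is deliberately small so that the
whole TLS/TSL training loop runs on a single CPU core in seconds on the
synthetic image sizes (side ≈ 20), while keeping the training ingredients —
Adam, cross-entropy, dropout — identical to the full-scale protocol.

All randomness (weight init, batch shuffling, dropout masks) comes from one
``numpy.random.Generator`` seeded at construction, so training is exactly
reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["TinyConvNet"]


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded stride-1 cross-correlation.

    x: (N, C, H, W); w: (F, C, 3, 3); b: (F,) → (N, F, H, W)
    """
    k = w.shape[-1]
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (N, C, H, W, k, k)
    return np.einsum("nchwij,fcij->nfhw", win, w, optimize=True) + b[None, :, None, None]


def _conv_backward(
    x: np.ndarray, w: np.ndarray, dout: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of the same-padded stride-1 correlation."""
    k = w.shape[-1]
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    dw = np.einsum("nchwij,nfhw->fcij", win, dout, optimize=True)
    db = dout.sum(axis=(0, 2, 3))
    # dx: full correlation of dout with w flipped in both spatial axes
    dop = np.pad(dout, ((0, 0), (0, 0), (p, p), (p, p)))
    dwin = np.lib.stride_tricks.sliding_window_view(dop, (k, k), axis=(2, 3))
    wflip = w[:, :, ::-1, ::-1]
    dx = np.einsum("nfhwij,fcij->nchw", dwin, wflip, optimize=True)
    return dx, dw, db


def _pool_forward(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2×2 max pool, stride 2 (odd trailing rows/cols are cropped)."""
    n, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    xc = x[:, :, : 2 * h2, : 2 * w2]
    blocks = xc.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5)
    blocks = blocks.reshape(n, c, h2, w2, 4)
    idx = blocks.argmax(axis=-1)
    out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _pool_backward(dout: np.ndarray, idx: np.ndarray, shape: tuple) -> np.ndarray:
    n, c, h, w = shape
    h2, w2 = h // 2, w // 2
    dblocks = np.zeros((n, c, h2, w2, 4), dtype=dout.dtype)
    np.put_along_axis(dblocks, idx[..., None], dout[..., None], axis=-1)
    dx = np.zeros(shape, dtype=dout.dtype)
    dx[:, :, : 2 * h2, : 2 * w2] = (
        dblocks.reshape(n, c, h2, w2, 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, 2 * h2, 2 * w2)
    )
    return dx


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class TinyConvNet:
    """conv(8)→relu→pool → conv(16)→relu→pool → dropout → linear → softmax."""

    def __init__(
        self,
        side: int,
        n_classes: int = 2,
        channels: tuple[int, int] = (8, 16),
        dropout: float = 0.4,
        seed: int = 0,
    ):
        if side < 4:
            raise ValueError(f"image side {side} too small for two pooling stages")
        self.side = side
        self.n_classes = n_classes
        self.dropout = dropout
        self.rng = np.random.default_rng(seed)
        c1, c2 = channels
        s2 = (side // 2) // 2
        self.flat_dim = c2 * s2 * s2
        r = self.rng
        self.params = {
            "w1": r.normal(0, np.sqrt(2.0 / 9), size=(c1, 1, 3, 3)),
            "b1": np.zeros(c1),
            "w2": r.normal(0, np.sqrt(2.0 / (9 * c1)), size=(c2, c1, 3, 3)),
            "b2": np.zeros(c2),
            "w3": r.normal(0, np.sqrt(2.0 / self.flat_dim), size=(self.flat_dim, n_classes)),
            "b3": np.zeros(n_classes),
        }
        self.history: list[float] = []  # mean training loss per epoch

    # -- forward / backward -------------------------------------------------

    def _forward(self, x: np.ndarray, train: bool) -> tuple[np.ndarray, dict]:
        p = self.params
        cache: dict = {"x": x}
        z1 = _conv_forward(x, p["w1"], p["b1"])
        a1 = np.maximum(z1, 0)
        p1, i1 = _pool_forward(a1)
        z2 = _conv_forward(p1, p["w2"], p["b2"])
        a2 = np.maximum(z2, 0)
        p2, i2 = _pool_forward(a2)
        flat = p2.reshape(x.shape[0], -1)
        if train and self.dropout > 0:
            mask = (self.rng.random(flat.shape) >= self.dropout) / (1 - self.dropout)
            flat = flat * mask
            cache["mask"] = mask
        logits = flat @ p["w3"] + p["b3"]
        cache.update(z1=z1, a1=a1, p1=p1, i1=i1, z2=z2, a2=a2, p2=p2, i2=i2, flat=flat)
        return logits, cache

    def _backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        grads = {
            "w3": cache["flat"].T @ dlogits,
            "b3": dlogits.sum(axis=0),
        }
        dflat = dlogits @ p["w3"].T
        if "mask" in cache:
            dflat = dflat * cache["mask"]
        dp2 = dflat.reshape(cache["p2"].shape)
        da2 = _pool_backward(dp2, cache["i2"], cache["a2"].shape)
        dz2 = da2 * (cache["z2"] > 0)
        dp1, grads["w2"], grads["b2"] = _conv_backward(cache["p1"], p["w2"], dz2)
        da1 = _pool_backward(dp1, cache["i1"], cache["a1"].shape)
        dz1 = da1 * (cache["z1"] > 0)
        _, grads["w1"], grads["b1"] = _conv_backward(cache["x"], p["w1"], dz1)
        return grads

    @staticmethod
    def _softmax(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    # -- public API ---------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int = 10,
        batch_size: int = 16,
        learning_rate: float = 1e-3,
    ) -> "TinyConvNet":
        """Minimize softmax cross-entropy with Adam.

        ``X``: (N, side, side) floats, ``y``: integer class labels.
        Records the mean per-example loss of each epoch in :attr:`history`.
        """
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        if X.ndim != 3 or X.shape[1:] != (self.side, self.side):
            raise ValueError(f"expected X of shape (N, {self.side}, {self.side})")
        n = X.shape[0]
        opt = _Adam(self.params, learning_rate)
        xin = X[:, None, :, :] - 0.5  # center gray levels
        for _ in range(epochs):
            order = self.rng.permutation(n)
            total = 0.0
            for start in range(0, n, batch_size):
                sel = order[start : start + batch_size]
                xb, yb = xin[sel], y[sel]
                logits, cache = self._forward(xb, train=True)
                probs = self._softmax(logits)
                eps = 1e-12
                total += -np.log(probs[np.arange(len(yb)), yb] + eps).sum()
                dlogits = probs.copy()
                dlogits[np.arange(len(yb)), yb] -= 1.0
                dlogits /= len(yb)
                grads = self._backward(cache, dlogits)
                opt.step(self.params, grads)
            self.history.append(total / n)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        xin = X[:, None, :, :] - 0.5
        out = []
        for start in range(0, X.shape[0], 256):
            logits, _ = self._forward(xin[start : start + 256], train=False)
            out.append(self._softmax(logits))
        return np.concatenate(out, axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)
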