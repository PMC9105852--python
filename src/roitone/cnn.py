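"""Shallow convolutional network for small grey-level ROI patches.

The classifier is deliberately small, sized for a few hundred training
images: two conv(3x3, 32 filters, same padding, ReLU) + 2x2 max-pool blocks
reduce a 32x32 input to 32 feature maps of 8x8, which are flattened to a
2048-vector and classified by a 2048-100-2 fully connected head with ReLU,
dropout 0.5 before the output layer, and softmax output.  Training uses
softmax cross-entropy minimised with Adam (lr 0.001, default moments) over
100 epochs at batch size 400 — with 400 training images that is full-batch
gradient descent.

The network is implemented directly in numpy (im2col convolution, argmax
max-pool, inverted dropout), which keeps training bit-deterministic under a
seed: identical config, data and seed give identical weights.  Inputs are
scaled to [0, 1] by division by ``fmax`` before the first layer; nothing
else is normalised, so grey-level corrections applied to the images are
seen by the network at face value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CNNConfig", "ShallowCNN", "CNNClassifier", "cnn_factory"]


@dataclass(frozen=True)
class CNNConfig:
    input_side: int = 32
    conv_filters: int = 32
    kernel_side: int = 3
    pool_side: int = 2
    n_blocks: int = 2
    hidden_units: int = 100
    n_classes: int = 2
    dropout_rate: float = 0.5
    batch_size: int = 400
    epochs: int = 100
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel_side % 2 != 1:
            raise ValueError("kernel_side must be odd (same-size padding)")
        if self.input_side % self.pool_side**self.n_blocks != 0:
            raise ValueError(
                f"input_side {self.input_side} not divisible by "
                f"pool_side**n_blocks = {self.pool_side ** self.n_blocks}"
            )
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")

    @property
    def final_side(self) -> int:
        return self.input_side // self.pool_side**self.n_blocks

    @property
    def flatten_width(self) -> int:
        """Width of the flattened feature vector (2048 for the default 32x32 net)."""
        return self.conv_filters * self.final_side**2


# ---------------------------------------------------------------------------
# layer primitives (channels-last, float32 by default)

def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, k: int):
    """Same-padding convolution in shift-accumulate form.

    Equivalent to im2col followed by one big matmul, but accumulates k*k
    small matmuls against slices of the padded input, avoiding the column
    buffer.  x: (N, H, W, C); w: (k*k*C, F); returns (out, xp) with out
    (N, H, W, F) and xp the padded input kept for the backward pass.
    """
    n, h, wd, c = x.shape
    f = w.shape[1]
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    out = np.tile(b.astype(x.dtype), (n * h * wd, 1))
    i = 0
    for di in range(k):
        for dj in range(k):
            patch = xp[:, di : di + h, dj : dj + wd, :].reshape(-1, c)
            out += patch @ w[i * c : (i + 1) * c]
            i += 1
    return out.reshape(n, h, wd, f), xp


def _conv_backward(dout: np.ndarray, xp: np.ndarray, w: np.ndarray, x_shape, k: int):
    n, h, wd, c = x_shape
    f = w.shape[1]
    pad = k // 2
    d2 = dout.reshape(-1, f)
    dw = np.empty_like(w)
    db = d2.sum(axis=0)
    dxp = np.zeros_like(xp)
    i = 0
    for di in range(k):
        for dj in range(k):
            patch = xp[:, di : di + h, dj : dj + wd, :].reshape(-1, c)
            dw[i * c : (i + 1) * c] = patch.T @ d2
            dxp[:, di : di + h, dj : dj + wd, :] += (d2 @ w[i * c : (i + 1) * c].T).reshape(
                n, h, wd, c
            )
            i += 1
    dx = dxp[:, pad : pad + h, pad : pad + wd, :]
    return dx, dw, db


def _pool_forward(x: np.ndarray, p: int):
    """Non-overlapping p x p max-pool; ties go to the first maximum."""
    n, h, wd, c = x.shape
    xr = (
        x.reshape(n, h // p, p, wd // p, p, c)
        .transpose(0, 1, 3, 5, 2, 4)
        .reshape(n, h // p, wd // p, c, p * p)
    )
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _pool_backward(dout: np.ndarray, idx: np.ndarray, x_shape, p: int):
    n, h, wd, c = x_shape
    dxr = np.zeros((n, h // p, wd // p, c, p * p), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    return (
        dxr.reshape(n, h // p, wd // p, c, p, p)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(n, h, wd, c)
    )


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ShallowCNN:
    """The network itself: parameter store, forward/backward, training loop."""

    def __init__(self, config: CNNConfig, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        self.history: list[dict] = []
        self._rng = np.random.default_rng(config.seed)
        self.params = self._init_params()
        self._opt = _Adam(self.params, config.learning_rate)

    def _init_params(self) -> dict:
        cfg = self.config
        rng = self._rng
        params: dict[str, np.ndarray] = {}
        c_in = 1
        k = cfg.kernel_side
        for blk in range(cfg.n_blocks):
            fan_in = k * k * c_in
            params[f"Wc{blk}"] = (
                rng.standard_normal((fan_in, cfg.conv_filters)) * np.sqrt(2.0 / fan_in)
            ).astype(self.dtype)
            params[f"bc{blk}"] = np.zeros(cfg.conv_filters, self.dtype)
            c_in = cfg.conv_filters
        params["Wh"] = (
            rng.standard_normal((cfg.flatten_width, cfg.hidden_units))
            * np.sqrt(2.0 / cfg.flatten_width)
        ).astype(self.dtype)
        params["bh"] = np.zeros(cfg.hidden_units, self.dtype)
        params["Wo"] = (
            rng.standard_normal((cfg.hidden_units, cfg.n_classes))
            * np.sqrt(2.0 / cfg.hidden_units)
        ).astype(self.dtype)
        params["bo"] = np.zeros(cfg.n_classes, self.dtype)
        return params

    # -- forward / backward -------------------------------------------------

    def _forward(self, x: np.ndarray, train: bool):
        """x: (N, side, side, 1) scaled to [0,1]; returns (probs, cache)."""
        cfg = self.config
        cache: dict = {"inputs": [], "padded": [], "pre": [], "pool_idx": [], "pool_in": []}
        h = x
        for blk in range(cfg.n_blocks):
            cache["inputs"].append(h)
            z, xp = _conv_forward(h, self.params[f"Wc{blk}"], self.params[f"bc{blk}"], cfg.kernel_side)
            cache["padded"].append(xp)
            cache["pre"].append(z)
            a = np.maximum(z, 0)
            cache["pool_in"].append(a)
            h, idx = _pool_forward(a, cfg.pool_side)
            cache["pool_idx"].append(idx)
        flat = h.reshape(h.shape[0], -1)
        cache["flat_shape"] = h.shape
        cache["flat"] = flat
        zh = flat @ self.params["Wh"] + self.params["bh"]
        ah = np.maximum(zh, 0)
        cache["zh"], cache["ah_raw"] = zh, ah
        if train and cfg.dropout_rate > 0:
            keep = 1.0 - cfg.dropout_rate
            mask = (self._rng.random(ah.shape) < keep).astype(self.dtype) / keep
            ah = ah * mask
            cache["drop_mask"] = mask
        cache["ah"] = ah
        logits = ah @ self.params["Wo"] + self.params["bo"]
        return _softmax(logits), cache

    def _backward(self, probs: np.ndarray, y: np.ndarray, cache: dict) -> dict:
        cfg = self.config
        n = len(y)
        grads: dict[str, np.ndarray] = {}
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grads["Wo"] = cache["ah"].T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        dah = dlogits @ self.params["Wo"].T
        if "drop_mask" in cache:
            dah = dah * cache["drop_mask"]
        dzh = dah * (cache["zh"] > 0)
        grads["Wh"] = cache["flat"].T @ dzh
        grads["bh"] = dzh.sum(axis=0)
        dflat = dzh @ self.params["Wh"].T
        dh = dflat.reshape(cache["flat_shape"])
        for blk in reversed(range(cfg.n_blocks)):
            da = _pool_backward(dh, cache["pool_idx"][blk], cache["pool_in"][blk].shape, cfg.pool_side)
            dz = da * (cache["pre"][blk] > 0)
            dh, grads[f"Wc{blk}"], grads[f"bc{blk}"] = _conv_backward(
                dz, cache["padded"][blk], self.params[f"Wc{blk}"], cache["inputs"][blk].shape, cfg.kernel_side
            )
        return grads

    def loss(self, x: np.ndarray, y: np.ndarray, train: bool = False) -> float:
        probs, _ = self._forward(x, train=train)
        p = probs[np.arange(len(y)), y]
        return float(-np.mean(np.log(np.maximum(p, 1e-12))))

    # -- training / inference ----------------------------------------------

    def _prepare(self, images: np.ndarray, fmax: int) -> np.ndarray:
        x = np.asarray(images, dtype=self.dtype) / fmax
        if x.ndim != 3 or x.shape[1] != self.config.input_side or x.shape[2] != self.config.input_side:
            raise ValueError(
                f"expected (n, {self.config.input_side}, {self.config.input_side}) images, got {x.shape}"
            )
        return x[..., None]

    def fit(self, images: np.ndarray, labels: np.ndarray, fmax: int = 255) -> "ShallowCNN":
        if len(images) == 0:
            raise ValueError("empty training set")
        x = self._prepare(images, fmax)
        y = np.asarray(labels, dtype=np.int64)
        cfg = self.config
        n = len(x)
        for epoch in range(cfg.epochs):
            order = self._rng.permutation(n) if cfg.batch_size < n else np.arange(n)
            losses, correct = [], 0
            for start in range(0, n, cfg.batch_size):
                sel = order[start : start + cfg.batch_size]
                probs, cache = self._forward(x[sel], train=True)
                p = probs[np.arange(len(sel)), y[sel]]
                losses.append(-np.mean(np.log(np.maximum(p, 1e-12))) * len(sel))
                correct += int((probs.argmax(axis=1) == y[sel]).sum())
                grads = self._backward(probs, y[sel], cache)
                self._opt.step(self.params, grads)
            self.history.append(
                {"epoch": epoch, "loss": float(sum(losses) / n), "accuracy": correct / n}
            )
        return self

    def predict_proba(self, images: np.ndarray, fmax: int = 255) -> np.ndarray:
        x = self._prepare(images, fmax)
        probs, _ = self._forward(x, train=False)
        return probs

    def predict(self, images: np.ndarray, fmax: int = 255) -> np.ndarray:
        return self.predict_proba(images, fmax).argmax(axis=1)

    # -- persistence --------------------------------------------------------

    def history_frame(self):
        """Per-epoch loss/accuracy as a DataFrame (write with .to_csv)."""
        import pandas as pd

        return pd.DataFrame(self.history, columns=["epoch", "loss", "accuracy"])

    def save(self, path) -> None:
        """Checkpoint weights + config to an .npz archive."""
        import json
        from dataclasses import asdict

        np.savez(path, __config__=json.dumps(asdict(self.config)), **self.params)

    @classmethod
    def load(cls, path) -> "ShallowCNN":
        import json

        with np.load(path, allow_pickle=False) as archive:
            cfg = CNNConfig(**json.loads(str(archive["__config__"])))
            model = cls(cfg)
            for k in model.params:
                model.params[k] = archive[k]
        return model


class CNNClassifier:
    """Holdout-protocol adapter: fresh :class:`ShallowCNN` fit per split."""

    def __init__(self, config: CNNConfig):
        self.config = config
        self.model: ShallowCNN | None = None

    def fit(self, images: np.ndarray, labels: np.ndarray, fmax: int = 255) -> "CNNClassifier":
        self._fmax = fmax
        self.model = ShallowCNN(self.config).fit(images, labels, fmax)
        return self

    def predict(self, images: np.ndarray) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("classifier not fitted")
        return self.model.predict(images, self._fmax)


def cnn_factory(config: CNNConfig):
    """Return a per-trial classifier factory: ``factory(seed) -> CNNClassifier``."""
    from dataclasses import replace

    def make(seed: int) -> CNNClassifier:
        return CNNClassifier(replace(config, seed=int(seed)))

    return make
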