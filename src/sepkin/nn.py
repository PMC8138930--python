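"""Compact numpy neural networks for binary sequence classification.

Three architectures share one training loop (mini-batch Adagrad on binary
cross-entropy, sigmoid output, early stopping on a training-loss plateau):

* :class:`LSTMClassifier` — a single LSTM layer read out at the last hour,
  with inverted dropout on the final hidden state during training;
* :class:`ConvClassifier` — one 1-D convolution over the time axis, ReLU,
  global max-pooling, dense sigmoid head;
* :class:`LinearClassifier` — a single dense layer on the flattened
  time x feature vector (a linear model with a sigmoid output).

All randomness (initialization, batch shuffling, dropout masks) comes from
one seeded generator, so training is reproducible on a fixed thread count.
Inputs are (n_patients, T, C) arrays; labels are 0/1.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # tanh form is stable for large |z|
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    """Orthogonal columns blocks — the usual init for recurrent kernels."""
    blocks = []
    for start in range(0, cols, rows):
        a = rng.normal(size=(rows, min(rows, cols - start)))
        q, r = np.linalg.qr(a)
        blocks.append(q * np.sign(np.diag(r))[: q.shape[1]])
    return np.concatenate(blocks, axis=1)


def _clip_global_norm(grads: dict[str, np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        for g in grads.values():
            g *= scale


class _Adagrad:
    """Per-parameter Adagrad accumulator."""

    def __init__(self, params: dict[str, np.ndarray], lr: float, eps: float = 1e-8):
        self.lr = lr
        self.eps = eps
        self.cache = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        for k, g in grads.items():
            self.cache[k] += g * g
            params[k] -= self.lr * g / (np.sqrt(self.cache[k]) + self.eps)


class _SequenceNet:
    """Shared fit/predict loop; subclasses provide init/forward/backward."""

    def __init__(
        self,
        lr: float = 0.1,
        batch_size: int = 64,
        epochs: int = 50,
        patience: int = 5,
        min_delta: float = 1e-4,
        clip_norm: float = 5.0,
        seed: int = 0,
    ):
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.patience = patience
        self.min_delta = min_delta
        self.clip_norm = clip_norm
        self.seed = seed
        self.params: dict[str, np.ndarray] = {}
        self.loss_history: list[float] = []

    # subclass hooks -----------------------------------------------------
    def _init_params(self, rng: np.random.Generator, t_len: int, n_chan: int) -> None:
        raise NotImplementedError

    def _forward(self, x: np.ndarray, train: bool, rng: np.random.Generator):
        """Return (probabilities (N,), cache for backward)."""
        raise NotImplementedError

    def _backward(self, x, y, p, cache) -> dict[str, np.ndarray]:
        raise NotImplementedError

    # training -----------------------------------------------------------
    def fit(self, x: np.ndarray, y: np.ndarray) -> "_SequenceNet":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if x.ndim != 3:
            raise ValueError("expected input of shape (n, T, C)")
        rng = np.random.default_rng(self.seed)
        self._init_params(rng, x.shape[1], x.shape[2])
        opt = _Adagrad(self.params, lr=self.lr)
        n = len(x)
        best = np.inf
        stall = 0
        self.loss_history = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = x[idx], y[idx]
                p, cache = self._forward(xb, train=True, rng=rng)
                losses.append(_bce(p, yb))
                grads = self._backward(xb, yb, p, cache)
                _clip_global_norm(grads, self.clip_norm)
                opt.step(self.params, grads)
            epoch_loss = float(np.mean(losses))
            self.loss_history.append(epoch_loss)
            if epoch_loss < best - self.min_delta:
                best = epoch_loss
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        p, _ = self._forward(x, train=False, rng=np.random.default_rng(0))
        return p

    def predict(self, x: np.ndarray) -> np.ndarray:
        return (self.predict_proba(x) >= 0.5).astype(int)


class LinearClassifier(_SequenceNet):
    """Single dense layer on the flattened input, sigmoid output."""

    def _init_params(self, rng, t_len, n_chan):
        d = t_len * n_chan
        self.params = {"W": _glorot(rng, (d, 1)), "b": np.zeros(1)}

    def _forward(self, x, train, rng):
        flat = x.reshape(len(x), -1)
        p = _sigmoid(flat @ self.params["W"] + self.params["b"]).ravel()
        return p, flat

    def _backward(self, x, y, p, flat):
        dz = ((p - y) / len(y))[:, None]
        return {"W": flat.T @ dz, "b": dz.sum(axis=0)}


class ConvClassifier(_SequenceNet):
    """1-D convolution over time, ReLU, global max-pool, dense sigmoid head."""

    def __init__(self, filters: int = 64, kernel_size: int = 3, **kwargs):
        super().__init__(**kwargs)
        self.filters = filters
        self.kernel_size = kernel_size

    def _init_params(self, rng, t_len, n_chan):
        if t_len < self.kernel_size:
            raise ValueError("series shorter than the convolution kernel")
        k, c, f = self.kernel_size, n_chan, self.filters
        self.params = {
            "Wc": _glorot(rng, (k * c, f)).reshape(k, c, f),
            "bc": np.zeros(f),
            "Wd": _glorot(rng, (f, 1)),
            "bd": np.zeros(1),
        }

    def _forward(self, x, train, rng):
        # windows: (N, T-k+1, C, k)
        windows = sliding_window_view(x, self.kernel_size, axis=1)
        z = np.einsum("ntck,kcf->ntf", windows, self.params["Wc"]) + self.params["bc"]
        r = np.maximum(z, 0.0)
        arg = r.argmax(axis=1)                      # (N, F)
        pooled = np.take_along_axis(r, arg[:, None, :], axis=1)[:, 0, :]
        p = _sigmoid(pooled @ self.params["Wd"] + self.params["bd"]).ravel()
        return p, (windows, z, arg, pooled)

    def _backward(self, x, y, p, cache):
        windows, z, arg, pooled = cache
        dz_out = ((p - y) / len(y))[:, None]
        d_pooled = dz_out @ self.params["Wd"].T     # (N, F)
        dr = np.zeros_like(z)
        np.put_along_axis(dr, arg[:, None, :], d_pooled[:, None, :], axis=1)
        dz = dr * (z > 0)
        return {
            "Wc": np.einsum("ntck,ntf->kcf", windows, dz),
            "bc": dz.sum(axis=(0, 1)),
            "Wd": pooled.T @ dz_out,
            "bd": dz_out.sum(axis=0),
        }


class LSTMClassifier(_SequenceNet):
    """One LSTM layer, last-hour readout, dropout before the dense head.

    Gate layout in the packed weight matrices is [input, forget, cell, output];
    the forget-gate bias starts at +1 so memory is retained early in training.
    """

    def __init__(self, hidden_units: int = 128, dropout: float = 0.2, **kwargs):
        super().__init__(**kwargs)
        self.hidden_units = hidden_units
        self.dropout = dropout

    def _init_params(self, rng, t_len, n_chan):
        h = self.hidden_units
        b = np.zeros(4 * h)
        b[h : 2 * h] = 1.0
        self.params = {
            "Wx": _glorot(rng, (n_chan, 4 * h)),
            "Wh": _orthogonal(rng, h, 4 * h),
            "b": b,
            # zero head: training starts from the base-rate prediction, which
            # keeps the first Adagrad steps from swamping the recurrent layer
            "Wd": np.zeros((h, 1)),
            "bd": np.zeros(1),
        }

    def _forward(self, x, train, rng):
        n, t_len, _ = x.shape
        h_dim = self.hidden_units
        h = np.zeros((n, h_dim))
        c = np.zeros((n, h_dim))
        steps = []
        for t in range(t_len):
            xt = x[:, t, :]
            a = xt @ self.params["Wx"] + h @ self.params["Wh"] + self.params["b"]
            i = _sigmoid(a[:, :h_dim])
            f = _sigmoid(a[:, h_dim : 2 * h_dim])
            g = np.tanh(a[:, 2 * h_dim : 3 * h_dim])
            o = _sigmoid(a[:, 3 * h_dim :])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            steps.append((xt, h, c, i, f, g, o, c_new))
            h, c = h_new, c_new
        if train and self.dropout > 0:
            keep = 1.0 - self.dropout
            mask = (rng.random(h.shape) < keep) / keep
        else:
            mask = np.ones_like(h)
        h_drop = h * mask
        p = _sigmoid(h_drop @ self.params["Wd"] + self.params["bd"]).ravel()
        return p, (steps, h_drop, mask)

    def _backward(self, x, y, p, cache):
        steps, h_drop, mask = cache
        h_dim = self.hidden_units
        dz = ((p - y) / len(y))[:, None]
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        grads["Wd"] = h_drop.T @ dz
        grads["bd"] = dz.sum(axis=0)
        dh = (dz @ self.params["Wd"].T) * mask
        dc = np.zeros_like(dh)
        for xt, h_prev, c_prev, i, f, g, o, c_new in reversed(steps):
            tanh_c = np.tanh(c_new)
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            da = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            grads["Wx"] += xt.T @ da
            grads["Wh"] += h_prev.T @ da
            grads["b"] += da.sum(axis=0)
            dh = da @ self.params["Wh"].T
            dc = dc * f
        return grads
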