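"""A compact NumPy LSTM binary classifier.

Architecture (fixed by default): each sample's ordered feature vector is fed
as a length-T sequence of scalars through two stacked LSTM layers (128 and 32
units), the final hidden state passes through a fully connected sigmoid layer
with 8 units and a single sigmoid output unit. Training minimizes mean
squared error with Adam. All randomness (weight initialization, minibatch
shuffling) flows from one seed, so a rerun with the same seed reproduces the
parameters bit for bit on a given platform.

Computation is float32 throughout; gradients come from backpropagation
through time and are verified against finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

DTYPE = np.float32


@dataclass(frozen=True)
class ModelConfig:
    """Stratifier hyperparameters.

    ``hidden`` = (LSTM1 units, LSTM2 units, dense units); ``sequence_mode``
    controls how a feature vector enters the recurrence: ``"timesteps"``
    (default) feeds T timesteps of one scalar each, ``"flat"`` feeds a single
    timestep carrying all T features.
    """

    hidden: tuple[int, int, int] = (128, 32, 8)
    epochs: int = 1000
    learning_rate: float = 1e-3
    batch_size: int | None = 32
    seed: int = 20210723
    threshold: float = 0.5
    sequence_mode: str = "timesteps"

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.hidden) or len(self.hidden) != 3:
            raise ValueError("hidden must be three positive layer sizes")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if self.sequence_mode not in ("timesteps", "flat"):
            raise ValueError("sequence_mode must be 'timesteps' or 'flat'")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # clip keeps exp finite in float32; accuracy is unaffected at |x| >= 30
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def _orthogonal(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Block-orthogonal recurrent initialization (one block per gate)."""
    rows, cols = shape
    blocks = []
    for lo in range(0, cols, rows):
        a = rng.normal(size=(rows, min(rows, cols - lo)))
        q, r = np.linalg.qr(a)
        q *= np.sign(np.diag(r))
        blocks.append(q)
    return np.concatenate(blocks, axis=1).astype(DTYPE)


class _LSTMLayer:
    """One LSTM layer over a (T, n, D) input; gate layout i, f, o, g."""

    def __init__(self, rng: np.random.Generator, dim_in: int, units: int) -> None:
        self.units = units
        self.Wx = _glorot(rng, (dim_in, 4 * units))
        self.Wh = _orthogonal(rng, (units, 4 * units))
        self.b = np.zeros(4 * units, dtype=DTYPE)
        self.b[units:2 * units] = 1.0  # forget-gate bias
        self._cache = None

    @property
    def params(self) -> list[np.ndarray]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, X: np.ndarray) -> np.ndarray:
        T, n, _ = X.shape
        H = self.units
        proj = X @ self.Wx + self.b  # (T, n, 4H), one GEMM for all timesteps
        h = np.zeros((n, H), dtype=DTYPE)
        c = np.zeros((n, H), dtype=DTYPE)
        Hs = np.empty((T, n, H), dtype=DTYPE)
        gates = np.empty((T, n, 4 * H), dtype=DTYPE)
        Cs = np.empty((T, n, H), dtype=DTYPE)
        TanhC = np.empty((T, n, H), dtype=DTYPE)
        Cprev = np.empty((T, n, H), dtype=DTYPE)
        Hprev = np.empty((T, n, H), dtype=DTYPE)
        for t in range(T):
            Hprev[t] = h
            Cprev[t] = c
            z = gates[t]
            np.matmul(h, self.Wh, out=z)
            z += proj[t]
            z[:, :3 * H] = _sigmoid(z[:, :3 * H])   # i, f, o
            np.tanh(z[:, 3 * H:], out=z[:, 3 * H:])  # g
            c = z[:, H:2 * H] * c
            c += z[:, :H] * z[:, 3 * H:]
            tc = np.tanh(c)
            h = z[:, 2 * H:3 * H] * tc
            Cs[t] = c
            TanhC[t] = tc
            Hs[t] = h
        self._cache = (X, Hs, gates, Cs, TanhC, Cprev, Hprev)
        return Hs

    def backward(self, dH: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        X, Hs, gates, Cs, TanhC, Cprev, Hprev = self._cache
        T, n, H = Hs.shape
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dX = np.empty_like(X)
        dh_next = np.zeros((n, H), dtype=DTYPE)
        dc_next = np.zeros((n, H), dtype=DTYPE)
        dz = np.empty((n, 4 * H), dtype=DTYPE)
        for t in range(T - 1, -1, -1):
            g = gates[t]
            i, f, o, gg = g[:, :H], g[:, H:2 * H], g[:, 2 * H:3 * H], g[:, 3 * H:]
            tc = TanhC[t]
            dh = dH[t] + dh_next
            dc = dc_next + dh * o * (1.0 - tc * tc)
            dz[:, :H] = dc * gg * i * (1.0 - i)
            dz[:, H:2 * H] = dc * Cprev[t] * f * (1.0 - f)
            dz[:, 2 * H:3 * H] = dh * tc * o * (1.0 - o)
            dz[:, 3 * H:] = dc * i * (1.0 - gg * gg)
            dWx += X[t].T @ dz
            dWh += Hprev[t].T @ dz
            db += dz.sum(axis=0)
            np.matmul(dz, self.Wx.T, out=dX[t])
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        self._cache = None
        return dX, [dWx, dWh, db]


class _Adam:
    def __init__(self, params: Sequence[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)


class LSTMClassifier:
    """The recurrent stratifier network (two LSTM layers + dense head)."""

    def __init__(self, n_features: int, config: ModelConfig) -> None:
        self.n_features = int(n_features)
        self.config = config
        rng = np.random.default_rng(config.seed)
        h1, h2, h3 = config.hidden
        dim_in = 1 if config.sequence_mode == "timesteps" else self.n_features
        self.lstm1 = _LSTMLayer(rng, dim_in, h1)
        self.lstm2 = _LSTMLayer(rng, h1, h2)
        self.W1 = _glorot(rng, (h2, h3))
        self.b1 = np.zeros(h3, dtype=DTYPE)
        self.W2 = _glorot(rng, (h3, 1))
        self.b2 = np.zeros(1, dtype=DTYPE)
        self._rng = rng
        self.history: dict[str, list[float]] = {"loss": [], "accuracy": []}

    # -- plumbing ----------------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        return (self.lstm1.params + self.lstm2.params
                + [self.W1, self.b1, self.W2, self.b2])

    def _to_sequence(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=DTYPE)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(f"expected (n, {self.n_features}) feature matrix")
        if self.config.sequence_mode == "timesteps":
            return X.T[:, :, None]  # (T, n, 1)
        return X[None, :, :]        # (1, n, T)

    # -- forward / backward ------------------------------------------------
    def _forward(self, seq: np.ndarray) -> np.ndarray:
        h1 = self.lstm1.forward(seq)
        h2 = self.lstm2.forward(h1)
        self._h_last = h2[-1]
        self._u = _sigmoid(self._h_last @ self.W1 + self.b1)
        self._v = _sigmoid(self._u @ self.W2 + self.b2)
        return self._v[:, 0]

    def _backward(self, proba: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
        n = y.size
        p = proba[:, None]
        dv = (2.0 / n) * (p - y[:, None]) * p * (1.0 - p)
        dW2 = self._u.T @ dv
        db2 = dv.sum(axis=0)
        du = dv @ self.W2.T * self._u * (1.0 - self._u)
        dW1 = self._h_last.T @ du
        db1 = du.sum(axis=0)
        dh_last = du @ self.W1.T
        T = self.lstm2._cache[1].shape[0]
        dH2 = np.zeros((T, n, self.config.hidden[1]), dtype=DTYPE)
        dH2[-1] = dh_last
        dH1, g2 = self.lstm2.backward(dH2)
        _, g1 = self.lstm1.backward(dH1)
        return g1 + g2 + [dW1.astype(DTYPE), db1.astype(DTYPE),
                          dW2.astype(DTYPE), db2.astype(DTYPE)]

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray):
        """MSE loss and parameter gradients for one batch (test hook)."""
        proba = self._forward(self._to_sequence(X))
        loss = float(np.mean((proba - y) ** 2))
        return loss, self._backward(proba, np.asarray(y, dtype=DTYPE))

    # -- API ---------------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "LSTMClassifier":
        X = np.asarray(X, dtype=DTYPE)
        y = np.asarray(y, dtype=DTYPE)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("labels must be binary 0/1")
        n = X.shape[0]
        bs = self.config.batch_size or n
        opt = _Adam(self.params, self.config.learning_rate)
        for _ in range(self.config.epochs):
            order = self._rng.permutation(n)
            losses = []
            correct = 0
            for lo in range(0, n, bs):
                idx = order[lo:lo + bs]
                proba = self._forward(self._to_sequence(X[idx]))
                losses.append(float(np.mean((proba - y[idx]) ** 2)) * idx.size)
                correct += int(((proba > self.config.threshold) == (y[idx] > 0.5)).sum())
                grads = self._backward(proba, y[idx])
                opt.step(grads)
            self.history["loss"].append(sum(losses) / n)
            self.history["accuracy"].append(correct / n)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        proba = self._forward(self._to_sequence(np.asarray(X, dtype=DTYPE)))
        self.lstm1._cache = self.lstm2._cache = None
        return proba.astype(float)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) > self.config.threshold).astype(int)

    # -- serialization -----------------------------------------------------
    _PARAM_NAMES = ("l1.Wx", "l1.Wh", "l1.b", "l2.Wx", "l2.Wh", "l2.b",
                    "W1", "b1", "W2", "b2")

    def state_dict(self) -> dict[str, np.ndarray]:
        return dict(zip(self._PARAM_NAMES, self.params))

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for name, target in zip(self._PARAM_NAMES, self.params):
            arr = np.asarray(state[name], dtype=DTYPE)
            if arr.shape != target.shape:
                raise ValueError(f"shape mismatch for parameter {name}")
            target[...] = arr

    def config_json(self) -> str:
        d = asdict(self.config)
        d["hidden"] = list(d["hidden"])
        return json.dumps(d)
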