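"""Minimal seeded neural-network components.

Two trainable models are provided, both plain numpy with an Adam
optimizer and fully deterministic given their seed:

* :class:`SoftmaxMLP` — a compact multilayer perceptron over flattened
  frame pixels, trained with a focal-loss objective.  It serves as the
  pluggable image backbone: ``predict_proba`` gives per-class
  probabilities and ``hidden`` exposes the penultimate activations as a
  frame embedding.
* :class:`LSTMBinaryClassifier` — a single-layer LSTM over a fixed-length
  sequence with a logistic readout on the final hidden state, the
  time-averaged hidden state and the time-averaged input.

Gradients are hand-derived and checked against finite differences in the
test suite.
"""

from __future__ import annotations

import json

import numpy as np

__all__ = ["focal_loss", "softmax", "SoftmaxMLP", "LSTMBinaryClassifier"]

_EPS = 1e-12  # probability clamp used by the focal loss


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def focal_loss(
    probs: np.ndarray,
    y: np.ndarray,
    gamma: float = 0.0,
    class_weights: np.ndarray | None = None,
) -> float:
    """Mean focal loss of predicted class probabilities.

    Per sample the loss is ``-w[y] * (1 - p_y)**gamma * log(p_y)`` where
    ``p_y`` is the probability assigned to the true class ``y`` (integer
    index).  With ``gamma=0`` and unit weights this is the ordinary
    cross-entropy; positive ``gamma`` down-weights well-classified
    samples, which matters when one class (here the short 3-cell stage)
    is rare.  ``p_y`` is clamped at 1e-12 before the log.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=int)
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    p = np.clip(probs[np.arange(len(y)), y], _EPS, 1.0)
    if class_weights is None:
        w = np.ones_like(p)
    else:
        class_weights = np.asarray(class_weights, dtype=float)
        if np.any(class_weights <= 0):
            raise ValueError("class weights must be positive")
        w = class_weights[y]
    return float(np.mean(-w * (1.0 - p) ** gamma * np.log(p)))


class _Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _clip_global_norm(grads: list[np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float((g * g).sum()) for g in grads))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for g in grads:
            g *= scale


class SoftmaxMLP:
    """Fully connected softmax classifier with ReLU hidden layers."""

    def __init__(
        self,
        input_dim: int,
        hidden_dims: tuple[int, ...],
        n_classes: int,
        seed: int = 0,
        dtype=np.float32,
    ):
        self.input_dim = int(input_dim)
        self.hidden_dims = tuple(int(h) for h in hidden_dims)
        self.n_classes = int(n_classes)
        self.seed = int(seed)
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(self.seed)
        dims = [self.input_dim, *self.hidden_dims, self.n_classes]
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / dims[i]), size=(dims[i], dims[i + 1])).astype(self.dtype)
            for i in range(len(dims) - 1)
        ]
        self.b = [np.zeros(dims[i + 1], dtype=self.dtype) for i in range(len(dims) - 1)]
        self._rng = rng

    # -- forward -----------------------------------------------------------
    def _forward(self, X: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        acts = [X]
        a = X
        for W, b in zip(self.W[:-1], self.b[:-1]):
            a = np.maximum(a @ W + b, 0.0)
            acts.append(a)
        logits = a @ self.W[-1] + self.b[-1]
        return acts, logits

    def predict_proba(self, X: np.ndarray, batch_size: int = 8192) -> np.ndarray:
        X = np.asarray(X, dtype=self.dtype)
        out = np.empty((len(X), self.n_classes), dtype=float)
        for i in range(0, len(X), batch_size):
            _, logits = self._forward(X[i : i + batch_size])
            out[i : i + batch_size] = softmax(logits.astype(float))
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def hidden(self, X: np.ndarray, batch_size: int = 8192) -> np.ndarray:
        """Penultimate-layer activations, used as a frame embedding."""
        X = np.asarray(X, dtype=self.dtype)
        out = np.empty((len(X), self.hidden_dims[-1]), dtype=self.dtype)
        for i in range(0, len(X), batch_size):
            acts, _ = self._forward(X[i : i + batch_size])
            out[i : i + batch_size] = acts[-1]
        return out

    # -- training ----------------------------------------------------------
    def loss_and_grads(
        self,
        X: np.ndarray,
        y: np.ndarray,
        gamma: float,
        class_weights: np.ndarray | None,
    ) -> tuple[float, list[np.ndarray]]:
        n = len(X)
        acts, logits = self._forward(X)
        p = softmax(logits.astype(np.float64))
        idx = np.arange(n)
        py = np.clip(p[idx, y], _EPS, 1.0)
        w = np.ones(n) if class_weights is None else np.asarray(class_weights, dtype=float)[y]
        loss = float(np.mean(-w * (1.0 - py) ** gamma * np.log(py)))
        # dL/dp_y, then chain through the softmax:
        #   dL/dz_k = a * (delta_{ky} - p_k)  with  a = (dL/dp_y) * p_y
        if gamma == 0:
            dLdpy = -w / py
        else:
            q = np.clip(1.0 - py, _EPS, 1.0)
            dLdpy = -w * (-gamma * q ** (gamma - 1.0) * np.log(py) + q**gamma / py)
        a = (dLdpy * py) / n
        dz = (-a[:, None] * p).astype(self.dtype)
        dz[idx, y] += a.astype(self.dtype)

        gW = [np.empty(0)] * len(self.W)
        gb = [np.empty(0)] * len(self.b)
        for layer in range(len(self.W) - 1, -1, -1):
            gW[layer] = acts[layer].T @ dz
            gb[layer] = dz.sum(axis=0)
            if layer > 0:
                dz = (dz @ self.W[layer].T) * (acts[layer] > 0)
        return loss, [*gW, *gb]

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int = 30,
        batch_size: int = 128,
        lr: float = 1e-3,
        gamma: float = 0.0,
        class_weights: np.ndarray | None = None,
    ) -> "SoftmaxMLP":
        X = np.asarray(X, dtype=self.dtype)
        y = np.asarray(y, dtype=int)
        params = [*self.W, *self.b]
        opt = _Adam(params, lr=lr)
        for _ in range(int(epochs)):
            order = self._rng.permutation(len(X))
            for i in range(0, len(X), batch_size):
                sel = order[i : i + batch_size]
                _, grads = self.loss_and_grads(X[sel], y[sel], gamma, class_weights)
                opt.step(params, grads)
        return self

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        meta = dict(
            input_dim=self.input_dim,
            hidden_dims=list(self.hidden_dims),
            n_classes=self.n_classes,
            seed=self.seed,
            dtype=self.dtype.name,
        )
        arrays = {f"W{i}": W for i, W in enumerate(self.W)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.b)})
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "SoftmaxMLP":
        data = np.load(path)
        meta = json.loads(bytes(data["meta"]).decode())
        model = cls(meta["input_dim"], tuple(meta["hidden_dims"]), meta["n_classes"],
                    seed=meta["seed"], dtype=np.dtype(meta["dtype"]))
        model.W = [data[f"W{i}"] for i in range(len(model.W))]
        model.b = [data[f"b{i}"] for i in range(len(model.b))]
        return model


class LSTMBinaryClassifier:
    """Single-layer LSTM with a logistic readout for binary sequences.

    The readout sees the final hidden state, the mean hidden state over
    time and the mean input over time; the latter makes stage-duration
    fractions directly available, which is the natural sufficient
    statistic for morphokinetic outcomes, while the recurrent states
    capture ordering effects.
    """

    def __init__(self, input_dim: int, hidden_size: int = 24, seed: int = 0):
        self.input_dim = int(input_dim)
        self.hidden_size = int(hidden_size)
        self.seed = int(seed)
        d, H = self.input_dim, self.hidden_size
        rng = np.random.default_rng(self.seed)
        s = 1.0 / np.sqrt(H + d)
        self.Wx = rng.uniform(-s, s, size=(d, 4 * H))
        self.Wh = rng.uniform(-s, s, size=(H, 4 * H))
        self.b = np.zeros(4 * H)
        self.b[H : 2 * H] = 1.0  # forget-gate bias
        self.v = rng.uniform(-s, s, size=(2 * H + d,))
        self.v0 = 0.0
        self._rng = rng

    @property
    def _params(self) -> list[np.ndarray]:
        return [self.Wx, self.Wh, self.b, self.v]

    def _forward(self, X: np.ndarray):
        B, T, d = X.shape
        H = self.hidden_size
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = {k: np.empty((T, B, H)) for k in ("i", "f", "o", "g", "c", "tc", "h", "hprev", "cprev")}
        for t in range(T):
            z = X[:, t] @ self.Wx + h @ self.Wh + self.b
            i = 1.0 / (1.0 + np.exp(-z[:, :H]))
            f = 1.0 / (1.0 + np.exp(-z[:, H : 2 * H]))
            o = 1.0 / (1.0 + np.exp(-z[:, 2 * H : 3 * H]))
            g = np.tanh(z[:, 3 * H :])
            cache["hprev"][t] = h
            cache["cprev"][t] = c
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            for k, val in zip(("i", "f", "o", "g", "c", "tc", "h"), (i, f, o, g, c, tc, h)):
                cache[k][t] = val
        hmean = cache["h"].mean(axis=0)
        xmean = X.mean(axis=1)
        feats = np.concatenate([h, hmean, xmean], axis=1)
        p = 1.0 / (1.0 + np.exp(-(feats @ self.v + self.v0)))
        return p, feats, cache

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty(len(X))
        for i in range(0, len(X), batch_size):
            out[i : i + batch_size] = self._forward(X[i : i + batch_size])[0]
        return out

    def features(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Readout features [h_final, mean_t h_t, mean_t x_t] per sequence."""
        X = np.asarray(X, dtype=float)
        out = np.empty((len(X), 2 * self.hidden_size + self.input_dim))
        for i in range(0, len(X), batch_size):
            out[i : i + batch_size] = self._forward(X[i : i + batch_size])[1]
        return out

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray):
        B, T, d = X.shape
        H = self.hidden_size
        p, feats, cache = self._forward(X)
        pc = np.clip(p, _EPS, 1.0 - _EPS)
        loss = float(np.mean(-(y * np.log(pc) + (1 - y) * np.log(1 - pc))))
        dlogit = (p - y) / B
        gv = feats.T @ dlogit
        gv0 = float(dlogit.sum())
        dfeats = dlogit[:, None] * self.v[None, :]
        dh_last = dfeats[:, :H]
        dh_mean = dfeats[:, H : 2 * H]
        # the x-mean readout term has no upstream parameters

        gWx = np.zeros_like(self.Wx)
        gWh = np.zeros_like(self.Wh)
        gb = np.zeros_like(self.b)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            i, f, o, g = cache["i"][t], cache["f"][t], cache["o"][t], cache["g"][t]
            tc, cprev, hprev = cache["tc"][t], cache["cprev"][t], cache["hprev"][t]
            dh = dh_next + dh_mean / T
            if t == T - 1:
                dh = dh + dh_last
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di, dg, df = dc * g, dc * i, dc * cprev
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), do * o * (1 - o), dg * (1 - g * g)], axis=1
            )
            gWx += X[:, t].T @ dz
            gWh += hprev.T @ dz
            gb += dz.sum(axis=0)
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        grads = [gWx, gWh, gb, gv]
        return loss, grads, gv0

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int = 40,
        batch_size: int = 64,
        lr: float = 5e-3,
        clip_norm: float = 5.0,
    ) -> "LSTMBinaryClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        params = self._params
        opt = _Adam(params, lr=lr)
        opt_v0 = _Adam([np.zeros(1)], lr=lr)
        v0 = np.array([self.v0])
        for _ in range(int(epochs)):
            order = self._rng.permutation(len(X))
            for i in range(0, len(X), batch_size):
                sel = order[i : i + batch_size]
                _, grads, gv0 = self.loss_and_grads(X[sel], y[sel])
                _clip_global_norm(grads, clip_norm)
                opt.step(params, grads)
                opt_v0.step([v0], [np.array([gv0])])
                self.v0 = float(v0[0])
        return self

    def save(self, path) -> None:
        meta = dict(input_dim=self.input_dim, hidden_size=self.hidden_size, seed=self.seed, v0=self.v0)
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 Wx=self.Wx, Wh=self.Wh, b=self.b, v=self.v)

    @classmethod
    def load(cls, path) -> "LSTMBinaryClassifier":
        data = np.load(path)
        meta = json.loads(bytes(data["meta"]).decode())
        model = cls(meta["input_dim"], meta["hidden_size"], seed=meta["seed"])
        model.Wx, model.Wh, model.b, model.v = data["Wx"], data["Wh"], data["b"], data["v"]
        model.v0 = float(meta["v0"])
        return model
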