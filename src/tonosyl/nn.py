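"""Minimal numpy recurrent-network engine for the dual-stream decoders.

Implements exactly the pieces the decoder architecture needs — bidirectional
LSTM layers, layer normalization, dropout, a per-timestep linear head with
probability averaging, cross-entropy and focal losses, Adam, and a
plateau-based learning-rate schedule — with hand-derived backward passes.
Everything is float64 and seeded, so training is bit-reproducible on one
machine, and the backward pass exposes the gradient with respect to the
*input*, which the electrode-contribution (saliency) analysis consumes
directly.

All backward passes are verified against central finite differences in the
test suite; keep any change here covered by those checks.
"""

from __future__ import annotations

import numpy as np

EPS_PROB = 1e-8


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _Layer:
    def params(self):
        return {}

    def grads(self):
        return {}


class LSTM(_Layer):
    """Single-direction LSTM over (batch, time, features)."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator,
                 reverse: bool = False):
        s_in = 1.0 / np.sqrt(d_in)
        s_h = 1.0 / np.sqrt(hidden)
        self.Wx = rng.uniform(-s_in, s_in, size=(d_in, 4 * hidden))
        self.Wh = rng.uniform(-s_h, s_h, size=(hidden, 4 * hidden))
        self.b = np.zeros(4 * hidden)
        self.hidden = hidden
        self.reverse = reverse
        self.dWx = self.dWh = self.db = None

    def params(self):
        return {"Wx": self.Wx, "Wh": self.Wh, "b": self.b}

    def grads(self):
        return {"Wx": self.dWx, "Wh": self.dWh, "b": self.db}

    def forward(self, x: np.ndarray):
        if self.reverse:
            x = x[:, ::-1]
        B, T, _ = x.shape
        H = self.hidden
        xw = x @ self.Wx + self.b
        I = np.empty((B, T, H)); F = np.empty((B, T, H))
        G = np.empty((B, T, H)); O = np.empty((B, T, H))
        C = np.empty((B, T, H)); Hs = np.empty((B, T, H))
        h = np.zeros((B, H)); c = np.zeros((B, H))
        for t in range(T):
            a = xw[:, t] + h @ self.Wh
            i = _sigmoid(a[:, :H]); f = _sigmoid(a[:, H:2 * H])
            g = np.tanh(a[:, 2 * H:3 * H]); o = _sigmoid(a[:, 3 * H:])
            c = f * c + i * g
            h = o * np.tanh(c)
            I[:, t], F[:, t], G[:, t], O[:, t], C[:, t], Hs[:, t] = i, f, g, o, c, h
        cache = (x, I, F, G, O, C, Hs)
        y = Hs[:, ::-1] if self.reverse else Hs
        return y, cache

    def backward(self, dy: np.ndarray, cache):
        x, I, F, G, O, C, Hs = cache
        if self.reverse:
            dy = dy[:, ::-1]
        B, T, H = Hs.shape
        dA = np.empty((B, T, 4 * H))
        dh_next = np.zeros((B, H)); dc_next = np.zeros((B, H))
        WhT = self.Wh.T
        for t in range(T - 1, -1, -1):
            dh = dy[:, t] + dh_next
            tc = np.tanh(C[:, t])
            do = dh * tc
            dc = dh * O[:, t] * (1 - tc * tc) + dc_next
            c_prev = C[:, t - 1] if t > 0 else 0.0
            di = dc * G[:, t]
            df = dc * c_prev
            dg = dc * I[:, t]
            dc_next = dc * F[:, t]
            da = dA[:, t]
            da[:, :H] = di * I[:, t] * (1 - I[:, t])
            da[:, H:2 * H] = df * F[:, t] * (1 - F[:, t])
            da[:, 2 * H:3 * H] = dg * (1 - G[:, t] ** 2)
            da[:, 3 * H:] = do * O[:, t] * (1 - O[:, t])
            dh_next = da @ WhT
        D = x.shape[2]
        self.dWx = x.reshape(B * T, D).T @ dA.reshape(B * T, 4 * H)
        Hprev = np.concatenate([np.zeros((B, 1, H)), Hs[:, :-1]], axis=1)
        self.dWh = Hprev.reshape(B * T, H).T @ dA.reshape(B * T, 4 * H)
        self.db = dA.sum(axis=(0, 1))
        dx = dA @ self.Wx.T
        return dx[:, ::-1] if self.reverse else dx


class BiLSTM(_Layer):
    """Direction-concatenated bidirectional LSTM: d_in -> 2*hidden."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        self.fwd = LSTM(d_in, hidden, rng, reverse=False)
        self.bwd = LSTM(d_in, hidden, rng, reverse=True)
        self.hidden = hidden

    def params(self):
        return {**{f"f.{k}": v for k, v in self.fwd.params().items()},
                **{f"b.{k}": v for k, v in self.bwd.params().items()}}

    def grads(self):
        return {**{f"f.{k}": v for k, v in self.fwd.grads().items()},
                **{f"b.{k}": v for k, v in self.bwd.grads().items()}}

    def forward(self, x):
        yf, cf = self.fwd.forward(x)
        yb, cb = self.bwd.forward(x)
        return np.concatenate([yf, yb], axis=2), (cf, cb)

    def backward(self, dy, cache):
        cf, cb = cache
        H = self.hidden
        return self.fwd.backward(dy[:, :, :H], cf) + \
            self.bwd.backward(dy[:, :, H:], cb)


class LayerNorm(_Layer):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = np.ones(d)
        self.beta = np.zeros(d)
        self.eps = eps
        self.dgamma = self.dbeta = None

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        return xhat * self.gamma + self.beta, (xhat, inv)

    def backward(self, dy, cache):
        xhat, inv = cache
        self.dgamma = (dy * xhat).sum(axis=(0, 1))
        self.dbeta = dy.sum(axis=(0, 1))
        dxhat = dy * self.gamma
        n = xhat.shape[-1]
        return inv / n * (n * dxhat
                          - dxhat.sum(axis=-1, keepdims=True)
                          - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True))


class Dropout(_Layer):
    def __init__(self, p: float):
        self.p = p

    def forward(self, x, rng: np.random.Generator | None, train: bool):
        if not train or self.p == 0:
            return x, None
        mask = (rng.uniform(size=x.shape) >= self.p) / (1.0 - self.p)
        return x * mask, mask

    def backward(self, dy, mask):
        return dy if mask is None else dy * mask


class TimeDense(_Layer):
    """Per-timestep affine map on the last axis."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        s = 1.0 / np.sqrt(d_in)
        self.W = rng.uniform(-s, s, size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self.dW = self.db = None

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x):
        return x @ self.W + self.b, x

    def backward(self, dy, x):
        B, T, D = x.shape
        self.dW = x.reshape(B * T, D).T @ dy.reshape(B * T, -1)
        self.db = dy.sum(axis=(0, 1))
        return dy @ self.W.T


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class StackedBiLSTM:
    """Two blocks of (2-layer BiLSTM -> LayerNorm -> Dropout), linear head.

    Per-timestep class distributions are averaged over the whole segment to
    form the output probability vector, so the result lives on the simplex by
    construction. With the reference dimensions the first block maps the
    per-electrode input to 500 features (250 hidden units per direction) and
    the second to 200.
    """

    def __init__(self, n_inputs: int, n_classes: int,
                 hidden1: int = 250, hidden2: int = 100,
                 dropout: float = 0.3, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.layers = [
            BiLSTM(n_inputs, hidden1, rng),
            BiLSTM(2 * hidden1, hidden1, rng),
            LayerNorm(2 * hidden1),
            Dropout(dropout),
            BiLSTM(2 * hidden1, hidden2, rng),
            BiLSTM(2 * hidden2, hidden2, rng),
            LayerNorm(2 * hidden2),
            Dropout(dropout),
            TimeDense(2 * hidden2, n_classes, rng),
        ]
        self.n_inputs = n_inputs
        self.n_classes = n_classes

    # -- parameter bookkeeping -------------------------------------------
    def named_params(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params().items():
                out[f"l{i}.{k}"] = v
        return out

    def named_grads(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.grads().items():
                out[f"l{i}.{k}"] = v
        return out

    def get_weights(self):
        return {k: v.copy() for k, v in self.named_params().items()}

    def set_weights(self, weights):
        for k, v in self.named_params().items():
            v[...] = weights[k]

    # -- forward/backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        """Return (probs (B, C), caches); probs = mean over time of softmax."""
        caches = []
        h = x
        for layer in self.layers:
            if isinstance(layer, Dropout):
                h, c = layer.forward(h, rng, train)
            else:
                h, c = layer.forward(h)
            caches.append(c)
        S = softmax(h)                      # (B, T, C) per-timestep distributions
        probs = S.mean(axis=1)
        caches.append(S)
        return probs, caches

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, train=False)[0]

    def backward(self, dprobs: np.ndarray, caches) -> np.ndarray:
        """Backprop d(loss)/d(probs) to parameters; returns d(loss)/d(input)."""
        S = caches[-1]
        T = S.shape[1]
        dS = np.repeat(dprobs[:, None, :] / T, T, axis=1)
        dz = S * (dS - (dS * S).sum(axis=-1, keepdims=True))
        d = dz
        for layer, cache in zip(reversed(self.layers), reversed(caches[:-1])):
            d = layer.backward(d, cache)
        return d


# ---------------------------------------------------------------------------
# Losses (soft labels supported for mixup)
# ---------------------------------------------------------------------------

def cross_entropy(probs: np.ndarray, targets: np.ndarray):
    """Mean CE over the batch; returns (loss, dloss/dprobs)."""
    p = np.clip(probs, EPS_PROB, None)
    B = probs.shape[0]
    loss = -(targets * np.log(p)).sum() / B
    return loss, -targets / p / B


def focal_loss(probs: np.ndarray, targets: np.ndarray, gamma: float = 2.0):
    """Focal loss -(1-p)^gamma log p, soft-label generalized; (loss, grad).

    With gamma=0 this equals cross-entropy exactly. Probabilities are clamped
    at 1e-8 before the log.
    """
    p = np.clip(probs, EPS_PROB, 1.0)
    B = probs.shape[0]
    onem = 1.0 - p
    loss = -(targets * onem ** gamma * np.log(p)).sum() / B
    dterm = onem ** gamma / p
    if gamma > 0:
        dterm = dterm - gamma * onem ** (gamma - 1) * np.log(p)
    return loss, -targets * dterm / B


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, model: StackedBiLSTM, lr: float = 1e-2,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in model.named_params().items()}
        self.v = {k: np.zeros_like(v) for k, v in model.named_params().items()}

    def step(self):
        self.t += 1
        params = self.model.named_params()
        grads = self.model.named_grads()
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


class ReduceLROnPlateau:
    """Halve the learning rate when the monitored loss stops improving."""

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 5,
                 min_lr: float = 1e-5):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.bad = 0

    def step(self, value: float):
        if value < self.best - 1e-12:
            self.best = value
            self.bad = 0
        else:
            self.bad += 1
            if self.bad > self.patience:
                self.opt.lr = max(self.min_lr, self.opt.lr * self.factor)
                self.bad = 0
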