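"""Minimal numpy neural-network stack for the risk regressors.

Implements exactly the four neural families used by the benchmark (MLP,
1-D CNN, GCN, LSTM) with hand-written backward passes and an Adam
optimizer.  Everything is float64 and seeded, so training is
bitwise-deterministic for a given seed.  Networks expose

* ``params`` — dict of named arrays (updated in place by the optimizer);
* ``forward(X, train=False)`` — predictions (B,) plus a cache;
* ``backward(cache, grad)`` — parameter gradients for ``dL/dyhat``.

Dropout is inverted dropout, active only when ``train=True``, drawing its
masks from the network's own generator.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _he(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class Adam:
    """Adam with the standard moment defaults (0.9, 0.999, eps 1e-8)."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def update(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)


class _Net:
    """Base: parameter bookkeeping and the shared dropout helper."""

    dropout_p = 0.1

    def __init__(self, seed: int):
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}

    def _dropout(self, x: np.ndarray, train: bool):
        if not train or self.dropout_p <= 0.0:
            return x, None
        mask = (self.rng.random(x.shape) >= self.dropout_p) / (1.0 - self.dropout_p)
        return x * mask, mask

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def predict(self, X: np.ndarray) -> np.ndarray:
        yhat, _ = self.forward(np.asarray(X, float), train=False)
        return yhat

    def copy_params(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict) -> None:
        for k in self.params:
            self.params[k] = params[k].copy()


class MLPNet(_Net):
    """26 -> 256 -> 128 -> 1, ReLU after hidden layers, dropout 0.1."""

    def __init__(self, seed: int, in_dim: int = 26, hidden: tuple[int, int] = (256, 128)):
        super().__init__(seed)
        h1, h2 = hidden
        self.params = {
            "W1": _he(self.rng, in_dim, (in_dim, h1)),
            "b1": np.zeros(h1),
            "W2": _he(self.rng, h1, (h1, h2)),
            "b2": np.zeros(h2),
            "W3": _glorot(self.rng, h2, 1),
            "b3": np.zeros(1),
        }

    def forward(self, X, train=False):
        p = self.params
        z1 = X @ p["W1"] + p["b1"]
        a1 = np.maximum(z1, 0.0)
        d1, m1 = self._dropout(a1, train)
        z2 = d1 @ p["W2"] + p["b2"]
        a2 = np.maximum(z2, 0.0)
        d2, m2 = self._dropout(a2, train)
        out = (d2 @ p["W3"] + p["b3"])[:, 0]
        return out, (X, z1, d1, m1, z2, d2, m2)

    def backward(self, cache, grad):
        X, z1, d1, m1, z2, d2, m2 = cache
        p = self.params
        g = grad[:, None]
        grads = {"W3": d2.T @ g, "b3": g.sum(0)}
        gd2 = g @ p["W3"].T
        if m2 is not None:
            gd2 = gd2 * m2
        gz2 = gd2 * (z2 > 0)
        grads["W2"] = d1.T @ gz2
        grads["b2"] = gz2.sum(0)
        gd1 = gz2 @ p["W2"].T
        if m1 is not None:
            gd1 = gd1 * m1
        gz1 = gd1 * (z1 > 0)
        grads["W1"] = X.T @ gz1
        grads["b1"] = gz1.sum(0)
        return grads


def _conv1d_forward(x, W, b):
    """x (B, C, L), W (O, C, K) -> (B, O, L-K+1) valid convolution."""
    xw = sliding_window_view(x, W.shape[2], axis=2)  # (B, C, P, K)
    return np.einsum("bcpk,ock->bop", xw, W, optimize=True) + b[None, :, None]


def _conv1d_backward(x, W, grad_out):
    xw = sliding_window_view(x, W.shape[2], axis=2)
    dW = np.einsum("bcpk,bop->ock", xw, grad_out, optimize=True)
    db = grad_out.sum(axis=(0, 2))
    dx = np.zeros_like(x)
    P = grad_out.shape[2]
    for k in range(W.shape[2]):
        dx[:, :, k : k + P] += np.einsum("bop,oc->bcp", grad_out, W[:, :, k], optimize=True)
    return dx, dW, db


class CNNNet(_Net):
    """Two valid length-3 convolutions (2->32->64) over the 13 keypoint
    positions, global average pooling, head 64 -> 64 -> 1."""

    def __init__(self, seed: int):
        super().__init__(seed)
        self.params = {
            "Wc1": _he(self.rng, 2 * 3, (32, 2, 3)),
            "bc1": np.zeros(32),
            "Wc2": _he(self.rng, 32 * 3, (64, 32, 3)),
            "bc2": np.zeros(64),
            "Wh": _he(self.rng, 64, (64, 64)),
            "bh": np.zeros(64),
            "Wo": _glorot(self.rng, 64, 1),
            "bo": np.zeros(1),
        }

    @staticmethod
    def reshape_input(X: np.ndarray) -> np.ndarray:
        """(B, 26) interleaved u -> (B, 2, 13) coordinate channels."""
        B = X.shape[0]
        return X.reshape(B, 13, 2).transpose(0, 2, 1)

    def forward(self, X, train=False):
        p = self.params
        x = self.reshape_input(X)
        z1 = _conv1d_forward(x, p["Wc1"], p["bc1"])  # (B, 32, 11)
        a1 = np.maximum(z1, 0.0)
        z2 = _conv1d_forward(a1, p["Wc2"], p["bc2"])  # (B, 64, 9)
        a2 = np.maximum(z2, 0.0)
        pooled = a2.mean(axis=2)  # global average pool -> (B, 64)
        dp, mp = self._dropout(pooled, train)
        zh = dp @ p["Wh"] + p["bh"]
        ah = np.maximum(zh, 0.0)
        dh, mh = self._dropout(ah, train)
        out = (dh @ p["Wo"] + p["bo"])[:, 0]
        return out, (x, z1, a1, z2, a2, dp, mp, zh, dh, mh)

    def backward(self, cache, grad):
        x, z1, a1, z2, a2, dp, mp, zh, dh, mh = cache
        p = self.params
        g = grad[:, None]
        grads = {"Wo": dh.T @ g, "bo": g.sum(0)}
        gdh = g @ p["Wo"].T
        if mh is not None:
            gdh = gdh * mh
        gzh = gdh * (zh > 0)
        grads["Wh"] = dp.T @ gzh
        grads["bh"] = gzh.sum(0)
        gdp = gzh @ p["Wh"].T
        if mp is not None:
            gdp = gdp * mp
        ga2 = np.repeat(gdp[:, :, None], a2.shape[2], axis=2) / a2.shape[2]
        gz2 = ga2 * (z2 > 0)
        ga1, grads["Wc2"], grads["bc2"] = _conv1d_backward(a1, p["Wc2"], gz2)
        gz1 = ga1 * (z1 > 0)
        _, grads["Wc1"], grads["bc1"] = _conv1d_backward(x, p["Wc1"], gz1)
        return grads


class GCNNet(_Net):
    """Two graph convolutions (2 -> 64 -> 64) over the fixed skeleton graph
    with self-loops and symmetric adjacency normalization, flattened to
    13*64 = 832 and fed to a 832 -> 256 -> 128 -> 64 -> 1 head."""

    def __init__(self, seed: int, adjacency: np.ndarray):
        super().__init__(seed)
        self.A = self._normalize_adjacency(adjacency)
        self.params = {
            "Wg1": _he(self.rng, 2, (2, 64)),
            "bg1": np.zeros(64),
            "Wg2": _he(self.rng, 64, (64, 64)),
            "bg2": np.zeros(64),
            "W1": _he(self.rng, 832, (832, 256)),
            "b1": np.zeros(256),
            "W2": _he(self.rng, 256, (256, 128)),
            "b2": np.zeros(128),
            "W3": _he(self.rng, 128, (128, 64)),
            "b3": np.zeros(64),
            "W4": _glorot(self.rng, 64, 1),
            "b4": np.zeros(1),
        }

    @staticmethod
    def _normalize_adjacency(A: np.ndarray) -> np.ndarray:
        A = np.asarray(A, float) + np.eye(A.shape[0])
        d = A.sum(axis=1)
        dinv = 1.0 / np.sqrt(d)
        return A * dinv[:, None] * dinv[None, :]

    def forward(self, X, train=False):
        p = self.params
        x = X.reshape(X.shape[0], 13, 2)
        h1 = np.einsum("ij,bjf->bif", self.A, x) @ p["Wg1"] + p["bg1"]
        a1 = np.maximum(h1, 0.0)
        d1, m1 = self._dropout(a1, train)
        h2 = np.einsum("ij,bjf->bif", self.A, d1) @ p["Wg2"] + p["bg2"]
        a2 = np.maximum(h2, 0.0)
        d2, m2 = self._dropout(a2, train)
        flat = d2.reshape(X.shape[0], 832)
        acts = [flat]
        caches = []
        h = flat
        for li, (W, b) in enumerate((("W1", "b1"), ("W2", "b2"), ("W3", "b3"))):
            z = h @ p[W] + p[b]
            a = np.maximum(z, 0.0)
            d, m = self._dropout(a, train)
            caches.append((z, d, m))
            h = d
        out = (h @ p["W4"] + p["b4"])[:, 0]
        return out, (x, h1, d1, m1, h2, d2, m2, flat, caches)

    def backward(self, cache, grad):
        x, h1, d1, m1, h2, d2, m2, flat, caches = cache
        p = self.params
        g = grad[:, None]
        grads = {"W4": caches[-1][1].T @ g, "b4": g.sum(0)}
        gh = g @ p["W4"].T
        inputs = [flat, caches[0][1], caches[1][1]]
        for li in (2, 1, 0):
            z, d, m = caches[li]
            if m is not None:
                gh = gh * m
            gz = gh * (z > 0)
            Wn, bn = f"W{li + 1}", f"b{li + 1}"
            grads[Wn] = inputs[li].T @ gz
            grads[bn] = gz.sum(0)
            gh = gz @ p[Wn].T
        gd2 = gh.reshape(x.shape[0], 13, 64)
        if m2 is not None:
            gd2 = gd2 * m2
        gh2 = gd2 * (h2 > 0)
        Ad1 = np.einsum("ij,bjf->bif", self.A, d1)
        grads["Wg2"] = np.einsum("bif,bio->fo", Ad1, gh2)
        grads["bg2"] = gh2.sum(axis=(0, 1))
        gAd1 = gh2 @ p["Wg2"].T
        gd1 = np.einsum("ij,bif->bjf", self.A, gAd1)
        if m1 is not None:
            gd1 = gd1 * m1
        gh1 = gd1 * (h1 > 0)
        Ax = np.einsum("ij,bjf->bif", self.A, x)
        grads["Wg1"] = np.einsum("bif,bio->fo", Ax, gh1)
        grads["bg1"] = gh1.sum(axis=(0, 1))
        return grads


class LSTMNet(_Net):
    """One-layer LSTM (hidden 64) over (5, 26) frame sequences; the head
    maps the last hidden state through dropout to a scalar."""

    def __init__(self, seed: int, in_dim: int = 26, hidden: int = 64, seq_len: int = 5):
        super().__init__(seed)
        self.H = hidden
        self.seq_len = seq_len
        k = 1.0 / np.sqrt(hidden)
        u = lambda shape: self.rng.uniform(-k, k, size=shape)
        self.params = {
            "Wx": u((in_dim, 4 * hidden)),
            "Wh": u((hidden, 4 * hidden)),
            "b": u(4 * hidden),
            "Wo": u((hidden, 1)),
            "bo": np.zeros(1),
        }

    def forward(self, X, train=False):
        X = np.asarray(X, float)
        if X.ndim == 2:  # flattened (B, 5*26)
            X = X.reshape(X.shape[0], self.seq_len, -1)
        B, T, _ = X.shape
        H = self.H
        p = self.params
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        steps = []
        for t in range(T):
            z = X[:, t] @ p["Wx"] + h @ p["Wh"] + p["b"]
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g_ = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g_
            tc = np.tanh(c_new)
            h_new = o * tc
            steps.append((X[:, t], h, c, i, f, g_, o, c_new, tc))
            h, c = h_new, c_new
        dh, mh = self._dropout(h, train)
        out = (dh @ p["Wo"] + p["bo"])[:, 0]
        return out, (steps, dh, mh, h)

    def backward(self, cache, grad):
        steps, dh_drop, mh, h_last = cache
        p = self.params
        H = self.H
        g = grad[:, None]
        grads = {
            "Wo": dh_drop.T @ g,
            "bo": g.sum(0),
            "Wx": np.zeros_like(p["Wx"]),
            "Wh": np.zeros_like(p["Wh"]),
            "b": np.zeros_like(p["b"]),
        }
        gh = g @ p["Wo"].T
        if mh is not None:
            gh = gh * mh
        gc = np.zeros_like(gh)
        for t in range(len(steps) - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g_, o, c_new, tc = steps[t]
            go = gh * tc
            gc = gc + gh * o * (1.0 - tc * tc)
            gi = gc * g_
            gf = gc * c_prev
            gg = gc * i
            dz = np.concatenate(
                [
                    gi * i * (1.0 - i),
                    gf * f * (1.0 - f),
                    gg * (1.0 - g_ * g_),
                    go * o * (1.0 - o),
                ],
                axis=1,
            )
            grads["Wx"] += x_t.T @ dz
            grads["Wh"] += h_prev.T @ dz
            grads["b"] += dz.sum(0)
            gh = dz @ p["Wh"].T
            gc = gc * f
        return grads
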