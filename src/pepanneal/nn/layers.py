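"""Layers with explicit forward caches and hand-written backward passes.

Every layer exposes
  - ``p``: dict of named parameter arrays (updated in place by the optimizer)
  - ``g``: dict of gradient arrays with matching shapes (overwritten by
    ``backward``)
  - ``forward(x)`` / ``backward(dout)`` where ``backward`` returns the
    gradient with respect to the layer input.

Recurrent layers take input of shape (B, L, D) and return the full hidden
sequence (B, L, H) so they stack and wrap bidirectionally.  The per-step
recurrences run in a Python loop over L; the large input/output projections
are batched into single matrix products over all timesteps.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable piecewise logistic
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _uniform(rng, shape, k, dtype):
    return rng.uniform(-k, k, size=shape).astype(dtype)


class Dense:
    """Affine map ``y = x @ W + b`` over the last axis."""

    def __init__(self, d_in: int, d_out: int, rng, dtype=np.float32):
        k = 1.0 / np.sqrt(d_in)
        self.p = {
            "W": _uniform(rng, (d_in, d_out), k, dtype),
            "b": np.zeros(d_out, dtype=dtype),
        }
        self.g = {n: np.zeros_like(v) for n, v in self.p.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.p["W"] + self.p["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        d_in = x.shape[-1]
        x2 = x.reshape(-1, d_in)
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.g["W"][...] = x2.T @ dy2
        self.g["b"][...] = dy2.sum(axis=0)
        return (dy2 @ self.p["W"].T).reshape(x.shape)


class RNNLayer:
    """Elman RNN: ``h_t = tanh(x_t @ Wx + h_{t-1} @ Wh + b)``."""

    def __init__(self, d_in: int, hidden: int, rng, dtype=np.float32):
        k = 1.0 / np.sqrt(hidden)
        self.hidden = hidden
        self.p = {
            "Wx": _uniform(rng, (d_in, hidden), k, dtype),
            "Wh": _uniform(rng, (hidden, hidden), k, dtype),
            "b": np.zeros(hidden, dtype=dtype),
        }
        self.g = {n: np.zeros_like(v) for n, v in self.p.items()}

    def forward(self, X: np.ndarray) -> np.ndarray:
        B, L, D = X.shape
        H = self.hidden
        Z = (X.reshape(B * L, D) @ self.p["Wx"]).reshape(B, L, H)
        Hs = np.empty((B, L, H), dtype=X.dtype)
        h = np.zeros((B, H), dtype=X.dtype)
        for t in range(L):
            h = np.tanh(Z[:, t] + h @ self.p["Wh"] + self.p["b"])
            Hs[:, t] = h
        self._X, self._Hs = X, Hs
        return Hs

    def backward(self, dH: np.ndarray) -> np.ndarray:
        X, Hs = self._X, self._Hs
        B, L, D = X.shape
        H = self.hidden
        dZ = np.empty((B, L, H), dtype=X.dtype)
        dh = np.zeros((B, H), dtype=X.dtype)
        for t in reversed(range(L)):
            dz = (dH[:, t] + dh) * (1.0 - Hs[:, t] ** 2)
            dZ[:, t] = dz
            dh = dz @ self.p["Wh"].T
        Hprev = np.concatenate(
            [np.zeros((B, 1, H), dtype=X.dtype), Hs[:, :-1]], axis=1
        )
        dZ2 = dZ.reshape(B * L, H)
        self.g["Wx"][...] = X.reshape(B * L, D).T @ dZ2
        self.g["Wh"][...] = Hprev.reshape(B * L, H).T @ dZ2
        self.g["b"][...] = dZ2.sum(axis=0)
        return (dZ2 @ self.p["Wx"].T).reshape(B, L, D)


class LSTMLayer:
    """LSTM with combined gate projections, gate order (i, f, g, o).

    The forget-gate bias is initialised to 1 so early training does not
    erase the cell state.
    """

    def __init__(self, d_in: int, hidden: int, rng, dtype=np.float32):
        k = 1.0 / np.sqrt(hidden)
        self.hidden = hidden
        self.p = {
            "Wx": _uniform(rng, (d_in, 4 * hidden), k, dtype),
            "Wh": _uniform(rng, (hidden, 4 * hidden), k, dtype),
            "b": np.zeros(4 * hidden, dtype=dtype),
        }
        self.p["b"][hidden : 2 * hidden] = 1.0
        self.g = {n: np.zeros_like(v) for n, v in self.p.items()}

    def forward(self, X: np.ndarray) -> np.ndarray:
        B, L, D = X.shape
        H = self.hidden
        Z = (X.reshape(B * L, D) @ self.p["Wx"]).reshape(B, L, 4 * H)
        gates = np.empty((B, L, 4 * H), dtype=X.dtype)  # activated i,f,g,o
        C = np.empty((B, L, H), dtype=X.dtype)
        Ct = np.empty((B, L, H), dtype=X.dtype)  # tanh(c_t)
        Hs = np.empty((B, L, H), dtype=X.dtype)
        h = np.zeros((B, H), dtype=X.dtype)
        c = np.zeros((B, H), dtype=X.dtype)
        Wh, b = self.p["Wh"], self.p["b"]
        for t in range(L):
            z = Z[:, t] + h @ Wh + b
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = sigmoid(z[:, 3 * H :])
            c = f * c + i * g
            ct = np.tanh(c)
            h = o * ct
            gates[:, t, :H], gates[:, t, H : 2 * H] = i, f
            gates[:, t, 2 * H : 3 * H], gates[:, t, 3 * H :] = g, o
            C[:, t], Ct[:, t], Hs[:, t] = c, ct, h
        self._X, self._gates, self._C, self._Ct, self._Hs = X, gates, C, Ct, Hs
        return Hs

    def backward(self, dH: np.ndarray) -> np.ndarray:
        X, gates, C, Ct, Hs = self._X, self._gates, self._C, self._Ct, self._Hs
        B, L, D = X.shape
        H = self.hidden
        dZ = np.empty((B, L, 4 * H), dtype=X.dtype)
        dh = np.zeros((B, H), dtype=X.dtype)
        dc = np.zeros((B, H), dtype=X.dtype)
        Wh = self.p["Wh"]
        for t in reversed(range(L)):
            i = gates[:, t, :H]
            f = gates[:, t, H : 2 * H]
            g = gates[:, t, 2 * H : 3 * H]
            o = gates[:, t, 3 * H :]
            ct = Ct[:, t]
            c_prev = C[:, t - 1] if t > 0 else np.zeros((B, H), dtype=X.dtype)
            dht = dH[:, t] + dh
            do = dht * ct
            dc = dc + dht * o * (1.0 - ct**2)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc = dc * f
            dZ[:, t, :H] = di * i * (1.0 - i)
            dZ[:, t, H : 2 * H] = df * f * (1.0 - f)
            dZ[:, t, 2 * H : 3 * H] = dg * (1.0 - g**2)
            dZ[:, t, 3 * H :] = do * o * (1.0 - o)
            dh = dZ[:, t] @ Wh.T
        Hprev = np.concatenate(
            [np.zeros((B, 1, H), dtype=X.dtype), Hs[:, :-1]], axis=1
        )
        dZ2 = dZ.reshape(B * L, 4 * H)
        self.g["Wx"][...] = X.reshape(B * L, D).T @ dZ2
        self.g["Wh"][...] = Hprev.reshape(B * L, H).T @ dZ2
        self.g["b"][...] = dZ2.sum(axis=0)
        return (dZ2 @ self.p["Wx"].T).reshape(B, L, D)


class GRULayer:
    """GRU with gate order (r, z, n); the reset gate multiplies the hidden
    contribution of the candidate state, so the hidden bias is kept separate
    from the input bias."""

    def __init__(self, d_in: int, hidden: int, rng, dtype=np.float32):
        k = 1.0 / np.sqrt(hidden)
        self.hidden = hidden
        self.p = {
            "Wx": _uniform(rng, (d_in, 3 * hidden), k, dtype),
            "Wh": _uniform(rng, (hidden, 3 * hidden), k, dtype),
            "bx": np.zeros(3 * hidden, dtype=dtype),
            "bh": np.zeros(3 * hidden, dtype=dtype),
        }
        self.g = {n: np.zeros_like(v) for n, v in self.p.items()}

    def forward(self, X: np.ndarray) -> np.ndarray:
        B, L, D = X.shape
        H = self.hidden
        Zx = (X.reshape(B * L, D) @ self.p["Wx"]).reshape(B, L, 3 * H) + self.p["bx"]
        R = np.empty((B, L, H), dtype=X.dtype)
        Zg = np.empty((B, L, H), dtype=X.dtype)
        N = np.empty((B, L, H), dtype=X.dtype)
        HN = np.empty((B, L, H), dtype=X.dtype)  # h_{t-1} @ Whn + bhn
        Hs = np.empty((B, L, H), dtype=X.dtype)
        h = np.zeros((B, H), dtype=X.dtype)
        Wh, bh = self.p["Wh"], self.p["bh"]
        for t in range(L):
            zh = h @ Wh + bh
            r = sigmoid(Zx[:, t, :H] + zh[:, :H])
            zg = sigmoid(Zx[:, t, H : 2 * H] + zh[:, H : 2 * H])
            hn = zh[:, 2 * H :]
            n = np.tanh(Zx[:, t, 2 * H :] + r * hn)
            h = (1.0 - zg) * n + zg * h
            R[:, t], Zg[:, t], N[:, t], HN[:, t], Hs[:, t] = r, zg, n, hn, h
        self._X, self._R, self._Zg, self._N, self._HN, self._Hs = X, R, Zg, N, HN, Hs
        return Hs

    def backward(self, dH: np.ndarray) -> np.ndarray:
        X, R, Zg, N, HN, Hs = self._X, self._R, self._Zg, self._N, self._HN, self._Hs
        B, L, D = X.shape
        H = self.hidden
        dZx = np.empty((B, L, 3 * H), dtype=X.dtype)
        dZh = np.empty((B, L, 3 * H), dtype=X.dtype)
        dh = np.zeros((B, H), dtype=X.dtype)
        Wh = self.p["Wh"]
        for t in reversed(range(L)):
            h_prev = Hs[:, t - 1] if t > 0 else np.zeros((B, H), dtype=X.dtype)
            r, zg, n, hn = R[:, t], Zg[:, t], N[:, t], HN[:, t]
            dht = dH[:, t] + dh
            dzg = dht * (h_prev - n)
            dn = dht * (1.0 - zg)
            dh = dht * zg
            dn_pre = dn * (1.0 - n**2)
            dhn = dn_pre * r
            dr = dn_pre * hn
            dr_pre = dr * r * (1.0 - r)
            dzg_pre = dzg * zg * (1.0 - zg)
            dZx[:, t, :H], dZx[:, t, H : 2 * H], dZx[:, t, 2 * H :] = (
                dr_pre, dzg_pre, dn_pre,
            )
            dZh[:, t, :H], dZh[:, t, H : 2 * H], dZh[:, t, 2 * H :] = (
                dr_pre, dzg_pre, dhn,
            )
            dh = dh + dZh[:, t] @ Wh.T
        Hprev = np.concatenate(
            [np.zeros((B, 1, H), dtype=X.dtype), Hs[:, :-1]], axis=1
        )
        dZx2 = dZx.reshape(B * L, 3 * H)
        dZh2 = dZh.reshape(B * L, 3 * H)
        self.g["Wx"][...] = X.reshape(B * L, D).T @ dZx2
        self.g["Wh"][...] = Hprev.reshape(B * L, H).T @ dZh2
        self.g["bx"][...] = dZx2.sum(axis=0)
        self.g["bh"][...] = dZh2.sum(axis=0)
        return (dZx2 @ self.p["Wx"].T).reshape(B, L, D)


class Bidirectional:
    """Run a recurrent layer in both directions and concatenate the hidden
    sequences along the feature axis (output width 2H)."""

    def __init__(self, layer_cls, d_in: int, hidden: int, rng, dtype=np.float32):
        self.fwd = layer_cls(d_in, hidden, rng, dtype)
        self.bwd = layer_cls(d_in, hidden, rng, dtype)
        self.hidden = hidden

    @property
    def p(self):
        out = {f"fwd.{n}": v for n, v in self.fwd.p.items()}
        out.update({f"bwd.{n}": v for n, v in self.bwd.p.items()})
        return out

    @property
    def g(self):
        out = {f"fwd.{n}": v for n, v in self.fwd.g.items()}
        out.update({f"bwd.{n}": v for n, v in self.bwd.g.items()})
        return out

    def forward(self, X: np.ndarray) -> np.ndarray:
        out_f = self.fwd.forward(X)
        out_b = self.bwd.forward(X[:, ::-1])[:, ::-1]
        return np.concatenate([out_f, out_b], axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        H = self.hidden
        dX_f = self.fwd.backward(np.ascontiguousarray(dout[:, :, :H]))
        dX_b = self.bwd.backward(np.ascontiguousarray(dout[:, ::-1, H:]))[:, ::-1]
        return dX_f + dX_b


class LayerNorm:
    """Layer normalisation over the last axis."""

    def __init__(self, dim: int, dtype=np.float32, eps: float = 1e-5):
        self.eps = eps
        self.p = {
            "gamma": np.ones(dim, dtype=dtype),
            "beta": np.zeros(dim, dtype=dtype),
        }
        self.g = {n: np.zeros_like(v) for n, v in self.p.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.p["gamma"] * self._xhat + self.p["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        axes = tuple(range(dy.ndim - 1))
        self.g["gamma"][...] = (dy * xhat).sum(axis=axes)
        self.g["beta"][...] = dy.sum(axis=axes)
        dxhat = dy * self.p["gamma"]
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        return inv * (dxhat - m1 - xhat * m2)


class MultiHeadSelfAttention:
    """Scaled dot-product self-attention with ``nhead`` heads."""

    def __init__(self, d_model: int, nhead: int, rng, dtype=np.float32):
        if d_model % nhead:
            raise ValueError("d_model must be divisible by nhead")
        self.nhead = nhead
        self.dk = d_model // nhead
        self.q = Dense(d_model, d_model, rng, dtype)
        self.k = Dense(d_model, d_model, rng, dtype)
        self.v = Dense(d_model, d_model, rng, dtype)
        self.o = Dense(d_model, d_model, rng, dtype)
        self._subs = {"q": self.q, "k": self.k, "v": self.v, "o": self.o}

    @property
    def p(self):
        return {f"{s}.{n}": v for s, lay in self._subs.items() for n, v in lay.p.items()}

    @property
    def g(self):
        return {f"{s}.{n}": v for s, lay in self._subs.items() for n, v in lay.g.items()}

    def _split(self, x):
        B, L, D = x.shape
        return x.reshape(B, L, self.nhead, self.dk).transpose(0, 2, 1, 3)

    def _merge(self, x):
        B, h, L, dk = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, L, h * dk)

    def forward(self, x: np.ndarray) -> np.ndarray:
        Q = self._split(self.q.forward(x))
        K = self._split(self.k.forward(x))
        V = self._split(self.v.forward(x))
        scale = 1.0 / np.sqrt(self.dk)
        S = (Q @ K.transpose(0, 1, 3, 2)) * scale
        S = S - S.max(axis=-1, keepdims=True)
        P = np.exp(S)
        P /= P.sum(axis=-1, keepdims=True)
        ctx = P @ V
        self._Q, self._K, self._V, self._P, self._scale = Q, K, V, P, scale
        return self.o.forward(self._merge(ctx))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        Q, K, V, P, scale = self._Q, self._K, self._V, self._P, self._scale
        dctx = self._split(self.o.backward(dy))
        dP = dctx @ V.transpose(0, 1, 3, 2)
        dV = P.transpose(0, 1, 3, 2) @ dctx
        dS = P * (dP - (dP * P).sum(axis=-1, keepdims=True))
        dQ = (dS @ K) * scale
        dK = (dS.transpose(0, 1, 3, 2) @ Q) * scale
        dx = self.q.backward(self._merge(dQ))
        dx = dx + self.k.backward(self._merge(dK))
        dx = dx + self.v.backward(self._merge(dV))
        return dx


class TransformerBlock:
    """Pre-norm transformer encoder block: attention and position-wise
    feed-forward sublayers, each with a residual connection."""

    def __init__(self, d_model: int, nhead: int, d_ff: int, rng, dtype=np.float32):
        self.ln1 = LayerNorm(d_model, dtype)
        self.attn = MultiHeadSelfAttention(d_model, nhead, rng, dtype)
        self.ln2 = LayerNorm(d_model, dtype)
        self.ff1 = Dense(d_model, d_ff, rng, dtype)
        self.ff2 = Dense(d_ff, d_model, rng, dtype)
        self._subs = {
            "ln1": self.ln1, "attn": self.attn, "ln2": self.ln2,
            "ff1": self.ff1, "ff2": self.ff2,
        }

    @property
    def p(self):
        return {f"{s}.{n}": v for s, lay in self._subs.items() for n, v in lay.p.items()}

    @property
    def g(self):
        return {f"{s}.{n}": v for s, lay in self._subs.items() for n, v in lay.g.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        a = x + self.attn.forward(self.ln1.forward(x))
        h = self.ff1.forward(self.ln2.forward(a))
        self._relu_mask = h > 0
        y = a + self.ff2.forward(h * self._relu_mask)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dff = self.ff2.backward(dy) * self._relu_mask
        da = dy + self.ln2.backward(self.ff1.backward(dff))
        dx = da + self.ln1.backward(self.attn.backward(da))
        return dx


def positional_encoding(L: int, d_model: int, dtype=np.float32) -> np.ndarray:
    """Fixed sinusoidal position encoding, shape (L, d_model)."""
    pos = np.arange(L)[:, None]
    i = np.arange(d_model)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc.astype(dtype)
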