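"""Sequence regressor assembly and the Adam optimizer."""

from __future__ import annotations

import numpy as np

from .layers import (
    Bidirectional,
    Dense,
    GRULayer,
    LayerNorm,
    LSTMLayer,
    RNNLayer,
    TransformerBlock,
    positional_encoding,
)

ARCHITECTURES = ("lstm", "bilstm", "gru", "rnn", "transformer")

_RECURRENT = {"lstm": LSTMLayer, "gru": GRULayer, "rnn": RNNLayer}


class SequenceRegressor:
    """One-hot sequence in, scalar score out.

    Recurrent variants stack ``num_layers`` cells and read out from the
    final hidden state (for the bidirectional variant, the concatenation of
    the forward chain's last state and the backward chain's state at the
    first position).  The transformer variant embeds residues, adds fixed
    sinusoidal position encodings, applies ``num_layers`` pre-norm encoder
    blocks and mean-pools over positions before the linear readout.
    """

    def __init__(
        self,
        architecture: str,
        input_dim: int,
        num_layers: int,
        hidden_dim: int,
        rng: np.random.Generator,
        nhead: int = 4,
        dtype=np.float32,
    ):
        if architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {architecture!r}")
        if num_layers < 1 or hidden_dim < 1:
            raise ValueError("num_layers and hidden_dim must be >= 1")
        self.architecture = architecture
        self.num_layers = num_layers
        self.hidden_dim = hidden_dim
        self.dtype = dtype
        self.layers: list = []
        if architecture == "transformer":
            self.embed = Dense(input_dim, hidden_dim, rng, dtype)
            for _ in range(num_layers):
                self.layers.append(
                    TransformerBlock(hidden_dim, nhead, 2 * hidden_dim, rng, dtype)
                )
            self.final_ln = LayerNorm(hidden_dim, dtype)
            readout_dim = hidden_dim
        elif architecture == "bilstm":
            d = input_dim
            for _ in range(num_layers):
                self.layers.append(Bidirectional(LSTMLayer, d, hidden_dim, rng, dtype))
                d = 2 * hidden_dim
            readout_dim = 2 * hidden_dim
        else:
            cell = _RECURRENT[architecture]
            d = input_dim
            for _ in range(num_layers):
                self.layers.append(cell(d, hidden_dim, rng, dtype))
                d = hidden_dim
            readout_dim = hidden_dim
        self.readout = Dense(readout_dim, 1, rng, dtype)
        self._posenc = None

    # -- parameter bookkeeping ---------------------------------------------

    def _named(self):
        if self.architecture == "transformer":
            yield "embed", self.embed
            for i, lay in enumerate(self.layers):
                yield f"block{i}", lay
            yield "final_ln", self.final_ln
        else:
            for i, lay in enumerate(self.layers):
                yield f"layer{i}", lay
        yield "readout", self.readout

    def params(self) -> dict[str, np.ndarray]:
        return {
            f"{ln}.{pn}": arr
            for ln, lay in self._named()
            for pn, arr in lay.p.items()
        }

    def grads(self) -> dict[str, np.ndarray]:
        return {
            f"{ln}.{pn}": arr
            for ln, lay in self._named()
            for pn, arr in lay.g.items()
        }

    def n_parameters(self) -> int:
        return sum(v.size for v in self.params().values())

    # -- forward / backward -------------------------------------------------

    def forward(self, X: np.ndarray) -> np.ndarray:
        """X: (B, L, A) float one-hot; returns (B,) predictions."""
        X = X.astype(self.dtype, copy=False)
        if self.architecture == "transformer":
            h = self.embed.forward(X)
            if self._posenc is None or self._posenc.shape[0] != h.shape[1]:
                self._posenc = positional_encoding(h.shape[1], self.hidden_dim, self.dtype)
            h = h + self._posenc
            for blk in self.layers:
                h = blk.forward(h)
            h = self.final_ln.forward(h)
            self._pool_L = h.shape[1]
            feat = h.mean(axis=1)
        else:
            h = X
            for lay in self.layers:
                h = lay.forward(h)
            if self.architecture == "bilstm":
                H = self.hidden_dim
                feat = np.concatenate([h[:, -1, :H], h[:, 0, H:]], axis=1)
            else:
                feat = h[:, -1]
            self._seq_shape = h.shape
        return self.readout.forward(feat)[:, 0]

    def backward(self, dpred: np.ndarray) -> None:
        """Backpropagate d(loss)/d(prediction), filling all gradients."""
        dfeat = self.readout.backward(dpred[:, None].astype(self.dtype, copy=False))
        if self.architecture == "transformer":
            B = dfeat.shape[0]
            dh = np.repeat(dfeat[:, None, :], self._pool_L, axis=1) / self._pool_L
            dh = self.final_ln.backward(dh)
            for blk in reversed(self.layers):
                dh = blk.backward(dh)
            self.embed.backward(dh)
            return
        B, L, W = self._seq_shape
        dh = np.zeros((B, L, W), dtype=self.dtype)
        if self.architecture == "bilstm":
            H = self.hidden_dim
            dh[:, -1, :H] = dfeat[:, :H]
            dh[:, 0, H:] = dfeat[:, H:]
        else:
            dh[:, -1] = dfeat
        for lay in reversed(self.layers):
            dh = lay.backward(dh)

    # -- state I/O -----------------------------------------------------------

    def get_state(self) -> dict[str, np.ndarray]:
        return {n: v.copy() for n, v in self.params().items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        params = self.params()
        if set(params) != set(state):
            raise ValueError("state does not match model parameters")
        for n, v in params.items():
            v[...] = state[n]


class Adam:
    """Adaptive-moment gradient descent over a named parameter dict."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {n: np.zeros_like(v) for n, v in params.items()}
        self.v = {n: np.zeros_like(v) for n, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for n, p in self.params.items():
            g = grads[n]
            m = self.m[n]
            v = self.v[n]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
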