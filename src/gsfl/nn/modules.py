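"""Neural-network building blocks on top of :mod:`gsfl.nn.tensor`.

Initialisation draws from an explicit :class:`numpy.random.Generator`
so a model built twice from the same seed is bitwise identical.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat

__all__ = [
    "Module",
    "Linear",
    "MLP",
    "Dropout",
    "Embedding",
    "LayerNorm",
    "BiLSTM",
    "TransformerEncoderLayer",
]


class Module:
    """Base class: tracks parameters of itself and nested sub-modules."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model has {len(params)} parameters"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = a.astype(np.float64).copy()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.W = Tensor(_glorot(rng, d_in, d_out), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class MLP(Module):
    """Stack of Linear layers with ReLU between them (none after the last)."""

    def __init__(self, dims: list[int], rng: np.random.Generator, dropout: float = 0.0):
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.dropout = Dropout(dropout)

    def __call__(self, x: Tensor, *, train: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
                x = self.dropout(x, train=train, rng=rng)
        return x


class Dropout(Module):
    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0,1)")
        self.p = p

    def __call__(self, x: Tensor, *, train: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        if not train or self.p == 0.0:
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        keep = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator):
        self.weight = Tensor(rng.normal(0.0, 0.1, size=(n_tokens, dim)), requires_grad=True)

    def __call__(self, indices: np.ndarray) -> Tensor:
        indices = np.asarray(indices)
        if indices.min() < 0 or indices.max() >= self.weight.shape[0]:
            raise IndexError("token index out of dictionary range")
        return self.weight[indices]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class _LSTMCellParams(Module):
    """One direction of one LSTM layer; gate order (i, f, g, o)."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.W_x = Tensor(_glorot(rng, d_in, 4 * d_hidden), requires_grad=True)
        self.W_h = Tensor(_glorot(rng, d_hidden, 4 * d_hidden), requires_grad=True)
        b = np.zeros(4 * d_hidden)
        b[d_hidden:2 * d_hidden] = 1.0  # forget-gate bias, standard trick
        self.b = Tensor(b, requires_grad=True)
        self.d_hidden = d_hidden

    def run(self, x: Tensor, mask: np.ndarray, reverse: bool) -> Tensor:
        """x: [B,T,D]; mask: [B,T] 0/1. Returns hidden states [B,T,H].

        Masked steps carry the previous state through, so pads at the
        end of a sequence never touch the recurrence in either direction.
        """
        B, T, _ = x.shape
        H = self.d_hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        xw = x @ self.W_x  # [B,T,4H]
        order = range(T - 1, -1, -1) if reverse else range(T)
        outs: list[Tensor | None] = [None] * T
        for t in order:
            gates = xw[:, t, :] + h @ self.W_h + self.b
            i = gates[:, :H].sigmoid()
            f = gates[:, H:2 * H].sigmoid()
            g = gates[:, 2 * H:3 * H].tanh()
            o = gates[:, 3 * H:].sigmoid()
            c_new = f * c + i * g
            h_new = o * c_new.tanh()
            m = Tensor(mask[:, t:t + 1])
            keep = Tensor(1.0 - mask[:, t:t + 1])
            c = m * c_new + keep * c
            h = m * h_new + keep * h
            outs[t] = h * m  # zero output at pad positions
        from .tensor import stack
        return stack(outs, axis=1)


class BiLSTM(Module):
    """Stacked bidirectional LSTM; output width 2*d_hidden per layer."""

    def __init__(self, d_in: int, d_hidden: int, n_layers: int, rng: np.random.Generator,
                 dropout: float = 0.0):
        self.cells_fw = []
        self.cells_bw = []
        for layer in range(n_layers):
            d = d_in if layer == 0 else 2 * d_hidden
            self.cells_fw.append(_LSTMCellParams(d, d_hidden, rng))
            self.cells_bw.append(_LSTMCellParams(d, d_hidden, rng))
        self.dropout = Dropout(dropout)
        self.d_hidden = d_hidden

    def __call__(self, x: Tensor, mask: np.ndarray, *, train: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        out = x
        for layer, (fw, bw) in enumerate(zip(self.cells_fw, self.cells_bw)):
            h_fw = fw.run(out, mask, reverse=False)
            h_bw = bw.run(out, mask, reverse=True)
            out = concat([h_fw, h_bw], axis=-1)
            if layer < len(self.cells_fw) - 1:
                out = self.dropout(out, train=train, rng=rng)
        return out


class TransformerEncoderLayer(Module):
    """Pre-built single encoder block: MHSA + FFN, residual + LayerNorm."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator,
                 d_ff: int | None = None, dropout: float = 0.0):
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        d_ff = d_ff or 4 * d_model
        self.q = Linear(d_model, d_model, rng)
        self.k = Linear(d_model, d_model, rng)
        self.v = Linear(d_model, d_model, rng)
        self.o = Linear(d_model, d_model, rng)
        self.ff1 = Linear(d_model, d_ff, rng)
        self.ff2 = Linear(d_ff, d_model, rng)
        self.ln1 = LayerNorm(d_model)
        self.ln2 = LayerNorm(d_model)
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.dropout = Dropout(dropout)

    def __call__(self, x: Tensor, mask: np.ndarray, *, train: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        B, T, D = x.shape
        nh, dh = self.n_heads, self.d_head

        def split_heads(t: Tensor) -> Tensor:
            return t.reshape(B, T, nh, dh).transpose(0, 2, 1, 3)  # [B,nh,T,dh]

        q = split_heads(self.q(x))
        k = split_heads(self.k(x))
        v = split_heads(self.v(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (dh ** -0.5)  # [B,nh,T,T]
        att_mask = np.broadcast_to(mask[:, None, None, :], scores.shape)
        att = scores.softmax(axis=-1, mask=att_mask)
        ctx = (att @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
        x = self.ln1(x + self.dropout(self.o(ctx), train=train, rng=rng))
        ff = self.ff2(self.ff1(x).relu())
        x = self.ln2(x + self.dropout(ff, train=train, rng=rng))
        # keep pad rows at zero so downstream pooling can ignore them
        return x * Tensor(mask[:, :, None].astype(np.float64))
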