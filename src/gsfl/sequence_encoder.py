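"""Multi-level SMILES sequence encoder.

Token indices are embedded (with an added 3-way embedding of the token
level: functional group / ion group / atom), weighted by a hierarchical
attention (HA) over positions, then passed through a stacked BiLSTM and
a Transformer self-attention block.  The HA stage computes softmax
scores over the sequence, forms the attention-weighted input and its
pooled context vector, and broadcasts that context back over the
timesteps; the BiLSTM consumes the weighted input plus the broadcast
context so that token order is preserved.
"""

from __future__ import annotations

import numpy as np

from .nn import BiLSTM, Embedding, Linear, Module, Tensor, TransformerEncoderLayer

__all__ = ["HierarchicalAttention", "SequenceEncoder"]

N_LEVELS = 3


class HierarchicalAttention(Module):
    """Position attention: Z = tanh(W1 X + b); S = softmax(W2 Z) over T."""

    def __init__(self, d_in: int, d_att: int, rng: np.random.Generator):
        if d_att < 1:
            raise ValueError("attention width must be positive")
        self.W1 = Linear(d_in, d_att, rng, bias=True)
        self.W2 = Linear(d_att, 1, rng, bias=False)

    def scores(self, x: Tensor, mask: np.ndarray) -> Tensor:
        """Masked attention weights S, [B,T,1], summing to 1 over T."""
        if (mask.sum(axis=1) == 0).any():
            raise ValueError("every sample needs at least one unmasked position")
        z = self.W1(x).tanh()
        s = self.W2(z)  # [B,T,1]
        return s.softmax(axis=1, mask=mask[:, :, None])

    def __call__(self, x: Tensor, mask: np.ndarray) -> tuple[Tensor, Tensor, Tensor]:
        """Returns (X_atten, h_atten, h_expanded)."""
        s = self.scores(x, mask)
        x_atten = x * s
        h_atten = x_atten.sum(axis=1)  # [B,H]
        T = x.shape[1]
        h_exp = h_atten.reshape(h_atten.shape[0], 1, h_atten.shape[1]) * Tensor(
            np.ones((1, T, 1))
        )
        return x_atten, h_atten, h_exp


class SequenceEncoder(Module):
    def __init__(
        self,
        vocab_size: int,
        d_embed: int,
        d_hidden: int,
        n_lstm_layers: int,
        rng: np.random.Generator,
        dropout: float = 0.0,
        d_att: int | None = None,
        n_heads: int = 4,
        use_hierarchical_attention: bool = True,
    ):
        self.token_embedding = Embedding(vocab_size, d_embed, rng)
        self.level_embedding = Embedding(N_LEVELS, d_embed, rng)
        self.use_ha = use_hierarchical_attention
        if use_hierarchical_attention:
            self.ha = HierarchicalAttention(d_embed, d_att or d_embed, rng)
        self.bilstm = BiLSTM(d_embed, d_hidden, n_lstm_layers, rng, dropout=dropout)
        self.transformer = TransformerEncoderLayer(2 * d_hidden, n_heads, rng,
                                                   dropout=dropout)
        self.d_out = 2 * d_hidden

    def embed_tokens(self, indices: np.ndarray, levels: np.ndarray,
                     mask: np.ndarray) -> Tensor:
        """[B,T] int indices -> [B,T,H] embeddings, zeroed at pads."""
        x = self.token_embedding(indices) + self.level_embedding(levels)
        return x * Tensor(mask[:, :, None].astype(np.float64))

    def __call__(
        self,
        indices: np.ndarray,
        levels: np.ndarray,
        mask: np.ndarray,
        *,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Encode a padded batch to [B,T,2*d_hidden]."""
        x = self.embed_tokens(indices, levels, mask)
        if self.use_ha:
            x_atten, _, h_exp = self.ha(x, mask)
            seq_in = (x_atten + h_exp) * Tensor(mask[:, :, None].astype(np.float64))
        else:
            seq_in = x
        h = self.bilstm(seq_in, mask, train=train, rng=rng)
        h = self.transformer(h, mask, train=train, rng=rng)
        return h
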