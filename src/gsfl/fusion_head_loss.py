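"""Branch pooling, weighted fusion, prediction head, and training losses.

Each branch is pooled to one molecule-level vector by global attention
(a learned scalar gate per item, softmax-normalized over the molecule's
atoms or the sequence's tokens).  The pooled vectors are projected to a
common fusion width and combined affinely, H = Ws·Hs + Wg·Hg + b, then
classified by a 3-layer head (fusion_dim→256→64→1) producing one
pre-sigmoid logit per molecule.

The training loss is summed binary cross-entropy on the logits plus
α times a cross-modal contrastive term computed on the L2-normalized
pooled vectors.  The contrastive term is, for each anchor modality,
−(1/N)·Σ_i log[ exp(cos(Z_si,Z_gi)/T) / Σ_{j≠i} exp(cos(Z_si,Z_gj)/T) ];
the denominator deliberately excludes the positive pair, so the loss
can go negative.  ``variant="ntxent"`` includes the positive pair in
the denominator (standard bounded form).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Linear, MLP, Module, Tensor, segment_max, segment_sum

__all__ = [
    "LossConfig",
    "global_attention_pool_segments",
    "global_attention_pool_masked",
    "FusionHead",
    "contrastive_loss",
    "bce_with_logits",
    "fusion_loss",
]


@dataclass
class LossConfig:
    alpha: float = 0.1
    temperature: float = 0.5
    contrastive_variant: str = "as_printed"  # or "ntxent"

    def __post_init__(self):
        if not np.isfinite(self.alpha) or self.alpha < 0:
            raise ValueError("alpha must be finite and >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.contrastive_variant not in ("as_printed", "ntxent"):
            raise ValueError(f"unknown variant {self.contrastive_variant!r}")


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def global_attention_pool_segments(
    x: Tensor, segment_ids: np.ndarray, n_segments: int, gate: Linear
) -> Tensor:
    """Pool ragged per-item vectors to one vector per segment (molecule)."""
    if x.shape[0] == 0:
        raise ValueError("cannot pool an empty item set")
    scores = gate(x)  # [n,1]
    # stabilized segment softmax
    seg_max = np.zeros((n_segments, 1))
    np.maximum.at(seg_max, segment_ids, scores.data)
    e = (scores - Tensor(seg_max[segment_ids])).exp()
    denom = segment_sum(e, segment_ids, n_segments)
    w = e / denom[segment_ids]
    return segment_sum(x * w, segment_ids, n_segments)


def global_attention_pool_masked(x: Tensor, mask: np.ndarray, gate: Linear) -> Tensor:
    """Pool dense padded sequences [B,T,d] to [B,d] with a masked softmax."""
    if (mask.sum(axis=1) == 0).any():
        raise ValueError("cannot pool a fully masked sequence")
    scores = gate(x)  # [B,T,1]
    w = scores.softmax(axis=1, mask=mask[:, :, None])
    return (x * w).sum(axis=1)


# ---------------------------------------------------------------------------
# fusion + head
# ---------------------------------------------------------------------------

class FusionHead(Module):
    """Projection to fusion width, affine fusion, and the MLP classifier."""

    def __init__(
        self,
        d_seq: int,
        d_graph: int,
        fusion_dim: int,
        rng: np.random.Generator,
        dropout: float = 0.0,
        use_sequence_branch: bool = True,
    ):
        self.use_sequence_branch = use_sequence_branch
        self.gate_g = Linear(d_graph, 1, rng)
        self.proj_g = Linear(d_graph, fusion_dim, rng)
        self.W_g = Linear(fusion_dim, fusion_dim, rng, bias=False)
        if use_sequence_branch:
            self.gate_s = Linear(d_seq, 1, rng)
            self.proj_s = Linear(d_seq, fusion_dim, rng)
            self.W_s = Linear(fusion_dim, fusion_dim, rng, bias=False)
        self.b = Tensor(np.zeros(fusion_dim), requires_grad=True)
        self.head = _PredictionHead(fusion_dim, rng, dropout)
        self.fusion_dim = fusion_dim

    def weighted_fusion(self, H_s: Tensor | None, H_g: Tensor) -> Tensor:
        """H = Ws·Hs + Wg·Hg + b (graph-only: H = Wg·Hg + b)."""
        H = self.W_g(H_g) + self.b
        if H_s is not None:
            if not self.use_sequence_branch:
                raise ValueError("sequence branch disabled in this head")
            if H_s.shape[-1] != H_g.shape[-1]:
                raise ValueError(
                    f"fusion width mismatch: {H_s.shape[-1]} vs {H_g.shape[-1]}")
            H = H + self.W_s(H_s)
        return H

    def __call__(
        self,
        pooled_seq: Tensor | None,
        pooled_graph: Tensor,
        *,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, Tensor | None, Tensor]:
        """Returns (logits [B], Z_s [B,F] or None, Z_g [B,F])."""
        Z_g = self.proj_g(pooled_graph)
        Z_s = self.proj_s(pooled_seq) if (pooled_seq is not None) else None
        H = self.weighted_fusion(Z_s, Z_g)
        logits = self.head(H, train=train, rng=rng)
        return logits, Z_s, Z_g


class _PredictionHead(Module):
    """fusion_dim -> 256 (ReLU, dropout) -> 64 (ReLU) -> 1."""

    def __init__(self, fusion_dim: int, rng: np.random.Generator, dropout: float):
        self.mlp = MLP([fusion_dim, 256, 64, 1], rng, dropout=0.0)
        from .nn import Dropout
        self.dropout = Dropout(dropout)

    def __call__(self, H: Tensor, *, train: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        l1, l2, l3 = self.mlp.layers
        h = l1(H).relu()
        h = self.dropout(h, train=train, rng=rng)
        h = l2(h).relu()
        return l3(h).reshape(-1)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _l2_normalize(z: Tensor) -> Tensor:
    sq = (z * z).sum(axis=-1, keepdims=True)
    return z * ((sq + 1e-12) ** -0.5)


def contrastive_loss(
    Z_s: Tensor,
    Z_g: Tensor,
    temperature: float,
    variant: str = "as_printed",
) -> Tensor:
    """Symmetric cross-modal contrastive loss on cosine similarities."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    N = Z_s.shape[0]
    if N < 2:
        raise ValueError("contrastive loss needs a batch of at least 2")
    if Z_s.shape != Z_g.shape:
        raise ValueError("Z_s and Z_g must have identical shapes")
    zs = _l2_normalize(Z_s)
    zg = _l2_normalize(Z_g)
    sim = (zs @ zg.transpose()) * (1.0 / temperature)  # [N,N], cos/T
    e = sim.exp()
    eye = np.eye(N)
    off = Tensor(1.0 - eye)
    pos = (e * Tensor(eye)).sum(axis=1)  # exp(cos_ii/T)
    if variant == "as_printed":
        denom_s = (e * off).sum(axis=1)  # anchor s_i over Z_gj, j != i
        denom_g = (e * off).sum(axis=0)  # anchor g_i over Z_sj, j != i
    elif variant == "ntxent":
        denom_s = e.sum(axis=1)
        denom_g = e.sum(axis=0)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    term_s = ((pos / denom_s).log() * (-1.0 / N)).sum()
    term_g = ((pos / denom_g).log() * (-1.0 / N)).sum()
    return term_s + term_g


def bce_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Numerically stable binary cross-entropy, summed over samples."""
    labels = np.asarray(labels, dtype=np.float64)
    if not np.isin(labels, (0.0, 1.0)).all():
        raise ValueError("labels must be 0/1")
    if labels.shape[0] != logits.shape[0]:
        raise ValueError("logits and labels length mismatch")
    # max(z,0) - z*y + log(1 + exp(-|z|))
    abs_z = logits.relu() + (-logits).relu()
    per = logits.relu() - logits * Tensor(labels) + ((-abs_z).exp() + 1.0).log()
    return per.sum()


def fusion_loss(
    logits: Tensor,
    labels: np.ndarray,
    Z_s: Tensor | None,
    Z_g: Tensor | None,
    config: LossConfig,
) -> tuple[Tensor, float, float]:
    """L = BCE + α·L_contrast.  Returns (loss, bce_value, contrast_value)."""
    bce = bce_with_logits(logits, labels)
    if config.alpha > 0 and Z_s is not None and Z_g is not None:
        con = contrastive_loss(Z_s, Z_g, config.temperature,
                               config.contrastive_variant)
        total = bce + config.alpha * con
        return total, float(bce.data), float(con.data)
    return bce, float(bce.data), 0.0
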