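"""Molecular-graph encoder: communicative message passing + feature attention.

Atoms and bonds are first projected into a shared hidden space.  For L
iterations, each atom aggregates the hidden states of its incoming
directed edges — the sum of the edge states gated by their element-wise
maximum — and communicates the aggregate with its own state through a
per-layer MLP; each directed edge is then refreshed from its source
atom's new state against the edge's initial projection.  After the last
iteration a readout step re-aggregates and mixes the raw atom features
back in.  The feature-attention (FA) stage squeezes each molecule into
sum- and max-pooled descriptors, excites them through a shared
bottleneck of reduction ratio r, and reweights every atom's channels
with the resulting sigmoid gates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import ATOM_FDIM, BOND_FDIM, MolGraph
from .nn import MLP, Linear, Module, Tensor, concat, segment_max, segment_sum

__all__ = ["BatchedGraphs", "batch_graphs", "GraphEncoder"]


@dataclass
class BatchedGraphs:
    """Several molecular graphs packed into one ragged batch."""

    atom_features: np.ndarray  # [sumN_V, 133]
    edge_features: np.ndarray  # [sumE, 14] (bond rows duplicated per direction)
    edge_src: np.ndarray  # [sumE] source atom of each directed edge
    edge_dst: np.ndarray  # [sumE] destination atom
    atom_graph_ids: np.ndarray  # [sumN_V] molecule index per atom
    n_graphs: int

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_src.shape[0]


def batch_graphs(graphs: list[MolGraph]) -> BatchedGraphs:
    atom_feats, edge_feats, srcs, dsts, gids = [], [], [], [], []
    offset = 0
    for gi, g in enumerate(graphs):
        atom_feats.append(g.atom_features)
        if g.edges:
            edge_feats.append(g.bond_features[g.edge_to_bond])
            e = np.asarray(g.edges, dtype=np.int64) + offset
            srcs.append(e[:, 0])
            dsts.append(e[:, 1])
        gids.append(np.full(g.n_atoms, gi, dtype=np.int64))
        offset += g.n_atoms
    return BatchedGraphs(
        atom_features=np.concatenate(atom_feats, axis=0),
        edge_features=(np.concatenate(edge_feats, axis=0) if edge_feats
                       else np.zeros((0, BOND_FDIM))),
        edge_src=(np.concatenate(srcs) if srcs else np.zeros(0, dtype=np.int64)),
        edge_dst=(np.concatenate(dsts) if dsts else np.zeros(0, dtype=np.int64)),
        atom_graph_ids=np.concatenate(gids),
        n_graphs=len(graphs),
    )


class GraphEncoder(Module):
    def __init__(
        self,
        d_hidden: int,
        n_layers: int,
        rng: np.random.Generator,
        dropout: float = 0.0,
        reduction_ratio: int = 4,
        use_feature_attention: bool = True,
    ):
        if n_layers < 1:
            raise ValueError("need at least one message-passing layer")
        if use_feature_attention and d_hidden % reduction_ratio != 0:
            raise ValueError("reduction ratio must divide the hidden width")
        self.d_hidden = d_hidden
        self.n_layers = n_layers
        self.use_fa = use_feature_attention
        self.W_iV = Linear(ATOM_FDIM, d_hidden, rng, bias=False)
        self.W_iE = Linear(BOND_FDIM, d_hidden, rng, bias=False)
        self.W_edge = Linear(d_hidden, d_hidden, rng, bias=False)
        self.communicate = [
            MLP([2 * d_hidden, d_hidden, d_hidden], rng, dropout=dropout)
            for _ in range(n_layers)
        ]
        self.readout_mlp = MLP([2 * d_hidden + ATOM_FDIM, d_hidden, d_hidden],
                               rng, dropout=dropout)
        if use_feature_attention:
            d_r = d_hidden // reduction_ratio
            self.W2_fa = Linear(d_hidden, d_r, rng, bias=False)  # squeeze
            self.W1_fa = Linear(d_r, d_hidden, rng, bias=False)  # excite

    # -- individual stages ----------------------------------------------

    def init_hidden(self, batch: BatchedGraphs) -> tuple[Tensor, Tensor]:
        """h_v0 = ReLU(X_V W_iV); h_e0 = ReLU(X_E W_iE)."""
        h_v = self.W_iV(Tensor(batch.atom_features)).relu()
        h_e = self.W_iE(Tensor(batch.edge_features)).relu()
        return h_v, h_e

    def _aggregate(self, h_e: Tensor, batch: BatchedGraphs) -> Tensor:
        """Per-atom message: (sum of incoming edge states) ⊙ (their max).

        Atoms with no incoming edges receive a zero message.
        """
        if batch.n_edges == 0:
            return Tensor(np.zeros((batch.n_atoms, self.d_hidden)))
        s = segment_sum(h_e, batch.edge_dst, batch.n_atoms)
        m = segment_max(h_e, batch.edge_dst, batch.n_atoms)
        return s * m

    def message_pass_step(
        self,
        h_v: Tensor,
        h_e: Tensor,
        h_e0: Tensor,
        batch: BatchedGraphs,
        k: int,
        *,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, Tensor]:
        if not 1 <= k <= self.n_layers:
            raise ValueError(f"iteration index {k} outside [1,{self.n_layers}]")
        m_v = self._aggregate(h_e, batch)
        h_v = self.communicate[k - 1](concat([m_v, h_v], axis=-1),
                                      train=train, rng=rng)
        if batch.n_edges:
            delta = self.W_edge(h_v[batch.edge_src] - h_e)
            h_e = (h_e0 + delta).relu()
        return h_v, h_e

    def readout_nodes(
        self,
        h_v: Tensor,
        h_e: Tensor,
        batch: BatchedGraphs,
        *,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Final aggregation mixing the raw atom features back in."""
        m_v = self._aggregate(h_e, batch)
        x_v = Tensor(batch.atom_features)
        return self.readout_mlp(concat([m_v, h_v, x_v], axis=-1),
                                train=train, rng=rng)

    def feature_attention(self, h: Tensor, batch: BatchedGraphs) -> Tensor:
        """Channel-wise reweighting from pooled molecule descriptors."""
        if batch.n_atoms == 0:
            raise ValueError("feature attention needs at least one atom")
        g_sum = segment_sum(h, batch.atom_graph_ids, batch.n_graphs)
        g_max = segment_max(h, batch.atom_graph_ids, batch.n_graphs)
        excited = self.W2_fa(g_sum).relu() + self.W2_fa(g_max).relu()
        c = self.W1_fa(excited).sigmoid()  # [n_graphs, d], each in (0,1)
        return h * c[batch.atom_graph_ids]

    # -- full forward ---------------------------------------------------

    def __call__(
        self,
        batch: BatchedGraphs,
        *,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        h_v, h_e = self.init_hidden(batch)
        h_e0 = h_e
        for k in range(1, self.n_layers + 1):
            h_v, h_e = self.message_pass_step(h_v, h_e, h_e0, batch, k,
                                              train=train, rng=rng)
        h = self.readout_nodes(h_v, h_e, batch, train=train, rng=rng)
        if self.use_fa:
            h = self.feature_attention(h, batch)
        return h
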