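"""Full fusion model: graph branch + sequence branch + fusion head.

A :class:`GSFLModel` owns its tokenizer state (functional-group
vocabulary and token dictionary mined from the training set), so a
saved checkpoint is self-contained: weights in an ``.npz`` file plus a
JSON sidecar with the configuration and tokenizer state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .config import ModelConfig
from .data_io import MoleculeRecord, build_mol_graph
from .fg_tokenizer import (
    FunctionalGroupVocab,
    TokenDictionary,
    build_dictionary,
    encode_sequence,
    mine_functional_groups,
    tokenize,
    tokenize_characters,
)
from .fusion_head_loss import (
    FusionHead,
    LossConfig,
    global_attention_pool_masked,
    global_attention_pool_segments,
)
from .graph_encoder import BatchedGraphs, GraphEncoder, batch_graphs
from .nn import Module, Tensor
from .sequence_encoder import SequenceEncoder

__all__ = ["MoleculeBatch", "GSFLModel"]


@dataclass
class MoleculeBatch:
    graphs: BatchedGraphs
    token_indices: np.ndarray  # [B,T]
    token_levels: np.ndarray  # [B,T]
    token_mask: np.ndarray  # [B,T]
    labels: np.ndarray  # [B]


class GSFLModel(Module):
    def __init__(
        self,
        config: ModelConfig,
        fg_vocab: FunctionalGroupVocab,
        dictionary: TokenDictionary,
    ):
        self.config = config
        self.fg_vocab = fg_vocab
        self.dictionary = dictionary
        rng = np.random.default_rng(config.seed)
        self.graph_encoder = GraphEncoder(
            d_hidden=config.gnn_hidden,
            n_layers=config.gnn_layers,
            rng=rng,
            dropout=config.dropout,
            reduction_ratio=config.reduction_ratio,
            use_feature_attention=config.use_fa,
        )
        if config.use_sequence_branch:
            self.sequence_encoder = SequenceEncoder(
                vocab_size=len(dictionary),
                d_embed=config.seq_hidden,
                d_hidden=config.seq_hidden,
                n_lstm_layers=config.seq_layers,
                rng=rng,
                dropout=config.dropout,
                n_heads=config.transformer_heads,
                use_hierarchical_attention=config.use_ha,
            )
            d_seq = self.sequence_encoder.d_out
        else:
            self.sequence_encoder = None
            d_seq = 1  # unused
        self.fusion = FusionHead(
            d_seq=d_seq,
            d_graph=config.gnn_hidden,
            fusion_dim=config.fusion_dim,
            rng=rng,
            dropout=config.dropout,
            use_sequence_branch=config.use_sequence_branch,
        )
        self.loss_config = LossConfig(
            alpha=config.alpha,
            temperature=config.temperature,
            contrastive_variant=config.contrastive_variant,
        )

    # -- dataset preparation --------------------------------------------

    @classmethod
    def build(cls, config: ModelConfig,
              train_records: Sequence[MoleculeRecord]) -> "GSFLModel":
        """Mine tokenizer state from the training set and build the model."""
        smiles = [r.smiles for r in train_records]
        vocab = mine_functional_groups(smiles, min_count=config.fg_min_count)
        if config.use_fg_splitting:
            seqs = [tokenize(s, vocab) for s in smiles]
        else:
            seqs = [tokenize_characters(s) for s in smiles]
        dictionary = build_dictionary(seqs)
        return cls(config, vocab, dictionary)

    def _tokenize(self, smiles: str):
        if self.config.use_fg_splitting:
            return tokenize(smiles, self.fg_vocab)
        return tokenize_characters(smiles)

    def _featurize(self, smiles: str):
        """Graph + encoded token sequence for one molecule (memoized)."""
        cache = getattr(self, "_feat_cache", None)
        if cache is None:
            cache = self._feat_cache = {}
        if smiles not in cache:
            seq = self._tokenize(smiles)
            enc = encode_sequence(seq, self.dictionary, self.config.max_len)
            cache[smiles] = (build_mol_graph(smiles), enc)
        return cache[smiles]

    def collate(self, records: Sequence[MoleculeRecord]) -> MoleculeBatch:
        feats = [self._featurize(r.smiles) for r in records]
        graphs = [f[0] for f in feats]
        idxs = [f[1][0] for f in feats]
        lvls = [f[1][1] for f in feats]
        masks = [f[1][2] for f in feats]
        return MoleculeBatch(
            graphs=batch_graphs(graphs),
            token_indices=np.stack(idxs),
            token_levels=np.stack(lvls),
            token_mask=np.stack(masks),
            labels=np.array([r.label for r in records], dtype=np.float64),
        )

    # -- forward --------------------------------------------------------

    def __call__(
        self,
        batch: MoleculeBatch,
        *,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, Tensor | None, Tensor]:
        """Returns (logits [B], Z_s or None, Z_g) for a collated batch."""
        h_atoms = self.graph_encoder(batch.graphs, train=train, rng=rng)
        H_g = global_attention_pool_segments(
            h_atoms, batch.graphs.atom_graph_ids, batch.graphs.n_graphs,
            self.fusion.gate_g,
        )
        if self.sequence_encoder is not None:
            h_tokens = self.sequence_encoder(
                batch.token_indices, batch.token_levels, batch.token_mask,
                train=train, rng=rng,
            )
            H_s = global_attention_pool_masked(
                h_tokens, batch.token_mask, self.fusion.gate_s)
        else:
            H_s = None
        return self.fusion(H_s, H_g, train=train, rng=rng)

    def predict_proba(self, records: Sequence[MoleculeRecord],
                      batch_size: int = 64) -> np.ndarray:
        """Deterministic evaluation-mode activity probabilities."""
        probs = []
        for start in range(0, len(records), batch_size):
            batch = self.collate(records[start:start + batch_size])
            logits, _, _ = self(batch, train=False)
            probs.append(1.0 / (1.0 + np.exp(-logits.data)))
        return np.concatenate(probs)

    # -- checkpointing --------------------------------------------------

    def save(self, path) -> None:
        """Write `<path>.npz` (weights) and `<path>.json` (config + tokenizer)."""
        path = Path(path)
        arrays = {f"p{i}": a for i, a in enumerate(self.state_arrays())}
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {
            "config": self.config.to_dict(),
            "fg_vocab": {"patterns": self.fg_vocab.patterns,
                         "counts": self.fg_vocab.counts},
            "dictionary": {"index": self.dictionary.index,
                           "pad": self.dictionary.pad_index,
                           "unk": self.dictionary.unk_index},
        }
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def load(cls, path) -> "GSFLModel":
        path = Path(path)
        with open(path.with_suffix(".json")) as fh:
            sidecar = json.load(fh)
        config = ModelConfig.from_dict(sidecar["config"])
        vocab = FunctionalGroupVocab(patterns=sidecar["fg_vocab"]["patterns"],
                                     counts=sidecar["fg_vocab"]["counts"])
        dictionary = TokenDictionary(index=sidecar["dictionary"]["index"],
                                     pad_index=sidecar["dictionary"]["pad"],
                                     unk_index=sidecar["dictionary"]["unk"])
        model = cls(config, vocab, dictionary)
        with np.load(path.with_suffix(".npz")) as data:
            arrays = [data[f"p{i}"] for i in range(len(data.files))]
        model.load_state_arrays(arrays)
        return model
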