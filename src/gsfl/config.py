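"""Model configuration.

Defaults are the best-performing configuration reported for the BACE-1
classification task: batch size 32, learning rate 1e-4, 3 layers for
both the graph and sequence networks, hidden widths 64 (graph) and 128
(sequence), dropout 0.5.  The contrastive-loss weight α and temperature
T, the fusion width, and the feature-attention reduction ratio are this
package's own defaults (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


@dataclass
class ModelConfig:
    batch_size: int = 32
    learning_rate: float = 1e-4
    gnn_layers: int = 3
    seq_layers: int = 3
    gnn_hidden: int = 64
    seq_hidden: int = 128
    dropout: float = 0.5
    alpha: float = 0.1
    temperature: float = 0.5
    contrastive_variant: str = "as_printed"
    fusion_dim: int = 128
    reduction_ratio: int = 4
    transformer_heads: int = 4
    max_len: int = 128
    epochs: int = 300
    patience: int = 20
    seed: int = 0
    fg_min_count: int = 1
    # ablation switches
    use_fa: bool = True
    use_ha: bool = True
    use_fg_splitting: bool = True
    use_sequence_branch: bool = True

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be non-negative")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0,1)")
        if self.gnn_hidden % self.reduction_ratio and self.use_fa:
            raise ValueError("reduction_ratio must divide gnn_hidden")
        if (2 * self.seq_hidden) % self.transformer_heads:
            raise ValueError("transformer_heads must divide 2*seq_hidden")

    def replace(self, **kw) -> "ModelConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in names})

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def smoke_config(seed: int = 0) -> ModelConfig:
    """Scaled-down configuration for CPU-bound fixture runs: same
    architecture, smaller widths/depths and no dropout so a small
    noise-free dataset can be memorized quickly."""
    return ModelConfig(
        batch_size=16,
        learning_rate=1e-3,
        gnn_layers=2,
        seq_layers=1,
        gnn_hidden=32,
        seq_hidden=32,
        dropout=0.0,
        fusion_dim=64,
        max_len=64,
        epochs=200,
        patience=200,
        seed=seed,
    )
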