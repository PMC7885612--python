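"""Model and pipeline configuration.

Defaults follow the published training setup for this architecture: LSTM
hidden size 256, note length cap 1000 tokens, batch size 5, learning rate
1e-4, early stopping after 20 stalled epochs within a 100-epoch cap, and a
0.9 dropout fraction on the fused vector.  Quantities the setup leaves open
(joint-space dimension, filter count, embedding dimension, similarity window)
carry package defaults documented in docs/methods.md.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

VARIANTS = ("lstm_only", "cn_only", "multi_cn", "multi_atten", "multi_atten_chronic")


@dataclass
class ModelConfig:
    variant: str = "multi_atten_chronic"
    # temporal branch
    n_hours: int = 48           # T: observation window length in hours
    hidden_dim: int = 256       # H: LSTM output dimension
    # text branch
    max_len: int = 1000         # L_max: token cap per patient
    embed_dim: int = 100        # E: word-embedding dimension
    joint_dim: int = 128        # P: joint word/label space dimension
    n_filters: int = 100        # convolutional filter count
    filter_size: int = 5        # conv filter width (2 and 5 perform best)
    sim_window: int = 3         # odd neighborhood width for word-label similarity
    # fused head + optimization
    dropout_rate: float = 0.9   # fraction of fused units dropped in training
    batch_norm: bool = True
    learning_rate: float = 1e-4
    batch_size: int = 5
    max_epochs: int = 100
    early_stop_rounds: int = 20
    # data handling
    window_h: float = 48.0      # observation window for note selection, hours
    truncate_side: str = "head" # keep head (history-first) or tail on overflow
    min_token_count: int = 1    # vocabulary frequency floor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.sim_window % 2 != 1:
            raise ValueError("sim_window must be odd")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate is the fraction dropped, in [0, 1)")
        if self.truncate_side not in ("head", "tail"):
            raise ValueError("truncate_side must be 'head' or 'tail'")

    @property
    def uses_text(self) -> bool:
        return self.variant != "lstm_only"

    @property
    def uses_temporal(self) -> bool:
        return self.variant != "cn_only"

    @property
    def uses_attention(self) -> bool:
        return self.variant in ("multi_atten", "multi_atten_chronic")

    @property
    def chronic_aware(self) -> bool:
        """Only the chronic-aware variant adds pre-window history notes."""
        return self.variant == "multi_atten_chronic"

    @property
    def fused_dim(self) -> int:
        dim = 0
        if self.uses_temporal:
            dim += self.hidden_dim
        if self.uses_text:
            dim += self.n_filters
        return dim

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ModelConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        return cls.from_dict(json.loads(path.read_text()))
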