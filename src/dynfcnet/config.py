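"""Run configuration: one flat, validated document driving the whole pipeline.

Every stage default lives here; a YAML/JSON file (or CLI overrides) may set
any subset. Unknown keys are rejected rather than ignored so a typo cannot
silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

from .model import ModelConfig, TrainConfig

__all__ = ["RunConfig"]

_SIMULATE_KEYS = {
    "n_regions",
    "n_timepoints",
    "n_per_group",
    "effect_edges",
    "effect_size",
    "n_states",
    "switch_prob",
    "noise_sd",
}


@dataclass
class RunConfig:
    seed: int = 0

    # windowing
    window_length: int = 30
    window_step: int = 2
    drop_volumes: int = 0  # initial volumes to discard (magnetisation equilibrium)

    # connectivity
    fc_order: str = "low"  # "low" | "high"
    high_order_centered: bool = False

    # edge selection
    p_threshold: float = 0.05
    welch: bool = False
    per_window_stack: bool = False

    # graph features
    negative_policy: str = "abs"  # "abs" | "clip_zero"
    eq3_literal: bool = False

    # architecture
    gcn_widths: tuple = (1, 16, 1)
    lstm_hidden: int = 64
    lstm_layers: int = 3
    share_gcn_weights: bool = True

    # optimization
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 400
    l2_weight: float = 5e-4
    dropout_rate: float = 0.5
    patience: int = 40
    split: tuple = (0.7, 0.15, 0.15)

    # paths / data
    manifest: str | None = None
    partition: str | None = None
    output_dir: str = "runs"
    simulate: dict | None = None  # SimSpec fields; used when no manifest
    ablate: bool = False

    def __post_init__(self) -> None:
        if self.fc_order not in ("low", "high"):
            raise ValueError(f"fc_order must be 'low' or 'high', got {self.fc_order!r}")
        if self.negative_policy not in ("abs", "clip_zero"):
            raise ValueError("negative_policy must be 'abs' or 'clip_zero'")
        self.gcn_widths = tuple(self.gcn_widths)
        self.split = tuple(self.split)
        if self.simulate is not None:
            unknown = set(self.simulate) - _SIMULATE_KEYS
            if unknown:
                raise ValueError(f"unknown simulate keys: {sorted(unknown)}")
        # delegate numeric validation
        self.train_config()
        if self.manifest is None and self.simulate is None:
            raise ValueError("config needs either a manifest path or a simulate block")

    # ------------------------------------------------------------------
    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(doc)

    def to_dict(self) -> dict:
        doc = asdict(self)
        doc["gcn_widths"] = list(self.gcn_widths)
        doc["split"] = list(self.split)
        return doc

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    # ------------------------------------------------------------------
    def train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            epochs=self.epochs,
            l2_weight=self.l2_weight,
            dropout_rate=self.dropout_rate,
            patience=self.patience,
            seed=self.seed,
            split=self.split,
        )

    def model_config(self, n_regions: int, n_windows: int = 0) -> ModelConfig:
        return ModelConfig(
            n_regions=n_regions,
            gcn_widths=self.gcn_widths,
            lstm_hidden=self.lstm_hidden,
            lstm_layers=self.lstm_layers,
            share_gcn_weights=self.share_gcn_weights,
            n_windows=n_windows,
        )
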