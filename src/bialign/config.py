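"""Flat run configuration: YAML file with command-line overrides (flags win).

Every default equals the method's published setting where one exists
(alpha = beta = 1e4, tau = 0.5, learning rate 1e-4, weight decay 5e-5,
batch size 256, up to 1000 epochs).  Unknown keys are rejected so typos
never silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .model import LossWeights, TrainConfig


@dataclass
class RunConfig:
    # pairing
    k_mnn: int | None = None
    # preprocessing
    n_hvg: int = 2000
    clip: float = 10.0
    q: int = 100
    # loss weights
    alpha: float = 1e4
    beta: float = 1e4
    gamma_a: float = 1.0
    gamma_b: float = 1.0
    tau_c: float = 0.5
    tau_f: float = 0.5
    # training
    latent_dim: int = 50
    hidden_widths: tuple[int, int] = (512, 256)
    batch_size_cells: int = 256
    batch_size_features: int = 256
    learning_rate: float = 1e-4
    weight_decay: float = 5e-5
    max_epochs: int = 1000
    early_stop_patience: int = 30
    decoder: str = "bilinear_softplus"
    # metrics
    k_gc: int = 15
    k_sas: int = 10
    k_map: int = 30
    k_lta: int = 5
    # global
    seed: int = 0

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "RunConfig":
        values: dict = {}
        if path is not None:
            loaded = yaml.safe_load(Path(path).read_text()) or {}
            values.update(loaded)
        values.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        if "hidden_widths" in values:
            values["hidden_widths"] = tuple(values["hidden_widths"])
        return cls(**values)

    def loss_weights(self) -> LossWeights:
        return LossWeights(alpha=self.alpha, beta=self.beta, gamma_a=self.gamma_a,
                           gamma_b=self.gamma_b, tau_c=self.tau_c, tau_f=self.tau_f)

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            latent_dim=self.latent_dim, hidden_widths=tuple(self.hidden_widths),
            batch_size_cells=self.batch_size_cells, batch_size_features=self.batch_size_features,
            learning_rate=self.learning_rate, weight_decay=self.weight_decay,
            max_epochs=self.max_epochs, early_stop_patience=self.early_stop_patience,
            decoder=self.decoder, seed=self.seed,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden_widths"] = list(d["hidden_widths"])
        return d
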