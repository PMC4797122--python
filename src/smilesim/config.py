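"""Run configuration: a flat YAML-backed record of every knob.

One config may drive every CLI subcommand; command-line flags override
config-file values.  Every defaulted field is emitted explicitly when
the resolved configuration is written back out, so run metadata always
shows the exact parameters used.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .gip import GipConfig


@dataclass
class RunConfig:
    """All parameters of a similarity / prediction / evaluation run."""

    # kernel
    kernel: str = "lingosim"
    q: int = 4
    clcs_weights: tuple[float, float, float] = (0.33, 0.33, 0.33)
    alphabet: str = "smifp34"
    min_len: int = 2
    normalize: bool = True
    composite_lambda: float = 0.5
    # predictor
    gamma_scale: float = 1.0
    alpha: float = 0.5
    sigma: float = 1.0
    wnn_decay: float = 0.7
    wnn_enabled: bool = True
    # evaluation
    n_folds: int = 5
    n_repeats: int = 5
    seed: int = 0
    # I/O
    drugs: str | None = None
    adjacency: str | None = None
    target_sim: str | None = None
    composite_matrix: str | None = None
    out: str | None = None

    def gip_config(self) -> GipConfig:
        return GipConfig(
            gamma_scale=self.gamma_scale,
            alpha=self.alpha,
            sigma=self.sigma,
            wnn_decay=self.wnn_decay,
            wnn_enabled=self.wnn_enabled,
        )

    def kernel_params(self) -> dict:
        """Parameters relevant to the selected kernel."""
        if self.kernel == "clcs":
            w1, w2, w3 = self.clcs_weights
            return {"w1": w1, "w2": w2, "w3": w3}
        if self.kernel == "substring":
            return {"min_len": self.min_len, "normalize": self.normalize}
        if self.kernel in ("lingosim", "tf-cosine", "tfidf-cosine"):
            return {"q": self.q}
        if self.kernel.startswith("smifp"):
            return {"alphabet": self.alphabet}
        return {}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["clcs_weights"] = list(self.clcs_weights)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "clcs_weights" in data:
            data = {**data, "clcs_weights": tuple(data["clcs_weights"])}
        return cls(**data)

    def merged(self, **overrides) -> "RunConfig":
        """New config with non-None overrides applied (CLI precedence)."""
        data = self.to_dict()
        for key, value in overrides.items():
            if value is not None:
                data[key] = value
        return RunConfig.from_dict(data)
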