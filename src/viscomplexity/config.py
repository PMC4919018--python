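"""Run configuration: every knob of the feature extractors and the fitter.

A :class:`RunConfig` bundles the feature settings, the PSO/logistic options
and the base seed.  Commands resolve their configuration from an optional
YAML file plus command-line overrides and write the resolved config next to
their outputs, so any run can be reproduced from its artifacts alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .features import FeatureConfig
from .model import PsoConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    features: FeatureConfig = field(default_factory=FeatureConfig)
    pso: PsoConfig = field(default_factory=PsoConfig)
    outlier_half_width_sd: float = 2.0
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "features": self.features.to_dict(),
            "pso": self.pso.to_dict(),
            "outlier_half_width_sd": self.outlier_half_width_sd,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            features=FeatureConfig.from_dict(d.get("features", {})),
            pso=PsoConfig.from_dict(d.get("pso", {})),
            outlier_half_width_sd=d.get("outlier_half_width_sd", 2.0),
            seed=d.get("seed", 0),
        )

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
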