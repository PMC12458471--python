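"""Run configuration: one serializable object reproduces a run."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class RunConfig:
    """All knobs for a pipeline run; (config, seeds) determine every artifact."""

    species: str = "Synthetheca exemplaris"
    out_dir: str = "runs/default"
    observations_csv: str | None = None
    climate_path: str | None = None
    population_path: str | None = None

    grid_resolution: float = 0.25
    seq_len: int = 30
    absence_ratio: float = 0.2
    split: str = "random"            # random | chronological
    test_fraction: float = 0.2
    k_folds: int = 5

    fnr_threshold: float = 0.5       # burden accounting
    season_mass: float = 0.95        # season diameter mass
    exclusion_days: int = 10         # midpoint exclusion window around Jan 1

    hidden: tuple[int, ...] = (128, 64, 32)
    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 1000
    patience_cv: int = 10
    patience_final: int = 100
    val_fraction: float = 0.1        # final-model early-stopping monitor

    seed: int = 0

    # synthetic-world overrides (synthetic stages only)
    world: dict = field(default_factory=dict)
    n_presences: int = 2000

    def __post_init__(self) -> None:
        if self.split not in ("random", "chronological"):
            raise ConfigurationError(f"unknown split type {self.split!r}")
        if not (0 < self.absence_ratio <= 1):
            raise ConfigurationError("absence_ratio must be in (0, 1]")
        self.hidden = tuple(self.hidden)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def hash(self) -> str:
        """Stable digest of the full configuration (provenance tag)."""
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
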