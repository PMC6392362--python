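"""Run configuration: a validated, YAML-round-trippable settings record."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Settings for the end-to-end pipeline. Unknown keys are rejected."""

    detections: str = "detections.csv"
    covariates: str = "covariates.csv"
    output_dir: str = "results"
    species: str = "synthetic"
    habitat_covariates: list[str] = field(default_factory=lambda: ["habitat"])
    climate_covariates: list[str] = field(default_factory=lambda: ["heat", "cold"])
    starts: int = 3
    tol: float = 1e-8
    seed: int = 0
    reduce_nuisance: bool = True
    gof_bins: int = 10
    gof_min_expected: float = 4.0
    gof_conditioning: str = "history"  # or "year"
    deviation_timing: str = "origin"  # or "destination"
    theta0_mode: str = "theta"  # or "stationary"

    def __post_init__(self) -> None:
        if self.gof_conditioning not in ("history", "year"):
            raise ValueError("gof_conditioning must be 'history' or 'year'")
        if self.deviation_timing not in ("origin", "destination"):
            raise ValueError("deviation_timing must be 'origin' or 'destination'")
        if self.theta0_mode not in ("theta", "stationary"):
            raise ValueError("theta0_mode must be 'theta' or 'stationary'")
        if self.starts < 1:
            raise ValueError("starts must be >= 1")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
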