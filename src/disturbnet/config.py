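"""Pipeline run configuration: every named threshold with its default.

Defaults follow the study design this pipeline implements: significance
level 0.05, high-abundance cutoff 1%, low-abundance band 0.1–1%, ensemble
of 1,000 replicates at a 90% member subsample, sign-consensus proportion
0.9, and retention of the strongest 10% of reliable pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    # classification
    alpha: float = 0.05
    ha_threshold: float = 0.01
    la_threshold: float = 0.001
    ncore_min_presence: int = 3
    # ensemble network inference
    n_replicates: int = 1000
    subsample_fraction: float = 0.9
    p0: float = 0.9
    mode: str = "threshold"
    consensus_alpha: float = 0.05
    top_frac: float = 0.1
    ridge: float = 1e-3
    pseudocount: float = 1e-6
    renormalize: bool = False
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        checks = [
            (0 < self.alpha < 1, "alpha must lie in (0, 1)"),
            (0 < self.consensus_alpha < 1, "consensus_alpha must lie in (0, 1)"),
            (
                0 < self.la_threshold <= self.ha_threshold < 1,
                "need 0 < la_threshold <= ha_threshold < 1",
            ),
            (self.n_replicates >= 1, "n_replicates must be >= 1"),
            (
                0 < self.subsample_fraction <= 1,
                "subsample_fraction must lie in (0, 1]",
            ),
            (0 < self.p0 < 1, "p0 must lie in (0, 1)"),
            (self.mode in ("threshold", "test"), "mode must be 'threshold' or 'test'"),
            (0 < self.top_frac <= 1, "top_frac must lie in (0, 1]"),
            (self.ridge >= 0, "ridge must be >= 0"),
            (self.pseudocount >= 0, "pseudocount must be >= 0"),
            (self.ncore_min_presence >= 0, "ncore_min_presence must be >= 0"),
        ]
        for ok, message in checks:
            if not ok:
                raise ValueError(f"invalid configuration: {message}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)


def load_config(path: str | Path | None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML/JSON config file and apply explicit overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    for key, value in (overrides or {}).items():
        if value is not None:
            data[key] = value
    return RunConfig.from_dict(data)
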