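"""Run configuration: feature subset, binning, acceptable-level policy,
threshold, splitting and seeding for a fit/evaluate run."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


@dataclass
class RunConfig:
    features: list[str] | None = None  # None = all catalog features in order
    bin_overrides: dict[str, dict] = field(default_factory=dict)
    # acceptable-level policy: "table" (explicit per-feature values) or
    # "mean_sd" (positive-class mean +/- k*SD, far side of the pooled mean)
    acceptable_policy: str = "mean_sd"
    acceptable_table: dict[str, float] = field(default_factory=dict)
    acceptable_k: float = 1.0
    threshold_frac: float = 0.05
    threshold_direction: str = "below"
    split_fraction: float = 0.8
    folds: int = 5
    seed: int = 0
    standardize: bool = False
    drop_incomplete: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_frac < 1.0:
            raise ValueError("threshold_frac must be in (0, 1)")
        if self.threshold_direction not in ("below", "above"):
            raise ValueError("threshold_direction must be 'below' or 'above'")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.acceptable_policy not in ("table", "mean_sd"):
            raise ValueError("acceptable_policy must be 'table' or 'mean_sd'")
        if self.acceptable_policy == "table" and not self.acceptable_table:
            raise ValueError("table policy requires acceptable_table entries")
        if self.acceptable_k <= 0:
            raise ValueError("acceptable_k must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> RunConfig:
    """Load and validate a JSON run configuration.

    Unknown keys are an error (listed by name) rather than silently ignored.
    """
    with open(path) as fh:
        doc = json.load(fh)
    return config_from_dict(doc)


def config_from_dict(doc: dict) -> RunConfig:
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(doc) - known)
    if unknown:
        raise ValueError(f"unknown configuration keys: {unknown}")
    return RunConfig(**doc)
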