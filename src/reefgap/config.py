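"""Run configuration: one YAML document drives the whole pipeline.

Every constant of the method — filter bounds, diel clock times, season
months, swim speeds, the model term set, selection rules, the
cross-validation fraction and seed — is a config key, with defaults
matching the reef-shark analysis the package was designed around.  Column-name maps let VEMCO VUE exports and generic
CSVs load without code changes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .covariates import DEFAULT_DAY_END, DEFAULT_DAY_START, DEFAULT_TZ, DEFAULT_WET_MONTHS
from .glmm import DEFAULT_GLOBAL_TERMS
from .movements import DEFAULT_SWIM_SPEEDS

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # inputs
    detections_path: str = "detections.csv"
    receivers_path: str = "receivers.csv"
    individuals_path: str = "individuals.csv"
    detection_columns: dict = field(default_factory=dict)  # e.g. {"timestamp": "Date and Time (UTC)"}
    receiver_columns: dict = field(default_factory=dict)
    individual_columns: dict = field(default_factory=dict)
    input_tz: str = "UTC"  # zone detection timestamps are recorded in
    local_tz: str = DEFAULT_TZ  # zone for diel/season assignment

    # movement filters
    min_recursion_gap_s: float = 360.0
    rdet_max: float = 5.0
    swim_speeds: dict = field(default_factory=lambda: dict(DEFAULT_SWIM_SPEEDS))

    # covariates
    day_start: int = DEFAULT_DAY_START
    day_end: int = DEFAULT_DAY_END
    wet_months: tuple = DEFAULT_WET_MONTHS
    anchor: str = "start"  # movement instant anchoring diel/season
    receiver_role: str = "dest"  # receiver grouping factor for transitions

    # inference
    global_terms: tuple = DEFAULT_GLOBAL_TERMS
    re_factors: tuple = ("tag_id", "receiver_id")
    weight_threshold: float = 0.9
    averaging: str = "full"
    train_fraction: float = 0.8
    cv_seed: int = 0

    # outputs
    output_dir: str = "out"

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for f in fields(cls):
            v = getattr(cfg, f.name)
            if isinstance(v, list):
                object.__setattr__(cfg, f.name, tuple(v))
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.min_recursion_gap_s <= 0 or self.rdet_max <= 0:
            raise ValueError("filter constants must be positive")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.anchor not in ("start", "end"):
            raise ValueError("anchor must be 'start' or 'end'")
        if self.receiver_role not in ("origin", "dest"):
            raise ValueError("receiver_role must be 'origin' or 'dest'")
        if any(s <= 0 for s in self.swim_speeds.values()):
            raise ValueError("swim speeds must be positive")
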