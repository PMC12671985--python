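"""Pipeline configuration.

Every default echoes a constant of the study design: the 70 % / 5 µg/m³
A/B agreement rule, the 1 µg/m³ → 1/√2 floor, the whole-day 80/20
chronological split, 576-hour expanding CV windows, the March–May /
September–November wet season, and the UTC+3 local clock used for all
hourly aggregation (the study region has no DST).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .errors import ConfigError
from .types import FLOOR_SUBSTITUTE

WET_MONTHS_DEFAULT = (3, 4, 5, 9, 10, 11)


@dataclass
class PipelineConfig:
    # QC
    pct_threshold: float = 70.0          # % A/B deviation
    abs_threshold: float = 5.0           # µg/m³ A/B deviation
    min_completeness: float = 0.75       # fraction of 2-min intervals per hour
    floor: float = 1.0                   # µg/m³
    substitute: float = FLOOR_SUBSTITUTE

    # calibration
    train_fraction: float = 0.8
    cv_initial: int = 576                # hours
    cv_horizon: int = 576
    cv_step: int = 576
    residual_k_sd: float = 2.0
    final_model: str = "lin3"
    models: tuple[str, ...] = (
        "lin1", "lin2", "lin3", "lin4", "lin5", "lin6",
        "lin7", "lin8", "lin9", "lin10", "lin11", "barkjohn",
    )

    # trends
    wet_months: tuple[int, ...] = WET_MONTHS_DEFAULT
    idw_power: float = 2.0

    # simulation scale
    n_days: int = 387                    # Oct 2022 – Nov 2023 deployment span
    start: str = "2022-10-27 00:00"
    n_rural: int = 18
    n_masaka: int = 4
    n_kampala: int = 5

    # misc
    utc_offset_hours: int = 3            # informational; timestamps are local-naive
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pct_threshold <= 0 or self.abs_threshold <= 0:
            raise ConfigError("A/B agreement thresholds must be positive")
        if not 0.0 <= self.min_completeness <= 1.0:
            raise ConfigError("min_completeness must be in [0, 1]")
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigError("train_fraction must be in (0, 1)")
        if self.floor <= 0 or self.substitute >= self.floor:
            raise ConfigError("need 0 < substitute < floor")
        wet = set(self.wet_months)
        if not wet < set(range(1, 13)) or len(wet) != len(self.wet_months):
            raise ConfigError("wet_months must be distinct months in 1..12")
        if self.idw_power <= 0:
            raise ConfigError("idw_power must be positive")
        if min(self.cv_initial, self.cv_horizon, self.cv_step) <= 0:
            raise ConfigError("CV window sizes must be positive")

    @property
    def dry_months(self) -> tuple[int, ...]:
        return tuple(m for m in range(1, 13) if m not in set(self.wet_months))

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["wet_months"] = list(self.wet_months)
        d["models"] = list(self.models)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("wet_months", "models"):
            if key in d:
                d[key] = tuple(d[key])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
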