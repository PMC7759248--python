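"""Pipeline configuration.

All study constants live here: the 21-hour valid-day rule, the 70 %
valid-day requirement per aggregate interval, the 7–120-day interval and
leeway grids, the minimum of 10 aligned observations, and the 0.5 / 0.8
correlation-strength thresholds used by the pattern metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

#: Interval durations (days) over which daily wearable data are aggregated.
DEFAULT_DURATIONS: tuple[int, ...] = (7, 14, 21, 28, 60, 90, 120)

#: Allowed gaps (days) between an interval's end and the questionnaire
#: administration date.
DEFAULT_LEEWAYS: tuple[int, ...] = (0, 7, 14, 21, 28, 60, 90, 120)

HEALTH_GROUPS: tuple[str, ...] = ("all", "healthy", "diseased")


@dataclass
class PipelineConfig:
    """Tunable constants of the co-calibration pipeline."""

    min_wear_hours: float = 21.0
    min_valid_fraction: float = 0.7
    interval_durations: tuple[int, ...] = DEFAULT_DURATIONS
    leeways: tuple[int, ...] = DEFAULT_LEEWAYS
    min_observations: int = 10
    total_threshold: float = 0.5
    strong_threshold: float = 0.8
    alpha: float = 0.05
    zero_replacement_minutes: float = 1.0
    health_groups: tuple[str, ...] = HEALTH_GROUPS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_valid_fraction <= 1:
            raise ValueError("min_valid_fraction must be in (0, 1]")
        for name in ("total_threshold", "strong_threshold", "alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        for name in ("min_observations",):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be at least 2")
        if self.min_wear_hours < 0 or self.zero_replacement_minutes <= 0:
            raise ValueError("wear threshold must be >= 0 and zero replacement > 0")
        self.interval_durations = tuple(sorted(int(d) for d in self.interval_durations))
        self.leeways = tuple(sorted(int(l) for l in self.leeways))
        unknown = set(self.health_groups) - set(HEALTH_GROUPS)
        if unknown:
            raise ValueError(f"unknown health groups: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("interval_durations", "leeways", "health_groups"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {
            f.name: (list(v) if isinstance(v := getattr(self, f.name), tuple) else v)
            for f in fields(self)
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
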