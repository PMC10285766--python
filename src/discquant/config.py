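"""Run configuration: every protocol constant lives here so it can be overridden.

Defaults reflect the measurement protocol this package implements: circular
localization regions whose *diameters* are 20/40/60/80% of the disc's largest
lateral width, toe (50-200 N) and linear (500-900 N) stiffness windows, a 1%
cycle-to-cycle preconditioning criterion, a 70% nucleus water fraction for
wet-to-dry mass conversion, and the empirical 0.8 mm-per-gram height-loss
coefficient of Brinckmann & Grootenboer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # Localization: fractions of the lateral width W defining the concentric
    # circles; interpreted as circle diameters ("diameter" mode, default) or
    # radii ("radius" mode).
    partition_fractions: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)
    radius_mode: str = "diameter"
    # Stiffness windows in N, half-open [lo, hi).
    toe_window: tuple[float, float] = (50.0, 200.0)
    linear_window: tuple[float, float] = (500.0, 900.0)
    # Preconditioning: max allowed cycle-to-cycle stiffness change, percent.
    precondition_threshold_pct: float = 1.0
    # Mass bookkeeping.
    water_fraction: float = 0.70
    brinckman_mm_per_g: float = 0.8
    # Reproducibility.
    seed: int = 0

    def __post_init__(self) -> None:
        fr = tuple(float(f) for f in self.partition_fractions)
        if any(not 0 < f <= 1 for f in fr) or any(
            b <= a for a, b in zip(fr, fr[1:])
        ):
            raise ValueError(
                f"partition fractions must be strictly increasing in (0, 1], got {fr}"
            )
        self.partition_fractions = fr
        if self.radius_mode not in ("diameter", "radius"):
            raise ValueError(f"radius_mode must be 'diameter' or 'radius', got {self.radius_mode!r}")
        for name in ("toe_window", "linear_window"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must have lower < upper, got ({lo}, {hi})")
            setattr(self, name, (float(lo), float(hi)))
        if self.toe_window[1] > self.linear_window[0]:
            raise ValueError("toe and linear windows must not overlap")
        if not 0 <= self.water_fraction < 1:
            raise ValueError(f"water_fraction must be in [0, 1), got {self.water_fraction}")
        if self.precondition_threshold_pct <= 0:
            raise ValueError("precondition threshold must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["partition_fractions"] = list(self.partition_fractions)
        d["toe_window"] = list(self.toe_window)
        d["linear_window"] = list(self.linear_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
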