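"""Evaporation-corrected ablated-mass estimation and derived mass arithmetic.

During a thermal (laser) nuclectomy the removed mass cannot be collected and
weighed; instead the specimen is weighed every minute for ten minutes before
and after the procedure.  Mass drifts linearly as surface water evaporates,
so a straight line is fitted to each window, both lines are extrapolated to
the procedure start (t1) and end (t2), and the ablated mass is the average
of the two line gaps: ``(Delta(t1) + Delta(t2)) / 2`` with
``Delta(t) = line_pre(t) - line_post(t)``.  For parallel fitted lines the
two gaps coincide; averaging makes both anchor times matter when the
evaporation rates differ slightly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .containers import MassTimeSeries


@dataclass
class EvaporationFit:
    slope: float  # g/min
    intercept: float  # g
    r2: float
    window: tuple[float, float]  # min
    n: int

    def predict(self, t: float) -> float:
        return self.intercept + self.slope * t


def fit_evaporation_line(series: MassTimeSeries, phase: str) -> EvaporationFit:
    """OLS line of mass vs time over one labeled phase window.

    ``phase`` is ``'pre'`` or ``'post'``; intra-procedure samples are never
    fitted — they are logged observations taken while mass is stepping down.
    """
    if phase not in ("pre", "post"):
        raise ValueError("phase must be 'pre' or 'post'")
    t, m = series.in_phase(phase)
    if t.size < 3:
        raise ValueError(f"need at least 3 samples in phase {phase!r}, got {t.size}")
    res = stats.linregress(t, m)
    r2 = float(res.rvalue**2) if not math.isnan(res.rvalue) else 1.0
    return EvaporationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=r2,
        window=(float(t.min()), float(t.max())),
        n=int(t.size),
    )


@dataclass
class AblatedMassEstimate:
    pre: EvaporationFit
    post: EvaporationFit
    t1: float
    t2: float
    delta_t1: float  # g
    delta_t2: float  # g

    @property
    def estimate_g(self) -> float:
        return 0.5 * (self.delta_t1 + self.delta_t2)

    @property
    def negative_flag(self) -> bool:
        """True when the estimate is negative (flagged, never clamped)."""
        return self.estimate_g < 0


def ablated_mass(
    pre: EvaporationFit,
    post: EvaporationFit,
    t1: float,
    t2: float,
) -> AblatedMassEstimate:
    """Two-line evaporation-corrected mass estimate between t1 and t2."""
    if not t1 < t2:
        raise ValueError(f"need t1 < t2, got t1={t1}, t2={t2}")
    d1 = pre.predict(t1) - post.predict(t1)
    d2 = pre.predict(t2) - post.predict(t2)
    return AblatedMassEstimate(
        pre=pre, post=post, t1=float(t1), t2=float(t2), delta_t1=d1, delta_t2=d2
    )


def estimate_ablated_mass(
    series: MassTimeSeries,
    t1: float | None = None,
    t2: float | None = None,
) -> AblatedMassEstimate:
    """Fit both windows of a mass series and estimate the ablated mass.

    Unless overridden, t1 is the last pre-phase sample time and t2 the
    first post-phase sample time.
    """
    pre = fit_evaporation_line(series, "pre")
    post = fit_evaporation_line(series, "post")
    if t1 is None:
        t1 = float(series.in_phase("pre")[0].max())
    if t2 is None:
        t2 = float(series.in_phase("post")[0].min())
    return ablated_mass(pre, post, t1, t2)


def dry_mass(wet_g: float, water_fraction: float = 0.70) -> float:
    """Dry mass from a hydrated mass given the tissue water fraction."""
    if not 0 <= water_fraction < 1:
        raise ValueError(f"water fraction must be in [0, 1), got {water_fraction}")
    return wet_g * (1.0 - water_fraction)


def brinckman_height_loss(wet_mass_g: float, coefficient: float = 0.8) -> float:
    """Predicted unloaded disc-height loss (mm) per hydrated gram removed."""
    if wet_mass_g < 0:
        raise ValueError(f"mass must be >= 0, got {wet_mass_g}")
    return coefficient * wet_mass_g


def cylinder_track_volume(length_mm: float, width_mm: float) -> float:
    """Volume of an idealized cylindrical ablation track, mm^3."""
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError("track dimensions must be positive")
    return math.pi * (width_mm / 2.0) ** 2 * length_mm
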