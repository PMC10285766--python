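"""Cycle segmentation and toe/linear stiffness extraction from load curves.

Stiffness is the ordinary-least-squares slope of force against displacement
over the samples of a cycle's loading half whose force lies in a half-open
window [F_lo, F_hi): 50-200 N for the toe region, 500-900 N for the linear
region by default.  OLS equals the secant on affine data and is
noise-robust on sampled nonlinear data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import LoadCycleSeries


@dataclass
class CycleSegment:
    start: int  # inclusive index of the cycle (displacement minimum)
    peak: int  # index of maximum displacement: loading = [start, peak]
    end: int  # exclusive index

    @property
    def loading(self) -> slice:
        return slice(self.start, self.peak + 1)

    @property
    def unloading(self) -> slice:
        return slice(self.peak, self.end)


def _moving_average(x: np.ndarray, w: int = 5) -> np.ndarray:
    if x.size < w:
        return x.astype(float)
    pad = w // 2
    xp = np.pad(x.astype(float), pad, mode="edge")
    return np.convolve(xp, np.ones(w) / w, mode="valid")


def segment_cycles(series: LoadCycleSeries) -> list[CycleSegment]:
    """Delimit full compression cycles at displacement minima.

    Minima are detected on a 5-sample moving average of displacement; the
    series start (end) counts as a boundary when it sits near the minimum
    level.  Segments that never rise to at least 80% of the overall
    displacement range (truncated tails) are discarded.
    """
    d = np.asarray(series.displacement, dtype=float)
    if d.size < 8:
        raise ValueError("series too short to contain a full cycle")
    ds = _moving_average(d)
    rng = ds.max() - ds.min()
    if rng <= 0:
        raise ValueError("no oscillation detected (flat displacement)")
    # an oscillation must dominate the high-frequency residual left by the
    # smoother, otherwise the extrema are noise artifacts
    hf = float(np.std(d - ds))
    if rng < 5.0 * hf:
        raise ValueError("no oscillation detected (displacement is noise-dominated)")

    interior = np.flatnonzero(
        (ds[1:-1] <= ds[:-2]) & (ds[1:-1] < ds[2:])
    ) + 1
    # suppress noise minima: must sit in the lower quarter of the range
    interior = interior[ds[interior] < ds.min() + 0.25 * rng]
    # merge plateaus / near-duplicates
    bounds: list[int] = []
    for i in interior:
        if not bounds or i - bounds[-1] > 2:
            bounds.append(int(i))
    tol = 0.1 * rng
    if ds[0] <= ds.min() + tol:
        bounds = [0] + [b for b in bounds if b > 2]
    if ds[-1] <= ds.min() + tol:
        bounds = [b for b in bounds if b < d.size - 3] + [d.size - 1]

    cycles: list[CycleSegment] = []
    for a, b in zip(bounds, bounds[1:]):
        seg = d[a : b + 1]
        if seg.max() < ds.min() + 0.8 * rng:
            continue  # truncated tail or spurious segment
        peak = a + int(np.argmax(seg))
        cycles.append(CycleSegment(start=a, peak=peak, end=b + 1))
    if not cycles:
        raise ValueError("no full compression cycle detected")
    return cycles


@dataclass
class StiffnessResult:
    k_toe: float  # N/mm
    k_lin: float  # N/mm
    cycle_index: int  # 1-based cycle the protocol values come from
    r2_toe: float
    r2_lin: float
    per_cycle_k_toe: np.ndarray
    per_cycle_k_lin: np.ndarray


def stiffness(
    series: LoadCycleSeries,
    cycle: CycleSegment,
    window: tuple[float, float],
) -> tuple[float, float]:
    """OLS slope (N/mm) and r^2 of force vs displacement in a force window.

    Uses the raw samples of the cycle's loading half with force in
    [window[0], window[1]).
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"stiffness window must have lower < upper, got ({lo}, {hi})")
    d = series.displacement[cycle.loading]
    f = series.force[cycle.loading]
    sel = (f >= lo) & (f < hi)
    if np.count_nonzero(sel) < 2:
        raise ValueError(
            f"fewer than 2 samples with force in [{lo}, {hi}) N on the loading half"
        )
    res = stats.linregress(d[sel], f[sel])
    return float(res.slope), float(res.rvalue**2)


def extract_stiffness(
    series: LoadCycleSeries,
    toe_window: tuple[float, float] = (50.0, 200.0),
    linear_window: tuple[float, float] = (500.0, 900.0),
    cycle_index: int | None = None,
) -> StiffnessResult:
    """Per-cycle toe/linear stiffness; protocol values from ``cycle_index``.

    ``cycle_index`` is 1-based and defaults to the last full cycle (the
    fifth under the standard five-cycle protocol).
    """
    cycles = segment_cycles(series)
    if cycle_index is None:
        cycle_index = len(cycles)
    if not 1 <= cycle_index <= len(cycles):
        raise ValueError(
            f"cycle index {cycle_index} outside the {len(cycles)} detected cycles"
        )
    toe, lin, r2t, r2l = [], [], [], []
    for c in cycles:
        kt, rt = stiffness(series, c, toe_window)
        kl, rl = stiffness(series, c, linear_window)
        toe.append(kt)
        lin.append(kl)
        r2t.append(rt)
        r2l.append(rl)
    i = cycle_index - 1
    return StiffnessResult(
        k_toe=toe[i],
        k_lin=lin[i],
        cycle_index=cycle_index,
        r2_toe=r2t[i],
        r2_lin=r2l[i],
        per_cycle_k_toe=np.array(toe),
        per_cycle_k_lin=np.array(lin),
    )


def precondition_check(
    per_cycle_k: np.ndarray, threshold_pct: float = 1.0
) -> dict:
    """Cycle-to-cycle stiffness convergence check.

    ``delta_i = 100 * |k_i - k_{i-1}| / k_{i-1}``; the protocol passes when
    the delta at the final cycle is at or below the threshold.
    """
    k = np.asarray(per_cycle_k, dtype=float)
    if k.size < 2:
        raise ValueError("need at least two cycles to check preconditioning")
    deltas = 100.0 * np.abs(np.diff(k)) / k[:-1]
    return {
        "deltas_pct": deltas,
        "final_delta_pct": float(deltas[-1]),
        "passed": bool(deltas[-1] <= threshold_pct),
        "threshold_pct": float(threshold_pct),
    }


def stiffness_change(intact: StiffnessResult, post: StiffnessResult) -> dict:
    """Percent stiffness reduction post-nuclectomy, per region."""
    if intact.k_toe <= 0 or intact.k_lin <= 0:
        raise ValueError("intact stiffness must be positive")
    return {
        "toe_reduction_pct": 100.0 * (intact.k_toe - post.k_toe) / intact.k_toe,
        "linear_reduction_pct": 100.0 * (intact.k_lin - post.k_lin) / intact.k_lin,
    }


def pressure_to_load(pressure_mpa: float, area_mm2: float) -> float:
    """Convert an intradiscal pressure (MPa) to an axial load (N)."""
    if pressure_mpa <= 0 or area_mm2 <= 0:
        raise ValueError("pressure and area must be positive")
    return pressure_mpa * area_mm2
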