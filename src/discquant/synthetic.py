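"""Synthetic phantoms and measurement series with known ground truth.

Every downstream estimator in this package is validated against data from
this module: elliptical-cylinder disc phantoms with technique-specific
cavities (central homogeneous for the automated shaver, multi-lobed with
annulus contact for rongeurs, a thin capsule track for the laser),
nonlinearly stiffening cyclic compression curves whose cycle-to-cycle
stiffness change falls below 1% by the fifth cycle, and mass-time series
with a linear evaporation drift and a step removal during the procedure
window.  Generators are deterministic under a seed and return (or record)
the ground-truth quantities that the estimators are expected to recover.

The loading law is ``F(d) = alpha * (exp(beta * d) - 1)``: a one-parameter-
per-scale monotone stiffening curve, the standard soft-tissue toe-region
idealization, whose window-secant stiffness is available in closed form.
Cycle-to-cycle preconditioning drift multiplies ``alpha`` by
``1 + gamma * exp(-i / tau)`` so that stiffness itself (not merely an
offset) changes across cycles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .containers import (
    AF,
    BACKGROUND,
    CAVITY,
    NP,
    TECHNIQUES,
    VERTEBRA,
    LabelVolume,
    LoadCycleSeries,
    MassTimeSeries,
    SpecimenRecord,
)

# --------------------------------------------------------------------------
# Phantom geometry
# --------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Elliptical-cylinder disc phantom between two vertebral slabs.

    ``a``/``b`` are the lateral and anterior-posterior half-widths of the
    outer (annulus) ellipse in mm, ``h`` the disc height in mm.  The nucleus
    is a concentric ellipse scaled by ``np_fraction``.  An optional posterior
    concavity carves a circular dimple into the posterior margin, producing
    the bean-like outline of real lumbar discs.
    """

    a: float = 27.0
    b: float = 20.0
    h: float = 10.0
    np_fraction: float = 0.6
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    concavity_depth: float = 0.0
    concavity_radius: float | None = None
    concavity_offset: float = 0.0  # lateral offset of the dimple center, mm
    vertebra_thickness: float = 4.0
    margin_voxels: int = 2

    def __post_init__(self) -> None:
        if not self.a >= self.b > 0:
            raise ValueError(f"need a >= b > 0, got a={self.a}, b={self.b}")
        if self.h <= 0:
            raise ValueError(f"disc height must be positive, got {self.h}")
        if not 0 < self.np_fraction < 1:
            raise ValueError("np_fraction must be in (0, 1): NP strictly inside AF")
        if self.concavity_depth < 0 or self.concavity_depth >= self.b:
            if self.concavity_depth != 0:
                raise ValueError("concavity depth must be in [0, b)")


def gen_disc_volume(spec: PhantomSpec, seed: int = 0) -> LabelVolume:
    """Rasterize a disc phantom onto a label grid.

    Voxels are classified by their center position: nucleus ellipse -> NP,
    outer ellipse -> AF, vertebral slabs above and below the disc (same
    elliptical footprint) -> vertebra.  Deterministic; ``seed`` is accepted
    for interface symmetry with the stochastic generators.
    """
    dx, dy, dz = spec.spacing
    na, nb = spec.np_fraction * spec.a, spec.np_fraction * spec.b
    if min(2 * na / dx, 2 * nb / dy, spec.h / dz) < 3:
        raise ValueError(
            "spacing too coarse to resolve the nucleus (thinner than 3 voxels)"
        )
    m = spec.margin_voxels
    nx = int(math.ceil(2 * spec.a / dx)) + 2 * m + 1
    ny = int(math.ceil(2 * spec.b / dy)) + 2 * m + 1
    nz = int(math.ceil((spec.h + 2 * spec.vertebra_thickness) / dz)) + 2 * m + 1
    cx, cy = (nx - 1) / 2 * dx, (ny - 1) / 2 * dy
    cz = (nz - 1) / 2 * dz

    x = np.arange(nx) * dx - cx
    y = np.arange(ny) * dy - cy
    z = np.arange(nz) * dz - cz
    X, Y = np.meshgrid(x, y, indexing="ij")

    outer = (X / spec.a) ** 2 + (Y / spec.b) ** 2 <= 1.0
    if spec.concavity_depth > 0:
        rc = (
            spec.concavity_radius
            if spec.concavity_radius is not None
            else 2.5 * spec.concavity_depth
        )
        # circle reaching depth `concavity_depth` into the posterior margin,
        # optionally off the midline to produce an asymmetric (tilted) bean
        yc = -spec.b - rc + spec.concavity_depth
        outer &= (X - spec.concavity_offset) ** 2 + (Y - yc) ** 2 > rc**2
    inner = (X / na) ** 2 + (Y / nb) ** 2 <= 1.0

    voxels = np.zeros((nx, ny, nz), dtype=np.int16)
    # half-open slab (-h/2, h/2]: a slab of thickness h covers h/dz voxel
    # centers when the grid aligns, avoiding a one-slice overcount
    in_disc_z = (z > -spec.h / 2) & (z <= spec.h / 2)
    lo_vert = (z <= -spec.h / 2) & (z > -spec.h / 2 - spec.vertebra_thickness)
    hi_vert = (z > spec.h / 2) & (z <= spec.h / 2 + spec.vertebra_thickness)
    voxels[outer[:, :, None] & in_disc_z[None, None, :]] = AF
    voxels[(outer & inner)[:, :, None] & in_disc_z[None, None, :]] = NP
    voxels[outer[:, :, None] & (lo_vert | hi_vert)[None, None, :]] = VERTEBRA
    return LabelVolume(voxels=voxels, spacing=spec.spacing)


# --------------------------------------------------------------------------
# Cavity carving
# --------------------------------------------------------------------------

ENTRY_QUADRANTS = (
    "posterior-left",
    "posterior-right",
    "anterior-left",
    "anterior-right",
)


@dataclass
class CavitySpec:
    """Technique-specific removed-tissue cavity.

    * ``shaver``: one compact homogeneous blob of ``target_volume_mm3``
      grown outward from the cavity center using nucleus voxels only.
    * ``rongeurs``: ``lobes`` separate blobs sharing the target volume; the
      entry-side lobe sits at the nucleus margin and may relabel annulus
      voxels (collateral damage).
    * ``laser``: a capsule (cylinder with hemispherical caps) of the track
      dimensions, entering from ``entry_quadrant`` toward the center; if
      ``target_volume_mm3`` is given the track width is rescaled so the
      capsule encloses that volume (emulating cavity shrinkage by internal
      tissue redistribution), otherwise the default track dimensions apply.
    """

    technique: str = "shaver"
    target_volume_mm3: float | None = 350.0
    center_offset_frac: tuple[float, float] = (0.0, 0.0)
    lobes: int = 3
    tract_length_mm: float = 14.5
    tract_width_mm: float = 2.75
    entry_quadrant: str = "posterior-left"

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise ValueError(f"technique must be one of {TECHNIQUES}")
        if self.entry_quadrant not in ENTRY_QUADRANTS:
            raise ValueError(f"entry quadrant must be one of {ENTRY_QUADRANTS}")
        if self.technique != "laser" and (
            self.target_volume_mm3 is None or self.target_volume_mm3 <= 0
        ):
            raise ValueError("shaver/rongeurs cavities need a positive target volume")
        if self.tract_length_mm <= 0 or self.tract_width_mm <= 0:
            raise ValueError("tract dimensions must be positive")
        if self.lobes < 1:
            raise ValueError("lobe count must be >= 1")


def _entry_direction(entry_quadrant: str) -> np.ndarray:
    sx = -1.0 if entry_quadrant.endswith("left") else 1.0
    sy = -1.0 if entry_quadrant.startswith("posterior") else 1.0
    return np.array([sx, sy]) / math.sqrt(2.0)


def capsule_volume(length: float, width: float) -> float:
    """Volume of a capsule with total length ``length`` and diameter ``width``."""
    r = width / 2.0
    if length < width:
        raise ValueError("capsule length must be at least its width")
    return math.pi * r**2 * (length - width) + 4.0 / 3.0 * math.pi * r**3


def _capsule_width_for_volume(length: float, volume: float) -> float:
    lo, hi = 1e-6, length
    if not capsule_volume(length, lo) < volume < capsule_volume(length, hi):
        raise ValueError(
            f"no capsule of length {length} mm encloses {volume} mm^3"
        )
    return brentq(lambda w: capsule_volume(length, w) - volume, lo, hi)


def _grow_blob(
    dist: np.ndarray, eligible: np.ndarray, n_vox: int, taken: np.ndarray
) -> np.ndarray:
    """Select the ``n_vox`` eligible, untaken voxels closest to a seed point."""
    cand = np.flatnonzero(eligible & ~taken)
    if cand.size < n_vox:
        raise ValueError(
            f"target volume unreachable: {n_vox} voxels requested, "
            f"{cand.size} eligible"
        )
    order = np.lexsort((cand, dist.ravel()[cand]))
    return cand[order[:n_vox]]


def carve_cavity(
    volume: LabelVolume, cavity: CavitySpec, seed: int = 0
) -> LabelVolume:
    """Relabel voxels of a disc phantom to the cavity label.

    Returns a new volume; the input is not modified.  For the shaver and
    rongeurs presets the achieved cavity volume matches the target to within
    voxel rounding (well inside 5%).
    """
    rng = np.random.default_rng(seed)
    dx, dy, dz = volume.spacing
    voxvol = volume.voxel_volume
    vox = volume.voxels.copy()

    disc = volume.disc_mask()
    if not disc.any():
        raise ValueError("volume contains no disc voxels")
    idx = np.argwhere(disc)
    center_vox = idx.mean(axis=0)
    center = center_vox * np.array([dx, dy, dz])
    xs = idx[:, 0] * dx
    lateral_width = xs.max() - xs.min()

    ox, oy = cavity.center_offset_frac
    cpt = center + np.array([ox * lateral_width, oy * lateral_width, 0.0])

    nx, ny, nz = vox.shape
    X = (np.arange(nx) * dx)[:, None, None]
    Y = (np.arange(ny) * dy)[None, :, None]
    Z = (np.arange(nz) * dz)[None, None, :]

    def aniso_dist(pt: np.ndarray, z_stretch: float = 2.0) -> np.ndarray:
        # z stretched: cavities spread in-plane more than axially
        return np.sqrt(
            (X - pt[0]) ** 2 + (Y - pt[1]) ** 2 + (z_stretch * (Z - pt[2])) ** 2
        )

    taken = np.zeros(vox.size, dtype=bool)

    if cavity.technique == "shaver":
        n_vox = int(round(cavity.target_volume_mm3 / voxvol))
        sel = _grow_blob(aniso_dist(cpt), (vox == NP).ravel(), n_vox, taken)
        vox.ravel()[sel] = CAVITY

    elif cavity.technique == "rongeurs":
        n_total = int(round(cavity.target_volume_mm3 / voxvol))
        per_lobe = np.full(cavity.lobes, n_total // cavity.lobes)
        per_lobe[: n_total % cavity.lobes] += 1
        np_idx = np.argwhere(vox == NP)
        np_extent = (np_idx.max(axis=0) - np_idx.min(axis=0)) * np.array([dx, dy, dz])
        edir = _entry_direction(cavity.entry_quadrant)
        for j in range(cavity.lobes):
            if j == 0:
                # entry-side lobe at the NP margin -> may bite into the AF
                lobe_c = cpt + np.array(
                    [edir[0] * 0.45 * np_extent[0], edir[1] * 0.45 * np_extent[1], 0.0]
                )
                eligible = (vox == NP) | (vox == AF)
            else:
                jitter = rng.uniform(-0.12, 0.12, size=2) * lateral_width
                lobe_c = cpt + np.array([jitter[0], jitter[1], 0.0])
                eligible = vox == NP
            sel = _grow_blob(aniso_dist(lobe_c), eligible.ravel(), per_lobe[j], taken)
            taken[sel] = True
            vox.ravel()[sel] = CAVITY

    else:  # laser
        length = cavity.tract_length_mm
        width = cavity.tract_width_mm
        if cavity.target_volume_mm3 is not None:
            width = _capsule_width_for_volume(length, cavity.target_volume_mm3)
        edir = _entry_direction(cavity.entry_quadrant)
        axis = np.array([-edir[0], -edir[1], 0.0])  # from entry toward far side
        half = (length - width) / 2.0
        p0 = cpt - axis * half
        p1 = cpt + axis * half
        # distance from each voxel center to the segment p0-p1
        P = np.stack(np.broadcast_arrays(X, Y, Z), axis=-1)
        seg = p1 - p0
        t = np.clip(((P - p0) @ seg) / (seg @ seg), 0.0, 1.0)
        closest = p0 + t[..., None] * seg
        d = np.linalg.norm(P - closest, axis=-1)
        sel = (d <= width / 2.0) & disc
        if not sel.any():
            raise ValueError("laser track lies entirely outside the disc")
        vox[sel] = CAVITY

    out = LabelVolume(voxels=vox, spacing=volume.spacing)
    if cavity.technique != "laser":
        achieved = out.label_volume_mm3(CAVITY)
        if abs(achieved - cavity.target_volume_mm3) > 0.05 * cavity.target_volume_mm3:
            raise ValueError(
                f"carved volume {achieved:.1f} mm^3 deviates more than 5% from "
                f"target {cavity.target_volume_mm3:.1f} mm^3"
            )
    return out


# --------------------------------------------------------------------------
# Cyclic compression series
# --------------------------------------------------------------------------


@dataclass
class LoadModelParams:
    """Parameters of the exponential stiffening loading law with drift.

    ``F_i(d) = alpha_i * (exp(beta * d) - 1)`` with
    ``alpha_i = alpha * (1 + gamma * exp(-i / tau))`` on cycle ``i`` (1-based).
    Displacement is driven sinusoidally between the displacements at the low
    and high force setpoints of each cycle's law.  Defaults emulate axial
    compression of a lumbar spinal unit between 50 N and 1 kN at 1 Hz and
    give a cycle-4 to cycle-5 toe-stiffness change well below 1%.  The
    default curvature is gentle (large ``alpha``) so that the windowed-OLS
    stiffness extractor's sampling-measure bias under the sinusoidal dwell
    stays well inside its recovery tolerance; per-specimen cohort curves use
    ``solve_load_params`` to hit realistic toe/linear stiffness pairs with
    stronger curvature.
    """

    alpha: float = 3000.0  # N
    beta: float = 0.2  # 1/mm
    drift_gamma: float = 0.1
    drift_tau: float = 1.0  # cycles
    noise_sd: float = 0.25  # N
    n_cycles: int = 5
    force_range: tuple[float, float] = (50.0, 1000.0)
    frequency_hz: float = 1.0
    sample_rate_hz: float = 100.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.drift_gamma < 0 or self.drift_tau <= 0:
            raise ValueError("gamma must be >= 0 and tau > 0")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        lo, hi = self.force_range
        if not 0 < lo < hi:
            raise ValueError("force range must satisfy 0 < lo < hi")
        if self.n_cycles < 1:
            raise ValueError("need at least one cycle")

    def alpha_at_cycle(self, i: int) -> float:
        return self.alpha * (1.0 + self.drift_gamma * math.exp(-i / self.drift_tau))


def inverse_law_displacement(force: float, alpha: float, beta: float) -> float:
    """Displacement at which the loading law reaches ``force`` (closed form)."""
    return math.log(force / alpha + 1.0) / beta


def secant_stiffness(
    alpha: float, beta: float, window: tuple[float, float]
) -> float:
    """Closed-form window-secant stiffness of the loading law, N/mm."""
    lo, hi = window
    d_lo = inverse_law_displacement(lo, alpha, beta)
    d_hi = inverse_law_displacement(hi, alpha, beta)
    return (hi - lo) / (d_hi - d_lo)


def solve_load_params(
    k_toe: float,
    k_lin: float,
    toe_window: tuple[float, float] = (50.0, 200.0),
    linear_window: tuple[float, float] = (500.0, 900.0),
) -> tuple[float, float]:
    """Invert the loading law: find (alpha, beta) with the given window secants.

    The secant ratio ``k_lin / k_toe`` depends on alpha alone and decreases
    monotonically toward 1 as the curve straightens, which makes the
    inversion a 1D root find followed by a beta rescale.
    """
    target = k_lin / k_toe
    if target <= 1.0:
        raise ValueError("k_lin must exceed k_toe for a stiffening law")

    def ratio(log_alpha: float) -> float:
        a = math.exp(log_alpha)
        return secant_stiffness(a, 1.0, linear_window) / secant_stiffness(
            a, 1.0, toe_window
        )

    lo, hi = math.log(1e-6), math.log(1e9)
    if not ratio(hi) < target < ratio(lo):
        raise ValueError(
            f"secant ratio {target:.3f} outside the attainable range "
            f"({ratio(hi):.3f}, {ratio(lo):.3f})"
        )
    log_alpha = brentq(lambda la: ratio(la) - target, lo, hi, xtol=1e-12)
    alpha = math.exp(log_alpha)
    beta = k_toe / secant_stiffness(alpha, 1.0, toe_window)
    return alpha, beta


def gen_force_displacement(
    params: LoadModelParams,
    seed: int = 0,
    truth_windows: dict[str, tuple[float, float]] | None = None,
) -> tuple[LoadCycleSeries, pd.DataFrame]:
    """Generate a displacement-controlled cyclic compression series.

    Returns the series and a per-cycle ground-truth table with the
    closed-form window-secant stiffnesses of each cycle's law (columns
    ``k_toe`` / ``k_lin`` by default), for recovery tests downstream.
    """
    if truth_windows is None:
        truth_windows = {"k_toe": (50.0, 200.0), "k_lin": (500.0, 900.0)}
    rng = np.random.default_rng(seed)
    spc = int(round(params.sample_rate_hz / params.frequency_hz))
    f_lo, f_hi = params.force_range

    t_all, d_all, f_all = [], [], []
    truth_rows = []
    for i in range(1, params.n_cycles + 1):
        a_i = params.alpha_at_cycle(i)
        d_lo = inverse_law_displacement(f_lo, a_i, params.beta)
        d_hi = inverse_law_displacement(f_hi, a_i, params.beta)
        tloc = np.arange(spc) / params.sample_rate_hz
        d = d_lo + (d_hi - d_lo) * (1.0 - np.cos(2.0 * np.pi * params.frequency_hz * tloc)) / 2.0
        f = a_i * (np.exp(params.beta * d) - 1.0)
        t_all.append(tloc + (i - 1) / params.frequency_hz)
        d_all.append(d)
        f_all.append(f)
        row = {"cycle": i, "alpha": a_i}
        for name, win in truth_windows.items():
            row[name] = secant_stiffness(a_i, params.beta, win)
        truth_rows.append(row)

    force = np.concatenate(f_all)
    if params.noise_sd > 0:
        force = force + rng.normal(0.0, params.noise_sd, size=force.size)
    series = LoadCycleSeries(
        time=np.concatenate(t_all),
        displacement=np.concatenate(d_all),
        force=force,
    )
    return series, pd.DataFrame(truth_rows)


# --------------------------------------------------------------------------
# Mass-time series
# --------------------------------------------------------------------------


@dataclass
class MassModelParams:
    """Linear evaporation drift with a step removal during the procedure.

    Mass decreases at ``evap_rate`` g/min throughout; between ``t1`` and
    ``t2`` the removed mass is taken out in equal steps at the energy-mark
    sample points (emulating mass logging at fixed delivered-energy
    intervals).  Ten-minute windows before ``t1`` and after ``t2`` are
    sampled every ``sample_interval`` minutes.
    """

    m0: float = 10.0  # g
    evap_rate: float = 0.002  # g/min
    removed_mass: float = 0.2  # g
    t1: float = 10.0  # min, procedure start
    t2: float = 20.0  # min, procedure end
    window: float = 10.0  # min, pre and post observation windows
    sample_interval: float = 1.0  # min
    n_energy_marks: int = 3  # e.g. 400 J marks for a 1200 J delivery
    noise_sd: float = 0.001  # g

    def __post_init__(self) -> None:
        if self.evap_rate <= 0:
            raise ValueError("evaporation rate must be positive")
        if not self.t1 < self.t2:
            raise ValueError("need t1 < t2")
        if self.removed_mass < 0 or self.noise_sd < 0:
            raise ValueError("removed mass and noise SD must be >= 0")
        if self.window <= 0 or self.sample_interval <= 0:
            raise ValueError("window and sample interval must be positive")


def gen_mass_series(
    params: MassModelParams, seed: int = 0
) -> tuple[MassTimeSeries, float]:
    """Generate a mass-time series; returns (series, true removed mass)."""
    rng = np.random.default_rng(seed)
    p = params
    t_pre = np.arange(p.t1 - p.window, p.t1 + p.sample_interval / 2, p.sample_interval)
    t_post = np.arange(p.t2, p.t2 + p.window + p.sample_interval / 2, p.sample_interval)
    # intra-procedure energy marks strictly inside (t1, t2); the final mark
    # coincides with t2 and is covered by the post window
    marks = np.arange(1, p.n_energy_marks) * (p.t2 - p.t1) / p.n_energy_marks + p.t1

    m_pre = p.m0 - p.evap_rate * t_pre
    frac = np.arange(1, p.n_energy_marks) / p.n_energy_marks
    m_intra = p.m0 - p.evap_rate * marks - frac * p.removed_mass
    m_post = p.m0 - p.evap_rate * t_post - p.removed_mass

    time = np.concatenate([t_pre, marks, t_post])
    mass = np.concatenate([m_pre, m_intra, m_post])
    phase = np.concatenate(
        [
            np.full(t_pre.size, "pre", dtype=object),
            np.full(marks.size, "intra", dtype=object),
            np.full(t_post.size, "post", dtype=object),
        ]
    )
    if p.noise_sd > 0:
        mass = mass + rng.normal(0.0, p.noise_sd, size=mass.size)
    return MassTimeSeries(time=time, mass=mass, phase=phase), p.removed_mass


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------

# Template mirroring a balanced three-technique cadaveric cohort: five
# specimens per technique spanning lumbar levels L1-L5 and moderate
# degeneration grades.
_COHORT_TEMPLATE = [
    # (donor age, sex, level, grade, technique)
    (22, "F", "L2-L3", 2, "rongeurs"),
    (22, "F", "L4-L5", 3, "shaver"),
    (38, "M", "L3-L4", 3, "laser"),
    (38, "M", "L4-L5", 3, "rongeurs"),
    (42, "M", "L1-L2", 2, "laser"),
    (42, "M", "L2-L3", 2, "shaver"),
    (40, "M", "L1-L2", 2, "laser"),
    (36, "M", "L1-L2", 2, "rongeurs"),
    (36, "M", "L2-L3", 3, "laser"),
    (36, "M", "L3-L4", 3, "shaver"),
    (36, "M", "L4-L5", 3, "laser"),
    (65, "M", "L1-L2", 4, "shaver"),
    (65, "M", "L2-L3", 3, "rongeurs"),
    (65, "M", "L3-L4", 3, "rongeurs"),
    (65, "M", "L4-L5", 3, "shaver"),
]


@dataclass
class CohortParams:
    """Group-level effect sizes for the synthetic cohort (config, not claims).

    Means/SDs emulate the magnitudes this class of experiment reports:
    similar several-hundred-mm^3 removals for shaver and rongeurs versus a
    roughly twenty-fold smaller laser cavity, larger toe- than linear-region
    stiffness reductions, and technique-ordered disc-height losses.
    """

    n_per_technique: int = 5
    # phantom geometry draws (mm)
    a_mean: float = 27.0
    a_sd: float = 1.5
    b_mean: float = 20.0
    b_sd: float = 1.2
    h_mean: float = 10.0
    h_sd: float = 1.0
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    # removed-volume targets (mm^3)
    volume_mean: dict = field(
        default_factory=lambda: {"shaver": 353.0, "rongeurs": 478.0, "laser": 20.9}
    )
    volume_sd: dict = field(
        default_factory=lambda: {"shaver": 100.0, "rongeurs": 120.0, "laser": 8.0}
    )
    # intact stiffness draws (N/mm)
    k_toe_mean: float = 600.0
    k_toe_sd: float = 80.0
    k_lin_mean: float = 2226.0
    k_lin_sd: float = 304.0
    # stiffness reductions post-nuclectomy (%)
    toe_drop: dict = field(
        default_factory=lambda: {"shaver": (35.0, 6.0), "rongeurs": (55.0, 7.0), "laser": (8.0, 3.0)}
    )
    lin_drop: dict = field(
        default_factory=lambda: {"shaver": (15.0, 5.0), "rongeurs": (30.0, 6.0), "laser": (3.0, 1.5)}
    )
    # disc-height loss (mm)
    height_drop: dict = field(
        default_factory=lambda: {"shaver": (1.4, 0.3), "rongeurs": (0.74, 0.3), "laser": (0.2, 0.1)}
    )
    # removed masses (g)
    wet_mass: dict = field(
        default_factory=lambda: {"shaver": (4.184, 1.310), "rongeurs": (0.879, 0.207), "laser": (0.228, 0.038)}
    )
    dry_mass: dict = field(
        default_factory=lambda: {"shaver": (0.229, 0.013), "rongeurs": (0.254, 0.078)}
    )
    annulotomy_width: dict = field(
        default_factory=lambda: {"shaver": (6.84, 1.34), "rongeurs": (6.91, 1.50)}
    )
    annulotomy_height: dict = field(
        default_factory=lambda: {"shaver": (2.34, 0.47), "rongeurs": (4.27, 0.70)}
    )
    # laser mass-series model for the whole potted specimen
    specimen_mass_mean: float = 120.0
    specimen_mass_sd: float = 15.0
    specimen_evap_rate: float = 0.02  # g/min


def _tnorm(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    """Normal draw truncated below at ``lo`` by redrawing (bounded retries)."""
    for _ in range(100):
        v = rng.normal(mean, sd)
        if v > lo:
            return float(v)
    return float(max(lo + abs(sd) * 1e-3, mean))


def gen_cohort(
    params: CohortParams | None = None,
    seed: int = 0,
    build_volumes: bool = False,
    build_series: bool = False,
) -> tuple[list[SpecimenRecord], pd.DataFrame, dict]:
    """Draw a balanced synthetic cohort.

    Returns ``(records, truth, assets)``: specimen metadata records, a
    ground-truth sidecar table (one row per specimen, every generated true
    value), and — when requested — per-specimen phantoms/series under
    ``assets[specimen_id]`` with keys ``pre_volume``, ``post_volume``,
    ``load_pre``, ``load_post`` and (laser only) ``mass_series``.
    """
    p = params or CohortParams()
    if p.n_per_technique < 1:
        raise ValueError("need at least one specimen per technique")
    rng = np.random.default_rng(seed)

    n = 3 * p.n_per_technique
    rows = []
    if p.n_per_technique == 5:
        template = list(_COHORT_TEMPLATE)
    else:
        levels = ["L1-L2", "L2-L3", "L3-L4", "L4-L5"]
        grades = [2, 3, 3, 4]
        template = []
        for j in range(n):
            tech = TECHNIQUES[j % 3]
            template.append(
                (int(round(_tnorm(rng, 40, 13, 18))), "M", levels[j % 4], grades[j % 4], tech)
            )

    records: list[SpecimenRecord] = []
    truth_rows = []
    assets: dict[str, dict] = {}

    for j, (age, sex, level, grade, tech) in enumerate(template, start=1):
        sid = f"S{j:02d}"
        a = _tnorm(rng, p.a_mean, p.a_sd, 10.0)
        b = min(_tnorm(rng, p.b_mean, p.b_sd, 8.0), a - 1e-6)
        h = _tnorm(rng, p.h_mean, p.h_sd, 6.0)
        target_vol = _tnorm(
            rng, p.volume_mean[tech], p.volume_sd[tech], 0.1 * p.volume_mean[tech]
        )

        k_toe = _tnorm(rng, p.k_toe_mean, p.k_toe_sd, 100.0)
        k_lin = _tnorm(rng, p.k_lin_mean, p.k_lin_sd, 2.0 * k_toe)
        toe_red = _tnorm(rng, *p.toe_drop[tech], 0.5)
        lin_red = _tnorm(rng, *p.lin_drop[tech], 0.2)
        # the exponential law's linear/toe secant ratio is bounded (~6.3 for
        # the standard windows); cap the toe reduction so the post-state
        # stiffness pair stays representable, and record the capped truth
        max_ratio = 6.0
        ratio_post = (k_lin * (1 - lin_red / 100.0)) / (k_toe * (1 - toe_red / 100.0))
        if ratio_post > max_ratio:
            toe_red = 100.0 * (
                1.0 - (k_lin / k_toe) * (1 - lin_red / 100.0) / max_ratio
            )
        dh = _tnorm(rng, *p.height_drop[tech], 0.02)
        wet = _tnorm(rng, *p.wet_mass[tech], 0.01)
        if tech == "laser":
            dry = np.nan  # not directly measurable; estimated via water fraction
        else:
            dry = _tnorm(rng, *p.dry_mass[tech], 0.01)
        aw = _tnorm(rng, *p.annulotomy_width[tech], 0.5) if tech != "laser" else np.nan
        ah = _tnorm(rng, *p.annulotomy_height[tech], 0.2) if tech != "laser" else np.nan

        rec = SpecimenRecord(
            specimen_id=sid,
            donor_age=age,
            sex=sex,
            lumbar_level=level,
            pfirrmann_grade=grade,
            technique=tech,
            entry_side="left",
            wet_mass_removed_g=wet,
            dry_mass_removed_g=dry,
            annulotomy_width_mm=aw,
            annulotomy_height_mm=ah,
        )
        records.append(rec)
        truth_rows.append(
            {
                "specimen_id": sid,
                "technique": tech,
                "a": a,
                "b": b,
                "h": h,
                "true_removed_volume_mm3": target_vol,
                "true_k_toe_pre": k_toe,
                "true_k_lin_pre": k_lin,
                "true_toe_reduction_pct": toe_red,
                "true_lin_reduction_pct": lin_red,
                "true_height_drop_mm": dh,
                "true_wet_mass_g": wet,
                "true_dry_mass_g": dry,
            }
        )

        asset: dict = {}
        if build_volumes:
            spec_pre = PhantomSpec(a=a, b=b, h=h, spacing=p.spacing)
            spec_post = PhantomSpec(a=a, b=b, h=max(h - dh, 5.0), spacing=p.spacing)
            pre_vol = gen_disc_volume(spec_pre)
            post_intact = gen_disc_volume(spec_post)
            if tech == "laser":
                cav = CavitySpec(
                    technique="laser",
                    target_volume_mm3=target_vol,
                    tract_length_mm=14.5,
                    entry_quadrant="posterior-left",
                )
            elif tech == "rongeurs":
                cav = CavitySpec(
                    technique="rongeurs",
                    target_volume_mm3=target_vol,
                    lobes=3,
                    entry_quadrant="posterior-left",
                )
            else:
                cav = CavitySpec(technique="shaver", target_volume_mm3=target_vol)
            post_vol = carve_cavity(
                post_intact, cav, seed=int(rng.integers(0, 2**31 - 1))
            )
            asset["pre_volume"] = pre_vol
            asset["post_volume"] = post_vol
            asset["cavity_spec"] = cav
        if build_series:
            a_pre, b_pre = solve_load_params(k_toe, k_lin)
            a_post, b_post = solve_load_params(
                k_toe * (1 - toe_red / 100.0), k_lin * (1 - lin_red / 100.0)
            )
            lp_pre = LoadModelParams(alpha=a_pre, beta=b_pre)
            lp_post = LoadModelParams(alpha=a_post, beta=b_post)
            asset["load_pre"], asset["load_pre_truth"] = gen_force_displacement(
                lp_pre, seed=int(rng.integers(0, 2**31 - 1))
            )
            asset["load_post"], asset["load_post_truth"] = gen_force_displacement(
                lp_post, seed=int(rng.integers(0, 2**31 - 1))
            )
            if tech == "laser":
                mp = MassModelParams(
                    m0=_tnorm(rng, p.specimen_mass_mean, p.specimen_mass_sd, 50.0),
                    evap_rate=p.specimen_evap_rate,
                    removed_mass=wet,
                )
                asset["mass_series"], asset["true_removed_mass"] = gen_mass_series(
                    mp, seed=int(rng.integers(0, 2**31 - 1))
                )
        if asset:
            assets[sid] = asset

    return records, pd.DataFrame(truth_rows), assets
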