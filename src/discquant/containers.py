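"""Core in-memory containers shared across the pipeline.

Axis convention (asserted, never inferred): axis 0 = +x, the specimen's
left-to-right lateral axis; axis 1 = +y, posterior-to-anterior; axis 2 = +z,
caudal-to-cranial.  Voxel indexing is 0-based and world coordinates are
voxel-center based (voxel ``i`` sits at ``i * spacing`` mm), with half-open
extents.  All quantities are SI-ish lab units: s, min, mm, N, g.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical label values for segmented disc volumes.
BACKGROUND = 0
VERTEBRA = 1
AF = 2  # annulus fibrosus
NP = 3  # nucleus pulposus
CAVITY = 4  # removed-tissue cavity

LABEL_MAP = {
    BACKGROUND: "background",
    VERTEBRA: "vertebra",
    AF: "annulus_fibrosus",
    NP: "nucleus_pulposus",
    CAVITY: "cavity",
}

#: Labels that together constitute the (intact-reference) disc.
DISC_LABELS = (AF, NP, CAVITY)

AXIS_CONVENTION = "+x lateral (left-to-right), +y anterior, +z cranial"


@dataclass
class LabelVolume:
    """A 3D integer label grid with anisotropic voxel spacing in mm."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    axis_convention: str = AXIS_CONVENTION

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"label volume must be 3D, got {self.voxels.ndim}D")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError(
                f"label volume must be an integer grid, got dtype {self.voxels.dtype}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")
        unknown = sorted(set(np.unique(self.voxels)) - set(LABEL_MAP))
        if unknown:
            raise ValueError(
                f"unknown labels {unknown} in volume; allowed labels are {sorted(LABEL_MAP)}"
            )
        if self.axis_convention != AXIS_CONVENTION:
            raise ValueError(
                f"unsupported axis convention {self.axis_convention!r}; "
                f"expected {AXIS_CONVENTION!r}"
            )

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def disc_mask(self) -> np.ndarray:
        """Boolean mask of disc voxels (AF + NP + cavity)."""
        return np.isin(self.voxels, DISC_LABELS)

    def label_volume_mm3(self, label: int) -> float:
        return float(np.count_nonzero(self.voxels == label)) * self.voxel_volume


@dataclass
class LoadCycleSeries:
    """A force-displacement-time record from cyclic axial compression.

    ``displacement`` is compression-positive, in mm; ``force`` in N;
    ``time`` in s, strictly increasing.
    """

    time: np.ndarray
    displacement: np.ndarray
    force: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        n = self.time.size
        if self.displacement.size != n or self.force.size != n:
            raise ValueError("time, displacement and force must have equal length")
        if n >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return int(self.time.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.time, "displacement": self.displacement, "force": self.force}
        )


MASS_PHASES = ("pre", "intra", "post")


@dataclass
class MassTimeSeries:
    """Timestamped specimen masses around a procedure window.

    ``time`` in minutes, ``mass`` in g; ``phase`` labels each sample as
    pre-procedure, intra-procedure or post-procedure.
    """

    time: np.ndarray
    mass: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        n = self.time.size
        if self.mass.size != n or self.phase.size != n:
            raise ValueError("time, mass and phase must have equal length")
        if n >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        bad = sorted(set(self.phase) - set(MASS_PHASES))
        if bad:
            raise ValueError(f"unknown phase labels {bad}; allowed: {MASS_PHASES}")

    def __len__(self) -> int:
        return int(self.time.size)

    def in_phase(self, phase: str) -> tuple[np.ndarray, np.ndarray]:
        if phase not in MASS_PHASES:
            raise ValueError(f"unknown phase {phase!r}; allowed: {MASS_PHASES}")
        sel = self.phase == phase
        return self.time[sel], self.mass[sel]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "mass": self.mass, "phase": self.phase})


TECHNIQUES = ("shaver", "rongeurs", "laser")


@dataclass
class SpecimenRecord:
    """Per-specimen metadata and headline measurements for one spinal unit."""

    specimen_id: str
    donor_age: int
    sex: str
    lumbar_level: str
    pfirrmann_grade: int  # observer metadata only, 1-5
    technique: str
    entry_side: str = "left"
    wet_mass_removed_g: float = np.nan
    dry_mass_removed_g: float = np.nan
    annulotomy_width_mm: float = np.nan
    annulotomy_height_mm: float = np.nan
    disc_height_pre_mm: float = np.nan
    disc_height_post_mm: float = np.nan
    k_toe_pre: float = np.nan
    k_toe_post: float = np.nan
    k_lin_pre: float = np.nan
    k_lin_post: float = np.nan
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise ValueError(
                f"technique must be one of {TECHNIQUES}, got {self.technique!r}"
            )
        if not 1 <= int(self.pfirrmann_grade) <= 5:
            raise ValueError(f"Pfirrmann grade must be 1-5, got {self.pfirrmann_grade}")
        for name in ("wet_mass_removed_g", "dry_mass_removed_g"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
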