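"""Disc centroid construction and quadrant / concentric-band localization.

The disc frame follows the rectangle construction of Little et al.: on the
mid-transverse slice, line 1 passes through the two most posterior points of
the disc boundary (one from each lateral half); lines 2 and 3 are
perpendicular to line 1 through the lateral-most boundary points measured
along the line-1 direction; line 4 is parallel to line 1 through the most
anterior point.  The rectangle's geometric center is the disc centroid C and
the distance between lines 2 and 3 is the largest lateral width W.

Concentric circles about C whose *diameters* (default) are the configured
fractions of W, crossed with the four quadrants split by the line-1-parallel
and perpendicular axes through C, partition every voxel of the volume; the
2D frame is extruded to all axial slices.  Distances are between voxel
centers in world mm, respecting anisotropic spacing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import CAVITY, LabelVolume

QUADRANTS = ("anterior-left", "anterior-right", "posterior-left", "posterior-right")


@dataclass
class DiscFrame:
    """Landmarks, bounding rectangle and centroid of the disc in-plane."""

    P1: np.ndarray
    P2: np.ndarray
    P3: np.ndarray
    P4: np.ndarray
    P5: np.ndarray
    u: np.ndarray  # unit vector along line 1 (lateral), +x-ish
    v: np.ndarray  # unit normal to line 1, anterior-pointing
    centroid: np.ndarray  # mm, in-plane
    corners: np.ndarray  # 4 x 2, rectangle corners (s2/s3 x t1/t4)
    width: float  # W, distance between lines 2 and 3, mm
    depth: float  # distance between lines 1 and 4, mm
    used_tangent_fallback: bool = False

    @property
    def rotation_deg(self) -> float:
        """In-plane rotation of line 1 relative to the grid lateral axis."""
        return float(np.degrees(np.arctan2(self.u[1], self.u[0])))


def extract_mid_transverse_mask(volume: LabelVolume) -> tuple[np.ndarray, int]:
    """Return the axial disc mask at the disc's mid-height and its z index.

    Mid-height is the median z index of disc voxels; cavity voxels count as
    disc so that a carved disc keeps its intact outline.
    """
    disc = volume.disc_mask()
    if not disc.any():
        raise ValueError("volume contains no disc voxels")
    zs = np.flatnonzero(disc.any(axis=(0, 1)))
    z_mid = int(np.floor(np.median(zs)))
    return disc[:, :, z_mid], z_mid


def _boundary_points(mask: np.ndarray, spacing: tuple[float, float]) -> np.ndarray:
    interior = ndimage.binary_erosion(mask)
    boundary = mask & ~interior
    ij = np.argwhere(boundary)
    return ij * np.asarray(spacing)


def find_landmarks(
    mask: np.ndarray, spacing: tuple[float, float] = (1.0, 1.0)
) -> dict:
    """Locate the five boundary landmarks on a 2D disc mask.

    P1/P5 are the posterior-most boundary points of the left and right
    halves (split at the lateral coordinate of the mask centroid); if their
    posterior coordinates coincide (convex posterior margin) line 1 falls
    back to the lateral-axis-aligned tangent at the posterior pole.  P2/P3
    are the extreme boundary points along the line-1 direction and P4 the
    extreme point on the anterior side.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 4 or (mask.any(axis=1).sum() < 2) or (mask.any(axis=0).sum() < 2):
        raise ValueError("mask too thin to extract landmarks")
    pts = _boundary_points(mask, spacing)
    centroid0 = np.argwhere(mask).mean(axis=0) * np.asarray(spacing)
    return landmarks_from_points(pts, centroid0[0], flat_tol=1.0001 * spacing[1])


def landmarks_from_points(
    pts: np.ndarray, lateral_split: float, flat_tol: float = 1e-9
) -> dict:
    """Landmark construction on an explicit boundary point set (x, y in mm).

    ``flat_tol`` is the posterior-flatness tolerance: when the two
    half-boundary posterior extremes differ in y by no more than this (one
    voxel, for rasterized masks), the posterior margin is convex at grid
    resolution and line 1 falls back to the lateral-axis tangent.
    """
    pts = np.asarray(pts, dtype=float)
    left = pts[pts[:, 0] < lateral_split]
    right = pts[pts[:, 0] >= lateral_split]

    fallback = left.size == 0 or right.size == 0
    if not fallback:
        P1 = _posterior_extreme(left, prefer_min_x=True)
        P5 = _posterior_extreme(right, prefer_min_x=False)
        if abs(P1[1] - P5[1]) <= flat_tol:
            fallback = True
    if fallback:
        # convex posterior margin: tangent at the posterior pole, grid-lateral
        y_min = pts[:, 1].min()
        P1 = P5 = pts[np.lexsort((pts[:, 0], pts[:, 1]))][0]
        P1 = np.array([P1[0], y_min])
        P5 = P1.copy()
        u = np.array([1.0, 0.0])
    else:
        u = (P5 - P1) / np.linalg.norm(P5 - P1)
        if u[0] < 0:
            u = -u
    v = np.array([-u[1], u[0]])
    if v[1] < 0:
        v = -v

    s = pts @ u
    t = pts @ v
    P2 = pts[int(np.argmin(s))]
    P3 = pts[int(np.argmax(s))]
    P4 = pts[int(np.argmax(t))]
    return {
        "P1": np.asarray(P1),
        "P2": P2,
        "P3": P3,
        "P4": P4,
        "P5": np.asarray(P5),
        "u": u,
        "v": v,
        "used_tangent_fallback": bool(fallback),
    }


def _posterior_extreme(pts: np.ndarray, prefer_min_x: bool) -> np.ndarray:
    y_min = pts[:, 1].min()
    cand = pts[np.abs(pts[:, 1] - y_min) < 1e-12]
    xs = cand[:, 0]
    return cand[int(np.argmin(xs) if prefer_min_x else np.argmax(xs))]


def build_disc_frame(landmarks: dict) -> DiscFrame:
    """Assemble the rectangle, centroid and lateral width from landmarks."""
    u, v = landmarks["u"], landmarks["v"]
    s = {k: float(landmarks[k] @ u) for k in ("P1", "P2", "P3", "P4", "P5")}
    t = {k: float(landmarks[k] @ v) for k in ("P1", "P2", "P3", "P4", "P5")}
    width = s["P3"] - s["P2"]
    depth = t["P4"] - t["P1"]
    if width <= 0 or depth <= 0:
        raise ValueError(f"degenerate rectangle: width={width}, depth={depth}")
    centroid = ((s["P2"] + s["P3"]) / 2) * u + ((t["P1"] + t["P4"]) / 2) * v
    corners = np.array(
        [
            s["P2"] * u + t["P1"] * v,
            s["P3"] * u + t["P1"] * v,
            s["P3"] * u + t["P4"] * v,
            s["P2"] * u + t["P4"] * v,
        ]
    )
    return DiscFrame(
        P1=landmarks["P1"],
        P2=landmarks["P2"],
        P3=landmarks["P3"],
        P4=landmarks["P4"],
        P5=landmarks["P5"],
        u=u,
        v=v,
        centroid=centroid,
        corners=corners,
        width=float(width),
        depth=float(depth),
        used_tangent_fallback=landmarks["used_tangent_fallback"],
    )


@dataclass
class RegionPartition:
    """Per-voxel (quadrant, band) assignment and per-region intact volumes."""

    frame: DiscFrame
    fractions: tuple[float, ...]
    radius_mode: str
    radii: np.ndarray  # mm, increasing; band k lies in [radii[k-1], radii[k])
    quadrant: np.ndarray  # 3D int8 codes into QUADRANTS, every voxel assigned
    band: np.ndarray  # 3D int8, 0..len(fractions); last = outside largest circle
    radial_distance: np.ndarray  # 3D float32, in-plane distance to C, mm
    intact_volumes: pd.DataFrame  # columns quadrant, band, intact_mm3
    entry_side: str = "left"

    @property
    def n_bands(self) -> int:
        return len(self.fractions) + 1


def partition_regions(
    frame: DiscFrame,
    volume: LabelVolume,
    fractions: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8),
    radius_mode: str = "diameter",
    entry_side: str = "left",
) -> RegionPartition:
    """Assign every voxel to a (quadrant, band) region.

    Band radii are ``f * W / 2`` in ``diameter`` mode (the fractions are
    circle diameters relative to the lateral width W) or ``f * W`` in
    ``radius`` mode.  The partition is computed in-plane and applied
    identically to every axial slice.  Tie-breaks (documented, deterministic):
    a voxel center exactly on a circle belongs to the outer band; exactly on
    the lateral axis -> anterior; exactly on the AP axis -> the entry side.
    """
    fr = tuple(float(f) for f in fractions)
    if any(b <= a for a, b in zip(fr, fr[1:])) or any(f <= 0 for f in fr):
        raise ValueError(f"fractions must be positive and strictly increasing: {fr}")
    if radius_mode not in ("diameter", "radius"):
        raise ValueError("radius_mode must be 'diameter' or 'radius'")
    if entry_side not in ("left", "right"):
        raise ValueError("entry_side must be 'left' or 'right'")
    scale = 0.5 if radius_mode == "diameter" else 1.0
    radii = np.array([f * scale * frame.width for f in fr])

    dx, dy, _ = volume.spacing
    nx, ny, nz = volume.voxels.shape
    X = (np.arange(nx) * dx)[:, None]
    Y = (np.arange(ny) * dy)[None, :]
    s = X * frame.u[0] + Y * frame.u[1] - frame.centroid @ frame.u
    t = X * frame.v[0] + Y * frame.v[1] - frame.centroid @ frame.v
    r = np.hypot(s, t)

    band2d = np.searchsorted(radii, r, side="right").astype(np.int8)
    anterior = t >= 0.0
    if entry_side == "left":
        left = s <= 0.0
    else:
        left = s < 0.0
    quad2d = np.where(
        anterior, np.where(left, 0, 1), np.where(left, 2, 3)
    ).astype(np.int8)

    quadrant = np.repeat(quad2d[:, :, None], nz, axis=2)
    band = np.repeat(band2d[:, :, None], nz, axis=2)
    radial = np.repeat(r[:, :, None].astype(np.float32), nz, axis=2)

    disc = volume.disc_mask()
    n_bands = len(fr) + 1
    code = (quadrant.astype(np.int32) * n_bands + band.astype(np.int32))[disc]
    counts = np.bincount(code, minlength=4 * n_bands)
    rows = []
    for qi, qname in enumerate(QUADRANTS):
        for bi in range(n_bands):
            rows.append(
                {
                    "quadrant": qname,
                    "band": bi,
                    "intact_mm3": counts[qi * n_bands + bi] * volume.voxel_volume,
                }
            )
    return RegionPartition(
        frame=frame,
        fractions=fr,
        radius_mode=radius_mode,
        radii=radii,
        quadrant=quadrant,
        band=band,
        radial_distance=radial,
        intact_volumes=pd.DataFrame(rows),
        entry_side=entry_side,
    )


def localize_removed_volume(
    partition: RegionPartition, volume: LabelVolume
) -> tuple[pd.DataFrame, dict]:
    """Attribute the cavity volume to the partition's regions.

    Returns a per-(quadrant, band) table with the removed volume in mm^3,
    its percentage of the total removed volume (normalization A, sums to
    100), and its percentage of that region's intact volume (normalization
    B), together with a summary dict including the percentage of removed
    volume lying within 0.4 W of the centroid.
    """
    cav = volume.voxels == CAVITY
    n_cav = int(np.count_nonzero(cav))
    voxvol = volume.voxel_volume
    n_bands = partition.n_bands

    if n_cav == 0:
        warnings.warn("no cavity voxels found; localization table is all zeros")
        counts = np.zeros(4 * n_bands, dtype=int)
        within = 0.0
    else:
        code = (
            partition.quadrant.astype(np.int32) * n_bands
            + partition.band.astype(np.int32)
        )[cav]
        counts = np.bincount(code, minlength=4 * n_bands)
        within = 100.0 * float(
            np.count_nonzero(partition.radial_distance[cav] < 0.4 * partition.frame.width)
        ) / n_cav

    total_mm3 = n_cav * voxvol
    table = partition.intact_volumes.copy()
    table["removed_mm3"] = counts * voxvol
    table["pct_of_removed"] = (
        100.0 * table["removed_mm3"] / total_mm3 if n_cav else 0.0
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        table["pct_of_region_intact"] = np.where(
            table["intact_mm3"] > 0,
            100.0 * table["removed_mm3"] / table["intact_mm3"],
            0.0,
        )
    summary = {
        "total_removed_mm3": total_mm3,
        "pct_within_0.4W": within,
        "lateral_width_mm": partition.frame.width,
        "centroid_mm": [float(c) for c in partition.frame.centroid],
    }
    return table, summary


def localize_volume(
    volume: LabelVolume,
    fractions: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8),
    radius_mode: str = "diameter",
    entry_side: str = "left",
) -> tuple[pd.DataFrame, dict, RegionPartition]:
    """One-shot localization: mid-slice frame, partition, cavity attribution."""
    mask, _ = extract_mid_transverse_mask(volume)
    landmarks = find_landmarks(mask, volume.spacing[:2])
    frame = build_disc_frame(landmarks)
    part = partition_regions(frame, volume, fractions, radius_mode, entry_side)
    table, summary = localize_removed_volume(part, volume)
    return table, summary, part
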