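"""Cavity volumetry, normalized removal, disc-height measurement, repeatability."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import AF, CAVITY, NP, VERTEBRA, LabelVolume


@dataclass
class VolumeResult:
    removed_mm3: float
    disc_mm3: float  # intact reference: AF + NP + cavity

    @property
    def normalized_removal_pct(self) -> float:
        return 100.0 * self.removed_mm3 / self.disc_mm3 if self.disc_mm3 else 0.0


def removed_volume(
    volume: LabelVolume, pre: LabelVolume | None = None
) -> VolumeResult:
    """Removed-tissue volume from the cavity label (or a pre/post pair).

    With a single volume the cavity label is counted directly.  With a
    pre/post pair the cavity is the symmetric difference of the AF+NP
    footprints; the intact disc reference is then taken from the pre scan.
    """
    if pre is None:
        cav_n = int(np.count_nonzero(volume.voxels == CAVITY))
        disc_n = int(np.count_nonzero(volume.disc_mask()))
        return VolumeResult(
            removed_mm3=cav_n * volume.voxel_volume,
            disc_mm3=disc_n * volume.voxel_volume,
        )
    if pre.voxels.shape != volume.voxels.shape:
        raise ValueError(
            f"pre/post grids differ in shape: {pre.voxels.shape} vs {volume.voxels.shape}"
        )
    tissue_pre = np.isin(pre.voxels, (AF, NP))
    tissue_post = np.isin(volume.voxels, (AF, NP))
    cav_n = int(np.count_nonzero(tissue_pre ^ tissue_post))
    disc_n = int(np.count_nonzero(pre.disc_mask()))
    return VolumeResult(
        removed_mm3=cav_n * pre.voxel_volume, disc_mm3=disc_n * pre.voxel_volume
    )


@dataclass
class HeightResult:
    height_mm: float  # mean of the three per-slice measurements
    per_slice_mm: tuple[float, float, float]
    coronal_index: int  # y index of the widest coronal slice


def disc_height(volume: LabelVolume) -> HeightResult:
    """Central disc height, averaged over three neighboring coronal slices.

    Protocol: on the mid-axial slice, pick the coronal (constant-y) slice
    with the largest lateral disc width; at its lateral midpoint column,
    measure the cranio-caudal disc extent; repeat on the two neighboring
    coronal slices and average.  The disc must be bounded by vertebra above
    and below at the midpoint column.
    """
    disc = volume.disc_mask()
    if not disc.any():
        raise ValueError("volume contains no disc voxels")
    dx, dy, dz = volume.spacing

    zs = np.flatnonzero(disc.any(axis=(0, 1)))
    z_mid = int(np.floor(np.median(zs)))
    axial = disc[:, :, z_mid]  # (x, y)

    widths = np.zeros(axial.shape[1])
    for j in range(axial.shape[1]):
        xs = np.flatnonzero(axial[:, j])
        if xs.size:
            widths[j] = (xs.max() - xs.min() + 1) * dx
    y_star = int(np.argmax(widths))  # ties -> lower index

    neighbors = [y for y in (y_star - 1, y_star, y_star + 1) if 0 <= y < axial.shape[1]]
    if len(neighbors) < 3:
        raise ValueError("widest coronal slice lies at the volume edge")

    heights = []
    for y in neighbors:
        coronal = disc[:, y, :]  # (x, z)
        xs = np.flatnonzero(coronal.any(axis=1))
        if xs.size == 0:
            raise ValueError(f"no disc voxels on coronal slice y={y}")
        x_mid = int((xs.min() + xs.max()) // 2)  # ties round toward lower index
        col = np.flatnonzero(coronal[x_mid, :])
        if col.size == 0:
            raise ValueError(f"no disc voxels at midpoint column x={x_mid}, y={y}")
        below = volume.voxels[x_mid, y, : col.min()]
        above = volume.voxels[x_mid, y, col.max() + 1 :]
        if VERTEBRA not in below or VERTEBRA not in above:
            raise ValueError(
                f"disc not bounded by vertebrae at midpoint column (x={x_mid}, y={y})"
            )
        heights.append((col.max() - col.min() + 1) * dz)

    order = [neighbors.index(y) for y in sorted(neighbors)]
    per_slice = tuple(heights[i] for i in order)
    return HeightResult(
        height_mm=float(np.mean(heights)),
        per_slice_mm=per_slice,
        coronal_index=y_star,
    )


def repeatability(measurements) -> dict:
    """Mean, sample SD (n-1) and coefficient of variation of repeated measures."""
    values = np.asarray(measurements, dtype=float)
    if values.size < 2:
        raise ValueError("repeatability needs at least two measurements")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    result = {"mean": mean, "sd": sd, "n": int(values.size)}
    if mean == 0:
        result["cv_pct"] = float("nan")
        result["cv_undefined"] = True
    else:
        result["cv_pct"] = 100.0 * sd / mean
        result["cv_undefined"] = False
    return result
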