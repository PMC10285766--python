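"""Readers and writers for label volumes (NIfTI) and measurement series (CSV)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import (
    AXIS_CONVENTION,
    LABEL_MAP,
    LabelVolume,
    LoadCycleSeries,
    MassTimeSeries,
)

_LOAD_COLUMNS = ("time", "displacement", "force")
_MASS_COLUMNS = ("time", "mass", "phase")


def write_label_volume(volume: LabelVolume, path: str | Path) -> None:
    """Write a label volume as NIfTI with spacing in the header zooms."""
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.voxels.astype(np.int16), affine)
    img.header.set_zooms(volume.spacing)
    img.header["descrip"] = AXIS_CONVENTION.encode()[:79]
    nib.save(img, str(path))


def read_label_volume(path: str | Path) -> LabelVolume:
    """Read a 3D integer NIfTI label volume; spacing taken from the header.

    Rejects 4D or floating-point images and any voxel value outside the
    known label map (the offending values are named in the error).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such label volume: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D label image, got {data.ndim}D")
    if not np.issubdtype(data.dtype, np.integer):
        raise ValueError(
            f"{path}: expected an integer label image, got dtype {data.dtype}"
        )
    unknown = sorted(set(np.unique(data)) - set(LABEL_MAP))
    if unknown:
        raise ValueError(
            f"{path}: unknown labels {unknown}; allowed labels are {sorted(LABEL_MAP)}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelVolume(voxels=data.astype(np.int16), spacing=spacing)


def read_series(path: str | Path, kind: str) -> LoadCycleSeries | MassTimeSeries:
    """Read a measurement series CSV.

    ``kind='load'`` expects columns (time, displacement, force) with time in
    s; ``kind='mass'`` expects (time, mass, phase) with time in min.  Time
    must be strictly increasing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such series file: {path}")
    if kind not in ("load", "mass"):
        raise ValueError(f"kind must be 'load' or 'mass', got {kind!r}")
    df = pd.read_csv(path)
    required = _LOAD_COLUMNS if kind == "load" else _MASS_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if kind == "load":
        return LoadCycleSeries(
            time=df["time"].to_numpy(float),
            displacement=df["displacement"].to_numpy(float),
            force=df["force"].to_numpy(float),
        )
    return MassTimeSeries(
        time=df["time"].to_numpy(float),
        mass=df["mass"].to_numpy(float),
        phase=df["phase"].to_numpy(object),
    )


def write_series(series: LoadCycleSeries | MassTimeSeries, path: str | Path) -> None:
    series.to_frame().to_csv(path, index=False)
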