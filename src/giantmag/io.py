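"""File formats: legacy-VTK vector fields, TIFF tilt series, CSV tables.

Vector fields are written as ASCII legacy VTK ``STRUCTURED_POINTS``
datasets (point data: a ``magnetization`` vector array and a ``mask``
scalar array) for drag-and-drop visualization in Paraview.  Tilt series
are stored as multipage TIFF stacks with a JSON sidecar carrying angles,
axis id, pixel size and the applied shifts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .fields import VectorField3D
from .projection import TiltSeries
from .topology import CorePath

__all__ = ["write_vtk", "read_vtk", "write_tilt_series",
           "read_tilt_series", "core_path_to_csv"]


def write_vtk(field3d: VectorField3D, path) -> None:
    """Write a vector field as an ASCII legacy-VTK structured-points file."""
    nx, ny, nz = field3d.grid_shape
    h = field3d.voxel_size
    ox, oy, oz = field3d.origin + h / 2.0  # point data at voxel centers
    n = nx * ny * nz
    # VTK structured points run x fastest
    vec = np.transpose(field3d.m, (3, 2, 1, 0)).reshape(-1, 3)
    msk = np.transpose(field3d.mask.astype(np.uint8), (2, 1, 0)).ravel()
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("giantmag magnetization field\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {ox:.9e} {oy:.9e} {oz:.9e}\n")
        fh.write(f"SPACING {h:.9e} {h:.9e} {h:.9e}\n")
        fh.write(f"POINT_DATA {n}\n")
        fh.write("VECTORS magnetization double\n")
        np.savetxt(fh, vec, fmt="%.9e")
        fh.write("SCALARS mask unsigned_char\nLOOKUP_TABLE default\n")
        np.savetxt(fh, msk[:, None], fmt="%d")


def read_vtk(path) -> VectorField3D:
    """Read a vector field written by :func:`write_vtk`."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    dims = spacing = origin = None
    i = 0
    vec = msk = None
    while i < len(lines):
        t = lines[i].split()
        if not t:
            i += 1
            continue
        key = t[0].upper()
        if key == "DIMENSIONS":
            dims = tuple(int(v) for v in t[1:4])
        elif key == "SPACING":
            spacing = float(t[1])
        elif key == "ORIGIN":
            origin = np.array([float(v) for v in t[1:4]])
        elif key == "VECTORS":
            n = dims[0] * dims[1] * dims[2]
            flat = " ".join(lines[i + 1:i + 1 + n]).split()
            vec = np.array(flat, dtype=float).reshape(n, 3)
            i += n
        elif key == "SCALARS":
            n = dims[0] * dims[1] * dims[2]
            flat = " ".join(lines[i + 2:i + 2 + n]).split()
            msk = np.array(flat, dtype=int).reshape(n)
            i += n + 1
        i += 1
    if dims is None or vec is None:
        raise ValueError(f"{path} is not a giantmag VTK field file")
    nx, ny, nz = dims
    m = np.transpose(vec.reshape(nz, ny, nx, 3), (3, 2, 1, 0))
    mask = (np.transpose(msk.reshape(nz, ny, nx), (2, 1, 0)) > 0
            if msk is not None else np.ones(dims, bool))
    return VectorField3D(m, mask, spacing, origin - spacing / 2.0)


def write_tilt_series(series: TiltSeries, basepath) -> None:
    """Write a tilt series as <base>.tif (+ <base>_charge.tif) and
    <base>.json metadata sidecar."""
    base = Path(basepath)
    tifffile.imwrite(base.with_suffix(".tif"),
                     series.images.astype(np.float32),
                     photometric="minisblack")
    if series.charge_images is not None:
        tifffile.imwrite(base.with_name(base.stem + "_charge.tif"),
                         series.charge_images.astype(np.float32),
                         photometric="minisblack")
    meta = dict(angles=series.angles.tolist(), axis_id=series.axis_id,
                pixel_size=series.pixel_size,
                applied_shifts=series.applied_shifts.tolist(),
                has_charge=series.charge_images is not None)
    base.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_tilt_series(basepath) -> TiltSeries:
    base = Path(basepath)
    meta = json.loads(base.with_suffix(".json").read_text())
    images = np.asarray(tifffile.imread(base.with_suffix(".tif")),
                        dtype=float)
    charge = None
    if meta.get("has_charge"):
        charge = np.asarray(
            tifffile.imread(base.with_name(base.stem + "_charge.tif")),
            dtype=float)
    return TiltSeries(images, np.array(meta["angles"]), meta["axis_id"],
                      meta["pixel_size"],
                      applied_shifts=np.array(meta["applied_shifts"]),
                      charge_images=charge)


def core_path_to_csv(core: CorePath, path) -> None:
    """Write a traced core path as CSV (z, x, y, polarization)."""
    df = pd.DataFrame(dict(z=core.points[:, 2], x=core.points[:, 0],
                           y=core.points[:, 1],
                           polarization=core.polarization.astype(int)))
    df.to_csv(path, index=False)
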