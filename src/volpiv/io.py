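"""Reading images/volumes and writing vector fields.

Volumes are multi-page grayscale TIFF stacks (page order = axis 0); images
are single-page TIFF or PNG.  Vector fields are written either as legacy
ASCII VTK structured-points datasets (openable in Paraview) or as CSV with
one row per grid cell.
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .core import VOXELS_PER_FRAME, VectorFieldResult
from .grid import GridGeometry

__all__ = [
    "read_volume",
    "write_volume",
    "write_vector_field",
    "read_vector_field_csv",
]

VTK_LEGACY = "vtk"
CSV = "csv"


def read_volume(path) -> np.ndarray:
    """Read a grayscale image (2D) or TIFF stack (3D) as float64.

    Multi-page TIFFs become volumes with the page index as axis 0; integer
    pixel types are cast to double exactly.  RGB(A) inputs are rejected.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        try:
            with tifffile.TiffFile(path) as tf:
                n_pages = len(tf.pages)
                arr = tf.asarray()
        except Exception as exc:  # corrupt file
            raise ValueError(f"could not read TIFF {path!r}: {exc}") from exc
        if arr.ndim == 3 and n_pages == 1:
            raise ValueError(f"{path!r} looks like an RGB image; grayscale input required")
        if arr.ndim not in (2, 3):
            raise ValueError(f"{path!r} has unsupported dimensionality {arr.ndim}")
    else:
        import imageio.v3 as iio

        try:
            arr = iio.imread(path)
        except Exception as exc:
            raise ValueError(f"could not read image {path!r}: {exc}") from exc
        if arr.ndim == 3:
            raise ValueError(f"{path!r} looks like an RGB image; grayscale input required")
    return np.asarray(arr, dtype=np.float64)


def write_volume(array: np.ndarray, path) -> None:
    """Write a 2D image or 3D volume as a (multi-page) TIFF."""
    tifffile.imwrite(os.fspath(path), np.asarray(array))


def _centers_voxels(grid: GridGeometry) -> np.ndarray:
    return grid.window_centers().reshape(-1, grid.ndim)


def write_vector_field(
    field: VectorFieldResult,
    path,
    format: str = VTK_LEGACY,
    voxel_pitch=None,
) -> None:
    """Write a vector field to disk.

    ``vtk``: legacy ASCII structured-points dataset with a 3-component
    vector attribute at the window centers; origin and spacing encode the
    grid geometry (times ``voxel_pitch`` when given) so Paraview displays
    physical coordinates.  ``csv``: one row per cell with grid indices,
    window-center coordinates (voxels of the analyzed volume), components
    and signal-to-noise, preceded by comment lines recording the grid.
    """
    fmt = str(format).lower().lstrip(".")
    if fmt in ("vtk", "vtk_legacy"):
        _write_vtk(field, path, voxel_pitch)
    elif fmt == "csv":
        _write_csv(field, path)
    else:
        raise ValueError(f"unknown vector-field format {format!r}")


def _components3(field: VectorFieldResult):
    comps = [field.vectors[d] for d in range(field.ndim)]
    while len(comps) < 3:
        comps.append(np.zeros(field.grid_shape))
    return comps


def _write_vtk(field: VectorFieldResult, path, voxel_pitch=None) -> None:
    grid = field.grid
    ndim = grid.ndim
    pitch = np.ones(ndim) if voxel_pitch is None else np.asarray(voxel_pitch, dtype=float)
    dims = list(field.grid_shape[::-1]) + [1] * (3 - ndim)
    centers0 = (np.asarray(grid.inter_size) - 1.0) / 2.0
    origin = list((centers0 * pitch)[::-1]) + [0.0] * (3 - ndim)
    spacing = list((np.asarray(grid.step) * pitch)[::-1]) + [1.0] * (3 - ndim)
    u, v, w = _components3(field)
    n = u.size
    lines = [
        "# vtk DataFile Version 3.0",
        "volpiv displacement field",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        "DIMENSIONS " + " ".join(str(d) for d in dims),
        "ORIGIN " + " ".join(f"{x:.9g}" for x in origin),
        "SPACING " + " ".join(f"{x:.9g}" for x in spacing),
        f"POINT_DATA {n}",
        "VECTORS displacement double",
    ]
    # VTK iterates x fastest; our axis order is (axis0, axis1[, axis2]) with
    # axis (ndim-1) stored fastest, mapped to VTK x — plain C-order ravel.
    vx, vy, vz = (w, v, u) if ndim == 3 else (v, u, np.zeros_like(u))
    for a, b, c in zip(vx.ravel(), vy.ravel(), vz.ravel()):
        lines.append(f"{a:.9g} {b:.9g} {c:.9g}")
    if field.sn is not None:
        lines.append("SCALARS ppr double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{x:.9g}" for x in field.sn.ravel())
    with open(os.fspath(path), "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _write_csv(field: VectorFieldResult, path) -> None:
    grid = field.grid
    ndim = grid.ndim
    idx = np.stack(np.meshgrid(*[np.arange(g) for g in field.grid_shape], indexing="ij"),
                   axis=-1).reshape(-1, ndim)
    centers = _centers_voxels(grid)
    u, v, w = _components3(field)
    data = {
        "i": idx[:, 0],
        "j": idx[:, 1],
        "k": idx[:, 2] if ndim == 3 else np.zeros(len(idx), dtype=int),
        "x": centers[:, 0],
        "y": centers[:, 1],
        "z": centers[:, 2] if ndim == 3 else np.zeros(len(idx)),
        "u": u.ravel(),
        "v": v.ravel(),
        "w": w.ravel(),
        "sn": (field.sn.ravel() if field.sn is not None else np.zeros(len(idx))),
    }
    header = [
        f"# volume_shape: {list(grid.volume_shape)}",
        f"# inter_size: {list(grid.inter_size)}",
        f"# step: {list(grid.step)}",
        f"# grid_shape: {list(grid.grid_shape)}",
        f"# units: {field.units}",
    ]
    with open(os.fspath(path), "w") as fh:
        fh.write("\n".join(header) + "\n")
        pd.DataFrame(data).to_csv(fh, index=False)


def read_vector_field_csv(path) -> VectorFieldResult:
    """Re-load a CSV vector field written by :func:`write_vector_field`."""
    meta = {}
    with open(os.fspath(path)) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
    import ast

    grid = GridGeometry(
        volume_shape=tuple(ast.literal_eval(meta["volume_shape"])),
        inter_size=tuple(ast.literal_eval(meta["inter_size"])),
        step=tuple(ast.literal_eval(meta["step"])),
        grid_shape=tuple(ast.literal_eval(meta["grid_shape"])),
    )
    df = pd.read_csv(os.fspath(path), comment="#")
    ndim = grid.ndim
    shape = grid.grid_shape
    comps = ["u", "v", "w"][:ndim]
    vectors = np.stack([df[c].to_numpy().reshape(shape) for c in comps])
    sn = df["sn"].to_numpy().reshape(shape)
    return VectorFieldResult(
        vectors=vectors, sn=sn, grid=grid, units=meta.get("units", VOXELS_PER_FRAME)
    )
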