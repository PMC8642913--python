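"""Interrogation-grid geometry and window extraction."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np


class GeometryError(ValueError):
    """Raised when interrogation windows cannot be placed inside a volume."""


@dataclass(frozen=True)
class GridGeometry:
    """Placement of interrogation windows inside a volume.

    Windows of shape ``inter_size`` are placed starting at the volume origin
    with stride ``step = inter_size - overlap`` per axis; trailing voxels
    that do not fit a full window are excluded.
    """

    volume_shape: Tuple[int, ...]
    inter_size: Tuple[int, ...]
    step: Tuple[int, ...]
    grid_shape: Tuple[int, ...]

    @property
    def ndim(self) -> int:
        return len(self.volume_shape)

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.grid_shape))

    def origin(self, cell: Sequence[int]) -> Tuple[int, ...]:
        """0-based corner coordinate of the interrogation window at ``cell``."""
        if len(cell) != self.ndim:
            raise ValueError(f"cell must have {self.ndim} indices")
        for c, g in zip(cell, self.grid_shape):
            if not 0 <= c < g:
                raise IndexError(f"cell {tuple(cell)} outside grid {self.grid_shape}")
        return tuple(int(c) * s for c, s in zip(cell, self.step))

    def window_origins(self) -> np.ndarray:
        """Array of shape ``grid_shape + (ndim,)`` with every window corner."""
        axes = [np.arange(g) * s for g, s in zip(self.grid_shape, self.step)]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack(mesh, axis=-1)

    def window_centers(self) -> np.ndarray:
        """Continuous window-center coordinates, shape ``grid_shape + (ndim,)``."""
        half = np.asarray(self.inter_size, dtype=float)
        return self.window_origins() + (half - 1.0) / 2.0


def grid_dimensions(
    volume_shape: Sequence[int],
    inter_size,
    overlap=0,
) -> GridGeometry:
    """Compute the interrogation-grid subdivision of a volume.

    Per axis the number of windows is
    ``floor((extent - inter) / (inter - overlap)) + 1``; e.g. a
    (60, 50, 50) volume with 16-voxel windows and no overlap subdivides
    into a 3x3x3 grid, and into 6x5x5 with 50% (8-voxel) overlap.
    """
    shape = tuple(int(s) for s in volume_shape)
    ndim = len(shape)
    if isinstance(inter_size, int):
        inter = (inter_size,) * ndim
    else:
        inter = tuple(int(i) for i in inter_size)
    if isinstance(overlap, int):
        over = (overlap,) * ndim
    else:
        over = tuple(int(o) for o in overlap)
    if len(inter) != ndim or len(over) != ndim:
        raise ValueError("inter_size/overlap dimensionality does not match volume")
    if any(o >= i for o, i in zip(over, inter)):
        raise GeometryError(f"overlap {over} must be < inter_size {inter} per axis")
    if any(i <= 0 for i in inter) or any(o < 0 for o in over):
        raise GeometryError("inter_size must be positive and overlap non-negative")
    if any(i > s for i, s in zip(inter, shape)):
        raise GeometryError(
            f"interrogation size {inter} exceeds volume shape {shape} on some axis"
        )
    step = tuple(i - o for i, o in zip(inter, over))
    grid = tuple((s - i) // st + 1 for s, i, st in zip(shape, inter, step))
    return GridGeometry(volume_shape=shape, inter_size=inter, step=step, grid_shape=grid)


def crop_pad(volume: np.ndarray, start: Sequence[int], shape: Sequence[int]) -> np.ndarray:
    """Crop ``volume[start : start + shape]``, zero-filling out-of-bounds parts."""
    start = tuple(int(s) for s in start)
    shape = tuple(int(s) for s in shape)
    out = np.zeros(shape, dtype=np.float64)
    src = []
    dst = []
    for st, sh, ext in zip(start, shape, volume.shape):
        lo = max(st, 0)
        hi = min(st + sh, ext)
        if lo >= hi:
            return out
        src.append(slice(lo, hi))
        dst.append(slice(lo - st, hi - st))
    out[tuple(dst)] = volume[tuple(src)]
    return out


def subsample_volume(volume: np.ndarray, factor) -> np.ndarray:
    """Keep every ``factor``-th voxel per axis (shape becomes ``ceil(extent/factor)``).

    Subsampling the inputs by a small factor accelerates a PIV analysis
    dramatically while preserving the direction of smooth motion fields;
    the interrogation size and overlap should be scaled down accordingly.
    """
    if isinstance(factor, int):
        factors = (factor,) * volume.ndim
    else:
        factors = tuple(int(f) for f in factor)
    if len(factors) != volume.ndim:
        raise ValueError("factor dimensionality does not match volume")
    if any(f < 1 for f in factors):
        raise ValueError("subsampling factor must be >= 1")
    return volume[tuple(slice(None, None, f) for f in factors)]
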