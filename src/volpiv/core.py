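"""Single-pass and multi-pass PIV over a pair of images or volumes.

The first input is tiled into interrogation windows (IV); for each IV a
search window (SV), enlarged by the search margin and optionally shifted by
a prior displacement estimate, is sampled from the second input.  The
translation maximizing the selected correlation score, refined to sub-voxel
precision, becomes the displacement vector of that grid cell.  With a
multi-pass factor f > 1 the analysis is repeated coarse-to-fine, earlier
rounds offsetting the search-window sampling of later rounds, which extends
the range of detectable displacements beyond half the final window size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from . import correlation, displacement as _disp
from .grid import GridGeometry, crop_pad, grid_dimensions
from .params import CorrMode, PIVParams, scale_parameters

__all__ = [
    "VolumePair",
    "VectorFieldResult",
    "extract_windows",
    "run_piv",
]


@dataclass(frozen=True)
class VolumePair:
    """Two same-shape scalar intensity arrays at consecutive time points."""

    vt: np.ndarray
    vt1: np.ndarray

    def __post_init__(self):
        vt = np.asarray(self.vt, dtype=np.float64)
        vt1 = np.asarray(self.vt1, dtype=np.float64)
        if vt.shape != vt1.shape:
            raise ValueError(f"volume shapes differ: {vt.shape} vs {vt1.shape}")
        if vt.ndim not in (2, 3):
            raise ValueError("inputs must be 2D images or 3D volumes")
        object.__setattr__(self, "vt", vt)
        object.__setattr__(self, "vt1", vt1)

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.vt.shape

    @property
    def ndim(self) -> int:
        return self.vt.ndim


VOXELS_PER_FRAME = "voxels_per_frame"
PHYSICAL = "physical"


@dataclass
class VectorFieldResult:
    """PIV displacement field on the interrogation grid.

    ``vectors`` has shape ``(ndim,) + grid_shape``; component ``u`` pairs
    with array axis 0, ``v`` with axis 1 and ``w`` with axis 2 (3D only).
    ``sn`` holds the per-vector primary peak ratio, with 0 at flagged
    (background / degenerate) cells marked in ``background``.
    """

    vectors: np.ndarray
    sn: Optional[np.ndarray]
    grid: GridGeometry
    units: str = VOXELS_PER_FRAME
    background: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.background is None:
            self.background = np.zeros(self.grid.grid_shape, dtype=bool)

    @property
    def ndim(self) -> int:
        return int(self.vectors.shape[0])

    @property
    def grid_shape(self) -> Tuple[int, ...]:
        return tuple(self.vectors.shape[1:])

    @property
    def u(self) -> np.ndarray:
        return self.vectors[0]

    @property
    def v(self) -> np.ndarray:
        return self.vectors[1]

    @property
    def w(self) -> np.ndarray:
        if self.ndim < 3:
            raise AttributeError("w component only exists for 3D fields")
        return self.vectors[2]

    def magnitude(self) -> np.ndarray:
        return np.sqrt(np.sum(self.vectors**2, axis=0))

    def copy(self) -> "VectorFieldResult":
        return VectorFieldResult(
            vectors=self.vectors.copy(),
            sn=None if self.sn is None else self.sn.copy(),
            grid=self.grid,
            units=self.units,
            background=self.background.copy(),
        )


def extract_windows(
    pair: VolumePair,
    cell,
    params: PIVParams,
    offset=None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Interrogation and search windows for one grid cell.

    The interrogation window is read from ``vt``; the search window from
    ``vt1``, enlarged by the search margin on all sides, centered on the
    interrogation footprint shifted by ``offset``, and zero-filled where it
    leaves the volume.
    """
    p = params.normalized(pair.ndim)
    geom = grid_dimensions(pair.shape, p.inter_size, p.overlap)
    origin = geom.origin(cell)
    if offset is None:
        offset = (0,) * pair.ndim
    iv = pair.vt[tuple(slice(o, o + n) for o, n in zip(origin, p.inter_size))]
    sv_start = tuple(
        o - m + int(f) for o, m, f in zip(origin, p.search_margin, offset)
    )
    sv_shape = tuple(n + 2 * m for n, m in zip(p.inter_size, p.search_margin))
    sv = crop_pad(pair.vt1, sv_start, sv_shape)
    return np.asarray(iv, dtype=np.float64), sv


def _clamp_offset(offset, origin, margin, inter, vol_shape):
    """Clamp an offset so the shifted search window still overlaps the volume."""
    out = []
    for off, o, m, n, ext in zip(offset, origin, margin, inter, vol_shape):
        start = o - m
        length = n + 2 * m
        lo = 1 - start - length  # keeps at least one voxel inside
        hi = ext - 1 - start
        out.append(int(np.clip(off, lo, hi)))
    return tuple(out)


def _single_pass(
    pair: VolumePair,
    params: PIVParams,
    geom: GridGeometry,
    offsets: Optional[np.ndarray],
) -> VectorFieldResult:
    ndim = pair.ndim
    p = params  # already normalized per-axis
    vectors = np.zeros((ndim,) + geom.grid_shape, dtype=np.float64)
    sn = np.zeros(geom.grid_shape, dtype=np.float64) if p.ppr_compute else None
    background = np.zeros(geom.grid_shape, dtype=bool)
    for cell in np.ndindex(*geom.grid_shape):
        origin = geom.origin(cell)
        off = (0,) * ndim if offsets is None else tuple(int(x) for x in offsets[(slice(None),) + cell])
        off = _clamp_offset(off, origin, p.search_margin, p.inter_size, pair.shape)
        iv = pair.vt[tuple(slice(o, o + n) for o, n in zip(origin, p.inter_size))]
        iv_max = float(iv.max()) if iv.size else 0.0
        if (p.background_threshold is not None and iv_max < p.background_threshold) or iv_max == 0.0:
            background[cell] = True
            continue
        sv_start = tuple(o - m + f for o, m, f in zip(origin, p.search_margin, off))
        sv_shape = tuple(n + 2 * m for n, m in zip(p.inter_size, p.search_margin))
        sv = crop_pad(pair.vt1, sv_start, sv_shape)
        C = correlation.correlate_windows(np.asarray(iv, dtype=np.float64), sv, p.corr_mode)
        peak = _disp.find_peak(C)
        vec = _disp.refine_peak(C, peak, p.subvoxel_mode)
        vectors[(slice(None),) + cell] = np.asarray(off, dtype=np.float64) + vec
        if sn is not None:
            sn[cell] = _disp.ppr(C, peak)
    return VectorFieldResult(vectors=vectors, sn=sn, grid=geom, background=background)


def _transfer_offsets(prev: VectorFieldResult, geom: GridGeometry) -> np.ndarray:
    """Integer search offsets for a finer grid, by nearest-cell lookup of the
    previous round's field at the new window centers."""
    prev_geom = prev.grid
    centers = geom.window_centers()  # grid_shape + (ndim,)
    prev_centers0 = (np.asarray(prev_geom.inter_size) - 1.0) / 2.0
    idx = np.rint(
        (centers - prev_centers0) / np.asarray(prev_geom.step, dtype=float)
    ).astype(np.int64)
    for d, g in enumerate(prev_geom.grid_shape):
        np.clip(idx[..., d], 0, g - 1, out=idx[..., d])
    gathered = prev.vectors[(slice(None),) + tuple(np.moveaxis(idx, -1, 0))]
    return np.rint(gathered).astype(np.int64)


def run_piv(pair: VolumePair, params: PIVParams) -> VectorFieldResult:
    """Run a (multi-pass) PIV analysis on a volume pair.

    Returns the displacement field in voxels/frame on the interrogation
    grid of the final round, with the per-vector primary peak ratio in
    ``sn`` when requested.  Cells skipped as background (window maximum
    below ``background_threshold``, or identically zero) carry a zero
    vector and are flagged.
    """
    if not isinstance(pair, VolumePair):
        pair = VolumePair(*pair)
    f = params.mpass_factor
    field: Optional[VectorFieldResult] = None
    for r in range(1, f + 1):
        p_r = scale_parameters(params, r, f).normalized(pair.ndim)
        geom = grid_dimensions(pair.shape, p_r.inter_size, p_r.overlap)
        offsets = None if field is None else _transfer_offsets(field, geom)
        field = _single_pass(pair, p_r, geom, offsets)
    assert field is not None
    return field
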