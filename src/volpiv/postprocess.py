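"""Vector-field post-processing: filtering, averaging, maps, trajectories.

All operators act on :class:`~volpiv.core.VectorFieldResult` grids and never
change the grid shape.  Neighborhoods are square/cubic windows of per-axis
radius r (window extent 2r+1), clipped at the field borders; clipped windows
use the clipped cell count.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from enum import Enum
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .core import PHYSICAL, VOXELS_PER_FRAME, VectorFieldResult

__all__ = [
    "Neighborhood",
    "Replacement",
    "filter_ppr",
    "filter_magnitude",
    "replace_vectors",
    "average_spatial",
    "average_spatiotemporal",
    "average_similarity_selective",
    "velocity_map",
    "divergence_map",
    "collectiveness_map",
    "Trajectory",
    "pseudo_trajectories",
    "to_physical_units",
]


@dataclass(frozen=True)
class Neighborhood:
    """Per-axis radii (grid cells) and temporal extent of a local window."""

    radii: Tuple[int, ...]
    n_t: int = 0

    def __post_init__(self):
        if any(r < 0 for r in self.radii) or self.n_t < 0:
            raise ValueError("radii and n_t must be >= 0")

    @classmethod
    def of(cls, radius, ndim: int, n_t: int = 0) -> "Neighborhood":
        if isinstance(radius, Neighborhood):
            return radius
        if isinstance(radius, int):
            return cls((radius,) * ndim, n_t)
        return cls(tuple(int(r) for r in radius), n_t)

    def footprint(self) -> Tuple[int, ...]:
        return tuple(2 * r + 1 for r in self.radii)


class Replacement(str, Enum):
    """How filtered-out vectors are re-filled."""

    ZERO = "zero"
    MEAN = "mean"
    MEDIAN = "median"


def _box_sum(arr: np.ndarray, radii) -> np.ndarray:
    size = tuple(2 * r + 1 for r in radii)
    return ndimage.uniform_filter(arr, size=size, mode="constant", cval=0.0) * float(np.prod(size))


def _box_count(shape, radii) -> np.ndarray:
    return _box_sum(np.ones(shape), radii)


def _iter_window(cell, radii, shape):
    slices = tuple(
        slice(max(c - r, 0), min(c + r + 1, s)) for c, r, s in zip(cell, radii, shape)
    )
    return slices


def replace_vectors(
    field: VectorFieldResult,
    mask: np.ndarray,
    scheme: Replacement = Replacement.ZERO,
    radius=1,
) -> VectorFieldResult:
    """Replace the vectors selected by ``mask`` according to ``scheme``.

    MEAN/MEDIAN are computed componentwise over the non-masked neighbors in
    the clipped window; a masked vector with no valid neighbor becomes zero.
    """
    scheme = Replacement(scheme)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != field.grid_shape:
        raise ValueError("mask shape must equal the grid shape")
    out = field.copy()
    if scheme is Replacement.ZERO:
        out.vectors[:, mask] = 0.0
        return out
    nb = Neighborhood.of(radius, len(field.grid_shape))
    for cell in zip(*np.nonzero(mask)):
        win = _iter_window(cell, nb.radii, field.grid_shape)
        valid = ~mask[win]
        if not np.any(valid):
            out.vectors[(slice(None),) + cell] = 0.0
            continue
        neighborhood = field.vectors[(slice(None),) + win]
        vals = neighborhood[:, valid]
        if scheme is Replacement.MEAN:
            out.vectors[(slice(None),) + cell] = vals.mean(axis=1)
        else:
            out.vectors[(slice(None),) + cell] = np.median(vals, axis=1)
    return out


def filter_ppr(
    field: VectorFieldResult,
    threshold: float,
    replacement: Replacement = Replacement.ZERO,
    radius=1,
) -> Tuple[VectorFieldResult, np.ndarray]:
    """Discard vectors whose primary peak ratio is below ``threshold``.

    Returns the filtered field and the discard mask.
    """
    if field.sn is None:
        raise ValueError("field has no signal-to-noise grid (run PIV with ppr_compute)")
    mask = field.sn < threshold
    return replace_vectors(field, mask, replacement, radius), mask


def filter_magnitude(
    field: VectorFieldResult,
    low: Optional[float] = None,
    high: Optional[float] = None,
    nsigma_global: Optional[float] = None,
    nsigma_local: Optional[float] = None,
    radius=1,
    replacement: Replacement = Replacement.ZERO,
) -> Tuple[VectorFieldResult, np.ndarray]:
    """Filter vectors by magnitude (low/high pass and global/local sigma rules).

    ``low``/``high`` discard magnitudes below/above the cutoffs (their
    conjunction is a band-pass); the sigma rules discard vectors whose
    magnitude is more than n standard deviations from the mean magnitude of
    the whole field (global) or of the clipped neighborhood (local).  All
    given criteria are OR-combined into one discard mask.
    """
    if low is None and high is None and nsigma_global is None and nsigma_local is None:
        raise ValueError("at least one filtering criterion is required")
    mag = field.magnitude()
    mask = np.zeros(mag.shape, dtype=bool)
    if low is not None:
        mask |= mag < low
    if high is not None:
        mask |= mag > high
    if nsigma_global is not None:
        mu, sigma = float(mag.mean()), float(mag.std())
        mask |= np.abs(mag - mu) > nsigma_global * sigma
    if nsigma_local is not None:
        nb = Neighborhood.of(radius, mag.ndim)
        counts = _box_count(mag.shape, nb.radii)
        local_mu = _box_sum(mag, nb.radii) / counts
        local_var = _box_sum(mag**2, nb.radii) / counts - local_mu**2
        local_sigma = np.sqrt(np.maximum(local_var, 0.0))
        mask |= np.abs(mag - local_mu) > nsigma_local * local_sigma
    return replace_vectors(field, mask, replacement, radius), mask


def average_spatial(field: VectorFieldResult, radius=1) -> VectorFieldResult:
    """Replace each component by its mean over the clipped neighborhood."""
    nb = Neighborhood.of(radius, len(field.grid_shape))
    out = field.copy()
    counts = _box_count(field.grid_shape, nb.radii)
    for d in range(field.ndim):
        out.vectors[d] = _box_sum(field.vectors[d], nb.radii) / counts
    return out


def average_spatiotemporal(
    fields: Sequence[VectorFieldResult], radius=1, n_t: int = 1
) -> List[VectorFieldResult]:
    """Average a time-ordered field sequence over space and time.

    Each output frame t is the mean over the clipped spatial neighborhood
    across frames t - n_t ... t + n_t (clipped at the sequence ends).
    """
    if len(fields) < 2:
        raise ValueError("need at least two fields for spatio-temporal averaging")
    shape = fields[0].grid_shape
    if any(f.grid_shape != shape for f in fields):
        raise ValueError("all fields must share the same grid shape")
    nb = Neighborhood.of(radius, len(shape))
    counts = _box_count(shape, nb.radii)
    sums = [
        np.stack([_box_sum(f.vectors[d], nb.radii) for d in range(f.ndim)])
        for f in fields
    ]
    out = []
    for t, f in enumerate(fields):
        lo, hi = max(t - n_t, 0), min(t + n_t, len(fields) - 1)
        total = sum(sums[s] for s in range(lo, hi + 1))
        res = f.copy()
        res.vectors = total / (counts[None] * (hi - lo + 1))
        out.append(res)
    return out


def _unit_vectors(vectors: np.ndarray):
    norms = np.sqrt(np.sum(vectors**2, axis=0))
    nonzero = norms > 0
    unit = np.zeros_like(vectors)
    np.divide(vectors, norms[None], where=nonzero[None], out=unit)
    return unit, nonzero


def average_similarity_selective(
    field: VectorFieldResult, radius=1, sim_threshold: float = 0.5
) -> VectorFieldResult:
    """Average each vector among its similar neighbors only.

    Two vectors are similar when their normalized dot product exceeds
    ``sim_threshold`` (zero vectors are never similar to anything but count
    toward the neighbor total).  The output direction is the unit-normalized
    mean of the similar neighbors (the center vector included); the output
    magnitude is the fraction of similar neighbors among all neighbors in
    the clipped window (center excluded from both counts), i.e. the local
    collectiveness.  Unlike plain averaging this neither dissolves vectors
    at tissue/background boundaries nor invents flow in incoherent regions.
    """
    shape = field.grid_shape
    nb = Neighborhood.of(radius, len(shape))
    unit, nonzero = _unit_vectors(field.vectors)
    out = field.copy()
    for cell in np.ndindex(*shape):
        win = _iter_window(cell, nb.radii, shape)
        u_c = unit[(slice(None),) + cell]
        win_unit = unit[(slice(None),) + win].reshape(field.ndim, -1)
        win_vecs = field.vectors[(slice(None),) + win].reshape(field.ndim, -1)
        win_nonzero = nonzero[win].ravel()
        # locate the center inside the flattened window to exclude it
        local = tuple(c - w.start for c, w in zip(cell, win))
        win_dims = tuple(w.stop - w.start for w in win)
        center_flat = int(np.ravel_multi_index(local, win_dims))
        total = win_unit.shape[1] - 1
        if total == 0:
            out.vectors[(slice(None),) + cell] = 0.0
            continue
        if not nonzero[cell]:
            out.vectors[(slice(None),) + cell] = 0.0
            continue
        dots = u_c @ win_unit
        similar = (dots > sim_threshold) & win_nonzero
        similar[center_flat] = False
        n_similar = int(np.count_nonzero(similar))
        mean_vec = field.vectors[(slice(None),) + cell] + win_vecs[:, similar].sum(axis=1)
        norm = float(np.sqrt(np.sum(mean_vec**2)))
        direction = mean_vec / norm if norm > 0 else np.zeros(field.ndim)
        out.vectors[(slice(None),) + cell] = direction * (n_similar / total)
    return out


def velocity_map(field: VectorFieldResult) -> np.ndarray:
    """Per-cell Euclidean magnitude of the vector field."""
    return field.magnitude()


def divergence_template(cube_size: int, ndim: int) -> np.ndarray:
    """Cube of unit vectors pointing radially outward from its center."""
    if cube_size % 2 == 0 or cube_size < 3:
        raise ValueError("cube_size must be odd and >= 3")
    r = cube_size // 2
    axes = [np.arange(-r, r + 1, dtype=float)] * ndim
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"))
    norms = np.sqrt(np.sum(mesh**2, axis=0))
    template = np.zeros_like(mesh)
    np.divide(mesh, norms[None], where=norms[None] > 0, out=template)
    return template


def divergence_map(field: VectorFieldResult, cube_size: int = 3) -> np.ndarray:
    """Source/sink map by correlating a radial template with the unit field.

    The field is normalized per vector (zeros stay zero) and cross-correlated
    componentwise with a cube of unit vectors diverging from its center
    (center cell zero).  Positive responses mark sources, negative sinks;
    ``cube_size`` sets the spatial scale probed.
    """
    template = divergence_template(cube_size, field.ndim)
    unit, _ = _unit_vectors(field.vectors)
    out = np.zeros(field.grid_shape)
    for d in range(field.ndim):
        out += ndimage.correlate(unit[d], template[d], mode="constant", cval=0.0)
    return out


def collectiveness_map(
    field: VectorFieldResult, radius=1, sim_threshold: float = 0.5
) -> np.ndarray:
    """Fraction of neighbors moving in a similar direction, per cell.

    Similarity is a normalized dot product above ``sim_threshold``; the
    window is clipped at borders and the center cell is excluded.  Zero
    vectors are never similar but count toward the total.
    """
    shape = field.grid_shape
    nb = Neighborhood.of(radius, len(shape))
    unit, nonzero = _unit_vectors(field.vectors)
    out = np.zeros(shape)
    for cell in np.ndindex(*shape):
        win = _iter_window(cell, nb.radii, shape)
        win_unit = unit[(slice(None),) + win].reshape(field.ndim, -1)
        win_nonzero = nonzero[win].ravel()
        local = tuple(c - w.start for c, w in zip(cell, win))
        win_dims = tuple(w.stop - w.start for w in win)
        center_flat = int(np.ravel_multi_index(local, win_dims))
        total = win_unit.shape[1] - 1
        if total == 0 or not nonzero[cell]:
            continue
        dots = unit[(slice(None),) + cell] @ win_unit
        similar = (dots > sim_threshold) & win_nonzero
        similar[center_flat] = False
        out[cell] = np.count_nonzero(similar) / total
    return out


@dataclass
class Trajectory:
    """Path of one advected pseudo-particle in continuous grid coordinates."""

    positions: np.ndarray  # (steps + 1, ndim)
    t_start: int
    alive: bool = True


def pseudo_trajectories(
    fields: Sequence[VectorFieldResult],
    n_particles: int,
    t_start: int = 0,
    t_end: Optional[int] = None,
    region=None,
    seed: int = 0,
) -> List[Trajectory]:
    """Advect randomly seeded particles through a sequence of PIV fields.

    Particles start uniformly distributed in ``region`` (pairs of per-axis
    (low, high) bounds in grid coordinates; default the whole grid).  At
    every step the particle position is rounded to the nearest grid cell to
    sample a displacement, which then shifts the particle.  Particles whose
    rounded position leaves the grid are frozen and flagged not alive.
    """
    if t_end is None:
        t_end = len(fields)
    if not 0 <= t_start < t_end <= len(fields):
        raise ValueError("need 0 <= t_start < t_end <= len(fields)")
    shape = fields[0].grid_shape
    ndim = len(shape)
    if region is None:
        lows = np.zeros(ndim)
        highs = np.asarray(shape, dtype=float) - 1.0
    else:
        lows = np.asarray([r[0] for r in region], dtype=float)
        highs = np.asarray([r[1] for r in region], dtype=float)
    if np.any(highs < lows) or np.any(lows < 0) or np.any(highs > np.asarray(shape) - 1):
        raise ValueError("region must be a non-empty box inside the grid")
    rng = np.random.default_rng(seed)
    pos = rng.uniform(lows, highs, size=(int(n_particles), ndim))
    trajs = [Trajectory(positions=p[None].copy(), t_start=t_start) for p in pos]
    for t in range(t_start, t_end):
        f = fields[t]
        for traj in trajs:
            last = traj.positions[-1]
            if not traj.alive:
                traj.positions = np.vstack([traj.positions, last])
                continue
            cell = np.rint(last).astype(int)
            if np.any(cell < 0) or np.any(cell >= np.asarray(shape)):
                traj.alive = False
                traj.positions = np.vstack([traj.positions, last])
                continue
            step = f.vectors[(slice(None),) + tuple(cell)]
            traj.positions = np.vstack([traj.positions, last + step])
    return trajs


def to_physical_units(
    field: VectorFieldResult, voxel_pitch, frame_interval: float
) -> VectorFieldResult:
    """Convert a voxels-per-frame field to physical units.

    Component d is scaled by ``voxel_pitch[d] / frame_interval`` (pitch may
    be anisotropic); converting an already-physical field is an error.
    """
    if field.units == PHYSICAL:
        raise ValueError("field is already in physical units")
    pitch = (
        (float(voxel_pitch),) * field.ndim
        if isinstance(voxel_pitch, (int, float))
        else tuple(float(p) for p in voxel_pitch)
    )
    if len(pitch) != field.ndim:
        raise ValueError("voxel_pitch dimensionality mismatch")
    if any(p <= 0 for p in pitch) or frame_interval <= 0:
        raise ValueError("pitch and frame_interval must be positive")
    out = field.copy()
    for d in range(field.ndim):
        out.vectors[d] *= pitch[d] / float(frame_interval)
    out.units = PHYSICAL
    return out
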