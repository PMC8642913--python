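"""Parameter types for a PIV analysis.

Coordinate convention used throughout the package: arrays are indexed in
storage order, axis 0 first.  In 2D a field has components (u, v) paired
with axes (0, 1); in 3D (u, v, w) pair with axes (0, 1, 2).  All sizes,
margins and overlaps are expressed per axis in voxels (pixels in 2D).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence, Tuple, Union


class CorrMode(str, Enum):
    """Correlation normalization used for template matching.

    UNNORM is the plain frequency-domain cross-correlation; ZNCC is
    zero-normalized cross-correlation (invariant to affine intensity
    changes of either window); NSQECC is the inverse-form normalized
    squared-error cross-correlation, 1/(1 + NSQECC), whose maximum marks
    the translation minimizing the squared differences.
    """

    UNNORM = "unnorm"
    ZNCC = "zncc"
    NSQECC = "nsqecc"


class SubvoxelMode(str, Enum):
    """Sub-voxel refinement of the integer correlation peak."""

    NONE = "none"
    CENTROID = "centroid"
    GAUSSIAN = "gaussian"


IntPerAxis = Union[int, Sequence[int]]


def _per_axis(value, ndim: int, name: str) -> Tuple[int, ...]:
    if isinstance(value, (int,)):
        return (int(value),) * ndim
    out = tuple(int(v) for v in value)
    if len(out) != ndim:
        raise ValueError(f"{name} must be a scalar or length-{ndim} sequence, got {value!r}")
    return out


def _float_per_axis(value, ndim: int, name: str) -> Tuple[float, ...]:
    if isinstance(value, (int, float)):
        return (float(value),) * ndim
    out = tuple(float(v) for v in value)
    if len(out) != ndim:
        raise ValueError(f"{name} must be a scalar or length-{ndim} sequence, got {value!r}")
    return out


@dataclass(frozen=True)
class PIVParams:
    """Full parameter set of a PIV analysis.

    Parameters
    ----------
    inter_size:
        Interrogation window size per axis (voxels).  The first volume is
        tiled into windows of this size.
    search_margin:
        Extra border added to the search window on all sides (voxels),
        countering out-of-frame loss.  The search window has shape
        ``inter_size + 2 * search_margin``.
    overlap:
        Overlap between adjacent interrogation windows (voxels); must be
        strictly smaller than ``inter_size`` on every axis.
    mpass_factor:
        Multi-pass factor ``f >= 1``.  ``f`` rounds are run coarse-to-fine;
        round ``r`` scales interrogation size, margin and overlap by
        ``(1 + f - r)``, and earlier displacements offset later search
        windows.
    corr_mode, subvoxel_mode:
        Correlation normalization and sub-voxel peak refinement.
    background_threshold:
        If set, interrogation windows whose maximum intensity is below the
        threshold are skipped (zero vector, flagged).
    ppr_compute:
        Whether to compute the primary peak ratio (signal-to-noise) grid.
    voxel_pitch, frame_interval:
        Optional physical calibration (length per voxel per axis, time per
        frame) used when converting a field to physical units.
    """

    inter_size: IntPerAxis = 32
    search_margin: IntPerAxis = 0
    overlap: IntPerAxis = 0
    mpass_factor: int = 1
    corr_mode: CorrMode = CorrMode.NSQECC
    subvoxel_mode: SubvoxelMode = SubvoxelMode.GAUSSIAN
    background_threshold: Optional[float] = None
    ppr_compute: bool = True
    voxel_pitch: Optional[Sequence[float]] = None
    frame_interval: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "corr_mode", CorrMode(self.corr_mode))
        object.__setattr__(self, "subvoxel_mode", SubvoxelMode(self.subvoxel_mode))
        if int(self.mpass_factor) < 1:
            raise ValueError("mpass_factor must be >= 1")
        object.__setattr__(self, "mpass_factor", int(self.mpass_factor))

    def normalized(self, ndim: int) -> "PIVParams":
        """Return a copy with all per-axis fields expanded to ``ndim``-tuples,
        validated."""
        inter = _per_axis(self.inter_size, ndim, "inter_size")
        margin = _per_axis(self.search_margin, ndim, "search_margin")
        overlap = _per_axis(self.overlap, ndim, "overlap")
        if any(i <= 0 for i in inter):
            raise ValueError(f"inter_size must be positive, got {inter}")
        if any(m < 0 for m in margin):
            raise ValueError(f"search_margin must be >= 0, got {margin}")
        if any(o < 0 for o in overlap):
            raise ValueError(f"overlap must be >= 0, got {overlap}")
        if any(o >= i for o, i in zip(overlap, inter)):
            raise ValueError(
                f"overlap must be strictly smaller than inter_size per axis "
                f"(got overlap={overlap}, inter_size={inter})"
            )
        pitch = None
        if self.voxel_pitch is not None:
            pitch = _float_per_axis(self.voxel_pitch, ndim, "voxel_pitch")
            if any(p <= 0 for p in pitch):
                raise ValueError("voxel_pitch must be positive")
        if self.frame_interval is not None and float(self.frame_interval) <= 0:
            raise ValueError("frame_interval must be positive")
        return dataclasses.replace(
            self, inter_size=inter, search_margin=margin, overlap=overlap, voxel_pitch=pitch
        )


def scale_parameters(params: PIVParams, round_index: int, factor: int) -> PIVParams:
    """Scale interrogation size, search margin and overlap for a multi-pass round.

    In round ``r`` of ``f`` total rounds each of the three geometric
    parameters kappa_0 becomes ``(1 + f - r) * kappa_0``; the final round
    (``r == f``) runs at the user-defined values.  All other fields are
    unchanged.
    """
    if not 1 <= round_index <= factor:
        raise ValueError(f"round_index must be in [1, {factor}], got {round_index}")
    s = 1 + factor - round_index

    def scaled(value):
        if isinstance(value, int):
            return s * value
        return tuple(s * int(v) for v in value)

    return dataclasses.replace(
        params,
        inter_size=scaled(params.inter_size),
        search_margin=scaled(params.search_margin),
        overlap=scaled(params.overlap),
    )
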