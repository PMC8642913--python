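"""Peak detection, sub-voxel refinement and signal-to-noise scoring.

A displacement vector is read off a correlation matrix as the vector from
the matrix center to its maximum peak.  The integer peak can be refined to
sub-voxel precision from its direct neighbors along each axis, either with
the centroid formula

    delta = (C[x+d] - C[x-d]) / (C[x+d] + C[x] + C[x-d])

or the 3-point Gaussian fit

    delta = (ln C[x-d] - ln C[x+d]) / (2 ln C[x+d] - 4 ln C[x] + 2 ln C[x-d]),

the vertex of the parabola through the log-samples (a peak truly centered
at x + delta returns +delta), which is exact when the peak profile is Gaussian (the case for Gaussian
particles, whose correlation is again Gaussian).  The Gaussian fit needs
three strictly positive samples; otherwise it falls back to the centroid
formula on that axis, with a flag.

The primary peak ratio PPR = C_max1 / C_max2 measures the specificity of
each vector; C_max2 is the highest score outside the 3-per-axis
neighborhood of the primary peak.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .correlation import CorrelationMatrix
from .params import SubvoxelMode

#: reported PPR when no meaningful (positive) secondary peak exists
PPR_CAP = 1e6

_EPS = 1e-300


@dataclass
class PeakInfo:
    """Primary/secondary peak of a correlation matrix."""

    index: Tuple[int, ...]
    value: float
    secondary_value: Optional[float]
    displacement: np.ndarray
    degenerate: bool = False


@dataclass
class SubvoxelDelta:
    """Per-axis fractional refinement of an integer peak."""

    delta: np.ndarray
    method: SubvoxelMode
    fallback_used: bool = False


def find_peak(C: CorrelationMatrix) -> PeakInfo:
    """Locate the primary and secondary peaks inside the allowed search region.

    Ties are broken toward the lexicographically smallest index (the first
    occurrence in C storage order).  The secondary peak is the maximum
    outside the 3^D neighborhood centered on the primary.  An all-equal
    region yields a degenerate peak at the matrix center.
    """
    if C.scores.size == 0:
        raise ValueError("empty correlation matrix")
    region = C.search_slices()
    sub = C.scores[region]
    offsets = tuple(s.start for s in region)
    center = np.asarray(C.center)
    allowed = None if C.valid_mask is None else C.valid_mask[region]
    in_range = sub if allowed is None else sub[allowed]
    if C.degenerate or in_range.size == 0 or np.all(in_range == in_range.flat[0]):
        value = float(in_range.flat[0]) if in_range.size else 0.0
        return PeakInfo(
            index=tuple(C.center), value=value, secondary_value=value,
            displacement=np.zeros(C.ndim, dtype=np.int64), degenerate=True,
        )
    search = sub if allowed is None else np.where(allowed, sub, -np.inf)
    local = np.unravel_index(np.argmax(search), search.shape)
    index = tuple(int(l + o) for l, o in zip(local, offsets))
    value = float(sub[local])
    # exclude the 3-per-axis neighborhood of the primary from the secondary scan
    masked = search.copy() if allowed is not None else sub.copy()
    excl = tuple(
        slice(max(l - 1, 0), min(l + 2, s)) for l, s in zip(local, sub.shape)
    )
    masked[excl] = -np.inf
    secondary = float(np.max(masked)) if np.any(np.isfinite(masked)) else None
    displacement = np.asarray(index) - center
    return PeakInfo(index=index, value=value, secondary_value=secondary,
                    displacement=displacement)


def ppr(C: CorrelationMatrix, peak: Optional[PeakInfo] = None) -> float:
    """Primary peak ratio C_max1 / C_max2 (>= 1 for a positive secondary).

    When the secondary peak is absent or non-positive the ratio is reported
    as the capped sentinel ``PPR_CAP``; an all-equal matrix scores 1.
    """
    if peak is None:
        peak = find_peak(C)
    if peak.degenerate:
        return 1.0
    if peak.secondary_value is None or peak.secondary_value <= 0.0:
        return PPR_CAP
    return min(peak.value / peak.secondary_value, PPR_CAP)


def _neighbors(C: CorrelationMatrix, peak: PeakInfo, axis: int):
    """(C[x-d], C[x], C[x+d]) along ``axis``, or None at the matrix border."""
    idx = peak.index
    if idx[axis] == 0 or idx[axis] == C.scores.shape[axis] - 1:
        return None
    lo = list(idx); lo[axis] -= 1
    hi = list(idx); hi[axis] += 1
    return (float(C.scores[tuple(lo)]), float(C.scores[tuple(idx)]),
            float(C.scores[tuple(hi)]))


def _centroid_axis(trio) -> Tuple[float, bool]:
    c_m, c_0, c_p = trio
    den = c_p + c_0 + c_m
    if abs(den) < 1e-12 * max(abs(c_p), abs(c_0), abs(c_m), _EPS):
        return 0.0, True
    return float(np.clip((c_p - c_m) / den, -0.999, 0.999)), False


def subvoxel_centroid(C: CorrelationMatrix, peak: PeakInfo) -> SubvoxelDelta:
    """Centroid-based fractional refinement; border peaks get delta 0, flagged."""
    delta = np.zeros(C.ndim)
    fallback = False
    for ax in range(C.ndim):
        trio = _neighbors(C, peak, ax)
        if trio is None:
            fallback = True
            continue
        delta[ax], flagged = _centroid_axis(trio)
        fallback = fallback or flagged
    return SubvoxelDelta(delta=delta, method=SubvoxelMode.CENTROID, fallback_used=fallback)


def subvoxel_gaussian(C: CorrelationMatrix, peak: PeakInfo) -> SubvoxelDelta:
    """3-point Gaussian fractional refinement.

    Falls back per axis to the centroid formula when any of the three
    samples is non-positive, and to delta 0 at borders or for flat
    log-profiles; every fallback sets the flag.
    """
    delta = np.zeros(C.ndim)
    fallback = False
    for ax in range(C.ndim):
        trio = _neighbors(C, peak, ax)
        if trio is None:
            fallback = True
            continue
        c_m, c_0, c_p = trio
        if min(c_m, c_0, c_p) <= 0.0:
            delta[ax], _ = _centroid_axis(trio)
            fallback = True
            continue
        lm, l0, lp = np.log(c_m), np.log(c_0), np.log(c_p)
        # log-parabola vertex: exact for a Gaussian peak profile
        den = 2.0 * lp - 4.0 * l0 + 2.0 * lm
        if abs(den) < 1e-12:
            fallback = True
            continue
        delta[ax] = float(np.clip((lm - lp) / den, -0.999, 0.999))
    return SubvoxelDelta(delta=delta, method=SubvoxelMode.GAUSSIAN, fallback_used=fallback)


def refine_peak(C: CorrelationMatrix, peak: PeakInfo, mode: SubvoxelMode) -> np.ndarray:
    """Total (integer + fractional) displacement for the requested mode."""
    mode = SubvoxelMode(mode)
    disp = peak.displacement.astype(np.float64)
    if mode is SubvoxelMode.NONE or peak.degenerate:
        return disp
    if mode is SubvoxelMode.CENTROID:
        return disp + subvoxel_centroid(C, peak).delta
    return disp + subvoxel_gaussian(C, peak).delta
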