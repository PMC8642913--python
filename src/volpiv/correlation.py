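"""Cross-correlation matrices for window pairs.

Three template-matching scores are implemented for an interrogation window
``iv`` (shape ``n``) and a search window ``sv`` (shape ``m >= n``):

* plain (unnormalized) cross-correlation, computed in the frequency domain;
* ZNCC, zero-normalized cross-correlation, computed with one frequency-domain
  correlation for the numerator and integral-array box sums for the
  per-translation denominators (the Lewis fast normalized correlation scheme);
* NSQECC in its inverse form ``1 / (1 + NSQECC)``, decomposed into the
  constant ``sum(iv^2)``, the per-translation ``sum(sv^2)`` from an integral
  array, and ``-2 * (iv x sv)`` from one frequency-domain correlation.

All scores are laid out on the full linear correlation support: index ``i``
along an axis corresponds to the lag ``i - (n - 1)`` of ``sv`` relative to
``iv``.  For a PIV window pair (``m = n + 2 * margin``) the zero-displacement
index is the matrix center ``n - 1 + margin``, and the peak search is
restricted to displacements with at least 50% per-axis overlap,
``|s| <= margin + n // 2``.

FFT work lengths are rounded up to products of small primes
(`scipy.fft.next_fast_len`), since FFT run time spikes at prime sizes.
Accumulation is always done in double precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Optional, Tuple

import numpy as np
import scipy.fft

from .params import CorrMode

#: variance below this fraction of the mean-square is treated as constant
_VAR_RTOL = 1e-8


@dataclass
class CorrelationMatrix:
    """Cross-correlation scores indexed by candidate translation.

    ``scores[i]`` corresponds to translation ``i - center`` (per axis);
    ``max_displacement`` bounds the arg-max search (``None`` = whole matrix);
    ``degenerate`` flags constant/zero interrogation windows.
    """

    scores: np.ndarray
    center: Tuple[int, ...]
    mode: CorrMode
    max_displacement: Optional[Tuple[int, ...]] = None
    degenerate: bool = False
    valid_mask: Optional[np.ndarray] = None

    @property
    def ndim(self) -> int:
        return self.scores.ndim

    def search_slices(self) -> Tuple[slice, ...]:
        """Slices delimiting the bounding box of the allowed peak-search region."""
        if self.max_displacement is None:
            return tuple(slice(0, s) for s in self.scores.shape)
        out = []
        for c, d, s in zip(self.center, self.max_displacement, self.scores.shape):
            out.append(slice(max(c - d, 0), min(c + d + 1, s)))
        return tuple(out)


def _linear_correlate(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Full linear cross-correlation ``out[s] = sum_x a[x] * b[x + s]``.

    Computed as ``IFFT(conj(FFT(a)) * FFT(b))`` on a zero-padded grid; the
    result has shape ``a.shape + b.shape - 1`` with lag ``i - (n_a - 1)``
    at index ``i``.
    """
    if a.size == 0 or b.size == 0:
        raise ValueError("cannot correlate empty arrays")
    if a.ndim != b.ndim:
        raise ValueError("arrays must have the same dimensionality")
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    full = tuple(na + nb - 1 for na, nb in zip(a.shape, b.shape))
    fshape = tuple(scipy.fft.next_fast_len(s) for s in full)
    fa = scipy.fft.rfftn(a, fshape)
    fb = scipy.fft.rfftn(b, fshape)
    cc = scipy.fft.irfftn(np.conj(fa) * fb, fshape)
    # negative lags wrap to the top of the circular result; roll them in front
    cc = np.roll(cc, shift=tuple(na - 1 for na in a.shape), axis=tuple(range(a.ndim)))
    return cc[tuple(slice(0, f) for f in full)]


def fft_cross_correlate(a: np.ndarray, b: np.ndarray) -> CorrelationMatrix:
    """Unnormalized frequency-domain cross-correlation of two arrays.

    The returned matrix covers every linear lag; its ``center`` marks zero
    lag (``a`` and ``b`` origins aligned).
    """
    scores = _linear_correlate(a, b)
    center = tuple(na - 1 for na in np.shape(a))
    return CorrelationMatrix(scores=scores, center=center, mode=CorrMode.UNNORM)


class IntegralArray:
    """Cumulative-sum table answering box sums in constant time.

    The table is padded with a zero layer so a D-dimensional box sum costs
    ``2^D`` reads (8 in 3D) combined by inclusion-exclusion.
    """

    def __init__(self, values: np.ndarray, squared: bool = False):
        values = np.asarray(values, dtype=np.float64)
        if squared:
            values = values * values
        table = values
        for ax in range(values.ndim):
            table = np.cumsum(table, axis=ax)
        self.table = np.pad(table, [(1, 0)] * values.ndim)
        self.shape = values.shape

    def box_sum(self, start, stop) -> float:
        """Sum of the source over the half-open box ``[start, stop)``."""
        start = tuple(int(s) for s in start)
        stop = tuple(int(s) for s in stop)
        ndim = len(self.shape)
        total = 0.0
        for corner in product((0, 1), repeat=ndim):
            idx = tuple(stop[d] if corner[d] else start[d] for d in range(ndim))
            sign = (-1) ** (ndim - sum(corner))
            total += sign * self.table[idx]
        return float(total)

    def sliding_sums(self, box_shape) -> np.ndarray:
        """Box sums of every in-bounds placement of a ``box_shape`` window.

        Output shape is ``source_shape - box_shape + 1``; entry ``p`` is the
        sum over ``[p, p + box_shape)``.
        """
        box = tuple(int(b) for b in box_shape)
        out = self.table
        for ax, b in enumerate(box):
            n = self.shape[ax]
            hi = out.take(np.arange(b, n + 1), axis=ax)
            lo = out.take(np.arange(0, n + 1 - b), axis=ax)
            out = hi - lo
        return out


def _piv_layout(n, m):
    """Center index, margin, search bound and overlap mask for an (iv, sv) pair.

    The peak search is restricted to translations where the interrogation
    window overlaps the search window by at least half its volume (product
    of per-axis overlap fractions >= 0.5); normalized scores over smaller
    supports are numerically unstable and admit spurious maxima.
    """
    margins = []
    for nd, md in zip(n, m):
        if md < nd:
            raise ValueError(f"search window {m} smaller than interrogation window {n}")
        if (md - nd) % 2:
            raise ValueError("search/interrogation size difference must be even per axis")
        margins.append((md - nd) // 2)
    center = tuple(nd - 1 + mg for nd, mg in zip(n, margins))
    max_disp = tuple(mg + nd // 2 for nd, mg in zip(n, margins))
    fractions = []
    for nd, md, mg, c in zip(n, m, margins, center):
        s = np.arange(nd + md - 1) - c  # displacement along this axis
        extent = np.clip(nd - np.maximum(np.abs(s) - mg, 0), 0, nd)
        fractions.append(extent / nd)
    frac = fractions[0]
    for f in fractions[1:]:
        frac = np.multiply.outer(frac, f)
    mask = frac >= 0.5
    return center, tuple(margins), max_disp, mask


def unnorm(iv: np.ndarray, sv: np.ndarray) -> CorrelationMatrix:
    """Plain cross-correlation of a PIV window pair with displacement-centered
    layout and the half-overlap peak-search restriction."""
    center, _, max_disp, mask = _piv_layout(iv.shape, sv.shape)
    scores = _linear_correlate(iv, sv)
    degenerate = not np.any(iv)
    return CorrelationMatrix(scores, center, CorrMode.UNNORM, max_disp, degenerate, mask)


def _padded_window_sums(sv: np.ndarray, n, squared: bool) -> np.ndarray:
    """Per-translation sums of sv (or sv^2) over the iv-sized support of the
    zero-padded search window; output shape ``n + m - 1``."""
    pad = [(nd - 1, nd - 1) for nd in n]
    padded = np.pad(np.asarray(sv, dtype=np.float64), pad)
    return IntegralArray(padded, squared=squared).sliding_sums(n)


def zncc(iv: np.ndarray, sv: np.ndarray) -> CorrelationMatrix:
    """Zero-normalized cross-correlation matrix of a window pair.

    At each translation the score is the Pearson correlation between ``iv``
    and the interrogation-sized window of the zero-padded ``sv``; scores lie
    in [-1, 1] and reach 1 exactly where ``sv`` contains an affine-intensity
    copy of ``iv``.  Translations whose support has (numerically) zero
    variance score 0; a constant ``iv`` yields an all-zero, degenerate
    matrix.
    """
    iv = np.asarray(iv, dtype=np.float64)
    sv = np.asarray(sv, dtype=np.float64)
    center, _, max_disp, mask = _piv_layout(iv.shape, sv.shape)
    n_vox = iv.size
    iv0 = iv - iv.mean()
    var_iv = float(np.sum(iv0 * iv0))
    if var_iv <= _VAR_RTOL * max(float(np.sum(iv * iv)), 1e-300):
        return CorrelationMatrix(
            np.zeros(tuple(a + b - 1 for a, b in zip(iv.shape, sv.shape))),
            center, CorrMode.ZNCC, max_disp, degenerate=True, valid_mask=mask,
        )
    # numerator: sum (iv - mu_iv) * sv_window  (window-mean term vanishes)
    num = _linear_correlate(iv0, sv)
    s1 = _padded_window_sums(sv, iv.shape, squared=False)
    s2 = _padded_window_sums(sv, iv.shape, squared=True)
    var_sv = s2 - (s1 * s1) / n_vox
    np.maximum(var_sv, 0.0, out=var_sv)
    valid = var_sv > _VAR_RTOL * np.maximum(s2, 1e-300)
    scores = np.zeros_like(num)
    np.divide(num, np.sqrt(var_iv * var_sv, where=valid, out=np.ones_like(var_sv)),
              where=valid, out=scores)
    np.clip(scores, -1.0, 1.0, out=scores)
    return CorrelationMatrix(scores, center, CorrMode.ZNCC, max_disp, valid_mask=mask)


def nsqecc(iv: np.ndarray, sv: np.ndarray) -> CorrelationMatrix:
    """Inverse normalized squared-error cross-correlation, ``1/(1 + NSQECC)``.

    NSQECC at each translation is the sum of squared differences between
    ``iv`` and the search-window support, normalized by
    ``sqrt(sum(iv^2) * sum(sv_window^2))``; the inverse form peaks (at 1)
    at the translation minimizing the differences.  Supports with zero norm
    score 0.
    """
    iv = np.asarray(iv, dtype=np.float64)
    sv = np.asarray(sv, dtype=np.float64)
    center, _, max_disp, mask = _piv_layout(iv.shape, sv.shape)
    sum_iv2 = float(np.sum(iv * iv))
    if sum_iv2 == 0.0:
        raise ValueError("NSQECC is undefined for an all-zero interrogation window")
    cross = _linear_correlate(iv, sv)
    sum_sv2 = _padded_window_sums(sv, iv.shape, squared=True)
    np.maximum(sum_sv2, 0.0, out=sum_sv2)
    num = sum_iv2 + sum_sv2 - 2.0 * cross
    np.maximum(num, 0.0, out=num)
    valid = sum_sv2 > _VAR_RTOL * sum_iv2
    den = np.sqrt(sum_iv2 * sum_sv2, where=valid, out=np.ones_like(sum_sv2))
    scores = np.zeros_like(num)
    np.divide(1.0, 1.0 + num / den, where=valid, out=scores)
    return CorrelationMatrix(scores, center, CorrMode.NSQECC, max_disp, valid_mask=mask)


def correlate_windows(iv: np.ndarray, sv: np.ndarray, mode: CorrMode) -> CorrelationMatrix:
    """Dispatch to the correlation matrix of the requested mode."""
    mode = CorrMode(mode)
    if mode is CorrMode.UNNORM:
        return unnorm(iv, sv)
    if mode is CorrMode.ZNCC:
        return zncc(iv, sv)
    return nsqecc(iv, sv)
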