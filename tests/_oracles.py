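"""Brute-force reference implementations used as independent oracles.

These evaluate the correlation definitions directly by looping over
translations and voxels; they are deliberately slow and independent of the
FFT/integral-array code paths they check.
"""

import numpy as np


def brute_correlate(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Direct spatial cross-correlation: out[s] = sum_x a[x] * b[x + s]."""
    na, nb = a.shape, b.shape
    out = np.zeros(tuple(x + y - 1 for x, y in zip(na, nb)))
    for idx in np.ndindex(*out.shape):
        s = tuple(i - (n - 1) for i, n in zip(idx, na))
        total = 0.0
        for x in np.ndindex(*na):
            bx = tuple(xi + si for xi, si in zip(x, s))
            if all(0 <= v < n for v, n in zip(bx, nb)):
                total += a[x] * b[bx]
        out[idx] = total
    return out


def _padded_window(sv, n, idx):
    pad = np.pad(sv, [(d - 1, d - 1) for d in n])
    return pad[tuple(slice(i, i + d) for i, d in zip(idx, n))]


def brute_zncc(iv: np.ndarray, sv: np.ndarray) -> np.ndarray:
    """Per-translation Pearson correlation of iv with the window of the
    zero-padded search volume."""
    n = iv.shape
    out = np.zeros(tuple(a + b - 1 for a, b in zip(iv.shape, sv.shape)))
    a = iv - iv.mean()
    for idx in np.ndindex(*out.shape):
        w = _padded_window(sv, n, idx)
        b = w - w.mean()
        den = np.sqrt((a * a).sum() * (b * b).sum())
        out[idx] = (a * b).sum() / den if den > 1e-12 else 0.0
    return out


def brute_nsqecc_inverse(iv: np.ndarray, sv: np.ndarray) -> np.ndarray:
    """Per-translation 1/(1 + NSQECC) with the normalized squared error
    evaluated directly."""
    n = iv.shape
    out = np.zeros(tuple(a + b - 1 for a, b in zip(iv.shape, sv.shape)))
    sum_iv2 = (iv * iv).sum()
    for idx in np.ndindex(*out.shape):
        w = _padded_window(sv, n, idx)
        sum_w2 = (w * w).sum()
        if sum_w2 <= 0:
            out[idx] = 0.0
            continue
        nsq = ((iv - w) ** 2).sum() / np.sqrt(sum_iv2 * sum_w2)
        out[idx] = 1.0 / (1.0 + nsq)
    return out


def brute_box_sum(arr: np.ndarray, start, stop) -> float:
    """Direct summation over the half-open box [start, stop)."""
    return float(arr[tuple(slice(a, b) for a, b in zip(start, stop))].sum())
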