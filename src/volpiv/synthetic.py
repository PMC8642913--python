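"""Synthetic particle scenes with known translations, and PIV error metrics.

A scene is a set of randomly placed point emitters rendered as Gaussian
spots: a particle centered at c contributes

    I(x) = I0 * exp(-8 * ||x - c||^2 / d^2),

so intensity falls to I0 * e^-2 at radius d/2 (the e^-2 diameter convention
common in synthetic PIV benchmarks).  A pair of frames related by a known
(possibly fractional) homogeneous translation is produced by analytically
re-rendering the same particle set at shifted positions — sub-pixel motion
therefore emerges from the continuous profile, not from resampling, and
particles drift in and out of the frame naturally (centers are drawn from a
band extending one diameter beyond the domain).

Accuracy is quantified against the known translation with the bias error
(mean absolute deviation from the truth) and the random error (standard
deviation around the mean estimate), evaluated per axis and pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import VolumePair, run_piv
from .params import CorrMode, PIVParams, SubvoxelMode

__all__ = [
    "SyntheticScene",
    "render_scene",
    "make_pair",
    "bias_error",
    "random_error",
    "ErrorReport",
    "evaluate_errors",
    "SweepAxis",
    "SweepConfig",
    "accuracy_sweep",
]

#: particles are rendered out to this many diameters from their center
_TRUNCATION_DIAMETERS = 3.0


@dataclass(frozen=True)
class SyntheticScene:
    """Randomly seeded particle field over a rectangular domain.

    Centers are drawn uniformly over the domain extended by one particle
    diameter on every side, so translations can move particles into and out
    of the frame.  Rendering with the same seed is bit-identical.
    """

    domain_shape: Tuple[int, ...]
    n_particles: int
    diameter: float = 2.0
    peak_intensity: float = 100.0
    seed: int = 0
    noise_sigma: float = 0.0
    bit_depth: Optional[int] = None
    centers: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        shape = tuple(int(s) for s in self.domain_shape)
        object.__setattr__(self, "domain_shape", shape)
        if self.diameter <= 0 or self.peak_intensity <= 0:
            raise ValueError("diameter and peak_intensity must be positive")
        rng = np.random.default_rng(self.seed)
        d = float(self.diameter)
        lo = np.full(len(shape), -d)
        hi = np.asarray(shape, dtype=float) - 1.0 + d
        centers = rng.uniform(lo, hi, size=(int(self.n_particles), len(shape)))
        object.__setattr__(self, "centers", centers)

    @property
    def ndim(self) -> int:
        return len(self.domain_shape)


def render_scene(scene: SyntheticScene, shift=None) -> np.ndarray:
    """Render the scene with every particle displaced by ``shift``.

    Gaussian profiles are additive and truncated at 3 diameters; the
    separable profile is evaluated on a small per-particle stamp and
    accumulated into the frame.  If the scene specifies a sensor
    ``bit_depth``, the frame is rounded to integer counts and clipped to
    the sensor range [0, 2^bits - 1] — dense overlapping particles then
    saturate into uniform patches, as on a real camera.
    """
    ndim = scene.ndim
    shape = scene.domain_shape
    if shift is None:
        shift = np.zeros(ndim)
    shift = np.asarray(shift, dtype=float)
    if shift.shape != (ndim,):
        raise ValueError(f"shift must have {ndim} components")
    out = np.zeros(shape, dtype=np.float64)
    if scene.n_particles:
        d = scene.diameter
        reach = int(np.ceil(_TRUNCATION_DIAMETERS * d))
        offsets = np.arange(-reach, reach + 1)
        centers = scene.centers + shift
        strides = np.array([int(np.prod(shape[a + 1:])) for a in range(ndim)])
        chunk = max(1, int(2e6 // (len(offsets) ** ndim)))
        for start in range(0, centers.shape[0], chunk):
            c = centers[start:start + chunk]
            base = np.rint(c).astype(np.int64)  # (N, ndim)
            # per-axis sample positions and 1D Gaussian factors, (N, W)
            gs, idxs = [], []
            for ax in range(ndim):
                pos = base[:, ax, None] + offsets[None, :]
                delta = pos - c[:, ax, None]
                gs.append(np.exp(-8.0 * delta**2 / d**2))
                idxs.append(pos)
            if ndim == 2:
                patch = gs[0][:, :, None] * gs[1][:, None, :]
                flat = (idxs[0][:, :, None] * strides[0]
                        + idxs[1][:, None, :] * strides[1])
                inside = ((idxs[0][:, :, None] >= 0) & (idxs[0][:, :, None] < shape[0])
                          & (idxs[1][:, None, :] >= 0) & (idxs[1][:, None, :] < shape[1]))
            else:
                patch = (gs[0][:, :, None, None] * gs[1][:, None, :, None]
                         * gs[2][:, None, None, :])
                flat = (idxs[0][:, :, None, None] * strides[0]
                        + idxs[1][:, None, :, None] * strides[1]
                        + idxs[2][:, None, None, :] * strides[2])
                inside = ((idxs[0][:, :, None, None] >= 0) & (idxs[0][:, :, None, None] < shape[0])
                          & (idxs[1][:, None, :, None] >= 0) & (idxs[1][:, None, :, None] < shape[1])
                          & (idxs[2][:, None, None, :] >= 0) & (idxs[2][:, None, None, :] < shape[2]))
            m = inside.ravel()
            out.ravel()[:] += np.bincount(
                flat.ravel()[m], weights=patch.ravel()[m], minlength=out.size
            )
    out *= scene.peak_intensity
    if scene.bit_depth is not None:
        np.rint(out, out=out)
        np.clip(out, 0.0, float(2**scene.bit_depth - 1), out=out)
    return out


def make_pair(scene: SyntheticScene, s_true) -> VolumePair:
    """Frame pair related by the homogeneous translation ``s_true``.

    The first frame renders the scene in place, the second with every
    particle shifted by ``s_true``; optional additive Gaussian sensor noise
    (``scene.noise_sigma``) is drawn independently per frame from the scene
    seed.
    """
    vt = render_scene(scene, None)
    vt1 = render_scene(scene, s_true)
    if scene.noise_sigma > 0:
        r1 = np.random.default_rng([scene.seed, 1])
        r2 = np.random.default_rng([scene.seed, 2])
        vt = np.clip(vt + r1.normal(0, scene.noise_sigma, vt.shape), 0, None)
        vt1 = np.clip(vt1 + r2.normal(0, scene.noise_sigma, vt1.shape), 0, None)
    return VolumePair(vt, vt1)


def bias_error(d_piv, d_true):
    """Mean absolute deviation of the estimates from the known translation.

    1D input (n,) returns a scalar; (n, D) input returns one value per axis.
    """
    d_piv = np.asarray(d_piv, dtype=float)
    if d_piv.size == 0:
        raise ValueError("need at least one displacement")
    err = np.abs(d_piv - np.asarray(d_true, dtype=float))
    return err.mean(axis=0)


def random_error(d_piv):
    """Standard deviation of the estimates around their own mean (per axis)."""
    d_piv = np.asarray(d_piv, dtype=float)
    if d_piv.size == 0:
        raise ValueError("need at least one displacement")
    return np.sqrt(np.mean((d_piv - d_piv.mean(axis=0)) ** 2, axis=0))


@dataclass
class ErrorReport:
    """Bias and random errors of a set of PIV displacement estimates."""

    bias_axes: np.ndarray
    random_axes: np.ndarray
    n: int
    d_true: np.ndarray
    displacements: np.ndarray

    @property
    def bias(self) -> float:
        return float(np.mean(self.bias_axes))

    @property
    def random(self) -> float:
        return float(np.mean(self.random_axes))


def evaluate_errors(displacements, d_true) -> ErrorReport:
    """Pool displacement samples (rows) into an :class:`ErrorReport`."""
    disp = np.atleast_2d(np.asarray(displacements, dtype=float))
    d_true = np.asarray(d_true, dtype=float)
    return ErrorReport(
        bias_axes=np.atleast_1d(bias_error(disp, d_true)),
        random_axes=np.atleast_1d(random_error(disp)),
        n=disp.shape[0],
        d_true=d_true,
        displacements=disp,
    )


class SweepAxis(str, Enum):
    """Quantity varied in an accuracy sweep."""

    INTER_SIZE = "inter_size"
    DENSITY = "density"
    DIAMETER = "diameter"
    FRACTIONAL_SHIFT = "fractional_shift"
    SEARCH_MARGIN = "search_margin"


@dataclass
class SweepConfig:
    """Fixed conditions of an accuracy sweep (the swept one is overridden).

    Defaults follow the 2D benchmark conditions: 200x200 px frames, 2 px
    particles on an 8-bit sensor, unnormalized correlation, a 4 px search
    margin and a homogeneous translation.  ``density`` is expressed as mean
    particles per interrogation window; ``n_particles`` wins when both are
    set.
    """

    domain_shape: Tuple[int, ...] = (200, 200)
    inter_size: int = 32
    search_margin: int = 4
    overlap: int = 0
    diameter: float = 2.0
    peak_intensity: float = 100.0
    bit_depth: Optional[int] = 8
    translation: Optional[Sequence[float]] = None
    n_particles: Optional[int] = 5000
    density: Optional[float] = None
    corr_mode: CorrMode = CorrMode.UNNORM
    subvoxel_mode: SubvoxelMode = SubvoxelMode.GAUSSIAN

    def resolve_particles(self, inter_size) -> int:
        if self.density is not None:
            ndim = len(self.domain_shape)
            inter = (inter_size,) * ndim if isinstance(inter_size, int) else tuple(inter_size)
            window = float(np.prod(inter))
            return int(round(self.density * float(np.prod(self.domain_shape)) / window))
        if self.n_particles is None:
            raise ValueError("either n_particles or density must be set")
        return int(self.n_particles)


def _sweep_point(axis: SweepAxis, value, config: SweepConfig):
    """Scene/params ingredients for one swept value."""
    inter = config.inter_size
    margin = config.search_margin
    diameter = config.diameter
    translation = config.translation
    ndim = len(config.domain_shape)
    density = config.density
    n_particles = config.n_particles
    if axis is SweepAxis.INTER_SIZE:
        inter = int(value)
    elif axis is SweepAxis.DENSITY:
        density, n_particles = float(value), None
    elif axis is SweepAxis.DIAMETER:
        diameter = float(value)
    elif axis is SweepAxis.FRACTIONAL_SHIFT:
        translation = (float(value),) + (0.0,) * (ndim - 1)
    elif axis is SweepAxis.SEARCH_MARGIN:
        margin = int(value)
    if translation is None:
        raise ValueError("sweep requires a translation (set config.translation)")
    cfg = SweepConfig(**{**config.__dict__,
                         "inter_size": inter, "search_margin": margin,
                         "diameter": diameter, "translation": tuple(translation),
                         "density": density, "n_particles": n_particles})
    return cfg


def accuracy_sweep(
    axis: SweepAxis,
    values: Sequence,
    config: Optional[SweepConfig] = None,
    n_repeats: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Tabulate bias and random errors while sweeping one benchmark knob.

    For every swept value, ``n_repeats`` independently seeded scenes are
    generated, each run through a full PIV analysis, and all window vectors
    are pooled into the error estimates.  Columns: the swept ``value``,
    per-axis ``bias_*``/``random_*`` (u, v[, w]), pooled ``bias``,
    ``random``, their sum ``total``, and the sample count ``n``.
    """
    axis = SweepAxis(axis)
    config = config or SweepConfig()
    ndim = len(config.domain_shape)
    comp_names = ["u", "v", "w"][:ndim]
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(values))
    rows = []
    for value, child in zip(values, children):
        cfg = _sweep_point(axis, value, config)
        params = PIVParams(
            inter_size=cfg.inter_size,
            search_margin=cfg.search_margin,
            overlap=cfg.overlap,
            corr_mode=cfg.corr_mode,
            subvoxel_mode=cfg.subvoxel_mode,
        )
        n_part = cfg.resolve_particles(cfg.inter_size)
        samples = []
        for rep_seed in child.spawn(n_repeats):
            scene = SyntheticScene(
                domain_shape=cfg.domain_shape,
                n_particles=n_part,
                diameter=cfg.diameter,
                peak_intensity=cfg.peak_intensity,
                bit_depth=cfg.bit_depth,
                seed=int(rep_seed.generate_state(1)[0] % (2**31)),
            )
            pair = make_pair(scene, cfg.translation)
            result = run_piv(pair, params)
            vecs = result.vectors.reshape(ndim, -1).T
            keep = ~result.background.ravel()
            samples.append(vecs[keep])
        report = evaluate_errors(np.concatenate(samples, axis=0), cfg.translation)
        row = {"value": value}
        for i, name in enumerate(comp_names):
            row[f"bias_{name}"] = report.bias_axes[i]
            row[f"random_{name}"] = report.random_axes[i]
        row["bias"] = report.bias
        row["random"] = report.random
        row["total"] = report.bias + report.random
        row["n"] = report.n
        rows.append(row)
    return pd.DataFrame(rows)
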