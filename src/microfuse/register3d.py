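"""Automatic affine co-registration of a preprocessed section stack to a
reference volume, plus resampling and transform propagation.

The reference (fixed) volume is typically the microCT scan — free of both
geometric distortion and section misalignment — and the moving volume is the
inverted, Gaussian-smoothed LM section stack.  Registration maximizes the
Pearson correlation between the fixed intensities and the transformed,
linearly interpolated moving intensities over their physical overlap, using
a deterministic multi-resolution (coarse-to-fine) derivative-free coordinate
search over the transform parameters: three rotations and three translations,
plus one or three scale factors depending on the requested mode.

The estimated transform is then propagated unchanged to companion stacks on
the same grid (the original unfiltered LM images, label volumes), exactly as
one would copy transform parameters between datasets in a GUI pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (
    AffineTransform3D,
    ImageGrid,
    LabelVolume,
    RegistrationResult,
    VolumeImage,
    compose,
    invert,
)

__all__ = [
    "RegistrationConfig",
    "InsufficientOverlapError",
    "DegenerateRegionError",
    "correlation_metric",
    "resample_volume",
    "affine_register",
    "propagate_transform",
    "initial_guess",
    "downsample_volume",
]


class InsufficientOverlapError(RuntimeError):
    """Mapped moving volume overlaps too little of the fixed volume."""


class DegenerateRegionError(RuntimeError):
    """A masked signal is constant; correlation is undefined."""


@dataclass(frozen=True)
class RegistrationConfig:
    """Knobs of the automatic affine registration.

    mode
        ``rigid`` (3 rotations + 3 translations), ``rigid_iso_scale``
        (+1 global scale) or ``rigid_aniso_scale`` (+3 per-axis scales;
        useful to absorb a systematic section-thickness error by rescaling
        only the stacking axis).
    pyramid_levels / downsample_factor
        Coarse-to-fine mean-pooling pyramid; pooling stops early if any
        axis would drop below 16 voxels.
    max_iterations
        Maximum coordinate-descent sweeps per pyramid level.
    translation_tol / rotation_tol / scale_tol
        Step-size floors (μm, radians, unitless) at which a level finishes.
    metric_tol
        Minimum metric improvement counted as progress.
    min_overlap_fraction
        Fraction of fixed voxels that must map inside the moving volume.
    seed
        Orders the parameter sweeps; metric evaluation itself uses all
        overlapping voxels and is seed-independent.
    """

    mode: str = "rigid"
    pyramid_levels: int = 3
    downsample_factor: int = 2
    metric: str = "correlation"
    max_iterations: int = 60
    translation_tol: float = 0.05
    rotation_tol: float = float(np.deg2rad(0.01))
    scale_tol: float = 1e-4
    metric_tol: float = 1e-8
    min_overlap_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("rigid", "rigid_iso_scale", "rigid_aniso_scale"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.metric != "correlation":
            raise ValueError("only the correlation metric is implemented")
        if self.pyramid_levels < 1 or self.downsample_factor < 2:
            raise ValueError("pyramid_levels >= 1 and downsample_factor >= 2 required")
        if min(self.translation_tol, self.rotation_tol, self.scale_tol,
               self.metric_tol) <= 0:
            raise ValueError("all tolerances must be > 0")
        if not 0 < self.min_overlap_fraction <= 1:
            raise ValueError("min_overlap_fraction must be in (0, 1]")


# ---------------------------------------------------------------------------
# metric


class _MetricSampler:
    """Evaluates the correlation metric for many candidate transforms
    against one (fixed, moving) pair, reusing the fixed voxel lattice."""

    def __init__(self, fixed: VolumeImage, moving: VolumeImage,
                 min_overlap_fraction: float):
        self.min_overlap_fraction = float(min_overlap_fraction)
        idx = np.indices(fixed.grid.shape, dtype=np.float64).reshape(3, -1).T
        self.fixed_world = (
            idx * np.asarray(fixed.grid.spacing) + np.asarray(fixed.grid.origin)
        )
        self.fixed_vals = fixed.voxels.reshape(-1).astype(np.float64)
        self.moving_vals = moving.voxels.astype(np.float64)
        self.m_origin = np.asarray(moving.grid.origin)
        self.m_spacing = np.asarray(moving.grid.spacing)
        self.m_upper = np.asarray(moving.grid.shape, dtype=float) - 1.0

    def __call__(self, t: AffineTransform3D) -> tuple[float, float]:
        """Return (pearson correlation, overlap fraction) for transform t."""
        inv = invert(t)
        mw = self.fixed_world @ inv.linear.T + inv.translation
        idx = (mw - self.m_origin) / self.m_spacing
        inside = np.all((idx >= 0.0) & (idx <= self.m_upper), axis=1)
        frac = float(inside.mean())
        if frac < self.min_overlap_fraction:
            raise InsufficientOverlapError(
                f"overlap fraction {frac:.3f} below minimum "
                f"{self.min_overlap_fraction:.3f}"
            )
        mv = ndimage.map_coordinates(
            self.moving_vals, idx[inside].T, order=1, mode="constant", cval=0.0
        )
        fv = self.fixed_vals[inside]
        fs, ms = fv.std(), mv.std()
        if fs == 0.0 or ms == 0.0:
            raise DegenerateRegionError(
                "constant signal in the overlap region; correlation undefined"
            )
        r = float(np.mean((fv - fv.mean()) * (mv - mv.mean())) / (fs * ms))
        return min(1.0, max(-1.0, r)), frac


def correlation_metric(
    fixed: VolumeImage,
    moving: VolumeImage,
    t: AffineTransform3D,
    min_overlap_fraction: float = 0.25,
    return_detail: bool = False,
):
    """Pearson correlation between fixed and transformed moving intensities.

    Computed over exactly the fixed voxels whose position, pulled back
    through ``invert(t)``, falls inside the moving volume's physical extent;
    moving values are linearly interpolated there.  With
    ``return_detail=True`` also returns the overlap fraction.

    Raises
    ------
    InsufficientOverlapError
        If the overlap fraction is below ``min_overlap_fraction``.
    DegenerateRegionError
        If either masked signal is constant.
    """
    r, frac = _MetricSampler(fixed, moving, min_overlap_fraction)(t)
    return (r, frac) if return_detail else r


# ---------------------------------------------------------------------------
# resampling


def resample_volume(
    moving: VolumeImage | LabelVolume,
    target_grid: ImageGrid,
    t: AffineTransform3D,
    interpolation: str = "linear",
    return_mask: bool = False,
):
    """Resample ``moving`` onto ``target_grid`` under transform ``t``.

    Each target voxel takes the moving volume's value at
    ``invert(t)(voxel world position)``; positions outside the moving extent
    take fill value 0.  Gray volumes use linear or nearest interpolation;
    label volumes must use nearest.  ``return_mask`` additionally returns
    the boolean occupancy mask of in-extent target voxels.
    """
    is_labels = isinstance(moving, LabelVolume)
    if is_labels and interpolation != "nearest":
        raise ValueError("label volumes must be resampled with nearest interpolation")
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")

    idx = np.indices(target_grid.shape, dtype=np.float64).reshape(3, -1).T
    world = idx * np.asarray(target_grid.spacing) + np.asarray(target_grid.origin)
    inv = invert(t)
    mw = world @ inv.linear.T + inv.translation
    src = (mw - np.asarray(moving.grid.origin)) / np.asarray(moving.grid.spacing)

    upper = np.asarray(moving.grid.shape, dtype=float) - 1.0
    if interpolation == "linear":
        inside = np.all((src >= 0.0) & (src <= upper), axis=1)
    else:  # nearest: each voxel's footprint is half a spacing wide
        inside = np.all((src >= -0.5) & (src <= upper + 0.5), axis=1)
    mask = inside.reshape(target_grid.shape)

    if is_labels:
        vals = ndimage.map_coordinates(
            moving.labels, src.T, order=0, mode="constant", cval=0
        )
        vals[~inside] = 0
        out = vals.reshape(target_grid.shape).astype(moving.labels.dtype)
        result = LabelVolume(grid=target_grid, labels=out, names=dict(moving.names))
    else:
        order = 1 if interpolation == "linear" else 0
        vals = ndimage.map_coordinates(
            moving.voxels.astype(np.float64), src.T, order=order,
            mode="constant", cval=0.0,
        )
        vals[~inside] = 0.0
        out = np.floor(vals + 0.5).clip(0, 255).astype(np.uint8)
        result = VolumeImage(
            grid=target_grid, voxels=out.reshape(target_grid.shape),
            modality=moving.modality,
        )
    return (result, mask) if return_mask else result


# ---------------------------------------------------------------------------
# pyramid


def downsample_volume(volume: VolumeImage, factor: int = 2) -> VolumeImage:
    """Mean-pool by ``factor`` per axis (edge-replicating partial blocks).

    Spacing is multiplied by the factor; the origin shifts by half the new
    voxel size so pooled voxel centers sit at the mean of their sources.
    """
    f = int(factor)
    v = volume.voxels.astype(np.float64)
    pads = [(0, (-n) % f) for n in v.shape]
    if any(p[1] for p in pads):
        v = np.pad(v, pads, mode="edge")
    nz, ny, nx = (s // f for s in v.shape)
    pooled = v.reshape(nz, f, ny, f, nx, f).mean(axis=(1, 3, 5))
    grid = ImageGrid(
        shape=pooled.shape,
        spacing=tuple(s * f for s in volume.grid.spacing),
        origin=tuple(
            o + (f - 1) / 2.0 * s
            for o, s in zip(volume.grid.origin, volume.grid.spacing)
        ),
    )
    return VolumeImage(
        grid=grid, voxels=np.floor(pooled + 0.5).clip(0, 255).astype(np.uint8),
        modality=volume.modality,
    )


def _build_pyramid(volume: VolumeImage, levels: int, factor: int,
                   min_size: int = 16) -> list[VolumeImage]:
    """Coarse-to-fine list; pooling stops before any axis drops below min_size."""
    pyramid = [volume]
    for _ in range(levels - 1):
        prev = pyramid[-1]
        if min(prev.grid.shape) // factor < min_size and min(prev.grid.shape) > min_size:
            break
        if min(prev.grid.shape) <= min_size:
            break
        pyramid.append(downsample_volume(prev, factor))
    return pyramid[::-1]


# ---------------------------------------------------------------------------
# optimizer


def _n_params(mode: str) -> int:
    return {"rigid": 6, "rigid_iso_scale": 7, "rigid_aniso_scale": 9}[mode]


def _params_to_transform(
    params: np.ndarray, mode: str, pivot: np.ndarray, init: AffineTransform3D
) -> AffineTransform3D:
    """Delta transform (rotation/translation/scale about pivot) composed on init."""
    angles = params[0:3]
    translation = params[3:6]
    if mode == "rigid":
        scales: float | np.ndarray = 1.0
    elif mode == "rigid_iso_scale":
        scales = float(params[6])
    else:
        scales = params[6:9]
    delta = AffineTransform3D.from_euler(
        angles, translation, scales=scales, pivot=pivot, mode=mode
    )
    return compose(delta, init)


def affine_register(
    fixed: VolumeImage,
    moving: VolumeImage,
    init: AffineTransform3D | None = None,
    config: RegistrationConfig = RegistrationConfig(),
) -> RegistrationResult:
    """Maximize the correlation metric by multi-resolution coordinate search.

    ``init`` plays the role of the manual coarse alignment and must already
    produce sufficient overlap; the optimizer only refines it.  Moving data
    is expected to be preprocessed to the fixed volume's contrast polarity
    (see :mod:`microfuse.preprocess`) — similarity between the inputs, not
    the optimizer, is what decides registration quality.

    At each pyramid level an adaptive step-halving coordinate search runs
    over the parameter vector: every sweep tries ±step on each parameter and
    keeps strict improvements; a sweep without improvement halves all steps
    until they fall below the configured tolerances.  Deterministic given
    ``config.seed`` (which only shuffles the sweep order).
    """
    if init is None:
        init = AffineTransform3D.identity()
    rng = np.random.default_rng(config.seed)

    fixed_pyr = _build_pyramid(fixed, config.pyramid_levels, config.downsample_factor)
    moving_pyr = _build_pyramid(moving, config.pyramid_levels, config.downsample_factor)
    n_levels = min(len(fixed_pyr), len(moving_pyr))
    fixed_pyr, moving_pyr = fixed_pyr[-n_levels:], moving_pyr[-n_levels:]

    pivot = np.asarray(init.apply(moving.grid.center))
    n_par = _n_params(config.mode)
    params = np.zeros(n_par)
    if config.mode == "rigid_iso_scale":
        params[6] = 1.0
    elif config.mode == "rigid_aniso_scale":
        params[6:9] = 1.0

    # reject a start without overlap on the *full-resolution* pair
    init_metric, _ = _MetricSampler(fixed, moving, config.min_overlap_fraction)(init)

    trace: list[tuple[int, int, float]] = []
    converged = False
    current = init_metric
    for level_idx in range(n_levels):
        fx, mv = fixed_pyr[level_idx], moving_pyr[level_idx]
        sampler = _MetricSampler(fx, mv, config.min_overlap_fraction)

        def safe_metric(p: np.ndarray) -> float:
            try:
                return sampler(_params_to_transform(p, config.mode, pivot, init))[0]
            except (InsufficientOverlapError, DegenerateRegionError):
                return -np.inf

        current = safe_metric(params)
        trace.append((level_idx, 0, max(-1.0, current)))

        # step sizes: 2 level-voxels translation, 2° rotation, 2% scale at the
        # coarsest level, refined at finer ones
        shrink = 2.0 ** (n_levels - 1 - level_idx) / 2.0 ** (n_levels - 1)
        steps = np.empty(n_par)
        steps[0:3] = np.deg2rad(2.0) * shrink
        steps[3:6] = 2.0 * max(fx.grid.spacing)
        steps[6:] = 0.02 * shrink

        tol = np.empty(n_par)
        tol[0:3] = config.rotation_tol
        tol[3:6] = config.translation_tol
        tol[6:] = config.scale_tol

        level_converged = False
        for sweep in range(1, config.max_iterations + 1):
            order = rng.permutation(n_par)
            improved = False
            for j in order:
                for sign in (+1.0, -1.0):
                    cand = params.copy()
                    cand[j] += sign * steps[j]
                    m = safe_metric(cand)
                    if m > current + config.metric_tol:
                        params, current = cand, m
                        trace.append((level_idx, sweep, min(1.0, max(-1.0, current))))
                        improved = True
                        break
            if not improved:
                steps = steps / 2.0
                if np.all(steps < tol):
                    level_converged = True
                    break
        if level_idx == n_levels - 1:
            converged = level_converged

    final_t = _params_to_transform(params, config.mode, pivot, init)
    final_metric, overlap = _MetricSampler(
        fixed, moving, config.min_overlap_fraction
    )(final_t)
    if final_metric + 1e-12 < init_metric:
        converged = False  # diverged: ended below the starting point
    trace.append((n_levels - 1, config.max_iterations + 1, final_metric))
    return RegistrationResult(
        transform=final_t,
        final_metric=final_metric,
        trace=trace,
        converged=converged,
        detail={"overlap_fraction": overlap, "init_metric": init_metric,
                "mode": config.mode},
    )


# ---------------------------------------------------------------------------
# propagation and initialization


def propagate_transform(
    companions: list[VolumeImage | LabelVolume],
    t: AffineTransform3D,
    moving_grid: ImageGrid,
    resample_to: ImageGrid | None = None,
):
    """Attach the registration transform unchanged to companion stacks.

    Companions must share the registered moving stack's grid.  Returns
    ``(companion, t)`` pairs — the *same* transform object, exactly as
    serialized — or, when ``resample_to`` is given, companions resampled
    onto that grid (linear interpolation for gray volumes, nearest for
    labels).
    """
    for c in companions:
        if c.grid != moving_grid:
            raise ValueError(
                f"companion grid {c.grid} does not match moving stack grid "
                f"{moving_grid}"
            )
    if resample_to is None:
        return [(c, t) for c in companions]
    out = []
    for c in companions:
        interp = "nearest" if isinstance(c, LabelVolume) else "linear"
        out.append(resample_volume(c, resample_to, t, interpolation=interp))
    return out


def _weighted_moments(volume: VolumeImage):
    w = volume.voxels.astype(np.float64)
    total = w.sum()
    if total == 0:
        raise DegenerateRegionError("all-zero volume has no centroid")
    idx = np.indices(volume.grid.shape, dtype=np.float64).reshape(3, -1)
    world = (idx.T * np.asarray(volume.grid.spacing) +
             np.asarray(volume.grid.origin)).T
    wf = w.reshape(-1)
    centroid = (world * wf).sum(axis=1) / total
    centered = world - centroid[:, None]
    cov = (centered * wf) @ centered.T / total
    return centroid, cov


def initial_guess(fixed: VolumeImage, moving: VolumeImage) -> AffineTransform3D:
    """Centroid-and-principal-axes coarse alignment (helper, never implicit).

    Aligns the intensity-weighted centroids and principal axes of the two
    volumes with a rigid transform.  This automates the manual coarse
    alignment step; callers must opt in explicitly — it is never applied
    behind :func:`affine_register`'s back.  Axis sign ambiguity is resolved
    toward the smallest rotation.
    """
    cf, covf = _weighted_moments(fixed)
    cm, covm = _weighted_moments(moving)
    _, uf = np.linalg.eigh(covf)
    _, um = np.linalg.eigh(covm)
    best = None
    for signs in ([1, 1], [1, -1], [-1, 1], [-1, -1]):
        u2 = um.copy()
        u2[:, 1] *= signs[0]
        u2[:, 2] *= signs[1]
        u2[:, 0] *= np.sign(np.linalg.det(uf) * np.linalg.det(u2))
        r = uf @ u2.T
        if np.linalg.det(r) < 0:
            continue
        angle = np.arccos(np.clip((np.trace(r) - 1) / 2, -1, 1))
        if best is None or angle < best[0]:
            best = (angle, r)
    r = best[1]
    return AffineTransform3D(r, cf - r @ cm, mode="rigid")
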