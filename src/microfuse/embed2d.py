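"""Embedding high-resolution 2D TEM images into the registered 3D scene.

A TEM image is an ultrathin re-section of one LM section, so its 3D position
is inherited from that section: a *template* is cropped from the registered
LM stack, upsampled to the TEM pixel size, the TEM image is registered to it
in 2D (similarity transform: rotation + translation + optional slight
isotropic scale), composited onto a black canvas with its histogram remapped
to 10–255, and finally placed in 3D by composing the template's own
pixel→world chain with the 2D registration.  The placement is stored
analytically — the TEM raster is never burnt into a 3D volume, which is how
its resolution survives.

2D transforms follow the same direction convention as 3D ones: the
similarity maps *moving* (TEM) pixel coordinates into *fixed* (template)
pixel coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (
    AffineTransform3D,
    AlphaColormap,
    ImageGrid,
    RegistrationResult,
    SimilarityTransform2D,
    VolumeImage,
    tem_alpha_colormap,
    voxel_to_world,
)

__all__ = [
    "SliceTemplate",
    "PlacedSlice",
    "extract_template",
    "resample_template",
    "register2d",
    "levels_remap",
    "composite_on_black",
    "place_in_3d",
    "compose2d",
]

MAX_UPSAMPLING = 64.0


def compose2d(outer: SimilarityTransform2D,
              inner: SimilarityTransform2D) -> SimilarityTransform2D:
    """Composition of 2D similarities: result(p) = outer(inner(p))."""
    t = outer.linear @ np.asarray(inner.translation) + np.asarray(outer.translation)
    return SimilarityTransform2D(
        angle=outer.angle + inner.angle,
        scale=outer.scale * inner.scale,
        translation=tuple(t),
    )


@dataclass
class SliceTemplate:
    """A 2D crop of one registered LM slice that remembers its 3D placement.

    ``pixel_size`` is (row, col) in μm — equal to the source in-plane
    spacing right after extraction, finer after resampling.  ``crop_offset``
    is the crop's top-left corner in source-slice voxels.  Pixels are
    cell-centered within the crop's physical extent: pixel ``q`` along an
    axis is centered at source-voxel coordinate ``(q + 0.5)·p/s − 0.5``
    (μm pixel size p, source spacing s), which reduces to ``q`` — pixel
    (0, 0) on voxel ``(slice_index, row0, col0)`` — while the pixel size
    equals the source spacing.  ``source_transform`` (the registered
    stack's transform) lifts the slice plane into the fixed world frame.
    """

    pixels: np.ndarray
    pixel_size: tuple[float, float]
    slice_index: int
    crop_offset: tuple[int, int]
    source_transform: AffineTransform3D
    source_grid: ImageGrid

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.dtype != np.uint8:
            raise ValueError("template pixels must be a 2D uint8 array")
        if any(p <= 0 for p in self.pixel_size):
            raise ValueError("pixel_size must be positive")
        if any(o < 0 for o in self.crop_offset):
            raise ValueError("crop_offset must be non-negative")

    def pixel_to_world(self, points) -> np.ndarray:
        """Map (fractional) template pixel (row, col) to world μm.

        The chain is: template pixel → fractional source voxel → source
        world → registered world (through the stack transform).
        """
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        sz, sy, sx = self.source_grid.spacing
        vox = np.empty((p.shape[0], 3))
        vox[:, 0] = self.slice_index
        vox[:, 1] = (self.crop_offset[0]
                     + (p[:, 0] + 0.5) * self.pixel_size[0] / sy - 0.5)
        vox[:, 2] = (self.crop_offset[1]
                     + (p[:, 1] + 0.5) * self.pixel_size[1] / sx - 0.5)
        world = self.source_transform.apply(voxel_to_world(self.source_grid, vox))
        return world[0] if single else world


def extract_template(
    registered_lm: VolumeImage,
    transform: AffineTransform3D,
    slice_index: int,
    roi: tuple[int, int, int, int] | None = None,
) -> SliceTemplate:
    """Crop one slice of the registered LM stack as a 2D template.

    ``roi`` is ``(row0, col0, height, width)`` in slice voxels (the full
    slice when omitted).  The crop is verbatim; the template records
    everything needed to map its pixel (0, 0) back to the world coordinate
    of source voxel ``(slice_index, row0, col0)``.
    """
    nz, ny, nx = registered_lm.grid.shape
    if not 0 <= slice_index < nz:
        raise IndexError(f"slice_index {slice_index} outside stack of {nz} slices")
    if roi is None:
        roi = (0, 0, ny, nx)
    r0, c0, h, w = (int(v) for v in roi)
    if r0 < 0 or c0 < 0 or h < 1 or w < 1 or r0 + h > ny or c0 + w > nx:
        raise ValueError(
            f"roi {roi} overhangs the {ny}x{nx} slice by "
            f"({max(0, r0 + h - ny)}, {max(0, c0 + w - nx)}) voxels"
        )
    _, sy, sx = registered_lm.grid.spacing
    return SliceTemplate(
        pixels=registered_lm.voxels[slice_index, r0:r0 + h, c0:c0 + w].copy(),
        pixel_size=(sy, sx),
        slice_index=slice_index,
        crop_offset=(r0, c0),
        source_transform=transform,
        source_grid=registered_lm.grid,
    )


def resample_template(
    template: SliceTemplate, target_pixel_size: tuple[float, float] | float
) -> SliceTemplate:
    """Resample a template to a new (usually much finer) pixel size.

    Output pixel count per axis is ``round(extent / target_pixel_size)``;
    values are linearly interpolated.  Both rasters are cell-centered in
    the same physical extent, so matching fractional pixel positions map
    to identical world coordinates — the 3D placement is restored onto the
    output unchanged.  Upsampling beyond 64× per axis is refused (crop a
    smaller region of interest instead).
    """
    if np.isscalar(target_pixel_size):
        target_pixel_size = (float(target_pixel_size), float(target_pixel_size))
    tp = tuple(float(v) for v in target_pixel_size)
    if any(v <= 0 for v in tp):
        raise ValueError("target_pixel_size must be positive")
    factors = [old / new for old, new in zip(template.pixel_size, tp)]
    if max(factors) > MAX_UPSAMPLING:
        raise ValueError(
            f"upsampling factor {max(factors):.1f} exceeds {MAX_UPSAMPLING:.0f}; "
            "crop a smaller region of interest before resampling"
        )
    new_shape = tuple(
        int(round(n * old / new))
        for n, old, new in zip(template.pixels.shape, template.pixel_size, tp)
    )
    rows = (np.arange(new_shape[0]) + 0.5) * tp[0] / template.pixel_size[0] - 0.5
    cols = (np.arange(new_shape[1]) + 0.5) * tp[1] / template.pixel_size[1] - 0.5
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    vals = ndimage.map_coordinates(
        template.pixels.astype(np.float64), [rr, cc], order=1, mode="nearest"
    )
    return SliceTemplate(
        pixels=np.floor(vals + 0.5).clip(0, 255).astype(np.uint8),
        pixel_size=tp,
        slice_index=template.slice_index,
        crop_offset=template.crop_offset,
        source_transform=template.source_transform,
        source_grid=template.source_grid,
    )


# ---------------------------------------------------------------------------
# 2D registration (same pyramid / coordinate-search machinery as 3D,
# specialized to similarity transforms in pixel coordinates)


def _pool2d(img: np.ndarray, f: int) -> np.ndarray:
    pads = [(0, (-n) % f) for n in img.shape]
    if any(p[1] for p in pads):
        img = np.pad(img, pads, mode="edge")
    ny, nx = (s // f for s in img.shape)
    return img.reshape(ny, f, nx, f).mean(axis=(1, 3))


class _Sampler2D:
    """Correlation metric for one (template, TEM) pair at one pyramid level.

    Level images are mean-pooled but all coordinates stay expressed in
    *original* pixel units so one parameter vector serves every level.
    """

    def __init__(self, fixed: np.ndarray, moving: np.ndarray, factor: int,
                 min_overlap_fraction: float,
                 fixed_origin: tuple[float, float] = (0.0, 0.0)):
        self.f = float(factor)
        self.min_overlap = float(min_overlap_fraction)
        self.fixed = fixed
        self.moving = moving
        off = (self.f - 1) / 2.0
        rr, cc = np.meshgrid(
            fixed_origin[0] + off + self.f * np.arange(fixed.shape[0]),
            fixed_origin[1] + off + self.f * np.arange(fixed.shape[1]),
            indexing="ij",
        )
        self.fixed_pts = np.stack([rr.ravel(), cc.ravel()], axis=1)
        self.fixed_vals = fixed.ravel()
        self.m_upper = (np.asarray(moving.shape, dtype=float) - 1.0) * self.f

    def __call__(self, t: SimilarityTransform2D) -> tuple[float, float]:
        inv = t.inverse()
        src = self.fixed_pts @ inv.linear.T + np.asarray(inv.translation)
        inside = np.all((src >= 0.0) & (src <= self.m_upper), axis=1)
        frac = float(inside.mean())
        if frac < self.min_overlap:
            raise ValueError(
                f"insufficient overlap: fraction {frac:.3f} below "
                f"{self.min_overlap:.3f}"
            )
        lvl = (src[inside] - (self.f - 1) / 2.0) / self.f
        mv = ndimage.map_coordinates(self.moving, lvl.T, order=1, mode="constant")
        fv = self.fixed_vals[inside]
        fs, ms = fv.std(), mv.std()
        if fs == 0.0 or ms == 0.0:
            raise ValueError("constant signal in overlap; correlation undefined")
        r = float(np.mean((fv - fv.mean()) * (mv - mv.mean())) / (fs * ms))
        return min(1.0, max(-1.0, r)), frac


def register2d(
    template: SliceTemplate,
    tem: np.ndarray,
    tem_pixel_size: tuple[float, float] | float,
    init: SimilarityTransform2D | None = None,
    allow_scale: bool = False,
    scale_bounds: tuple[float, float] = (0.9, 1.1),
    min_overlap_fraction: float = 0.25,
    pyramid_levels: int = 3,
    max_iterations: int = 60,
    translation_tol: float = 0.02,
    rotation_tol: float = float(np.deg2rad(0.005)),
    scale_tol: float = 5e-5,
    seed: int = 0,
) -> RegistrationResult:
    """Register a TEM image to its resolution-matched LM template.

    Maximizes the 2D Pearson correlation over rotation and translation
    (plus isotropic scale within ``scale_bounds`` when ``allow_scale``,
    covering TEM images that need slight rescaling) with the same
    coarse-to-fine step-halving coordinate search as the 3D path.  The TEM
    pixel size must already equal the template's within 0.5% — resample the
    template first, never the TEM image.
    """
    if np.isscalar(tem_pixel_size):
        tem_pixel_size = (float(tem_pixel_size), float(tem_pixel_size))
    for tpz, tz in zip(tem_pixel_size, template.pixel_size):
        if abs(tpz - tz) / tz > 0.005:
            raise ValueError(
                f"TEM pixel size {tem_pixel_size} differs from template "
                f"pixel size {template.pixel_size} by more than 0.5%; "
                "resample the template to the TEM resolution first"
            )
    tem = np.asarray(tem, dtype=np.float64)
    fixed = template.pixels.astype(np.float64)
    # exclude the template's outermost ring where the upsampled field is
    # edge-extrapolated rather than interpolated from source voxels: its
    # false content would bias the correlation peak
    margins = []
    for axis, spacing in enumerate(template.source_grid.spacing[1:]):
        ratio = spacing / template.pixel_size[axis]
        margins.append(int(np.ceil(max(0.0, 0.5 * ratio - 0.5))))
    mr, mc = margins
    fixed = fixed[mr:fixed.shape[0] - mr or None, mc:fixed.shape[1] - mc or None]
    fixed_origin = (float(mr), float(mc))
    if init is None:
        init = SimilarityTransform2D()
    rng = np.random.default_rng(seed)

    factors = [1]
    while (len(factors) < pyramid_levels
           and min(min(fixed.shape), min(tem.shape)) // (factors[-1] * 2) >= 16):
        factors.append(factors[-1] * 2)
    factors = factors[::-1]

    pivot = (np.asarray(template.pixels.shape, dtype=float) - 1.0) / 2.0
    n_par = 4 if allow_scale else 3  # angle, trow, tcol[, scale]
    params = np.zeros(n_par)
    if allow_scale:
        params[3] = 1.0

    def build(p: np.ndarray) -> SimilarityTransform2D:
        s = float(p[3]) if allow_scale else 1.0
        c, sn = np.cos(p[0]), np.sin(p[0])
        lin = s * np.array([[c, -sn], [sn, c]])
        shift = pivot + p[1:3] - lin @ pivot
        delta = SimilarityTransform2D(float(p[0]), s, tuple(shift))
        return compose2d(delta, init)

    trace: list[tuple[int, int, float]] = []
    converged = False
    current = -np.inf
    for li, f in enumerate(factors):
        sampler = _Sampler2D(_pool2d(fixed, f) if f > 1 else fixed,
                             _pool2d(tem, f) if f > 1 else tem,
                             f, min_overlap_fraction,
                             fixed_origin=fixed_origin)

        def safe(p: np.ndarray) -> float:
            if allow_scale and not scale_bounds[0] <= p[3] <= scale_bounds[1]:
                return -np.inf
            try:
                return sampler(build(p))[0]
            except ValueError:
                return -np.inf

        current = safe(params)
        if li == 0 and current == -np.inf:
            # distinguish the declared error paths at the starting point
            sampler(build(params))
        trace.append((li, 0, max(-1.0, current)))

        shrink = f / factors[0]
        steps = np.empty(n_par)
        steps[0] = np.deg2rad(2.0) * shrink
        steps[1:3] = 2.0 * f
        if allow_scale:
            steps[3] = 0.02 * shrink
        tol = np.empty(n_par)
        tol[0] = rotation_tol
        tol[1:3] = translation_tol
        if allow_scale:
            tol[3] = scale_tol

        level_done = False
        for sweep in range(1, max_iterations + 1):
            improved = False
            for j in rng.permutation(n_par):
                for sign in (+1.0, -1.0):
                    cand = params.copy()
                    cand[j] += sign * steps[j]
                    m = safe(cand)
                    if m > current + 1e-8:
                        params, current = cand, m
                        trace.append((li, sweep, min(1.0, current)))
                        improved = True
                        break
            if not improved:
                steps = steps / 2.0
                if np.all(steps < tol):
                    level_done = True
                    break
        if li == len(factors) - 1:
            converged = level_done

    final_t = build(params)
    final_metric, frac = _Sampler2D(fixed, tem, 1, min_overlap_fraction,
                                    fixed_origin=fixed_origin)(final_t)
    trace.append((len(factors) - 1, max_iterations + 1, final_metric))
    return RegistrationResult(
        transform=final_t, final_metric=final_metric, trace=trace,
        converged=converged, detail={"overlap_fraction": frac},
    )


# ---------------------------------------------------------------------------
# compositing and 3D placement


def levels_remap(image: np.ndarray, floor: int = 10, ceiling: int = 255) -> np.ndarray:
    """Linearly remap an 8-bit histogram onto [floor, ceiling].

    ``out = round_half_up(floor + in · (ceiling − floor) / 255)`` — with the
    default 10–255 range, gray 0 becomes 10, freeing the value 0 for a fully
    transparent background.  Monotone and order-preserving.
    """
    floor, ceiling = int(floor), int(ceiling)
    if not 0 <= floor < ceiling <= 255:
        raise ValueError(f"need 0 <= floor < ceiling <= 255, got {floor}, {ceiling}")
    image = np.asarray(image)
    if image.dtype != np.uint8:
        raise ValueError("levels_remap expects an 8-bit image")
    out = np.floor(floor + image.astype(np.float64) * (ceiling - floor) / 255.0 + 0.5)
    return out.astype(np.uint8)


def composite_on_black(
    tem_remapped: np.ndarray,
    canvas_shape: tuple[int, int],
    t2d: SimilarityTransform2D,
    floor: int = 10,
    template_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Resample the remapped TEM onto a black, template-shaped canvas.

    Canvas pixels covered by the transformed TEM footprint hold linearly
    interpolated TEM values clamped up to ``floor``; uncovered pixels are
    exactly 0 — the strict background/foreground separation the display
    colormap keys on.  The canvas size is the template's and must not
    change.
    """
    tem_remapped = np.asarray(tem_remapped)
    if tem_remapped.dtype != np.uint8:
        raise ValueError("expected an 8-bit (already remapped) TEM image")
    if int(tem_remapped.min()) < floor:
        raise ValueError(
            f"TEM image min {int(tem_remapped.min())} below floor {floor}; "
            "apply levels_remap first"
        )
    canvas_shape = tuple(int(v) for v in canvas_shape)
    if template_shape is not None and any(
        c < t for c, t in zip(canvas_shape, template_shape)
    ):
        raise ValueError(
            f"canvas {canvas_shape} smaller than template {tuple(template_shape)}; "
            "the canvas size must remain unchanged"
        )
    rr, cc = np.meshgrid(
        np.arange(canvas_shape[0], dtype=float),
        np.arange(canvas_shape[1], dtype=float),
        indexing="ij",
    )
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1)
    inv = t2d.inverse()
    src = pts @ inv.linear.T + np.asarray(inv.translation)
    upper = np.asarray(tem_remapped.shape, dtype=float) - 1.0
    inside = np.all((src >= 0.0) & (src <= upper), axis=1)
    vals = np.zeros(pts.shape[0])
    vals[inside] = ndimage.map_coordinates(
        tem_remapped.astype(np.float64), src[inside].T, order=1, mode="nearest"
    )
    out = np.floor(vals + 0.5).clip(0, 255)
    out[inside] = np.maximum(out[inside], floor)  # covered ⇒ visible
    out[~inside] = 0.0
    return out.reshape(canvas_shape).astype(np.uint8)


@dataclass
class PlacedSlice:
    """A composited TEM slice plus its analytic mapping into 3D world μm.

    ``basis`` (3×2) and ``offset`` define the affine canvas-pixel→world map
    ``world = offset + basis @ (row, col)``; ``tem_transform`` is the 2D
    registration (TEM pixel → canvas pixel), so native TEM pixel ``q`` sits
    at ``offset + basis @ tem_transform(q)``.
    """

    pixels: np.ndarray
    basis: np.ndarray
    offset: np.ndarray
    colormap: AlphaColormap
    tem_transform: SimilarityTransform2D
    provenance: dict = field(default_factory=dict)
    floor: int = 10

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.basis = np.asarray(self.basis, dtype=float)
        self.offset = np.asarray(self.offset, dtype=float).reshape(3)
        if self.basis.shape != (3, 2) or np.linalg.matrix_rank(self.basis) != 2:
            raise ValueError("basis must be a rank-2 3x2 matrix")
        v = self.pixels
        if np.any((v > 0) & (v < self.floor)):
            raise ValueError(
                f"pixels must be exactly 0 (background) or >= {self.floor} "
                "(foreground)"
            )

    def pixel_to_world(self, points) -> np.ndarray:
        """Canvas pixel (row, col) → world μm."""
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        world = p @ self.basis.T + self.offset
        return world[0] if single else world

    def tem_pixel_to_world(self, points) -> np.ndarray:
        """Native TEM pixel (row, col) → world μm (through the 2D transform)."""
        return self.pixel_to_world(self.tem_transform.apply(points))


def place_in_3d(
    composited: np.ndarray,
    t2d: SimilarityTransform2D,
    template: SliceTemplate,
    floor: int = 10,
) -> PlacedSlice:
    """Restore the 3D placement of a composited TEM slice from its template.

    The canvas shares the template's pixel lattice, so its pixel→world map
    *is* the template's chain; the 2D registration is kept alongside so
    native TEM pixel coordinates can be lifted to world as well.  The
    display colormap makes the black background fully transparent.
    """
    composited = np.asarray(composited)
    if composited.shape != template.pixels.shape:
        raise ValueError(
            f"composited shape {composited.shape} does not match template "
            f"shape {template.pixels.shape}"
        )
    origin = template.pixel_to_world((0.0, 0.0))
    e_row = template.pixel_to_world((1.0, 0.0)) - origin
    e_col = template.pixel_to_world((0.0, 1.0)) - origin
    basis = np.stack([e_row, e_col], axis=1)
    return PlacedSlice(
        pixels=composited,
        basis=basis,
        offset=origin,
        colormap=tem_alpha_colormap(),
        tem_transform=t2d,
        provenance={
            "slice_index": template.slice_index,
            "crop_offset": list(template.crop_offset),
            "pixel_size_um": list(template.pixel_size),
            "t2d": {"angle_rad": t2d.angle, "scale": t2d.scale,
                    "translation_px": list(t2d.translation)},
        },
        floor=floor,
    )
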