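"""Seeded multimodal phantoms with known ground-truth transforms.

No raw correlative dataset ships with the package, so every pipeline stage
is exercised on a synthetic specimen instead: a handful of ellipsoidal and
cuboidal "organs" with distinct densities inside a ~0.8 mm canvas (the scale
of a juvenile bivalve), rendered three ways —

* CT-like: bright specimen on dark background, isotropic grid, mild blur
  and noise;
* LM-like: dark specimen on bright (inverted) contrast on an anisotropic
  section grid related to the canvas frame by a known rigid(+scale)
  transform, with optional per-slice in-plane jitter (serial-section
  alignment residuals) and an optional mismatch between true and declared
  section thickness (a microtome calibration error);
* TEM-like: a high-resolution 2D crop of one LM section with added
  sub-LM-resolution texture, related to the section by a known 2D
  similarity transform.

All generators are pure functions of (spec, seed): the same spec yields
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import (
    AffineTransform3D,
    ImageGrid,
    LabelVolume,
    SimilarityTransform2D,
    VolumeImage,
    compose,
    voxel_to_world,
)

__all__ = [
    "Body",
    "PhantomSpec",
    "make_phantom",
    "simulate_microct",
    "simulate_lm_stack",
    "simulate_tem_image",
    "per_slice_jitter",
    "registration_residuals",
    "tem_scale_spec",
    "random_rigid_truth",
]

#: peak gray value of a density-1 structure in simulated 8-bit renderings
_PEAK_GRAY = 230.0


@dataclass(frozen=True)
class Body:
    """One phantom organ: an ellipsoid or axis-aligned cuboid.

    ``center`` and ``semi_axes`` are in world μm (z, y, x); ``density`` is
    the organ's X-ray-density surrogate in [0, 1].
    """

    kind: str
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    density: float
    label: int
    name: str

    def __post_init__(self) -> None:
        if self.kind not in ("ellipsoid", "cuboid"):
            raise ValueError(f"unknown body kind {self.kind!r}")
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("density must lie in [0, 1]")
        if self.label < 1:
            raise ValueError("body labels start at 1 (0 is background)")


def _default_bodies() -> tuple[Body, ...]:
    # asymmetric layout on a 0–800 μm canvas; densities pairwise >= 0.1 apart
    return (
        Body("ellipsoid", (400, 400, 400), (330, 300, 260), 0.30, 1, "soft tissue"),
        Body("ellipsoid", (400, 290, 300), (150, 115, 95), 0.55, 2, "muscle"),
        Body("cuboid", (430, 480, 420), (120, 85, 70), 0.45, 3, "digestive system"),
        Body("ellipsoid", (300, 430, 545), (75, 62, 55), 0.80, 4, "left kidney"),
        Body("ellipsoid", (520, 440, 545), (75, 62, 55), 0.90, 5, "right kidney"),
    )


def _default_canvas() -> ImageGrid:
    return ImageGrid(shape=(64, 64, 64), spacing=(12.5, 12.5, 12.5))


def _default_lm_grid() -> ImageGrid:
    # anisotropic section grid: coarse stacking (z) axis, finer in-plane
    return ImageGrid(shape=(50, 100, 100), spacing=(16.0, 8.0, 8.0))


@dataclass(frozen=True)
class PhantomSpec:
    """Seeded recipe for one multimodal phantom.

    ``lm_truth`` maps LM-stack world coordinates into the canvas (CT) frame
    and is what 3D registration must recover.  ``slice_thickness`` is the
    ``(declared, true)`` section thickness pair in μm — unequal values
    emulate a microtome cutting e.g. 0.95 μm while 1.0 μm is assumed.
    ``tem_truth`` maps TEM pixels into the high-resolution template frame.
    """

    seed: int = 0
    canvas: ImageGrid = field(default_factory=_default_canvas)
    bodies: tuple[Body, ...] = field(default_factory=_default_bodies)
    texture_amp: float = 0.06
    edge_width: float = 0.10
    ct_blur_sigma: float = 0.8
    ct_noise_sigma: float = 3.0
    lm_blur_sigma: float = 0.6
    lm_noise_sigma: float = 3.0
    lm_grid: ImageGrid = field(default_factory=_default_lm_grid)
    lm_truth: AffineTransform3D = field(
        default_factory=AffineTransform3D.identity
    )
    per_slice_jitter_sigma: float = 0.0
    slice_thickness: tuple[float, float] = (16.0, 16.0)
    tem_slice_index: int = 25
    tem_roi: tuple[int, int, int, int] = (38, 40, 26, 26)
    tem_pixel_size: float = 0.5
    tem_truth: SimilarityTransform2D = field(default_factory=SimilarityTransform2D)
    tem_texture_amp: float = 6.0
    tem_noise_sigma: float = 2.0

    def __post_init__(self) -> None:
        if not self.bodies:
            raise ValueError("a phantom needs at least one body")


def _body_radius(body: Body, world: np.ndarray) -> np.ndarray:
    """Normalized radius: <= 1 inside the body (world is (N, 3) μm)."""
    rel = np.abs(world - np.asarray(body.center)) / np.asarray(body.semi_axes)
    if body.kind == "ellipsoid":
        return np.sqrt((rel**2).sum(axis=1))
    return rel.max(axis=1)


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, LabelVolume]:
    """Render the continuous density field and matching label volume.

    Densities combine by maximum, so an organ embedded in the soft-tissue
    envelope keeps its own density; labels follow body order, later entries
    overwriting earlier ones where they overlap.  A seeded band-limited
    texture is added inside the specimen.
    """
    grid = spec.canvas
    idx = np.indices(grid.shape, dtype=np.float64).reshape(3, -1).T
    world = idx * np.asarray(grid.spacing) + np.asarray(grid.origin)

    density = np.zeros(world.shape[0])
    labels = np.zeros(world.shape[0], dtype=np.int32)
    for body in spec.bodies:
        r = _body_radius(body, world)
        contrib = body.density * _smoothstep((1.0 - r) / spec.edge_width)
        density = np.maximum(density, contrib)
        # membership is geometric; later bodies overwrite, so organs listed
        # after the enclosing envelope keep their own label
        labels[r <= 1.0] = body.label

    density = density.reshape(grid.shape)
    if spec.texture_amp > 0:
        rng = np.random.default_rng([spec.seed, 101])
        tex = ndimage.gaussian_filter(rng.standard_normal(grid.shape), 1.5)
        tex /= max(tex.std(), 1e-12)
        density = density + spec.texture_amp * tex * (density > 0.05)
    density = np.clip(density, 0.0, 1.0)

    names = {b.label: b.name for b in spec.bodies}
    label_vol = LabelVolume(
        grid=grid, labels=labels.reshape(grid.shape),
        names={k: v for k, v in names.items()
               if k in np.unique(labels)},
    )
    return density, label_vol


def simulate_microct(density: np.ndarray, spec: PhantomSpec) -> VolumeImage:
    """CT-like rendering: bright specimen on near-black background."""
    img = density * _PEAK_GRAY
    if spec.ct_blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.ct_blur_sigma)
    if spec.ct_noise_sigma > 0:
        rng = np.random.default_rng([spec.seed, 202])
        img = img + rng.normal(0.0, spec.ct_noise_sigma, img.shape)
    return VolumeImage(
        grid=spec.canvas,
        voxels=np.floor(img + 0.5).clip(0, 255).astype(np.uint8),
        modality="microct",
    )


def per_slice_jitter(spec: PhantomSpec) -> np.ndarray:
    """The (nz, 2) in-plane jitter shifts (μm) applied to each LM section.

    Serial-section alignment works section-to-section, so placement errors
    accumulate along the series rather than staying independent: the jitter
    is a mean-centered random walk whose per-section step has standard
    deviation ``per_slice_jitter_sigma``.  Sections far from the stack
    center therefore drift furthest — the misalignment pattern a rigid
    stack-to-stack registration cannot absorb and that shows up as
    peripheral deviations.  Deterministic per spec; exposed so
    residual-analysis code can compare a registration against the true
    (jittered) material positions.
    """
    rng = np.random.default_rng([spec.seed, 303])
    steps = rng.normal(0.0, spec.per_slice_jitter_sigma,
                       (spec.lm_grid.shape[0], 2))
    walk = np.cumsum(steps, axis=0)
    return walk - walk.mean(axis=0)


def simulate_lm_stack(
    density: np.ndarray, spec: PhantomSpec
) -> tuple[VolumeImage, AffineTransform3D]:
    """LM-like section stack plus the exact transform that places it.

    Each section samples the density field at positions pulled through
    ``lm_truth``; contrast is inverted (dark specimen on bright background).
    Sections are cut at the *true* thickness while the stack's grid declares
    the declared one, and each section may receive an independent in-plane
    jitter shift.  The returned transform is the effective map the
    registration should recover: ``lm_truth`` composed with the implied
    stacking-axis rescale when declared and true thickness differ.
    """
    grid = spec.lm_grid
    declared, true = spec.slice_thickness
    if abs(declared - grid.spacing[0]) > 1e-9:
        raise ValueError(
            f"declared slice thickness {declared} must equal the LM grid's "
            f"z-spacing {grid.spacing[0]}"
        )
    idx = np.indices(grid.shape, dtype=np.float64).reshape(3, -1).T
    # material positions: true thickness along z, declared in-plane spacing
    spacing_true = (true, grid.spacing[1], grid.spacing[2])
    pos = idx * np.asarray(spacing_true) + np.asarray(grid.origin)

    if spec.per_slice_jitter_sigma > 0:
        jit = per_slice_jitter(spec)
        pos = pos.reshape(grid.shape + (3,))
        pos[..., 1] += jit[:, 0, None, None]
        pos[..., 2] += jit[:, 1, None, None]
        pos = pos.reshape(-1, 3)

    canvas_pos = pos @ spec.lm_truth.linear.T + spec.lm_truth.translation
    src = (canvas_pos - np.asarray(spec.canvas.origin)) / np.asarray(
        spec.canvas.spacing
    )
    dens = ndimage.map_coordinates(density, src.T, order=1, mode="constant", cval=0.0)
    img = 255.0 - dens.reshape(grid.shape) * _PEAK_GRAY
    if spec.lm_blur_sigma > 0:
        img = ndimage.gaussian_filter(
            img, (0.0, spec.lm_blur_sigma, spec.lm_blur_sigma)
        )
    if spec.lm_noise_sigma > 0:
        rng = np.random.default_rng([spec.seed, 404])
        img = img + rng.normal(0.0, spec.lm_noise_sigma, img.shape)
    volume = VolumeImage(
        grid=grid,
        voxels=np.floor(img + 0.5).clip(0, 255).astype(np.uint8),
        modality="lm",
    )

    # effective truth in terms of the *declared* grid: rescale z about the
    # grid origin, then the nominal truth
    ratio = true / declared
    linear = np.diag([ratio, 1.0, 1.0])
    oz = np.asarray(grid.origin)
    rescale = AffineTransform3D(
        linear, oz - linear @ oz,
        mode="rigid" if abs(ratio - 1.0) < 1e-12 else "rigid_aniso_scale",
    )
    return volume, compose(spec.lm_truth, rescale)


def simulate_tem_image(
    lm_stack: VolumeImage, spec: PhantomSpec
) -> tuple[np.ndarray, SimilarityTransform2D]:
    """TEM-like high-resolution crop of one LM section, plus its 2D truth.

    The chosen section's region of interest is supersampled to
    ``tem_pixel_size``, warped by ``tem_truth`` (TEM pixel → template
    pixel, so the generated image is the template seen through the inverse
    map), and given seeded sub-LM-resolution texture and noise.
    """
    nz, ny, nx = lm_stack.grid.shape
    if not 0 <= spec.tem_slice_index < nz:
        raise ValueError(f"tem slice index {spec.tem_slice_index} out of bounds")
    r0, c0, h, w = spec.tem_roi
    if r0 < 0 or c0 < 0 or r0 + h > ny or c0 + w > nx:
        raise ValueError(f"tem roi {spec.tem_roi} outside the {ny}x{nx} section")
    section = lm_stack.voxels[spec.tem_slice_index].astype(np.float64)
    fy = lm_stack.grid.spacing[1] / spec.tem_pixel_size
    fx = lm_stack.grid.spacing[2] / spec.tem_pixel_size
    out_shape = (int(round(h * fy)), int(round(w * fx)))

    # TEM pixel q shows the template at tem_truth(q) (in high-res pixels);
    # convert to section voxels to sample the content.  Sampling the whole
    # section (not just the crop) keeps material beyond the template edge
    # physical rather than replicated.
    rr, cc = np.meshgrid(
        np.arange(out_shape[0], dtype=float),
        np.arange(out_shape[1], dtype=float),
        indexing="ij",
    )
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1)
    tpl = pts @ spec.tem_truth.linear.T + np.asarray(spec.tem_truth.translation)
    # cell-centered template pixels: HR pixel q sits at source-voxel
    # coordinate (q + 0.5)/f - 0.5 within the crop
    src = (tpl + 0.5) / np.array([fy, fx]) - 0.5 + np.array([r0, c0])
    img = ndimage.map_coordinates(section, src.T, order=1, mode="nearest")
    img = img.reshape(out_shape)

    rng = np.random.default_rng([spec.seed, 505])
    if spec.tem_texture_amp > 0:
        tex = ndimage.gaussian_filter(rng.standard_normal(out_shape), 1.0)
        tex /= max(tex.std(), 1e-12)
        img = img + spec.tem_texture_amp * tex
    if spec.tem_noise_sigma > 0:
        img = img + rng.normal(0.0, spec.tem_noise_sigma, out_shape)
    return (
        np.floor(img + 0.5).clip(0, 255).astype(np.uint8),
        spec.tem_truth,
    )


def registration_residuals(
    spec: PhantomSpec, recovered: AffineTransform3D
) -> tuple[np.ndarray, np.ndarray]:
    """Residual displacement of every LM voxel under a recovered transform.

    For each voxel the *true* canvas position of its material (including
    per-slice jitter and the true section thickness) is compared with where
    the recovered stack-to-stack transform puts the voxel's declared-grid
    position.  Returns ``(residual_magnitude_um, normalized_radius)`` flat
    arrays, where the radius is the Euclidean norm of per-axis offsets from
    the stack center normalized by the half-extent — 0 at the specimen
    center, ~1 at the corners.  A rigid stack-to-stack fit cannot absorb
    per-section misalignment, so residuals concentrate away from the center.
    """
    grid = spec.lm_grid
    declared, true = spec.slice_thickness
    idx = np.indices(grid.shape, dtype=np.float64).reshape(3, -1).T
    pos_true = idx * np.asarray((true, grid.spacing[1], grid.spacing[2]))
    pos_true += np.asarray(grid.origin)
    if spec.per_slice_jitter_sigma > 0:
        jit = per_slice_jitter(spec)
        pos_true = pos_true.reshape(grid.shape + (3,))
        pos_true[..., 1] += jit[:, 0, None, None]
        pos_true[..., 2] += jit[:, 1, None, None]
        pos_true = pos_true.reshape(-1, 3)
    target = pos_true @ spec.lm_truth.linear.T + spec.lm_truth.translation

    pos_declared = idx * np.asarray(grid.spacing) + np.asarray(grid.origin)
    mapped = pos_declared @ recovered.linear.T + recovered.translation
    residual = np.linalg.norm(mapped - target, axis=1)

    center = np.asarray(grid.center)
    half = np.asarray(grid.extent) / 2.0
    radius = np.linalg.norm((pos_declared - center) / half, axis=1)
    return residual, radius


def tem_scale_spec(
    seed: int = 0,
    tem_truth: SimilarityTransform2D | None = None,
    lm_truth: AffineTransform3D | None = None,
) -> PhantomSpec:
    """Phantom at true TEM working scale for the 2D embedding chain.

    The default phantom trades resolution for whole-specimen coverage; this
    variant instead mimics the physical scales of an actual re-sectioning
    setup — 1.2 μm isotropic CT-like canvas, 0.413 μm in-plane / 1.5 μm
    sections, 0.025 μm TEM pixels (a 16.52× supersampling) — over a ~100 μm
    field so that sub-micrometre placement accuracy is meaningful.
    """
    canvas = ImageGrid(shape=(8, 96, 96), spacing=(1.2, 1.2, 1.2))
    bodies = (
        Body("ellipsoid", (4.8, 57.6, 57.6), (6.0, 45.0, 40.0), 0.30, 1,
             "soft tissue"),
        Body("ellipsoid", (4.2, 40.0, 45.0), (4.5, 14.0, 11.0), 0.55, 2,
             "muscle"),
        Body("cuboid", (5.2, 68.0, 52.0), (4.0, 12.0, 9.0), 0.45, 3,
             "digestive system"),
        Body("ellipsoid", (4.6, 60.0, 72.0), (3.5, 8.0, 7.0), 0.80, 4,
             "left kidney"),
        Body("ellipsoid", (5.4, 44.0, 70.0), (3.5, 8.0, 7.0), 0.90, 5,
             "right kidney"),
    )
    lm_grid = ImageGrid(shape=(4, 140, 140), spacing=(1.5, 0.413, 0.413),
                        origin=(1.8, 29.0, 29.0))
    return PhantomSpec(
        seed=seed,
        canvas=canvas,
        bodies=bodies,
        texture_amp=0.10,
        lm_grid=lm_grid,
        lm_truth=lm_truth or AffineTransform3D.identity(),
        slice_thickness=(1.5, 1.5),
        tem_slice_index=2,
        tem_roi=(50, 52, 28, 28),
        tem_pixel_size=0.025,
        tem_truth=tem_truth or SimilarityTransform2D(),
    )


def random_rigid_truth(
    rng: np.random.Generator,
    max_rot_deg: float = 10.0,
    max_trans_um: float = 20.0,
    pivot: tuple[float, float, float] = (400.0, 400.0, 400.0),
) -> AffineTransform3D:
    """Draw a rigid ground-truth transform with bounded rotations and
    translations (uniform per axis), pivoting about the specimen center."""
    angles = np.deg2rad(rng.uniform(-max_rot_deg, max_rot_deg, 3))
    trans = rng.uniform(-max_trans_um, max_trans_um, 3)
    return AffineTransform3D.from_euler(angles, trans, pivot=pivot, mode="rigid")
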