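"""Grids, images, transforms and transform algebra in physical coordinates.

Conventions used throughout the package
---------------------------------------
* Array index order is ``(z, y, x)`` = (slice, row, column); world axes are
  ordered the same way and measured in micrometres (μm).
* Indices are 0-based and a voxel's world coordinate is the coordinate of
  its *center*; intervals are half-open in voxel space.
* 3D transforms map *moving-world* coordinates into *fixed-world*
  coordinates.  Resampling a moving image onto a fixed grid therefore pulls
  values back through the inverse transform.
* Rotations are parameterized as intrinsic Euler angles applied about an
  explicit pivot point (by default the physical center of the volume being
  moved), which keeps rotation and translation parameters comparably scaled
  during optimization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ImageGrid",
    "VolumeImage",
    "LabelVolume",
    "AffineTransform3D",
    "SimilarityTransform2D",
    "RegistrationResult",
    "AlphaColormap",
    "SingularTransformError",
    "compose",
    "invert",
    "voxel_to_world",
    "world_to_voxel",
    "tem_alpha_colormap",
]

#: ordering of transform rigidity modes, weakest constraint last
MODES = ("rigid", "rigid_iso_scale", "rigid_aniso_scale")

CONVENTION = "moving_world_to_fixed_world"


class SingularTransformError(ValueError):
    """Raised when a transform's linear part is (numerically) singular."""


@dataclass(frozen=True)
class ImageGrid:
    """A regular 3D voxel lattice embedded in physical space.

    Parameters
    ----------
    shape
        Voxel counts ``(nz, ny, nx)``.
    spacing
        Voxel edge lengths ``(sz, sy, sx)`` in μm; all positive.
    origin
        World coordinate (μm) of the *center* of voxel ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("shape, spacing and origin must have length 3")
        if any(n < 1 for n in shape):
            raise ValueError(f"all shape entries must be >= 1, got {shape}")
        if any(not np.isfinite(s) or s <= 0 for s in spacing):
            raise ValueError(f"all spacing entries must be > 0, got {spacing}")
        if any(not np.isfinite(o) for o in origin):
            raise ValueError(f"origin must be finite, got {origin}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size ``shape * spacing`` per axis, in μm."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    @property
    def center(self) -> tuple[float, float, float]:
        """World coordinate of the volume's physical center, in μm."""
        return tuple(
            o + (n - 1) / 2.0 * s
            for o, n, s in zip(self.origin, self.shape, self.spacing)
        )

    def voxel_to_world(self, index: Sequence[float]) -> np.ndarray:
        return voxel_to_world(self, index)

    def world_to_voxel(self, world: Sequence[float]) -> np.ndarray:
        return world_to_voxel(self, world)


def voxel_to_world(grid: ImageGrid, index: Sequence[float]) -> np.ndarray:
    """Map (fractional) voxel indices to world coordinates in μm.

    ``world = origin + index * spacing`` componentwise.  Accepts a single
    triple or an ``(N, 3)`` array of indices; out-of-range and fractional
    indices are allowed (the map is affine on all of R^3).
    """
    idx = np.asarray(index, dtype=float)
    return np.asarray(grid.origin) + idx * np.asarray(grid.spacing)


def world_to_voxel(grid: ImageGrid, world: Sequence[float]) -> np.ndarray:
    """Exact inverse of :func:`voxel_to_world`."""
    w = np.asarray(world, dtype=float)
    return (w - np.asarray(grid.origin)) / np.asarray(grid.spacing)


@dataclass
class VolumeImage:
    """An 8-bit intensity volume on an :class:`ImageGrid`.

    ``modality`` tags the acquisition source (``microct``, ``lm`` or
    ``other``); it never changes numerical behaviour.
    """

    grid: ImageGrid
    voxels: np.ndarray
    modality: str = "other"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.shape != self.grid.shape:
            raise ValueError(
                f"voxel array shape {self.voxels.shape} does not match "
                f"grid shape {self.grid.shape}"
            )
        if self.voxels.dtype != np.uint8:
            v = self.voxels
            if v.min() < 0 or v.max() > 255:
                raise ValueError("voxel values must lie in [0, 255]")
            self.voxels = v.astype(np.uint8)
        if self.modality not in ("microct", "lm", "other"):
            raise ValueError(f"unknown modality tag {self.modality!r}")


@dataclass
class LabelVolume:
    """Integer label field on an :class:`ImageGrid`; 0 is background.

    Every non-zero label present in ``labels`` must have an entry in
    ``names`` (e.g. an organ-system name); label 0 is never named.
    """

    grid: ImageGrid
    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.shape:
            raise ValueError(
                f"label array shape {self.labels.shape} does not match "
                f"grid shape {self.grid.shape}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels {sorted(missing)} have no name")
        if 0 in self.names:
            raise ValueError("label 0 (background) must not be named")


def _check_mode_invariants(linear: np.ndarray, mode: str, tol: float = 1e-9) -> None:
    det = np.linalg.det(linear)
    if abs(det) <= 1e-12:
        raise SingularTransformError(
            f"degenerate transform: |det linear| = {abs(det):.3g} <= 1e-12"
        )
    if mode == "rigid":
        if not np.allclose(linear.T @ linear, np.eye(3), atol=tol):
            raise ValueError("rigid mode requires an orthogonal linear part")
        if abs(det - 1.0) > tol:
            raise ValueError("rigid mode requires det = +1 (no reflection)")
    elif mode == "rigid_iso_scale":
        s = np.cbrt(det)
        if s <= 0:
            raise ValueError("rigid_iso_scale requires positive determinant")
        if not np.allclose((linear / s).T @ (linear / s), np.eye(3), atol=tol):
            raise ValueError("rigid_iso_scale requires linear = s * R, R orthogonal")
    elif mode != "rigid_aniso_scale":
        raise ValueError(f"unknown transform mode {mode!r}")


@dataclass(frozen=True)
class AffineTransform3D:
    """Affine map from moving-world to fixed-world coordinates (μm).

    ``linear`` is the 3×3 matrix acting on (z, y, x) world vectors and
    ``translation`` is added afterwards.  ``mode`` declares how constrained
    the map is and is enforced at construction:

    * ``rigid`` — rotation + translation (orthogonal, det +1),
    * ``rigid_iso_scale`` — one global scale factor times a rotation,
    * ``rigid_aniso_scale`` — per-axis scales times a rotation.
    """

    linear: np.ndarray
    translation: np.ndarray
    mode: str = "rigid"
    convention: str = CONVENTION

    def __post_init__(self) -> None:
        linear = np.array(self.linear, dtype=float)
        translation = np.array(self.translation, dtype=float).reshape(3)
        if linear.shape != (3, 3):
            raise ValueError("linear part must be a 3x3 matrix")
        _check_mode_invariants(linear, self.mode)
        linear.setflags(write=False)
        translation.setflags(write=False)
        object.__setattr__(self, "linear", linear)
        object.__setattr__(self, "translation", translation)

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls, mode: str = "rigid") -> "AffineTransform3D":
        return cls(np.eye(3), np.zeros(3), mode=mode)

    @classmethod
    def translate(cls, dz: float, dy: float, dx: float,
                  mode: str = "rigid") -> "AffineTransform3D":
        return cls(np.eye(3), np.array([dz, dy, dx]), mode=mode)

    @classmethod
    def from_euler(
        cls,
        angles_zyx: Sequence[float],
        translation: Sequence[float] = (0.0, 0.0, 0.0),
        scales: Sequence[float] | float = 1.0,
        pivot: Sequence[float] = (0.0, 0.0, 0.0),
        mode: str | None = None,
    ) -> "AffineTransform3D":
        """Build rotation(+scale)+translation about an explicit pivot.

        ``angles_zyx`` are intrinsic Euler rotations (radians) about the
        z, y and x world axes, applied in that order.  ``scales`` is a
        scalar (isotropic) or per-axis triple.  The map is::

            p  ↦  R S (p - pivot) + pivot + translation
        """
        az, ay, ax = (float(a) for a in angles_zyx)
        cz, sz = np.cos(az), np.sin(az)
        cy, sy = np.cos(ay), np.sin(ay)
        cx, sx = np.cos(ax), np.sin(ax)
        # rotation about world z-axis mixes (y, x); about y mixes (z, x); about
        # x mixes (z, y).  Axis order of vectors is (z, y, x).
        rz = np.array([[1, 0, 0], [0, cz, -sz], [0, sz, cz]])
        ry = np.array([[cy, 0, -sy], [0, 1, 0], [sy, 0, cy]])
        rx = np.array([[cx, -sx, 0], [sx, cx, 0], [0, 0, 1]])
        rot = rz @ ry @ rx
        s = np.asarray(scales, dtype=float)
        if s.ndim == 0:
            s = np.full(3, float(s))
        linear = rot @ np.diag(s)
        pivot = np.asarray(pivot, dtype=float)
        shift = pivot + np.asarray(translation, dtype=float) - linear @ pivot
        if mode is None:
            if np.allclose(s, 1.0, atol=1e-12):
                mode = "rigid"
            elif np.allclose(s, s[0], atol=1e-12):
                mode = "rigid_iso_scale"
            else:
                mode = "rigid_aniso_scale"
        return cls(linear, shift, mode=mode)

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, mode: str = "rigid_aniso_scale",
                    convention: str = CONVENTION) -> "AffineTransform3D":
        """Build from a 4×4 homogeneous matrix (last row (0,0,0,1))."""
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("expected a 4x4 homogeneous matrix")
        if not np.allclose(m[3], [0, 0, 0, 1], atol=1e-12):
            raise ValueError("last row of a homogeneous affine must be (0,0,0,1)")
        return cls(m[:3, :3], m[:3, 3], mode=mode, convention=convention)

    # -- queries -----------------------------------------------------------
    @property
    def matrix(self) -> np.ndarray:
        """4×4 homogeneous matrix form."""
        m = np.eye(4)
        m[:3, :3] = self.linear
        m[:3, 3] = self.translation
        return m

    def apply(self, points: Sequence[float] | np.ndarray) -> np.ndarray:
        """Apply to one (z, y, x) point or an (N, 3) array, in μm."""
        p = np.asarray(points, dtype=float)
        return p @ self.linear.T + self.translation

    def __call__(self, points) -> np.ndarray:
        return self.apply(points)

    def scales(self) -> np.ndarray:
        """Per-axis scale factors of the linear part (singular values)."""
        return np.linalg.svd(self.linear, compute_uv=False)

    def axis_scales(self) -> np.ndarray:
        """Scale applied to each (z, y, x) moving axis: column norms of
        the linear part.  For ``linear = R·diag(s)`` this recovers ``s``
        exactly, e.g. a stacking-axis scale absorbing a section-thickness
        error."""
        return np.linalg.norm(self.linear, axis=0)

    def rotation_angle(self) -> float:
        """Total rotation angle (radians) of the rotation factor.

        The linear part is polar-decomposed as R·P; the angle of R is
        returned.  For rigid and iso-scale transforms this is exact.
        """
        u, _, vt = np.linalg.svd(self.linear)
        r = u @ vt
        if np.linalg.det(r) < 0:  # reflection guard; not reachable for our modes
            u[:, -1] *= -1
            r = u @ vt
        c = (np.trace(r) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))


def compose(outer: AffineTransform3D, inner: AffineTransform3D) -> AffineTransform3D:
    """Composition ``outer ∘ inner``: for every p, result(p) = outer(inner(p)).

    The result's mode is the weakest (least constrained) of the two, so
    rigid∘rigid stays rigid while anything involving scale is widened.
    """
    if outer.convention != inner.convention:
        raise ValueError(
            f"cannot compose transforms with different conventions: "
            f"{outer.convention!r} vs {inner.convention!r}"
        )
    mode = MODES[max(MODES.index(outer.mode), MODES.index(inner.mode))]
    return AffineTransform3D(
        outer.linear @ inner.linear,
        outer.linear @ inner.translation + outer.translation,
        mode=mode,
        convention=outer.convention,
    )


def invert(t: AffineTransform3D) -> AffineTransform3D:
    """Inverse map; ``compose(t, invert(t))`` is the identity. Mode preserved."""
    try:
        inv = np.linalg.inv(t.linear)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded earlier
        raise SingularTransformError("degenerate transform cannot be inverted") from exc
    return AffineTransform3D(inv, -inv @ t.translation, mode=t.mode,
                             convention=t.convention)


@dataclass(frozen=True)
class SimilarityTransform2D:
    """2D similarity map in pixel coordinates: rotation + isotropic scale + shift.

    Maps *moving* (TEM) pixel coordinates ``(row, col)`` into *fixed*
    (template) pixel coordinates:  ``q = s R p + t``.
    """

    angle: float = 0.0
    scale: float = 1.0
    translation: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not np.isfinite(self.scale) or self.scale <= 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")
        object.__setattr__(self, "angle", float(self.angle))
        object.__setattr__(self, "scale", float(self.scale))
        object.__setattr__(
            self, "translation", tuple(float(v) for v in self.translation)
        )

    @property
    def linear(self) -> np.ndarray:
        c, s = np.cos(self.angle), np.sin(self.angle)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.linear.T + np.asarray(self.translation)

    def __call__(self, points) -> np.ndarray:
        return self.apply(points)

    def inverse(self) -> "SimilarityTransform2D":
        inv_lin = np.linalg.inv(self.linear)
        t = -inv_lin @ np.asarray(self.translation)
        return SimilarityTransform2D(-self.angle, 1.0 / self.scale, tuple(t))


@dataclass
class RegistrationResult:
    """Outcome of a metric-driven registration.

    ``trace`` records ``(pyramid_level, iteration, metric)`` for every
    accepted step; ``final_metric`` is the last trace entry.  Correlation
    metrics live in [-1, 1].
    """

    transform: object
    final_metric: float
    trace: list[tuple[int, int, float]]
    converged: bool
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for _, _, m in self.trace:
            if not -1.0 - 1e-9 <= m <= 1.0 + 1e-9:
                raise ValueError(f"trace metric {m} outside [-1, 1]")
        if self.trace and abs(self.trace[-1][2] - self.final_metric) > 1e-12:
            raise ValueError("final_metric must equal the last trace entry")


@dataclass(frozen=True)
class AlphaColormap:
    """Opacity lookup table: 256 integer opacities in [0, 255] by gray value."""

    opacity: tuple[int, ...]

    def __post_init__(self) -> None:
        op = tuple(int(v) for v in self.opacity)
        if len(op) != 256:
            raise ValueError(f"opacity table must have 256 entries, got {len(op)}")
        if any(v < 0 or v > 255 for v in op):
            raise ValueError("opacity entries must lie in [0, 255]")
        object.__setattr__(self, "opacity", op)

    def __getitem__(self, gray: int) -> int:
        return self.opacity[gray]


def tem_alpha_colormap() -> AlphaColormap:
    """Display colormap for embedded TEM slices.

    Gray values 0–9 are fully transparent (opacity 0) and 10–255 fully
    opaque (opacity 255): with the TEM histogram remapped to 10–255 and the
    background composited to exact 0, the black surround disappears while
    every true image pixel stays visible.
    """
    return AlphaColormap(tuple(0 if g < 10 else 255 for g in range(256)))
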