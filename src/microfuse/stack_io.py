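"""Read/write image stacks, 2D images, transforms and scene descriptions.

Stacks travel as plain multi-page 8-bit grayscale TIFF (page k = slice k)
with spacing recorded in ImageJ-style resolution metadata; transforms and
scenes are versioned JSON documents.  Spacing is *always* caller-provided on
read — TIFF resolution tags are recorded for interoperability but are never
trusted as the source of truth.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

from .core import CONVENTION, AffineTransform3D, ImageGrid, VolumeImage

__all__ = [
    "FORMAT_VERSION",
    "SceneEntry",
    "read_stack",
    "write_stack",
    "read_image2d",
    "write_image2d",
    "read_transform",
    "write_transform",
    "read_scene",
    "write_scene",
    "TransformFileError",
    "SceneFileError",
]

log = logging.getLogger(__name__)

FORMAT_VERSION = "1.0"


class TransformFileError(ValueError):
    """Malformed or inconsistent transform JSON."""


class SceneFileError(ValueError):
    """Malformed or inconsistent scene JSON."""


# ---------------------------------------------------------------------------
# stacks


def read_stack(
    path: str | os.PathLike,
    spacing: Sequence[float],
    modality: str = "other",
    origin: Sequence[float] = (0.0, 0.0, 0.0),
    rescale_16bit: bool = False,
) -> VolumeImage:
    """Read a multi-page single-channel TIFF stack as a :class:`VolumeImage`.

    ``spacing`` is mandatory, in μm as ``(sz, sy, sx)``: resolution tags in
    the file are compared against it (a mismatch beyond 0.1% is logged) but
    the caller's value always wins.  16-bit input is accepted only with
    ``rescale_16bit=True`` and is linearly rescaled to 0–255.
    """
    if spacing is None:
        raise ValueError("spacing is mandatory and never guessed from TIFF tags")
    with tifffile.TiffFile(str(path)) as tf:
        samples = tf.pages[0].samplesperpixel
        if samples != 1:
            raise ValueError(
                f"expected a single-channel stack, got {samples} channels"
            )
        arr = tf.asarray()
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise ValueError(
            f"expected a single-channel stack, got array with {arr.ndim} "
            f"dimensions (shape {arr.shape})"
        )
    if arr.dtype == np.uint16:
        if not rescale_16bit:
            raise ValueError(
                "16-bit stack requires rescale_16bit=True (explicit opt-in)"
            )
        lo, hi = int(arr.min()), int(arr.max())
        span = max(hi - lo, 1)
        arr = np.floor((arr.astype(np.float64) - lo) * 255.0 / span + 0.5).astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise ValueError(f"unsupported dtype {arr.dtype}; expected uint8 or uint16")

    _check_file_spacing(path, spacing)
    grid = ImageGrid(shape=arr.shape, spacing=tuple(spacing), origin=tuple(origin))
    return VolumeImage(grid=grid, voxels=arr, modality=modality)


def _check_file_spacing(path, spacing) -> None:
    """Warn if the file's resolution tags disagree with the caller > 0.1%."""
    try:
        with tifffile.TiffFile(str(path)) as tf:
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            yres = page.tags.get("YResolution")
            file_sp = []
            ij = tf.imagej_metadata or {}
            if "spacing" in ij:
                file_sp.append(("z", float(ij["spacing"]), float(spacing[0])))
            for name, tag, sp in (("y", yres, spacing[1]), ("x", xres, spacing[2])):
                if tag is not None:
                    num, den = tag.value
                    if num:
                        file_sp.append((name, den / num, float(sp)))
            for axis, from_file, from_caller in file_sp:
                if from_file > 0 and abs(from_file - from_caller) / from_caller > 1e-3:
                    log.warning(
                        "%s: %s-spacing in file (%.6g μm) differs from caller "
                        "(%.6g μm); caller value used",
                        path, axis, from_file, from_caller,
                    )
    except Exception:  # tag sniffing is best-effort only
        pass


def write_stack(
    volume: VolumeImage, path: str | os.PathLike, compress: bool = False
) -> Path:
    """Write a volume as multi-page 8-bit grayscale TIFF.

    Spacing goes into ImageJ-style metadata (XResolution/YResolution in
    pixels per μm, z-spacing in the ImageJ block) so standard viewers pick
    up the calibration.  Uncompressed by default; ``compress`` enables
    deflate.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory {path.parent} does not exist")
    sz, sy, sx = volume.grid.spacing
    tifffile.imwrite(
        str(path),
        volume.voxels,
        imagej=True,
        resolution=(1.0 / sx, 1.0 / sy),
        metadata={"spacing": sz, "unit": "um", "axes": "ZYX"},
        compression="deflate" if compress else None,
    )
    return path


# ---------------------------------------------------------------------------
# 2D images


def read_image2d(path: str | os.PathLike) -> np.ndarray:
    """Read a 2D 8-bit grayscale TIFF/PNG image."""
    arr = iio.imread(str(path))
    if arr.ndim == 3:
        if arr.shape[-1] in (3, 4) and np.all(arr[..., 0] == arr[..., 1]):
            arr = arr[..., 0]  # gray saved as RGB(A)
        else:
            raise ValueError(
                f"expected a single-channel image, got {arr.shape[-1]} channels"
            )
    if arr.dtype != np.uint8:
        raise ValueError(f"unsupported dtype {arr.dtype}; expected uint8")
    return arr


def write_image2d(image: np.ndarray, path: str | os.PathLike) -> Path:
    path = Path(path)
    image = np.asarray(image)
    if image.dtype != np.uint8 or image.ndim != 2:
        raise ValueError("expected a 2D uint8 image")
    iio.imwrite(str(path), image)
    return path


# ---------------------------------------------------------------------------
# transforms


def write_transform(
    t: AffineTransform3D, path: str | os.PathLike, provenance: str = ""
) -> Path:
    """Serialize a 3D affine transform to JSON (4×4 homogeneous matrix, μm)."""
    path = Path(path)
    doc = {
        "format_version": FORMAT_VERSION,
        "kind": "affine_transform_3d",
        "matrix": [[float(v) for v in row] for row in t.matrix],
        "convention": t.convention,
        "mode": t.mode,
        "provenance": provenance,
    }
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return path


def read_transform(path: str | os.PathLike) -> AffineTransform3D:
    """Read a transform JSON back into an :class:`AffineTransform3D`.

    Distinct errors for malformed JSON, a wrong convention string and a
    non-affine last row.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise TransformFileError(f"{path}: malformed JSON ({exc})") from exc
    matrix = np.asarray(doc.get("matrix", []), dtype=float)
    if matrix.shape != (4, 4):
        raise TransformFileError(f"{path}: matrix must be 4x4")
    if not np.allclose(matrix[3], [0, 0, 0, 1], atol=1e-12):
        raise TransformFileError(
            f"{path}: last row {matrix[3].tolist()} is not (0,0,0,1); "
            "not an affine transform"
        )
    convention = doc.get("convention")
    if convention != CONVENTION:
        raise TransformFileError(
            f"{path}: unknown convention {convention!r}; expected {CONVENTION!r}"
        )
    mode = doc.get("mode", "rigid_aniso_scale")
    return AffineTransform3D.from_matrix(matrix, mode=mode, convention=convention)


# ---------------------------------------------------------------------------
# scenes


@dataclass
class SceneEntry:
    """One dataset in a displayable scene.

    ``kind`` is ``volume``, ``labels`` or ``placed_slice``.  Volumes and
    label stacks carry grid parameters plus an optional transform file;
    placed slices must carry a full 2D→3D placement (a 3×2 in-plane basis
    and a 3-vector world offset, μm per pixel).
    """

    path: str
    kind: str
    spacing: tuple[float, float, float] | None = None
    origin: tuple[float, float, float] | None = None
    transform_path: str | None = None
    placement: dict | None = None
    colormap: str = "gray"
    opacity_scale: float = 1.0

    def to_json(self) -> dict:
        doc = {
            "path": self.path,
            "kind": self.kind,
            "display": {"colormap": self.colormap,
                        "opacity_scale": self.opacity_scale},
        }
        if self.spacing is not None:
            doc["spacing_um"] = list(self.spacing)
        if self.origin is not None:
            doc["origin_um"] = list(self.origin)
        if self.transform_path is not None:
            doc["transform_path"] = self.transform_path
        if self.placement is not None:
            doc["placement"] = self.placement
        return doc

    @classmethod
    def from_json(cls, doc: dict) -> "SceneEntry":
        display = doc.get("display", {})
        return cls(
            path=doc["path"],
            kind=doc["kind"],
            spacing=tuple(doc["spacing_um"]) if "spacing_um" in doc else None,
            origin=tuple(doc["origin_um"]) if "origin_um" in doc else None,
            transform_path=doc.get("transform_path"),
            placement=doc.get("placement"),
            colormap=display.get("colormap", "gray"),
            opacity_scale=display.get("opacity_scale", 1.0),
        )


def _validate_entries(entries: Sequence[SceneEntry], base: Path) -> None:
    for e in entries:
        if e.kind not in ("volume", "labels", "placed_slice"):
            raise SceneFileError(f"unknown entry kind {e.kind!r}")
        target = Path(e.path)
        if not target.is_absolute():
            target = base / target
        if not target.exists():
            raise SceneFileError(f"scene references missing file: {target}")
        if e.transform_path is not None:
            tpath = Path(e.transform_path)
            if not tpath.is_absolute():
                tpath = base / tpath
            if not tpath.exists():
                raise SceneFileError(f"scene references missing file: {tpath}")
        if e.kind == "placed_slice":
            pl = e.placement or {}
            if "basis" not in pl or "offset_um" not in pl:
                raise SceneFileError(
                    f"placed_slice entry {e.path!r} lacks a full 2D→3D "
                    "placement (needs 'basis' and 'offset_um')"
                )
            basis = np.asarray(pl["basis"], dtype=float)
            if basis.shape != (3, 2) or np.linalg.matrix_rank(basis) != 2:
                raise SceneFileError(
                    f"placed_slice entry {e.path!r}: basis must be a rank-2 "
                    "3x2 matrix"
                )
        elif e.spacing is None:
            raise SceneFileError(f"{e.kind} entry {e.path!r} lacks spacing_um")


def write_scene(entries: Sequence[SceneEntry], path: str | os.PathLike) -> Path:
    """Write a scene JSON; every referenced file must exist at write time.

    Keys are written in canonical sorted order so load + re-save is
    byte-identical.
    """
    path = Path(path)
    _validate_entries(entries, path.parent)
    doc = {
        "format_version": FORMAT_VERSION,
        "kind": "scene",
        "entries": [e.to_json() for e in entries],
    }
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return path


def read_scene(path: str | os.PathLike) -> list[SceneEntry]:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SceneFileError(f"{path}: malformed JSON ({exc})") from exc
    if doc.get("kind") != "scene":
        raise SceneFileError(f"{path}: not a scene file")
    return [SceneEntry.from_json(e) for e in doc.get("entries", [])]
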