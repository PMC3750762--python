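"""Similarity-enhancing preprocessing of the LM stack before registration.

MicroCT shows bright specimen on dark background; brightfield LM sections
show the opposite.  Before correlation-driven registration the LM stack is
therefore intensity-inverted (v ↦ 255 − v) and smoothed with a small 3D
Gaussian (3×3×3 voxel support by default) to suppress sub-CT-resolution
detail.  Both operators re-quantize to 8-bit, mirroring a pipeline of 8-bit
processing modules; a float-through option exists for numerical tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import VolumeImage

__all__ = ["GaussianSpec", "invert_intensities", "gaussian_smooth", "gaussian_kernel1d"]


@dataclass(frozen=True)
class GaussianSpec:
    """Separable sampled-Gaussian kernel: odd support and sigma per (z, y, x) axis.

    The default 3-voxel support with sigma 0.8 voxels is a common choice for
    a radius-1 Gaussian; both are configurable.
    """

    kernel_size: tuple[int, int, int] = (3, 3, 3)
    sigma: tuple[float, float, float] = (0.8, 0.8, 0.8)

    def __post_init__(self) -> None:
        ks = tuple(int(k) for k in self.kernel_size)
        sg = tuple(float(s) for s in self.sigma)
        if len(ks) != 3 or len(sg) != 3:
            raise ValueError("kernel_size and sigma must have one entry per axis")
        if any(k < 1 or k % 2 == 0 for k in ks):
            raise ValueError(f"kernel_size entries must be odd and >= 1, got {ks}")
        if any(s <= 0 for s in sg):
            raise ValueError(f"sigma entries must be > 0, got {sg}")
        object.__setattr__(self, "kernel_size", ks)
        object.__setattr__(self, "sigma", sg)


def gaussian_kernel1d(size: int, sigma: float) -> np.ndarray:
    """Sampled, normalized 1D Gaussian with given odd support (sum = 1)."""
    r = size // 2
    x = np.arange(-r, r + 1, dtype=float)
    w = np.exp(-0.5 * (x / sigma) ** 2)
    return w / w.sum()


def invert_intensities(volume: VolumeImage) -> VolumeImage:
    """Invert 8-bit intensities: every voxel v becomes 255 − v.

    An involution; turns dark-on-bright LM contrast into CT-like
    bright-on-dark.  Grid and modality are unchanged.
    """
    return VolumeImage(
        grid=volume.grid,
        voxels=(255 - volume.voxels).astype(np.uint8),
        modality=volume.modality,
    )


def gaussian_smooth(
    volume: VolumeImage,
    spec: GaussianSpec = GaussianSpec(),
    float_through: bool = False,
) -> VolumeImage | np.ndarray:
    """Separable 3D Gaussian smoothing with edge replication at borders.

    The normalized kernel preserves constants and never widens the value
    range.  Output is re-quantized to 8-bit by round-half-up; pass
    ``float_through=True`` to obtain the unquantized float field instead
    (for numerical comparisons).

    Edge replication (rather than zero padding) is deliberate: zero padding
    would darken the specimen rim and bias the registration metric toward
    background.
    """
    for axis, (k, n) in enumerate(zip(spec.kernel_size, volume.grid.shape)):
        if k > n:
            raise ValueError(
                f"kernel size {k} exceeds volume extent {n} along axis {axis}"
            )
    out = volume.voxels.astype(np.float64)
    for axis in range(3):
        w = gaussian_kernel1d(spec.kernel_size[axis], spec.sigma[axis])
        out = ndimage.correlate1d(out, w, axis=axis, mode="nearest")
    if float_through:
        return out
    quantized = np.floor(out + 0.5).clip(0, 255).astype(np.uint8)
    return VolumeImage(grid=volume.grid, voxels=quantized, modality=volume.modality)
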