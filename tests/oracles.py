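"""Independent brute-force oracles shared across test modules."""

import numpy as np

from microfuse import invert


def naive_pearson(fixed, moving, t):
    """Brute-force loop implementing the correlation metric's definition:

    Pearson correlation between fixed voxel values and trilinearly
    interpolated moving values over exactly the fixed voxels whose mapped
    position falls inside the moving volume's extent.
    """
    inv = invert(t)
    fvals, mvals = [], []
    nz, ny, nx = moving.grid.shape
    mv = moving.voxels.astype(float)
    for z in range(fixed.grid.shape[0]):
        for y in range(fixed.grid.shape[1]):
            for x in range(fixed.grid.shape[2]):
                w = fixed.grid.voxel_to_world((z, y, x))
                i, j, k = moving.grid.world_to_voxel(inv.apply(w))
                if not (0 <= i <= nz - 1 and 0 <= j <= ny - 1
                        and 0 <= k <= nx - 1):
                    continue
                i0 = int(np.floor(min(i, nz - 1 - 1e-12)))
                j0 = int(np.floor(min(j, ny - 1 - 1e-12)))
                k0 = int(np.floor(min(k, nx - 1 - 1e-12)))
                fz, fy, fx = i - i0, j - j0, k - k0
                val = 0.0
                for dz, wz in ((0, 1 - fz), (1, fz)):
                    for dy, wy in ((0, 1 - fy), (1, fy)):
                        for dx, wx in ((0, 1 - fx), (1, fx)):
                            val += wz * wy * wx * mv[i0 + dz, j0 + dy, k0 + dx]
                fvals.append(float(fixed.voxels[z, y, x]))
                mvals.append(val)
    f, m = np.asarray(fvals), np.asarray(mvals)
    return float(np.mean((f - f.mean()) * (m - m.mean())) / (f.std() * m.std()))
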