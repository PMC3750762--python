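"""Correlation metric, resampling, affine registration and propagation."""

import numpy as np
import pytest

from microfuse import (
    AffineTransform3D,
    ImageGrid,
    LabelVolume,
    RegistrationConfig,
    VolumeImage,
    affine_register,
    compose,
    correlation_metric,
    initial_guess,
    invert,
    invert_intensities,
    propagate_transform,
    resample_volume,
)
from microfuse.register3d import (
    DegenerateRegionError,
    InsufficientOverlapError,
    downsample_volume,
)
from oracles import naive_pearson


def random_volume(rng, shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0), origin=(0, 0, 0)):
    grid = ImageGrid(shape=shape, spacing=spacing, origin=origin)
    return VolumeImage(grid=grid,
                       voxels=rng.integers(0, 256, shape, dtype=np.uint8))


class TestCorrelationMetric:
    def test_self_correlation_is_one(self, rng):
        v = random_volume(rng)
        assert correlation_metric(v, v, AffineTransform3D.identity()) == \
            pytest.approx(1.0, abs=1e-12)

    def test_inverted_volume_anticorrelates(self, rng):
        v = random_volume(rng)
        r = correlation_metric(v, invert_intensities(v),
                               AffineTransform3D.identity())
        assert r == pytest.approx(-1.0, abs=1e-9)

    def test_matches_naive_loop_oracle(self, rng):
        for _ in range(10):
            fixed = random_volume(rng)
            moving = random_volume(rng)
            t = AffineTransform3D.from_euler(
                np.deg2rad(rng.uniform(-5, 5, 3)), rng.uniform(-1, 1, 3),
                pivot=(3.5, 3.5, 3.5), mode="rigid",
            )
            ours = correlation_metric(fixed, moving, t,
                                      min_overlap_fraction=0.1)
            assert ours == pytest.approx(naive_pearson(fixed, moving, t),
                                         abs=1e-10)

    def test_insufficient_overlap_raises(self, rng):
        v = random_volume(rng)
        far = AffineTransform3D.translate(100, 0, 0)
        with pytest.raises(InsufficientOverlapError):
            correlation_metric(v, v, far)

    def test_constant_region_raises(self):
        grid = ImageGrid(shape=(4, 4, 4), spacing=(1, 1, 1))
        flat = VolumeImage(grid=grid, voxels=np.full(grid.shape, 7, np.uint8))
        with pytest.raises(DegenerateRegionError):
            correlation_metric(flat, flat, AffineTransform3D.identity())

    def test_overlap_fraction_reported(self, rng):
        v = random_volume(rng)
        _, frac = correlation_metric(v, v, AffineTransform3D.identity(),
                                     return_detail=True)
        assert frac == pytest.approx(1.0)

    def test_symmetric_under_joint_inversion(self, rng):
        fixed, moving = random_volume(rng), random_volume(rng)
        t = AffineTransform3D.translate(0.3, -0.2, 0.6)
        a = correlation_metric(fixed, moving, t)
        b = correlation_metric(invert_intensities(fixed),
                               invert_intensities(moving), t)
        assert a == pytest.approx(b, abs=1e-9)


class TestResample:
    def test_identity_is_copy(self, rng):
        v = random_volume(rng)
        out = resample_volume(v, v.grid, AffineTransform3D.identity())
        np.testing.assert_array_equal(out.voxels, v.voxels)

    def test_one_voxel_translation_shifts_columns(self, rng):
        v = random_volume(rng, spacing=(1.0, 1.0, 2.0))
        t = AffineTransform3D.translate(0, 0, 2.0)  # exactly one x voxel
        out = resample_volume(v, v.grid, t)
        np.testing.assert_array_equal(out.voxels[:, :, 1:], v.voxels[:, :, :-1])
        assert (out.voxels[:, :, 0] == 0).all()

    def test_label_count_preserved_under_integer_shift(self):
        grid = ImageGrid(shape=(10, 10, 10), spacing=(1, 1, 1))
        labels = np.zeros(grid.shape, dtype=np.int32)
        labels[2:5, 3:6, 1:4] = 2
        lv = LabelVolume(grid=grid, labels=labels, names={2: "organ"})
        t = AffineTransform3D.translate(1.0, 2.0, 3.0)
        out = resample_volume(lv, grid, t, interpolation="nearest")
        assert (out.labels == 2).sum() == (labels == 2).sum()

    def test_linear_interpolation_rejected_for_labels(self):
        grid = ImageGrid(shape=(4, 4, 4), spacing=(1, 1, 1))
        lv = LabelVolume(grid=grid, labels=np.zeros(grid.shape, np.int32))
        with pytest.raises(ValueError, match="nearest"):
            resample_volume(lv, grid, AffineTransform3D.identity(),
                            interpolation="linear")

    def test_occupancy_mask(self, rng):
        v = random_volume(rng)
        t = AffineTransform3D.translate(0, 0, 4.0)
        _, mask = resample_volume(v, v.grid, t, return_mask=True)
        assert mask[:, :, 4:].all() and not mask[:, :, :4].any()

    def test_cross_check_against_simpleitk(self, rng):
        """Independent oracle: SimpleITK resamples to the same values."""
        sitk = pytest.importorskip("SimpleITK")
        v = random_volume(rng, shape=(12, 13, 14), spacing=(1.5, 0.7, 0.9))
        t = AffineTransform3D.from_euler(
            np.deg2rad([4, -3, 6]), [1.0, -0.5, 0.8],
            pivot=(8.0, 4.0, 5.0), mode="rigid",
        )
        ours, mask = resample_volume(v, v.grid, t, return_mask=True)

        img = sitk.GetImageFromArray(v.voxels.astype(np.float64))
        img.SetSpacing(v.grid.spacing[::-1])
        img.SetOrigin(v.grid.origin[::-1])
        inv = invert(t)
        st = sitk.AffineTransform(3)
        st.SetMatrix(inv.linear[::-1, ::-1].flatten())
        st.SetTranslation(inv.translation[::-1])
        ref = sitk.Resample(img, img, st, sitk.sitkLinear, 0.0)
        theirs = sitk.GetArrayFromImage(ref)

        interior = mask.copy()
        src = np.asarray(
            [invert(t).apply(v.grid.voxel_to_world(np.argwhere(mask)[i]))
             for i in range(0, mask.sum(), 37)]
        )  # spot-check interior correspondence is the mask itself
        diff = np.abs(ours.voxels.astype(float)
                      - np.floor(theirs + 0.5))[interior]
        assert np.median(diff) == 0
        assert (diff <= 1).mean() > 0.99


class TestDownsample:
    def test_mean_pooling_and_grid_update(self):
        grid = ImageGrid(shape=(4, 4, 4), spacing=(1, 2, 3), origin=(0, 0, 0))
        arr = np.arange(64, dtype=np.uint8).reshape(4, 4, 4)
        v = VolumeImage(grid=grid, voxels=arr)
        out = downsample_volume(v, 2)
        assert out.grid.shape == (2, 2, 2)
        assert out.grid.spacing == (2, 4, 6)
        assert out.grid.origin == (0.5, 1.0, 1.5)
        expected = arr.astype(float).reshape(2, 2, 2, 2, 2, 2).mean(
            axis=(1, 3, 5)
        )
        # reshape groups axes as (z,2,y,2,x,2) -> verify against direct blocks
        direct = np.zeros((2, 2, 2))
        for z in range(2):
            for y in range(2):
                for x in range(2):
                    direct[z, y, x] = arr[2 * z:2 * z + 2, 2 * y:2 * y + 2,
                                          2 * x:2 * x + 2].mean()
        np.testing.assert_allclose(
            out.voxels, np.floor(direct + 0.5).astype(np.uint8)
        )


class TestAffineRegister:
    def test_already_aligned_stays_put(self, default_phantom):
        ct = default_phantom["ct"]
        config = RegistrationConfig(seed=0, pyramid_levels=2)
        res = affine_register(ct, ct, config=config)
        assert res.final_metric >= 0.999
        t = res.transform
        assert np.rad2deg(t.rotation_angle()) < 0.05
        center = ct.grid.center
        assert np.linalg.norm(t.apply(center) - np.asarray(center)) < 0.1

    def test_trace_monotone_within_levels(self, default_phantom):
        ct = default_phantom["ct"]
        res = affine_register(ct, ct,
                              config=RegistrationConfig(seed=3,
                                                        pyramid_levels=2))
        by_level = {}
        for level, _, metric in res.trace[:-1]:
            by_level.setdefault(level, []).append(metric)
        for metrics in by_level.values():
            assert all(b >= a - 1e-12 for a, b in zip(metrics, metrics[1:]))

    def test_rejects_non_overlapping_init(self, default_phantom):
        ct = default_phantom["ct"]
        init = AffineTransform3D.translate(5000, 0, 0)
        with pytest.raises(InsufficientOverlapError):
            affine_register(ct, ct, init=init,
                            config=RegistrationConfig(seed=0))

    def test_deterministic_given_seed(self, default_phantom):
        ct = default_phantom["ct"]
        lm = default_phantom["lm"]
        cfg = RegistrationConfig(seed=7, pyramid_levels=2, max_iterations=8)
        pre = invert_intensities(lm)
        a = affine_register(ct, pre, config=cfg)
        b = affine_register(ct, pre, config=cfg)
        np.testing.assert_array_equal(a.transform.matrix, b.transform.matrix)
        assert a.final_metric == b.final_metric


class TestPropagate:
    def test_same_transform_object_attached(self, rng):
        v = random_volume(rng)
        twin = random_volume(rng)
        t = AffineTransform3D.translate(1, 2, 3)
        out = propagate_transform([v, twin], t, v.grid)
        assert all(tr is t for _, tr in out)
        # both companions map any voxel index to identical world coordinates
        idx = rng.uniform(0, 7, (20, 3))
        for (c1, t1), (c2, t2) in [(out[0], out[1])]:
            w1 = t1.apply(c1.grid.voxel_to_world(idx))
            w2 = t2.apply(c2.grid.voxel_to_world(idx))
            assert np.abs(w1 - w2).max() == 0.0

    def test_grid_mismatch_rejected(self, rng):
        v = random_volume(rng)
        other = random_volume(rng, spacing=(2.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="grid"):
            propagate_transform([other], AffineTransform3D.identity(), v.grid)

    def test_identity_propagation_leaves_labels_unchanged(self):
        grid = ImageGrid(shape=(6, 6, 6), spacing=(1, 1, 1))
        labels = np.zeros(grid.shape, np.int32)
        labels[1:4, 2:5, 0:3] = 1
        lv = LabelVolume(grid=grid, labels=labels, names={1: "organ"})
        out = propagate_transform([lv], AffineTransform3D.identity(), grid,
                                  resample_to=grid)
        np.testing.assert_array_equal(out[0].labels, labels)

    def test_label_cuboid_rigid_transform_dice(self):
        """Nearest-neighbour propagation matches the analytic shape."""
        grid = ImageGrid(shape=(64, 64, 64), spacing=(1, 1, 1))
        labels = np.zeros(grid.shape, np.int32)
        labels[20:44, 14:38, 24:48] = 1
        lv = LabelVolume(grid=grid, labels=labels, names={1: "organ"})
        t = AffineTransform3D.from_euler(np.deg2rad([7, 0, 0]), [2.0, -3.0, 4.0],
                                         pivot=(31.5, 31.5, 31.5), mode="rigid")
        out = propagate_transform([lv], t, grid, resample_to=grid)[0]

        idx = np.indices(grid.shape, dtype=float).reshape(3, -1).T
        back = invert(t).apply(idx)  # spacing 1, origin 0: world == index
        analytic = ((back[:, 0] >= 19.5) & (back[:, 0] < 43.5)
                    & (back[:, 1] >= 13.5) & (back[:, 1] < 37.5)
                    & (back[:, 2] >= 23.5) & (back[:, 2] < 47.5)
                    ).reshape(grid.shape)
        ours = out.labels == 1
        dice = 2 * (ours & analytic).sum() / (ours.sum() + analytic.sum())
        assert dice >= 0.95


class TestInitialGuess:
    def test_recovers_translation_between_shifted_phantoms(self, default_phantom):
        ct = default_phantom["ct"]
        shifted = resample_volume(
            ct, ct.grid, AffineTransform3D.translate(20.0, -12.0, 8.0)
        )
        guess = initial_guess(ct, shifted)
        # the guess maps the shifted (moving) centroid back onto the fixed one
        err = np.linalg.norm(
            guess.apply(np.asarray(ct.grid.center) + [20.0, -12.0, 8.0])
            - np.asarray(ct.grid.center)
        )
        assert err < 10.0  # coarse by design: one fixed voxel-ish
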