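# Methods

## Coordinate model

Everything is computed in physical micrometres.  Arrays are indexed
`(z, y, x)` = (slice, row, column) and world axes are ordered the same way.
Indices are 0-based; a voxel's world coordinate is the coordinate of its
**center**; `world = origin + index · spacing`.  3D transforms map
*moving-world* → *fixed-world* (`q = L p + t`), so resampling a moving image
onto a fixed grid pulls values back through the inverse map.  Three
rigidity modes are enforced at construction: `rigid` (orthogonal `L`,
det +1), `rigid_iso_scale` (`L = s·R`), `rigid_aniso_scale` (`L = R·diag(s)`
by construction).  Composition widens the mode to the least-constrained
participant; per-axis scales are read back as the column norms of `L`,
which is exact for `R·diag(s)` factorizations.

Rotations are parameterized as intrinsic Euler angles about an explicit
pivot — the moving volume's physical center (mapped through the initial
transform) during optimization.  A center pivot keeps rotation and
translation parameters comparably scaled; the alternative (rotation about
the coordinate origin) would make the two parameter groups differ by the
lever arm of the whole volume.

One subtle convention governs the 2D chain.  A template crop of `n` source
voxels spans a physical extent of `n·s`, and its resampled raster has
`round(n·s/p)` pixels of size `p`.  Template pixels are therefore
**cell-centered in the crop extent**: pixel `q` sits at source-voxel
coordinate `(q + 0.5)·p/s − 0.5`, which degenerates to `q` when `p = s`.
The earlier center-anchored variant (pixel 0 on voxel center 0) left the
trailing half-voxel of the upsampled raster extrapolated on one side only;
that asymmetric band of false content measurably biased the 2D correlation
peak (several tenths of a pixel).  With the cell-centered convention the
clamped margin is symmetric, and `register2d` additionally excludes it from
the metric entirely (its width, `⌈s/(2p) − 1/2⌉` pixels, follows from the
template's own metadata).

## Preprocessing

Correlation-driven registration needs the two inputs to *look alike*.  The
LM stack is inverted (`255 − v`) to give CT-like bright-on-dark contrast
and smoothed with a separable sampled-Gaussian kernel of 3×3×3-voxel
support.  The support is a kernel *size*; the Gaussian width is a free
parameter and defaults to σ = 0.8 voxels per axis, a standard choice for a
radius-1 kernel (the weights then still decay ~2.2× from center to edge).
Borders are edge-replicated: zero padding would darken the specimen rim and
bias the metric toward background.  Every 8-bit operator re-quantizes by
round-half-up, mirroring a pipeline of 8-bit processing modules; a
`float_through` flag exposes the unquantized field for numerical tests.

## Correlation metric

`r(T)` is the Pearson correlation between fixed voxel values and linearly
interpolated moving values, computed over **exactly** the fixed voxels
whose pulled-back position lies inside the moving volume's interpolation
domain (`[0, n−1]` per axis in voxel coordinates).  All overlapping voxels
are used — no stochastic subsampling — so the metric is deterministic and
the optimizer's seed only shuffles sweep order.  Declared failure modes:
overlap fraction below `min_overlap_fraction` (default 0.25, which also
guards the sub-region scenario where the reference should first be cropped
to the moving stack's coverage), and a constant signal in either masked
channel (correlation undefined).  Pearson correlation rather than
zero-mean cross-correlation was chosen because it is invariant to the
affine intensity differences that remain between modalities after
inversion.

## 3D optimizer

A derivative-free, per-level adaptive step-halving coordinate search over
the parameter vector (3 rotations, 3 translations, plus 1 or 3 scales by
mode), run coarse-to-fine over a factor-2 mean-pooling pyramid (default 3
levels; pooling stops before any axis drops below 16 voxels; pooled grids
keep physical coordinates consistent, the origin shifting by half the new
voxel).  Steps start at 2 level-voxels translation, 2° rotation and 2%
scale at the coarsest level (rotation/scale steps shrink with the level)
and halve whenever a full sweep yields no improvement, until they fall
below the tolerances (0.05 μm, 0.01°, 10⁻⁴ by default).  Only strict
improvements are accepted, so the per-level metric trace is monotone.
Joint optimization of all parameters was preferred over alternating
rotation/translation stages: the coordinate search visits each parameter
in turn anyway, and a joint vector avoids order-dependent stalls.

The initial transform is the caller's job — it mirrors the manual coarse
alignment a user performs in a viewer.  A centroid-and-principal-axes
helper (`initial_guess`) exists but is never applied implicitly.
Registration starting below the overlap floor raises instead of silently
optimizing garbage; an optimization that ends below its starting metric is
flagged `converged=False`.

`rigid_aniso_scale` exists specifically to absorb a systematic
section-thickness error: sections cut at 0.95× the declared thickness
compress the stack along z by exactly that factor, which a per-axis scale
on the stacking axis recovers while `rigid` mode structurally cannot.

## 2D embedding chain

`extract_template` crops a slice of the *registered* LM stack and records
slice index, crop offset, pixel size, source grid and stack transform —
enough to map any (fractional) template pixel to world μm.
`resample_template` refines the raster to the TEM pixel size (upsampling
capped at 64× per axis; crop a smaller region instead), preserving the
world coordinate of every material point.  `register2d` runs the same
pyramid/coordinate-search machinery in 2D over a similarity transform
(TEM pixel → template pixel, matching the 3D moving→fixed convention);
scale is optional and clamped to (0.9, 1.1) — TEM rescaling is expected to
be slight, and a tight bound prevents degenerate fits.  `levels_remap`
(default 10–255) then guarantees every true TEM pixel is ≥ 10,
`composite_on_black` writes the registered TEM onto a template-shaped
black canvas (covered pixels clamped up to the floor, uncovered exactly 0),
and `place_in_3d` attaches the analytic pixel→world map plus the 0–9
transparent / 10–255 opaque alpha colormap.  The separation
*background = 0 / foreground ≥ 10* is what makes the colormap render the
slice without a visible frame.

The placed slice keeps two maps: canvas pixels share the template lattice
(their map *is* the template chain), and native TEM pixels go through the
2D transform first.  The TEM plane is placed at its parent LM section's
center z; sub-slice placement within the 1.5 μm section is not modelled.

## Synthetic phantoms

The default phantom emulates a ~0.8 mm specimen: five ellipsoid/cuboid
bodies (soft-tissue envelope 0.30, muscle 0.55, digestive tract 0.45,
paired kidneys 0.80/0.90 on a [0, 1] density scale — pairwise ≥ 0.1 apart
so modalities can separate them) with smoothstep edges (10% of the
normalized radius) and seeded band-limited texture (amplitude 0.06,
correlation ~1.5 voxels) inside the specimen.  Renderings: CT-like (density
× 230, blur σ 0.8 voxel, Gaussian noise σ 3 gray, 64³ at 12.5 μm) and
LM-like (inverted contrast, in-plane blur σ 0.6, noise σ 3, 50×100×100 at
16×8×8 μm — the same ~z/xy anisotropy ratio as real semithin sections).
The grids are desk-scale stand-ins for the full-size acquisitions
(650×638×838 at 1.2 μm; 1,200×1,600×585 at 0.413×0.413×1.5 μm), which the
data model reaches but the test suite does not exercise.

Per-slice jitter models serial-section alignment error as a mean-centered
**random walk** across sections (step σ = `per_slice_jitter_sigma`, in-plane
translation only): section-to-section alignment accumulates error, so
sections far from the stack center drift furthest.  This is the mechanism
that makes residuals of a rigid stack-to-stack fit grow toward the
periphery; independent per-section shifts were tried first and do *not*
produce that radial pattern (their residual is slice-constant).  A
`(declared, true)` section-thickness pair emulates a microtome calibration
error; the generator returns the *effective* ground-truth transform
(nominal truth composed with the implied z-rescale) so recovery is judged
against what registration can actually see.

The TEM generator supersamples one LM section (sampling the whole section
so material beyond the crop edge is genuine, not edge-replicated — the
replicated variant biased the correlation peak), warps it by the
ground-truth similarity, then adds fine seeded texture (σ 6 gray,
correlation ~1 px) and noise (σ 2 gray).  Because that texture is absent
from the template, it is a *nuisance* field, and sub-pixel localization is
limited by the shared content, which is band-limited at LM resolution.
This is faithful to the real situation (TEM ultrastructure is invisible in
LM) and is why single-realization 2D recovery errors scatter around a few
tenths of a template pixel; recovery is therefore summarized by medians
over seed panels.  A second spec, `tem_scale_spec`, reproduces the true
working scales (1.2 μm CT canvas, 0.413 μm/1.5 μm LM sections, 0.025 μm TEM
pixels, 16.52× supersampling over a ~100 μm field) for placement-accuracy
checks, where sub-0.1 μm agreement is the meaningful yardstick.

What the phantoms do **not** model: CT projection/reconstruction physics,
optical PSFs, realistic EM texture statistics, section folds/tears, or
in-plane rotation jitter.  Passing recovery tests therefore demonstrates
the geometry/optimization machinery, not robustness to every artefact of
real acquisitions.

## Numerical choices

* Interpolation: trilinear/bilinear for gray values, nearest for labels
  (enforced); outside-fill 0 with an occupancy mask for metric use.
* Quantization: round-half-up (`floor(x + 0.5)`) everywhere an 8-bit
  result is produced.
* Acceptance of an optimizer step requires improvement > 10⁻⁸ to avoid
  chasing interpolation noise.
* Degenerate inputs raise typed errors (singular transform, insufficient
  overlap, constant region, 16-bit data without an explicit rescale flag,
  spacing never guessed from TIFF tags).
* Determinism: generators and optimizers are pure functions of their seeds;
  reruns are bit-identical.

## Problem sizes

The test suite and the acceptance script run desk-scale problems: 64³
reference volumes, 50×100×100 moving stacks, ~460² 2D registrations, 20
phantoms for the 3D recovery statistics and 5-seed panels for 2D recovery.
These sizes were chosen so the full validation cycle completes in minutes
on one CPU while every code path matches the full-scale configuration.

## Known limitations

* Stack-to-stack affine registration cannot repair *internal* misalignment
  of a section series; the jitter experiments quantify exactly that
  residual.  Elastic registration is out of scope.
* Only the Pearson correlation metric is implemented; the config tag is an
  extension point.
* The 2D transform class is similarity-only; TEM distortion beyond a
  slight isotropic rescale is not corrected.
* The coordinate-search optimizer is local: the initial alignment must be
  within its capture range (roughly the coarsest pyramid level's basin,
  ~10–15° and a few coarse voxels under default settings).
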