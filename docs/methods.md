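# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `synmicro`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Mask simulation

**Organism foreground.** Three sources are supported: a random
spherical-harmonics shape (default), a sample from a fitted statistical
shape model, or a user-provided binary mask. SH organisms default to radius
20 voxels with smoothness γ = 2 and l_max = 6 — visibly non-spherical but
star-convex with comfortable margin, which matches early-embryo/meristem
silhouettes at toy scale.

**Layer-wise cell placement.** Cells are seeded in depth shells of the
Euclidean distance transform: layer ℓ covers distances
[ℓ·t, (ℓ+1)·t) with layer thickness t (default 6 voxels, i.e. roughly one
cell diameter at the default spacing). Within a shell, candidate voxels are
visited in seeded random order and accepted greedily when at least
`target_spacing` (default 8 voxels) from all accepted centers — a
Poisson-disk process. Accepted centers are jittered uniformly by up to
`jitter` voxels per axis (default 1) and clamped back to the foreground, so
pairwise spacing within a layer is bounded below by
`target_spacing − 2·jitter`. Distance-transform thresholding is used instead
of morphological erosion because it is exact for arbitrary shell radii and
extends to anisotropic voxels via the sampling argument.

**Weighted tessellation.** Every foreground voxel is assigned to the cell
minimizing ‖x − x_cell_j‖₂ / γ_j. Weights γ_j are drawn i.i.d. from
U[0.9, 1.1]: this bends the cell interfaces noticeably without letting any
cell swallow its neighbours; the distribution is configurable. Ties are
broken deterministically by the lowest cell index (strict-less update order).
Distances are computed in physical units when a voxel size is attached.
The implementation streams over cells (O(N·J) time, O(N) memory) and is
tested voxel-exactly against the brute-force per-voxel minimizer.

**Membranes.** A voxel is membrane iff it lies within ⌈thickness/2⌉ voxels
(Euclidean, strict) of a face between two distinct positive labels; with
thickness 1 this is exactly the two voxel layers flanking each interface.
The organism outer surface is included by default (membrane signal outlines
boundary cells in real stacks); a flag disables it. Membranes are clipped to
the foreground.

**Nuclei.** One SH shape per cell position with radius ~ Normal(9, 1) voxels
and smoothness γ = 5 (the regime in which nuclei are near-ellipsoidal with
mild surface texture); non-positive radius draws are rejected and redrawn.
Overlaps are resolved by earlier-index priority, so label ids may be sparse
when a nucleus is fully occluded; this is recorded in the volume metadata.

## Spherical-harmonics shapes

The real orthonormal basis is used (cosine/sine combinations of the ±m
complex pair), so radius functions of real coefficients are real by
construction; orthonormality is verified by quadrature to 1e-3 on a 200×400
angular grid. The l = 0 term is rescaled so that the coefficient *is* the
radius: a shape with only c_0^0 = r has radius exactly r.

Random shapes use c_l^m = r·w(l, m)·e^(−γ·l) for l ≥ 1 with independent
standard-normal w per (l, m). The decay is applied per order l: damping
every non-spherical component is what makes γ a smoothness factor with a
clean sphere limit (γ → ∞ gives a discrete ball; verified to 2% of
(4/3)πr³ at γ = 50, r = 10) and keeps the positivity rejection rare. A
`decay_on="m"` switch damps by degree |m| instead, leaving order-l/degree-0
components undamped; it produces much rougher shapes and is provided for
completeness, not as the default. If the radius function is non-positive
anywhere on the evaluation grid, the draw is repeated with an incremented
seed (bounded retries), so the recorded seed always identifies the actual
coefficients.

**Voxelization** marks voxel centers with ‖v − c‖ ≤ S(θ_v, ϕ_v); it is
star-convex by construction and processes z-slabs to bound memory. A
`radius_bounds` hint lets bulk callers (nucleus placement) skip exact
evaluation outside an uncertainty shell. **Radial resampling** marches the
rays of a fixed angular grid (default: 642-ray Fibonacci sphere, near-uniform
without polar clustering) from the foreground centroid and takes the
farthest crossing of the trilinearly interpolated mask at the 0.5 isolevel.
The sub-voxel crossing estimate is what makes the
voxelize → resample → Delaunay-revoxelize round trip accurate (Jaccard
≥ 0.95, typically ≈ 0.98, for smooth shapes); nearest-neighbour sampling
with midpoint transitions loses ~5 Jaccard points to discretization.
**Delaunay voxelization** rasterizes the convex hull of the boundary points
(`find_simplex` ≥ 0 on voxel centers); strongly concave star-convex shapes
are therefore smoothed — acceptable for the near-convex organisms and nuclei
this package targets, and flagged as a limitation below.

## Statistical shape models

Boundary vectors (x₁, y₁, z₁, …) on a common angular grid are decomposed by
SVD of the centered data matrix; eigenvalues use the 1/(k−1) sample
normalization, and total variance is conserved to 1e-8 (relative) against
the mean squared deviation. New shapes use mode weights drawn uniformly from
[−3λ_j, 3λ_j]. This λ-proportional band (rather than the conventional
3√λ_j) is kept as the primary convention with `bound_scale="sqrt"`
available; with λ in squared voxel units the two differ materially, and the
bounds are enforced and tested in 1000 draws. With all positive-variance
modes and projection coefficients, any training shape is reconstructed to
1e-6.

## Positional encoding

`boundary_distance` is the Euclidean distance transform to the *opposite*
class, so the distance field approaches 1 (one voxel) on both sides of the
boundary and the encoded map tends to 0 there from both signs. The map is
strictly inside (−1, 1), positive in the foreground, negative in the
background, monotone in depth, and a pure pointwise function of (distance,
class). Defaults α = β = 100 voxels; synthesis-time quality levels override
α (the sweep α ∈ {10, 100, 500} is wired through the pipeline). The distance
is measured to the organism surface, not to membrane/nucleus boundaries:
the encoding exists to express depth-dependent signal degradation, which is
a property of the specimen geometry, not of individual structures.

## Patch pipeline

Patch geometry follows the reference setting — patches of 128×128×64
(x, y, z), overlap and crop margins (30, 30, 15) — stored in (z, y, x). The
stride is patch − 2·crop − overlap per axis and must be ≥ 1. Blending uses a
separable per-axis linear ramp from ε = 0.05 at the faces to 1 at the
center (corner weight ε³); the exact profile is not critical because
normalized weights form a partition of unity (≤ 1e-9 deviation), which
makes cut-then-assemble the identity to 1e-6 for consistent patches and the
accumulation order irrelevant. A Gaussian profile is available. Edge tiles
are shifted inward so cropping never discards true boundary voxels; volumes
smaller than one patch are reflect-padded and un-padded afterwards. The
whole output volume is accumulated in RAM (no out-of-core tiling).

## Synthesis GAN

Architecture defaults: depth-4 3D U-Net, base width 16, instance
normalization, leaky-ReLU 0.2, pixel-shuffle (s = 2) upsampling in the
decoder, sigmoid output head; 3-layer 3D PatchGAN discriminator on
(image, mask, positional map). The adversarial objective is the
least-squares form — d_loss = mean((D(real)−1)² + D(fake)²)/2,
g_loss = mean((D(fake)−1)²) — chosen for its stability in image-to-image
translation. The generator total is g_loss + λ_id·L_identity with λ_id = 5
and L_identity the per-voxel L1 between a real image and the generator's
output when that image replaces the mask channel (the positional map is kept
as the second channel, so the identity pass sees the same conditioning as
the synthesis pass). Optimization is rectified Adam (lr 2e-4, betas
0.9/0.999) for both networks.

ADA: r_ADA is the mean sign of the discriminator's per-patch real scores
centered at 0.5 (the least-squares "real" decision threshold). Every e_aug
(default 1) epochs, p_aug moves by δ = 0.05 towards the regime where
r_ADA = 0.6, clamped to [0, 1]. The five augmentations — intensity scaling
U[0.6, 1.2], additive Gaussian noise N(0, 0.1), voxel shuffling in a random
25³ region, zero inpainting of a random 15³ region, and a linear intensity
ramp down to a U[0.2, 0.8] endpoint along one random axis — fire
independently with probability p_aug, in that fixed order, from one seeded
generator; the zero fill and the ramp endpoint are this package's choices
where the transform family is otherwise underdetermined. Augmentation is
applied to the discriminator's image inputs (real and fake) only; the
generator's adversarial pass uses the unaugmented fake so that gradients
reach the generator unmodified.

Training extracts one uniformly located patch per volume per epoch (small
datasets are diversified by the patch sampler rather than by long epochs).
All randomness derives from the config seed through named substreams keyed
by (epoch, volume, role); checkpoints store weights, optimizer moments, ADA
state and the epoch index, so a resumed run reproduces an uninterrupted one
bitwise. Non-finite losses abort with the offending epoch/volume.

The networks run on a small reverse-mode autodiff engine over NumPy
(`synmicro.nn`): convolutions via im2col with exact col2im gradients
(verified against numerical differentiation to 1e-7), instance
normalization with the closed-form backward pass, and pixel shuffle as pure
reshape/transpose. Single precision, single process, deterministic.

## Surrogate renderer and metrics

The renderer produces microscopy-like targets from masks: binary structure
signal, multiplied by 1 − s·tanh(d/decay_alpha) inside the specimen
(depth attenuation, strength s = 0.8), Gaussian PSF blur with
σ = (1, 1.5, 1.5) voxels in (z, y, x) — the axial σ is smaller in voxel
units because axial sampling is usually coarser than lateral sampling — a
background offset of 0.05, then Poisson (scale 200) and
Gaussian (σ = 0.03) noise, clipped to [0, 1]. It is a deliberate caricature:
no real PSF model, no scattering, no bleaching, no spectral content. Its
sole role is to give the GAN a deterministic, seedable target domain so
every experiment runs offline; passing tests demonstrate that the pipeline
learns *this* domain at toy scale, not that it reproduces any particular
instrument.

Metrics: NRMSE is RMSE normalized by the reference (first-argument) range;
PSNR uses the same peak and returns +∞ for identical volumes; ZNCC is the
Pearson correlation of flattened voxels; SSIM uses 7³ uniform windows with
the standard constants over full 3D windows (not slice-wise), delegated to
scikit-image and cross-checked in the tests against an independent
sliding-window summation to 1e-10. The intensity profile sums a center
slice over one axis (e.g. the center xz-slice over z, plotted along x).

## Problem sizes

The package's own study conditions for CPU-scale verification: smoke GAN
training uses 8 simulated membrane volumes of 64×64×32 (x, y, z), patch
16×32×32 (z, y, x), depth-2 U-Net with base width 4, lr 1e-3, 20 epochs
(`synmicro.gan.smoke_config`); end-to-end pipeline checks use 2 volumes of
48×48×32 per structure mode with the α ∈ {10, 100, 500} sweep. Full-scale
defaults (depth-4 network, 128×128×64 patches, 5000 epochs) remain the
config defaults and are intended for GPU-class budgets or long CPU runs on
real data.

## Known limitations

- Shapes are star-convex by construction; the Delaunay back-conversion
  additionally convexifies, so deeply lobed cells are out of reach.
- No biophysical growth/division model and no time series: volumes are
  independent draws.
- Cell density/layer parameters have no data-derived defaults; they are
  exposed as configuration with documented toy-scale values.
- The NumPy networks are practical at smoke scale; large-scale training of
  the default architecture is compute-bound and untested here.
- The surrogate renderer's realism gap means quantitative scores against it
  do not transfer to any specific microscope.
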