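"""Spherical-harmonics shapes, voxel/boundary conversions, and shape models."""

import math

import numpy as np
import pytest

from synmicro.shapes import (
    AngularGrid,
    BoundaryPointList,
    SHShape,
    _basis_matrix,
    _lm_order,
    boundary_to_mask,
    fit_shape_model,
    project_shape,
    radial_resample,
    sample_shape,
    sample_sh_shape,
    sh_basis_value,
    sh_radius,
    voxelize_star_convex,
)


class TestBasis:
    def test_constant_basis_value(self):
        # Y_0^0 = 1 / (2 sqrt(pi)) everywhere
        expected = 1.0 / (2.0 * math.sqrt(math.pi))
        for theta, phi in [(0.1, 0.0), (1.3, 2.2), (3.0, 5.9)]:
            assert sh_basis_value(0, 0, theta, phi) == pytest.approx(expected, rel=1e-12)

    def test_legendre_zero(self):
        # P_1(cos(pi/2)) = 0
        assert sh_basis_value(1, 0, math.pi / 2, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_invalid_degree_raises(self):
        with pytest.raises(ValueError):
            sh_basis_value(1, 2, 0.5, 0.5)
        with pytest.raises(ValueError):
            sh_basis_value(-1, 0, 0.5, 0.5)

    def test_orthonormality_by_quadrature(self):
        # midpoint-rule quadrature of Y_j * Y_k over the sphere on a 200x400
        # angular grid must reproduce the identity matrix
        n_t, n_p = 200, 400
        th = (np.arange(n_t) + 0.5) * math.pi / n_t
        ph = (np.arange(n_p) + 0.5) * 2.0 * math.pi / n_p
        T, P = np.meshgrid(th, ph, indexing="ij")
        w = np.sin(T) * (math.pi / n_t) * (2.0 * math.pi / n_p)
        B = _basis_matrix(4, T.ravel(), P.ravel(), radius_convention=False)
        gram = (B * w.ravel()[:, None]).T @ B
        assert np.abs(gram - np.eye(gram.shape[0])).max() < 1e-3


class TestSampleSHShape:
    def test_constant_coefficient_equals_radius(self):
        shape = sample_sh_shape(r=9.0, gamma=5.0, l_max=4, seed=1)
        assert shape.coeffs[0] == 9.0
        assert shape.coeffs.size == 25

    def test_determinism_bitwise(self):
        a = sample_sh_shape(9.0, 2.0, 4, seed=42)
        b = sample_sh_shape(9.0, 2.0, 4, seed=42)
        assert np.array_equal(a.coeffs, b.coeffs)
        assert a.seed == b.seed

    def test_large_gamma_gives_sphere(self):
        shape = sample_sh_shape(10.0, 50.0, 4, seed=0)
        assert np.all(np.abs(shape.coeffs[1:]) < 1e-15 * 10.0)
        vol = voxelize_star_convex(shape.radius_fn, (16, 16, 16), (33, 33, 33))
        count = int(vol.data.sum())
        expected = 4.0 / 3.0 * math.pi * 10.0 ** 3
        assert abs(count - expected) / expected < 0.02

    def test_halfnormal_coefficient_magnitudes(self):
        # E|c_l^m| = r * exp(-gamma * l) * sqrt(2/pi) for the standard-normal
        # weights; Monte-Carlo over 1000 seeds, pooled over the 2l+1 degrees
        # of each order (they share the same expected magnitude)
        r, gamma, l_max = 9.0, 2.0, 3
        sums = np.zeros((l_max + 1) ** 2)
        n = 1000
        for seed in range(n):
            sums += np.abs(sample_sh_shape(r, gamma, l_max, seed=seed * 1000).coeffs)
        means = sums / n
        half_normal = math.sqrt(2.0 / math.pi)
        lm = _lm_order(l_max)
        for l in range(1, l_max + 1):
            pooled = np.mean([means[j] for j, (lj, _) in enumerate(lm) if lj == l])
            expected = r * math.exp(-gamma * l) * half_normal
            assert pooled == pytest.approx(expected, rel=0.05)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            sample_sh_shape(-1.0, 1.0, 2, seed=0)
        with pytest.raises(ValueError):
            sample_sh_shape(1.0, -0.5, 2, seed=0)


class TestSHRadius:
    def test_pure_sphere_radius_exact(self):
        shape = SHShape(9.0, 5.0, 2, [9.0] + [0.0] * 8)
        for theta, phi in [(0.0, 0.0), (1.0, 2.0), (2.7, 4.4)]:
            assert sh_radius(shape, theta, phi) == pytest.approx(9.0, rel=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(5)
        c1 = rng.standard_normal(16)
        c2 = rng.standard_normal(16)
        s1 = SHShape(c1[0], 0.0, 3, c1)
        s2 = SHShape(c2[0], 0.0, 3, c2)
        s12 = SHShape(c1[0] + c2[0], 0.0, 3, c1 + c2)
        theta, phi = 1.1, 0.7
        assert sh_radius(s12, theta, phi) == pytest.approx(
            sh_radius(s1, theta, phi) + sh_radius(s2, theta, phi), rel=1e-10)

    def test_matches_termwise_sum(self):
        # brute-force term-by-term oracle over all (l, m)
        shape = sample_sh_shape(9.0, 1.0, 4, seed=8)
        theta, phi = 0.9, 3.1
        total = 0.0
        for j, (l, m) in enumerate(_lm_order(4)):
            basis = 1.0 if l == 0 else sh_basis_value(l, m, theta, phi)
            total += shape.coeffs[j] * basis
        assert sh_radius(shape, theta, phi) == pytest.approx(total, rel=1e-12)


class TestVoxelize:
    def test_ball_volume(self, ball_mask_r10):
        count = int(ball_mask_r10.data.sum())
        expected = 4.0 / 3.0 * math.pi * 1000.0
        assert abs(count - expected) / expected < 0.02

    def test_subvoxel_radius(self):
        vol = voxelize_star_convex(lambda t, p: np.full_like(t, 0.4), (4, 4, 4), (9, 9, 9))
        # the center voxel is at distance 0 <= 0.4; nothing else qualifies
        assert vol.data.sum() == 1
        assert vol.data[4, 4, 4] == 1

    def test_star_convexity_along_rays(self):
        shape = sample_sh_shape(9.0, 1.0, 4, seed=12)
        vol = voxelize_star_convex(shape.radius_fn, (16, 16, 16), (33, 33, 33))
        arr = vol.data > 0
        rng = np.random.default_rng(0)
        fg = np.argwhere(arr)
        center = np.array([16.0, 16.0, 16.0])
        for i in rng.choice(len(fg), size=50, replace=False):
            v = fg[i].astype(float)
            for t in np.linspace(0.0, 1.0, 40):
                q = np.round(center + t * (v - center)).astype(int)
                assert arr[tuple(q)], "segment to center leaves the foreground"

    def test_truncation_flag(self):
        vol = voxelize_star_convex(lambda t, p: np.full_like(t, 10.0), (4, 16, 16), (17, 33, 33))
        assert vol.metadata["truncated"]
        assert not voxelize_star_convex(
            lambda t, p: np.full_like(t, 3.0), (8, 8, 8), (17, 17, 17)
        ).metadata["truncated"]


class TestRadialResample:
    def test_ball_boundary_distance(self, ball_mask_r10):
        grid = AngularGrid.fibonacci(642)
        bp = radial_resample(ball_mask_r10, grid)
        d = np.linalg.norm(bp.points - bp.centroid, axis=1)
        assert np.all(np.abs(d - 10.0) <= 0.8)

    def test_translation_equivariance(self, ball_mask_r10):
        grid = AngularGrid.fibonacci(162)
        base = radial_resample(ball_mask_r10, grid)
        shifted = np.zeros((43, 43, 43), dtype=np.uint8)
        shifted[5:38, 3:36, 7:40] = ball_mask_r10.data
        bp2 = radial_resample(shifted, grid)
        # shift (z, y, x) = (5, 3, 7) -> (x, y, z) = (7, 3, 5)
        assert np.allclose(bp2.points - base.points, [7.0, 3.0, 5.0], atol=1e-9)

    def test_centroid_in_background_raises(self):
        hollow = np.zeros((16, 16, 16), dtype=np.uint8)
        hollow[2:14, 2:14, 2:14] = 1
        hollow[5:11, 5:11, 5:11] = 0
        with pytest.raises(ValueError, match="star-convex"):
            radial_resample(hollow, AngularGrid.fibonacci(42))

    @pytest.mark.parametrize("seed", [1, 8, 15, 22, 29, 36, 43, 50, 57, 64])
    def test_roundtrip_jaccard(self, seed):
        # voxelize -> resample -> Delaunay re-voxelize keeps >= 0.95 overlap
        grid = AngularGrid.fibonacci(642)
        shape = sample_sh_shape(9.0, 2.0, 4, seed=seed)
        vol = voxelize_star_convex(shape.radius_fn, (16, 16, 16), (33, 33, 33))
        bp = radial_resample(vol, grid)
        back = boundary_to_mask(bp, (33, 33, 33))
        a, b = vol.data > 0, back.data > 0
        jaccard = (a & b).sum() / (a | b).sum()
        assert jaccard >= 0.95


class TestShapeModel:
    @staticmethod
    def _random_boundaries(k, n_rays, seed):
        grid = AngularGrid.fibonacci(n_rays)
        rng = np.random.default_rng(seed)
        dirs = grid.directions()
        shapes = []
        for _ in range(k):
            radii = 10.0 + rng.standard_normal(n_rays)
            shapes.append(BoundaryPointList(points=radii[:, None] * dirs,
                                            centroid=np.zeros(3), grid=grid))
        return grid, shapes

    def test_identical_shapes_zero_variance(self):
        grid, shapes = self._random_boundaries(1, 42, seed=0)
        clones = [shapes[0]] * 4
        model = fit_shape_model(clones)
        assert np.allclose(model.mean, shapes[0].as_vector())
        assert np.all(model.variances < 1e-20)

    def test_two_shape_model_by_hand(self):
        grid, shapes = self._random_boundaries(2, 42, seed=1)
        p, q = shapes[0].as_vector(), shapes[1].as_vector()
        model = fit_shape_model(shapes)
        assert np.allclose(model.mean, (p + q) / 2.0)
        # single non-zero mode along (p - q) with lambda_1 = ||p - q||^2 / 2
        assert model.variances[0] == pytest.approx(np.sum((p - q) ** 2) / 2.0, rel=1e-10)
        assert np.sum(model.variances[1:] > 1e-12 * model.variances[0]) == 0
        direction = (p - q) / np.linalg.norm(p - q)
        assert abs(np.dot(model.modes[0], direction)) == pytest.approx(1.0, rel=1e-10)

    def test_planted_mode_recovery(self):
        grid = AngularGrid.fibonacci(81)
        dirs = grid.directions()
        mean = (10.0 * dirs).reshape(-1)
        dim = mean.size
        rng = np.random.default_rng(7)
        planted, _ = np.linalg.qr(rng.standard_normal((dim, 3)))
        sds = np.array([3.0, 2.0, 1.0])
        X = mean + (rng.standard_normal((200, 3)) * sds) @ planted.T
        shapes = [BoundaryPointList(points=x.reshape(-1, 3), centroid=np.zeros(3), grid=grid)
                  for x in X]
        model = fit_shape_model(shapes)
        top3 = model.variances[:3].sum() / model.variances.sum()
        assert top3 >= 0.95
        for j in range(3):
            cos = np.abs(model.modes[j] @ planted[:, j])
            assert cos >= 0.99

    def test_total_variance_conservation(self):
        grid, shapes = self._random_boundaries(20, 42, seed=3)
        model = fit_shape_model(shapes)
        X = np.stack([s.as_vector() for s in shapes])
        msd = np.sum((X - X.mean(axis=0)) ** 2) / (len(shapes) - 1)
        assert model.variances.sum() == pytest.approx(msd, rel=1e-8)

    def test_mismatched_lengths_raise(self):
        _, a = self._random_boundaries(2, 42, seed=0)
        _, b = self._random_boundaries(1, 81, seed=0)
        with pytest.raises(ValueError):
            fit_shape_model([a[0], b[0]])


class TestSampleShape:
    @staticmethod
    def _model(seed=2, k=20, n_rays=42):
        grid = AngularGrid.fibonacci(n_rays)
        rng = np.random.default_rng(seed)
        dirs = grid.directions()
        shapes = [BoundaryPointList(points=(10.0 + rng.standard_normal(n_rays))[:, None] * dirs,
                                    centroid=np.zeros(3), grid=grid) for _ in range(k)]
        return fit_shape_model(shapes), shapes

    def test_zero_weights_give_mean(self):
        model, _ = self._model()
        bp = sample_shape(model, n_modes=3, b=np.zeros(3))
        assert np.allclose(bp.as_vector(), model.mean)

    def test_explicit_weight_evaluation(self):
        model, _ = self._model()
        lam1 = model.variances[0]
        bp = sample_shape(model, n_modes=2, b=np.array([3.0 * lam1, 0.0]))
        expected = model.mean + 3.0 * lam1 * model.modes[0]
        assert np.allclose(bp.as_vector(), expected)

    def test_sampled_weights_respect_bounds(self):
        model, _ = self._model()
        n_modes = 3
        lam = model.variances[:n_modes]
        for seed in range(1000):
            bp = sample_shape(model, n_modes=n_modes, seed=seed)
            b = model.modes[:n_modes] @ (bp.as_vector() - model.mean)
            assert np.all(np.abs(b) <= 3.0 * lam + 1e-9)

    def test_training_shape_reconstruction(self):
        # with all modes and projection coefficients, any training shape is
        # reconstructed exactly
        model, shapes = self._model()
        n = model.positive_modes()
        for s in shapes[:5]:
            b = project_shape(model, s)[:n]
            rec = sample_shape(model, n_modes=n, b=b)
            assert np.allclose(rec.as_vector(), s.as_vector(), atol=1e-6)

    def test_too_many_modes_raises(self):
        model, _ = self._model(k=5)
        with pytest.raises(ValueError):
            sample_shape(model, n_modes=model.positive_modes() + 1, seed=0)


class TestBoundaryToMask:
    def test_ball_volume_from_points(self):
        grid = AngularGrid.fibonacci(642)
        pts = 10.0 * grid.directions() + np.array([16.0, 16.0, 16.0])
        vol = boundary_to_mask(pts, (33, 33, 33))
        expected = 4.0 / 3.0 * math.pi * 1000.0
        assert abs(int(vol.data.sum()) - expected) / expected < 0.05

    def test_scaling_law(self):
        grid = AngularGrid.fibonacci(642)
        center = np.array([32.0, 32.0, 32.0])
        small = boundary_to_mask(8.0 * grid.directions() + center, (65, 65, 65))
        big = boundary_to_mask(16.0 * grid.directions() + center, (65, 65, 65))
        ratio = big.data.sum() / small.data.sum()
        assert ratio == pytest.approx(8.0, rel=0.05)

    def test_coplanar_points_raise(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [2, 2, 0], [0, 2, 0]])
        with pytest.raises(ValueError, match="degenerate"):
            boundary_to_mask(pts, (8, 8, 8))


class TestAngularGrid:
    def test_uniqueness_and_minimum(self):
        with pytest.raises(ValueError):
            AngularGrid(np.array([0.1] * 6), np.array([0.2] * 6))
        with pytest.raises(ValueError):
            AngularGrid(np.array([0.1, 0.2]), np.array([0.3, 0.4]))

    def test_serialization_roundtrip(self):
        shape = sample_sh_shape(9.0, 2.0, 4, seed=5)
        back = SHShape.from_json(shape.to_json())
        assert np.array_equal(shape.coeffs, back.coeffs)
        assert (back.r, back.gamma, back.l_max, back.seed) == (
            shape.r, shape.gamma, shape.l_max, shape.seed)
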