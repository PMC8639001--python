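"""Cell placement, weighted tessellation, membranes, nuclei and full simulation."""

import numpy as np
import pytest
from scipy.ndimage import center_of_mass, distance_transform_edt

from synmicro import (
    CellPlacement,
    LabelVolume,
    SHShape,
    SimulationConfig,
    extract_membranes,
    place_cells_layerwise,
    place_nuclei,
    simulate_annotation,
    voxelize_star_convex,
    weighted_tessellation,
)


def brute_force_tessellation(fg, positions, gammas):
    """Direct per-voxel minimization of ||x - x_j|| / gamma_j (tie: lowest j)."""
    out = np.zeros(fg.shape, dtype=np.int32)
    for idx in np.argwhere(fg):
        d = np.linalg.norm(idx - positions, axis=1) / gammas
        out[tuple(idx)] = int(np.argmin(d)) + 1  # argmin returns first minimum
    return out


@pytest.fixture(scope="module")
def ball20():
    return voxelize_star_convex(SHShape(20.0, 5.0, 0, [20.0]).radius_fn,
                                (24, 24, 24), (49, 49, 49))


class TestPlacement:
    def test_empty_foreground(self):
        placement = place_cells_layerwise(np.zeros((8, 8, 8), dtype=np.uint8), seed=0)
        assert placement.n_cells == 0

    def test_layer_depth_ranges(self, ball20):
        placement = place_cells_layerwise(ball20, layer_thickness=4, target_spacing=6,
                                          jitter=0, n_layers=2, seed=1)
        dist = distance_transform_edt(ball20.data > 0)
        for layer, lo, hi in [(0, 0.0, 4.0), (1, 4.0, 8.0)]:
            pos = placement.positions[placement.layers == layer].round().astype(int)
            assert len(pos) > 0
            d = dist[pos[:, 0], pos[:, 1], pos[:, 2]]
            assert np.all((d >= lo) & (d < hi))

    def test_all_positions_inside_foreground(self, ball20):
        placement = place_cells_layerwise(ball20, layer_thickness=5, target_spacing=7,
                                          jitter=2, n_layers=3, seed=5)
        fg = ball20.data > 0
        pos = placement.positions.round().astype(int)
        assert np.all(fg[pos[:, 0], pos[:, 1], pos[:, 2]])

    def test_in_layer_spacing_bound(self, ball20):
        spacing, jitter = 8.0, 1.5
        placement = place_cells_layerwise(ball20, layer_thickness=5, target_spacing=spacing,
                                          jitter=jitter, n_layers=2, seed=9)
        for layer in np.unique(placement.layers):
            pos = placement.positions[placement.layers == layer]
            if len(pos) < 2:
                continue
            diffs = pos[:, None, :] - pos[None, :, :]
            d = np.linalg.norm(diffs, axis=2)
            d[np.diag_indices(len(pos))] = np.inf
            assert d.min() >= spacing - 2 * jitter - 1e-9

    def test_determinism(self, ball20):
        a = place_cells_layerwise(ball20, seed=3)
        b = place_cells_layerwise(ball20, seed=3)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.gammas, b.gammas)

    def test_empty_shell_warns(self):
        small = np.zeros((8, 8, 8), dtype=np.uint8)
        small[3:5, 3:5, 3:5] = 1
        with pytest.warns(UserWarning, match="empty"):
            place_cells_layerwise(small, layer_thickness=4, target_spacing=2,
                                  n_layers=3, seed=0)


class TestTessellation:
    def test_single_cell_takes_everything(self, ball20):
        placement = CellPlacement(np.array([[24.0, 24.0, 24.0]]), np.array([1.0]),
                                  np.array([0]))
        inst = weighted_tessellation(ball20, placement)
        assert np.array_equal(inst.data > 0, ball20.data > 0)
        assert set(inst.labels()) == {1}

    def test_matches_bruteforce_weighted(self):
        rng = np.random.default_rng(4)
        fg = np.zeros((24, 24, 24), dtype=bool)
        fg[3:21, 3:21, 3:21] = True
        positions = rng.uniform(4, 20, size=(8, 3))
        gammas = rng.uniform(0.5, 2.0, size=8)
        placement = CellPlacement(positions, gammas, np.zeros(8, dtype=int))
        inst = weighted_tessellation(LabelVolume(fg.astype(np.uint8)), placement)
        oracle = brute_force_tessellation(fg, positions, gammas)
        assert np.array_equal(inst.data.astype(np.int32), oracle)

    def test_equal_gammas_reduce_to_voronoi(self):
        rng = np.random.default_rng(7)
        fg = np.ones((32, 32, 32), dtype=bool)
        positions = rng.uniform(2, 30, size=(8, 3))
        placement = CellPlacement(positions, np.full(8, 1.7), np.zeros(8, dtype=int))
        inst = weighted_tessellation(LabelVolume(fg.astype(np.uint8)), placement)
        # unweighted nearest-centroid oracle
        oracle = brute_force_tessellation(fg, positions, np.ones(8))
        assert np.array_equal(inst.data.astype(np.int32), oracle)

    def test_weight_increase_grows_region(self):
        rng = np.random.default_rng(11)
        fg = np.ones((24, 24, 24), dtype=bool)
        positions = rng.uniform(2, 22, size=(5, 3))
        gammas = np.ones(5)
        base = weighted_tessellation(LabelVolume(fg.astype(np.uint8)),
                                     CellPlacement(positions, gammas, np.zeros(5, int)))
        grown = weighted_tessellation(LabelVolume(fg.astype(np.uint8)),
                                      CellPlacement(positions, np.array([2.0, 1, 1, 1, 1]),
                                                    np.zeros(5, int)))
        region_before = base.data == 1
        region_after = grown.data == 1
        assert np.all(region_after[region_before])
        assert region_after.sum() > region_before.sum()

    def test_coverage_conservation(self, ball20):
        placement = place_cells_layerwise(ball20, seed=2)
        inst = weighted_tessellation(ball20, placement)
        assert np.array_equal(inst.data > 0, ball20.data > 0)

    def test_zero_positions_raise(self, ball20):
        empty = CellPlacement(np.empty((0, 3)), np.empty(0), np.empty(0, dtype=int))
        with pytest.raises(ValueError):
            weighted_tessellation(ball20, empty)


class TestMembranes:
    def test_single_label_no_interfaces(self):
        vol = np.zeros((12, 12, 12), dtype=np.uint16)
        vol[2:10, 2:10, 2:10] = 1
        mem = extract_membranes(LabelVolume(vol), thickness=1, include_outer=False)
        assert mem.data.sum() == 0

    def test_half_space_interface(self):
        vol = np.ones((10, 12, 12), dtype=np.uint16)
        vol[5:] = 2
        mem = extract_membranes(LabelVolume(vol), thickness=1, include_outer=False)
        expected = np.zeros_like(vol)
        expected[4:6] = 1  # the two voxel layers adjacent to the z=4/5 face
        assert np.array_equal(mem.data, expected)

    def test_thickness_monotonicity(self, ball20):
        placement = place_cells_layerwise(ball20, seed=2)
        inst = weighted_tessellation(ball20, placement)
        counts = [extract_membranes(inst, t).data.sum() for t in (1, 3, 5)]
        assert counts[0] <= counts[1] <= counts[2]

    def test_membrane_inside_foreground(self, ball20):
        placement = place_cells_layerwise(ball20, seed=2)
        inst = weighted_tessellation(ball20, placement)
        mem = extract_membranes(inst, thickness=3, include_outer=True)
        assert not np.any(mem.data[ball20.data == 0])

    def test_erosion_relabel_consistency(self, ball20):
        # instance and membrane masks are mutually consistent: eroding the
        # instances by the membrane and re-assigning membrane voxels to the
        # nearest remaining core reproduces the cells (mean Jaccard >= 0.95)
        placement = place_cells_layerwise(ball20, seed=2)
        inst = weighted_tessellation(ball20, placement)
        mem = extract_membranes(inst, thickness=1, include_outer=False)
        cores = np.where(mem.data > 0, 0, inst.data)
        _, (iz, iy, ix) = distance_transform_edt(cores == 0, return_indices=True)
        recon = np.where(ball20.data > 0, cores[iz, iy, ix], 0)
        scores = []
        for lab in inst.labels():
            cell = inst.data == lab
            back = recon == lab
            scores.append((cell & back).sum() / (cell | back).sum())
        assert np.mean(scores) >= 0.95


class TestNuclei:
    def test_large_gamma_spherical_nucleus(self):
        placement = CellPlacement(np.array([[16.0, 16.0, 16.0]]), np.array([1.0]),
                                  np.array([0]))
        nuc = place_nuclei(placement, (33, 33, 33), r_mean=9.0, r_sd=1e-9,
                           gamma=50.0, seed=1)
        count = (nuc.data == 1).sum()
        expected = 4.0 / 3.0 * np.pi * 9.0 ** 3
        assert abs(count - expected) / expected < 0.03

    def test_mean_equivalent_radius(self):
        # 500 nuclei at generous spacing: equivalent-sphere radii average to
        # the Normal(9, 1) mean
        rng = np.random.default_rng(3)
        grid = (64, 320, 320)
        zs, ys, xs = np.meshgrid(np.arange(32, 33), np.arange(16, 310, 24),
                                 np.arange(16, 310, 24), indexing="ij")
        pos = np.stack([zs.ravel(), ys.ravel(), xs.ravel()], axis=1).astype(float)
        pos = np.concatenate([pos + np.array([dz, 0, 0]) for dz in (-16, 0, 16)])[:500]
        placement = CellPlacement(pos, np.ones(len(pos)), np.zeros(len(pos), int))
        nuc = place_nuclei(placement, grid, r_mean=9.0, r_sd=1.0, gamma=5.0, seed=17)
        labels, counts = np.unique(nuc.data[nuc.data > 0], return_counts=True)
        assert len(labels) == len(pos)
        radii = (3.0 * counts / (4.0 * np.pi)) ** (1.0 / 3.0)
        assert np.mean(radii) == pytest.approx(9.0, abs=0.2)

    def test_disjoint_positions_all_labelled(self):
        pos = np.array([[12.0, 12, 12], [12, 12, 44], [12, 44, 12]])
        placement = CellPlacement(pos, np.ones(3), np.zeros(3, int))
        nuc = place_nuclei(placement, (25, 57, 57), r_mean=6.0, r_sd=0.5, gamma=5.0, seed=2)
        assert set(nuc.labels()) == {1, 2, 3}


class TestSimulateAnnotation:
    def test_bitwise_determinism(self):
        cfg = SimulationConfig(grid_shape=(32, 48, 48), structure="membranes",
                               organism_radius=16.0, seed=21)
        a = simulate_annotation(cfg)
        b = simulate_annotation(cfg)
        for x, y in zip(a, b):
            assert np.array_equal(x.data, y.data)

    def test_membrane_mode_consistency(self, membrane_annotation):
        inst, struct, fg = membrane_annotation
        assert inst.shape == struct.shape == fg.shape
        # membranes live inside the organism
        assert not np.any(struct.data[fg.data == 0])
        # tessellation covers the foreground exactly
        assert np.array_equal(inst.data > 0, fg.data > 0)

    def test_nuclei_mode_centroids_near_positions(self):
        cfg = SimulationConfig(grid_shape=(40, 56, 56), structure="nuclei",
                               organism_radius=18.0, jitter=1.0,
                               nucleus_r_mean=5.0, nucleus_r_sd=0.5, seed=5)
        inst, struct, fg = cfg_result = simulate_annotation(cfg)
        placement = inst.metadata["placement"]
        for lab in inst.labels():
            c = np.asarray(center_of_mass(inst.data == lab))
            target = placement.positions[lab - 1]
            # centroid within jitter + 1 voxel of the placed position (plus
            # sub-voxel shape asymmetry)
            assert np.linalg.norm(c - target) <= cfg.jitter + 2.0

    def test_unknown_structure_raises(self):
        with pytest.raises(ValueError):
            simulate_annotation(SimulationConfig(structure="spots"))
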