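"""Annotation-mask simulation: cell placement, weighted tessellation, membranes, nuclei.

Full annotation volumes are built in three refinement steps: an organism
foreground shape, layer-wise cell positions inside it, and cellular
structures (a weighted Voronoi tessellation into cells/membranes, or
spherical-harmonics nuclei) at those positions.

The tessellation assigns every foreground voxel to the cell minimizing
``||x - x_cell_j|| / gamma_j``; per-cell weights ``gamma_j`` bend the planar
interfaces of an unweighted Voronoi diagram into more natural curved walls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import center_of_mass, distance_transform_edt

from .shapes import AngularGrid, sample_sh_shape, voxelize_star_convex
from .volumes import LabelVolume, as_array, substream_seed, voxel_size_of

__all__ = [
    "CellPlacement",
    "place_cells_layerwise",
    "weighted_tessellation",
    "extract_membranes",
    "place_nuclei",
    "SimulationConfig",
    "simulate_annotation",
]


@dataclass
class CellPlacement:
    """Cell centers with per-cell tessellation weights and layer ids.

    ``positions`` is an (n, 3) float array in (z, y, x) voxel coordinates;
    ``gammas`` are the positive weights of the distance metric; ``layers``
    records which erosion layer each cell was placed in.
    """

    positions: np.ndarray
    gammas: np.ndarray
    layers: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.gammas = np.asarray(self.gammas, dtype=float).reshape(-1)
        self.layers = np.asarray(self.layers, dtype=int).reshape(-1)
        n = self.positions.shape[0]
        if self.gammas.size != n or self.layers.size != n:
            raise ValueError("positions, gammas and layers must have equal length")
        if np.any(self.gammas <= 0):
            raise ValueError("all gammas must be positive")

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]


def place_cells_layerwise(
    foreground,
    layer_thickness: float = 6.0,
    target_spacing: float = 8.0,
    jitter: float = 1.0,
    n_layers: int = 2,
    seed: int = 0,
    gamma_range: tuple[float, float] = (0.9, 1.1),
) -> CellPlacement:
    """Place cell centers layer by layer from the organism boundary inwards.

    Layer ``l`` consists of foreground voxels whose Euclidean distance to the
    background lies in ``[l*layer_thickness, (l+1)*layer_thickness)``. Within
    a layer, candidates are visited in seeded random order and accepted
    greedily if at least ``target_spacing`` from every already accepted
    center of the same layer (Poisson-disk style). Accepted centers are then
    jittered by a uniform per-axis offset of at most ``jitter`` voxels and
    clamped back to the foreground, so the effective in-layer spacing is
    bounded below by ``target_spacing - 2*jitter``.
    """
    fg = as_array(foreground) > 0
    rng = np.random.default_rng(seed)
    if not fg.any():
        return CellPlacement(np.empty((0, 3)), np.empty(0), np.empty(0, dtype=int))
    sampling = voxel_size_of(foreground)
    dist = distance_transform_edt(fg, sampling=sampling)
    positions, gammas, layer_ids = [], [], []
    for layer in range(n_layers):
        lo, hi = layer * layer_thickness, (layer + 1) * layer_thickness
        shell = np.argwhere((dist > 0) & (dist >= lo) & (dist < hi))
        if shell.shape[0] == 0:
            warnings.warn(f"layer {layer}: eroded shell is empty, skipping")
            continue
        order = rng.permutation(shell.shape[0])
        accepted: list[np.ndarray] = []
        for i in order:
            cand = shell[i].astype(float)
            if accepted:
                d = np.linalg.norm(np.asarray(accepted) - cand, axis=1)
                if d.min() < target_spacing:
                    continue
            accepted.append(cand)
        for pos in accepted:
            p = pos + rng.uniform(-jitter, jitter, size=3)
            pi = np.clip(np.round(p).astype(int), 0, np.array(fg.shape) - 1)
            if not fg[tuple(pi)]:
                p = pos  # clamp back: keep the pre-jitter foreground voxel
            positions.append(p)
            gammas.append(rng.uniform(*gamma_range))
            layer_ids.append(layer)
    if not positions:
        return CellPlacement(np.empty((0, 3)), np.empty(0), np.empty(0, dtype=int))
    positions = np.asarray(positions)
    # drop exact duplicates (possible after clamping)
    _, keep = np.unique(positions, axis=0, return_index=True)
    keep = np.sort(keep)
    return CellPlacement(positions[keep], np.asarray(gammas)[keep],
                         np.asarray(layer_ids)[keep])


def weighted_tessellation(foreground, placement: CellPlacement) -> LabelVolume:
    """Weighted Voronoi-like tessellation of the foreground region.

    Every foreground voxel ``x`` receives the label ``j+1`` of the cell
    minimizing ``||x - x_cell_j||_2 / gamma_j``; background stays 0. Ties are
    broken by the lowest cell index. Distances are computed in physical units
    when the foreground carries a voxel size.
    """
    fg = as_array(foreground) > 0
    if placement.n_cells == 0:
        raise ValueError("weighted_tessellation needs at least one cell position")
    coords = np.argwhere(fg).astype(float)  # (N, 3), zyx
    scale = np.ones(3)
    vs = voxel_size_of(foreground)
    if vs is not None:
        scale = np.asarray(vs, dtype=float)
    best = np.full(coords.shape[0], np.inf)
    label = np.zeros(coords.shape[0], dtype=np.int32)
    for j in range(placement.n_cells):
        d = np.linalg.norm((coords - placement.positions[j]) * scale, axis=1)
        d /= placement.gammas[j]
        better = d < best  # strict: earlier index wins ties
        best[better] = d[better]
        label[better] = j + 1
    out = np.zeros(fg.shape, dtype=np.int32)
    out[fg] = label
    max_label = int(label.max(initial=0))
    dtype = np.uint16 if max_label < 2 ** 16 else np.uint32
    return LabelVolume(out.astype(dtype), voxel_size=vs)


def extract_membranes(instances, thickness: int = 1, include_outer: bool = True) -> LabelVolume:
    """Binary membrane mask from an instance segmentation.

    A voxel is membrane iff its center lies within ``ceil(thickness/2)``
    voxels of a face between two distinct positive labels (equivalently:
    Euclidean distance < ceil(thickness/2) to the set of interface voxels).
    With ``include_outer`` the organism outer surface (foreground voxels
    adjacent to background) is treated as an interface as well, so the
    membrane signal outlines boundary cells. The mask is restricted to the
    foreground.
    """
    lab = as_array(instances)
    fg = lab > 0
    interface = np.zeros(lab.shape, dtype=bool)
    for axis in range(3):
        a = np.take(lab, range(lab.shape[axis] - 1), axis=axis)
        b = np.take(lab, range(1, lab.shape[axis]), axis=axis)
        diff = (a != b) & (a > 0) & (b > 0)
        if include_outer:
            diff |= (a > 0) != (b > 0)
        sl_a = [slice(None)] * 3
        sl_a[axis] = slice(0, lab.shape[axis] - 1)
        sl_b = [slice(None)] * 3
        sl_b[axis] = slice(1, lab.shape[axis])
        interface[tuple(sl_a)] |= diff
        interface[tuple(sl_b)] |= diff
    if include_outer:
        # volume faces where foreground touches the boundary of the grid
        for axis in range(3):
            for idx in (0, -1):
                sl = [slice(None)] * 3
                sl[axis] = idx
                interface[tuple(sl)] |= fg[tuple(sl)]
    out = np.zeros(lab.shape, dtype=np.uint8)
    if not interface.any():
        return LabelVolume(out, voxel_size=voxel_size_of(instances))
    half = math.ceil(thickness / 2)
    if half <= 1:
        mem = interface
    else:
        dist = distance_transform_edt(~interface)
        mem = dist < half
    out[mem & fg] = 1
    return LabelVolume(out, voxel_size=voxel_size_of(instances))


def place_nuclei(
    placement: CellPlacement,
    grid_shape,
    r_mean: float = 9.0,
    r_sd: float = 1.0,
    gamma: float = 5.0,
    l_max: int = 6,
    seed: int = 0,
    max_retries: int = 100,
) -> LabelVolume:
    """Instance mask of spherical-harmonics nuclei, one per cell position.

    Each nucleus radius is drawn from Normal(r_mean, r_sd) (non-positive
    draws are rejected and redrawn, bounded retries) and an SH shape with
    smoothness ``gamma`` is voxelized at the cell position. Overlaps are
    resolved by earlier-index priority; labels equal position index + 1, so
    the id set may be sparse if a nucleus is fully occluded or falls outside
    the grid (recorded in ``metadata['sparse_labels']``).
    """
    if placement.n_cells == 0:
        raise ValueError("place_nuclei needs a non-empty placement")
    grid_shape = tuple(int(s) for s in grid_shape)
    rng = np.random.default_rng(seed)
    out = np.zeros(grid_shape, dtype=np.uint16 if placement.n_cells < 2 ** 16 else np.uint32)
    check_grid = AngularGrid.fibonacci(162)
    for j in range(placement.n_cells):
        radius = -1.0
        for _ in range(max_retries):
            radius = rng.normal(r_mean, r_sd)
            if radius > 0:
                break
        if radius <= 0:
            raise RuntimeError("could not draw a positive nucleus radius")
        shape = sample_sh_shape(radius, gamma, l_max,
                                seed=substream_seed(seed, "nucleus", j),
                                grid=check_grid)
        center = placement.positions[j]
        rad_samples = shape.radius_fn(check_grid.thetas, check_grid.phis)
        # conservative bounds around the sampled radius range so only the
        # uncertain shell is evaluated exactly
        r_lo = float(np.min(rad_samples)) * 0.85
        r_hi = float(np.max(rad_samples)) * 1.15 + 1.0
        r_max = r_hi + 1.0
        lo = np.maximum(np.floor(center - r_max).astype(int), 0)
        hi = np.minimum(np.ceil(center + r_max).astype(int) + 1, np.array(grid_shape))
        if np.any(hi <= lo):
            continue
        local_shape = tuple(hi - lo)
        local_center = center - lo
        if np.any(local_center < 0) or np.any(local_center > np.array(local_shape) - 1):
            continue
        local = voxelize_star_convex(shape.radius_fn, local_center, local_shape,
                                     radius_bounds=(r_lo, r_hi))
        region = out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        write = (local.data > 0) & (region == 0)  # earlier-index priority
        region[write] = j + 1
    present = np.unique(out)
    n_present = int((present > 0).sum())
    return LabelVolume(out, metadata={"sparse_labels": n_present != placement.n_cells,
                                      "n_positions": placement.n_cells})


# ---------------------------------------------------------------------------
# Full annotation simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Parameters of one simulated annotation volume.

    ``organism`` selects the foreground source: ``"sh"`` draws a random SH
    organism shape, ``"model"`` samples a fitted :class:`~synmicro.shapes.ShapeModel`,
    ``"mask"`` uses a provided binary volume. ``structure`` is ``"membranes"``
    or ``"nuclei"``. Layer/spacing defaults are in voxels and sized for toy
    volumes (tens of voxels across); scale them with the grid.
    """

    grid_shape: tuple[int, int, int] = (48, 64, 64)
    structure: str = "membranes"
    organism: str = "sh"
    organism_radius: float = 20.0
    organism_gamma: float = 2.0
    organism_l_max: int = 6
    organism_model: object = None        # ShapeModel when organism == "model"
    organism_n_modes: int = 3
    organism_mask: object = None         # LabelVolume/ndarray when organism == "mask"
    layer_thickness: float = 6.0
    target_spacing: float = 8.0
    jitter: float = 1.0
    n_layers: int = 2
    gamma_range: tuple[float, float] = (0.9, 1.1)
    membrane_thickness: int = 1
    include_outer_membrane: bool = True
    nucleus_r_mean: float = 9.0
    nucleus_r_sd: float = 1.0
    nucleus_gamma: float = 5.0
    nucleus_l_max: int = 6
    seed: int = 0

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()
             if k not in ("organism_model", "organism_mask")}
        d["grid_shape"] = list(self.grid_shape)
        d["gamma_range"] = list(self.gamma_range)
        return d


def _simulate_foreground(cfg: SimulationConfig) -> LabelVolume:
    from .shapes import boundary_to_mask, sample_shape

    if cfg.organism == "mask":
        if cfg.organism_mask is None:
            raise ValueError("organism='mask' requires organism_mask")
        return LabelVolume((as_array(cfg.organism_mask) > 0).astype(np.uint8))
    if cfg.organism == "model":
        if cfg.organism_model is None:
            raise ValueError("organism='model' requires organism_model")
        bp = sample_shape(cfg.organism_model, cfg.organism_n_modes,
                          seed=substream_seed(cfg.seed, "organism"))
        return boundary_to_mask(bp, cfg.grid_shape)
    if cfg.organism == "sh":
        shape = sample_sh_shape(cfg.organism_radius, cfg.organism_gamma,
                                cfg.organism_l_max,
                                seed=substream_seed(cfg.seed, "organism"))
        center = (np.array(cfg.grid_shape) - 1) / 2.0
        return voxelize_star_convex(shape.radius_fn, center, cfg.grid_shape)
    raise ValueError(f"unknown organism source: {cfg.organism!r}")


def simulate_annotation(cfg: SimulationConfig):
    """Simulate one fully consistent annotation triple.

    Returns ``(instances, structure, foreground)`` on a common grid:
    cell/nucleus instance labels, the binary structure mask (membranes or
    nuclei foreground), and the organism foreground. Deterministic per
    ``cfg.seed``.
    """
    if cfg.structure not in ("membranes", "nuclei"):
        raise ValueError("structure must be 'membranes' or 'nuclei'")
    foreground = _simulate_foreground(cfg)
    placement = place_cells_layerwise(
        foreground,
        layer_thickness=cfg.layer_thickness,
        target_spacing=cfg.target_spacing,
        jitter=cfg.jitter,
        n_layers=cfg.n_layers,
        seed=substream_seed(cfg.seed, "placement"),
        gamma_range=cfg.gamma_range,
    )
    if cfg.structure == "membranes":
        instances = weighted_tessellation(foreground, placement)
        structure = extract_membranes(instances, cfg.membrane_thickness,
                                      include_outer=cfg.include_outer_membrane)
    else:
        instances = place_nuclei(
            placement, cfg.grid_shape,
            r_mean=cfg.nucleus_r_mean, r_sd=cfg.nucleus_r_sd,
            gamma=cfg.nucleus_gamma, l_max=cfg.nucleus_l_max,
            seed=substream_seed(cfg.seed, "nuclei"),
        )
        structure = LabelVolume((instances.data > 0).astype(np.uint8))
    instances.metadata["placement"] = placement
    return instances, structure, foreground
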