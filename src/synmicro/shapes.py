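"""Star-convex 3D shape generation: spherical harmonics and statistical shape models.

A star-convex shape is described by a radius-over-direction function
``S(theta, phi)`` sampled on a fixed set of angular rays from the centroid.
Two generative representations are provided:

* **Spherical harmonics (SH)** — the radius function is a weighted sum of
  real orthonormal spherical-harmonic basis functions ``Y_l^m``. The ``l=0``
  coefficient sets the approximate radius ``r`` and higher-order coefficients
  are random with exponentially decaying magnitude controlled by a smoothness
  factor ``gamma``.
* **Statistical shape models (SSM)** — PCA over aligned boundary-point
  vectors of a training population; new shapes are the mean plus a random
  linear combination of the leading eigenmodes.

Conversions between the voxel representation (binary masks) and the
boundary-point representation (radial resampling, Delaunay voxelization)
close the loop so that shapes can be learned from masks and written back
as masks.

Coordinate conventions: volumes are indexed ``(z, y, x)``; boundary points
are ``(x, y, z)`` triples; the polar angle ``theta`` in [0, pi] is measured
from the +z axis and the azimuth ``phi`` in [0, 2*pi) from the +x axis.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError
from scipy.special import sph_harm_y

from .volumes import LabelVolume, as_array

__all__ = [
    "AngularGrid",
    "SHShape",
    "BoundaryPointList",
    "ShapeModel",
    "sh_basis_value",
    "sample_sh_shape",
    "sh_radius",
    "voxelize_star_convex",
    "radial_resample",
    "fit_shape_model",
    "sample_shape",
    "project_shape",
    "boundary_to_mask",
]


# ---------------------------------------------------------------------------
# Angular grids
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AngularGrid:
    """Ordered list of (theta, phi) ray directions from a centroid.

    The same grid object must be reused for every shape entering one
    :func:`fit_shape_model` call so that boundary vectors are aligned.
    """

    thetas: np.ndarray
    phis: np.ndarray

    def __post_init__(self):
        thetas = np.asarray(self.thetas, dtype=float)
        phis = np.asarray(self.phis, dtype=float)
        object.__setattr__(self, "thetas", thetas)
        object.__setattr__(self, "phis", phis)
        if thetas.shape != phis.shape or thetas.ndim != 1:
            raise ValueError("thetas and phis must be 1D arrays of equal length")
        if thetas.size < 6:
            raise ValueError("an AngularGrid needs at least 6 rays")
        pairs = set(zip(thetas.tolist(), phis.tolist()))
        if len(pairs) != thetas.size:
            raise ValueError("(theta, phi) ray directions must be unique")

    @property
    def n_rays(self) -> int:
        return self.thetas.size

    def directions(self) -> np.ndarray:
        """Unit ray directions as an (n, 3) array of (x, y, z) components."""
        st = np.sin(self.thetas)
        return np.stack(
            [st * np.cos(self.phis), st * np.sin(self.phis), np.cos(self.thetas)],
            axis=1,
        )

    @classmethod
    def fibonacci(cls, n_rays: int = 642) -> "AngularGrid":
        """Near-uniform Fibonacci-sphere grid (default 642 rays)."""
        i = np.arange(n_rays)
        z = 1.0 - 2.0 * (i + 0.5) / n_rays
        thetas = np.arccos(np.clip(z, -1.0, 1.0))
        golden = math.pi * (3.0 - math.sqrt(5.0))
        phis = (i * golden) % (2.0 * math.pi)
        return cls(thetas, phis)


# ---------------------------------------------------------------------------
# Real spherical-harmonics basis
# ---------------------------------------------------------------------------

def sh_basis_value(l: int, m: int, theta, phi):
    """Real orthonormal spherical-harmonic basis value ``Y_l^m(theta, phi)``.

    The real basis combines the +m/-m complex pair into cosine (m > 0) and
    sine (m < 0) variants, so radius functions built from real coefficients
    are real-valued by construction. ``Y_0^0 = 1/(2*sqrt(pi))``.
    """
    if l < 0 or abs(m) > l:
        raise ValueError(f"invalid degree/order: need 0 <= |m| <= l, got l={l}, m={m}")
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if m == 0:
        return np.real(sph_harm_y(l, 0, theta, phi))
    y = sph_harm_y(l, abs(m), theta, phi)
    # Condon-Shortley phase is included in sph_harm_y; (-1)^m restores the
    # standard real-basis sign convention.
    if m > 0:
        return math.sqrt(2.0) * (-1.0) ** m * np.real(y)
    return math.sqrt(2.0) * (-1.0) ** m * np.imag(y)


def _lm_order(l_max: int) -> list[tuple[int, int]]:
    """Pyramid coefficient ordering: (0,0), (1,-1), (1,0), (1,1), (2,-2), ..."""
    return [(l, m) for l in range(l_max + 1) for m in range(-l, l + 1)]


def _basis_matrix(l_max: int, thetas, phis, radius_convention: bool = True) -> np.ndarray:
    """(n_points, (l_max+1)^2) matrix of real basis values.

    With ``radius_convention`` the constant (l=0) column is rescaled to 1 so
    that a shape with only ``c_0^0 = r`` has radius exactly ``r``. Evaluated
    through one vectorized complex-harmonics call (``sph_harm_y_all``); the
    real combinations match :func:`sh_basis_value`.
    """
    from scipy.special import sph_harm_y_all

    thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
    phis = np.atleast_1d(np.asarray(phis, dtype=float))
    Y = sph_harm_y_all(l_max, l_max, thetas, phis)  # (l_max+1, 2*l_max+1, n)
    sqrt2 = math.sqrt(2.0)
    out = np.empty((thetas.size, (l_max + 1) ** 2))
    for j, (l, m) in enumerate(_lm_order(l_max)):
        if l == 0:
            out[:, j] = 1.0 if radius_convention else np.real(Y[0, 0])
        elif m == 0:
            out[:, j] = np.real(Y[l, 0])
        elif m > 0:
            out[:, j] = sqrt2 * (-1.0) ** m * np.real(Y[l, m])
        else:
            out[:, j] = sqrt2 * (-1.0) ** m * np.imag(Y[l, -m])
    return out


# ---------------------------------------------------------------------------
# SH shapes
# ---------------------------------------------------------------------------

@dataclass
class SHShape:
    """Compact star-convex shape as real spherical-harmonics coefficients.

    ``coeffs`` holds ``(l_max+1)**2`` values in pyramid order
    (l ascending, m from -l to l); ``coeffs[0]`` equals ``r``.
    """

    r: float
    gamma: float
    l_max: int
    coeffs: np.ndarray
    seed: int | None = None

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.size != (self.l_max + 1) ** 2:
            raise ValueError(
                f"expected {(self.l_max + 1) ** 2} coefficients for l_max={self.l_max}, "
                f"got {self.coeffs.size}"
            )

    def radius_fn(self, theta, phi):
        return sh_radius(self, theta, phi)

    def to_json(self) -> str:
        return json.dumps(
            {
                "r": self.r,
                "gamma": self.gamma,
                "l_max": self.l_max,
                "coeffs": self.coeffs.tolist(),
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SHShape":
        d = json.loads(text)
        return cls(d["r"], d["gamma"], d["l_max"], np.array(d["coeffs"]), d.get("seed"))


def sh_radius(shape: SHShape, theta, phi):
    """Radius function ``S_SH(theta, phi)``: weighted sum of basis values.

    The l=0 term uses the radius convention (coefficient = radius), so a
    pure ``c_0^0 = r`` shape returns exactly ``r`` in every direction.
    """
    theta = np.asarray(theta, dtype=float)
    scalar = theta.ndim == 0
    B = _basis_matrix(shape.l_max, theta, phi)
    out = B @ shape.coeffs
    return float(out[0]) if scalar else out


def sample_sh_shape(
    r: float,
    gamma: float,
    l_max: int,
    seed: int,
    decay_on: str = "l",
    grid: AngularGrid | None = None,
    max_retries: int = 25,
) -> SHShape:
    """Draw a random smooth star-convex shape of approximate radius ``r``.

    Coefficients follow ``c_l^m = r * w(l, m) * exp(-gamma * d)`` for l >= 1
    with ``w`` i.i.d. standard normal, ``c_0^0 = r``, and the decay exponent
    ``d`` chosen by ``decay_on``:

    * ``"l"`` (default) — ``d = l``: every non-spherical component is damped,
      so ``gamma`` acts as a true smoothness factor and large ``gamma``
      converges to a sphere of radius ``r``.
    * ``"m"`` — ``d = |m|``: damping by degree only; order-l, degree-0
      components stay undamped, which produces much rougher shapes and is
      kept for completeness.

    If the radius function is non-positive anywhere on the evaluation grid
    the shape is resampled with an incremented seed (bounded retries).
    """
    if r <= 0:
        raise ValueError("r must be positive")
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    if l_max < 0:
        raise ValueError("l_max must be non-negative")
    if decay_on not in ("l", "m"):
        raise ValueError("decay_on must be 'l' or 'm'")
    if grid is None:
        grid = AngularGrid.fibonacci(642)
    B = _basis_matrix(l_max, grid.thetas, grid.phis)
    lm = _lm_order(l_max)
    for attempt in range(max_retries):
        s = seed + attempt
        rng = np.random.default_rng(s)
        coeffs = np.zeros(len(lm))
        coeffs[0] = r
        for j, (l, m) in enumerate(lm):
            if l == 0:
                continue
            d = l if decay_on == "l" else abs(m)
            coeffs[j] = r * rng.standard_normal() * math.exp(-gamma * d)
        if np.all(B @ coeffs > 0):
            return SHShape(r=r, gamma=gamma, l_max=l_max, coeffs=coeffs, seed=s)
    raise RuntimeError(
        f"could not draw a strictly positive radius function in {max_retries} "
        f"attempts (r={r}, gamma={gamma}, l_max={l_max}); increase gamma"
    )


# ---------------------------------------------------------------------------
# Voxelization and radial resampling
# ---------------------------------------------------------------------------

def _voxel_angles(center_zyx, grid_shape, voxel_size=None, z_slice=None):
    """Spherical coordinates (rho, theta, phi) of voxel centers about a center."""
    nz, ny, nx = grid_shape
    zs = np.arange(nz) if z_slice is None else np.arange(*z_slice)
    z, y, x = np.meshgrid(zs, np.arange(ny), np.arange(nx), indexing="ij")
    vz, vy, vx = (1.0, 1.0, 1.0) if voxel_size is None else voxel_size
    dz = (z - center_zyx[0]) * vz
    dy = (y - center_zyx[1]) * vy
    dx = (x - center_zyx[2]) * vx
    rho = np.sqrt(dx * dx + dy * dy + dz * dz)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(np.where(rho > 0, dz / np.where(rho > 0, rho, 1.0), 1.0), -1, 1))
    phi = np.arctan2(dy, dx) % (2.0 * math.pi)
    return rho, theta, phi


def voxelize_star_convex(
    radius_fn,
    center,
    grid_shape,
    voxel_size=None,
    slab: int = 16,
    radius_bounds: tuple[float, float] | None = None,
) -> LabelVolume:
    """Rasterize a star-convex shape given by a radius-over-direction function.

    A voxel belongs to the foreground iff its distance to ``center`` (in
    physical units when ``voxel_size`` is given) is at most the radius in its
    direction. ``center`` is in (z, y, x) voxel coordinates. If the shape
    touches the grid boundary, ``metadata['truncated']`` is set.

    ``radius_bounds = (r_lo, r_hi)`` is an optional performance hint: voxels
    closer than ``r_lo`` are accepted and voxels beyond ``r_hi`` rejected
    without evaluating ``radius_fn`` (the caller guarantees
    ``r_lo <= radius_fn <= r_hi`` everywhere).
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    center = np.asarray(center, dtype=float)
    if np.any(center < 0) or np.any(center > np.array(grid_shape) - 1):
        raise ValueError("center must lie inside the grid")
    nz = grid_shape[0]
    out = np.zeros(grid_shape, dtype=np.uint8)
    for z0 in range(0, nz, slab):
        z1 = min(z0 + slab, nz)
        rho, theta, phi = _voxel_angles(center, grid_shape, voxel_size, (z0, z1))
        if radius_bounds is not None:
            r_lo, r_hi = radius_bounds
            fg = rho <= r_lo
            shell = (rho > r_lo) & (rho <= r_hi)
            if shell.any():
                rad = np.asarray(radius_fn(theta[shell], phi[shell]))
                if np.any(rad <= 0):
                    raise ValueError("radius_fn must be strictly positive")
                fg[shell] = rho[shell] <= rad
            out[z0:z1] = fg.astype(np.uint8)
            continue
        rad = np.asarray(radius_fn(theta.ravel(), phi.ravel())).reshape(rho.shape)
        if np.any(rad <= 0):
            raise ValueError("radius_fn must be strictly positive")
        out[z0:z1] = (rho <= rad).astype(np.uint8)
    truncated = bool(
        out[0].any() or out[-1].any()
        or out[:, 0].any() or out[:, -1].any()
        or out[:, :, 0].any() or out[:, :, -1].any()
    )
    return LabelVolume(out, voxel_size=voxel_size, metadata={"truncated": truncated})


@dataclass
class BoundaryPointList:
    """Boundary of a star-convex shape sampled on an AngularGrid.

    ``points`` is an (n, 3) array of (x, y, z) coordinates; point ``i`` lies
    on ray ``i`` of ``grid`` from ``centroid`` (also (x, y, z)).
    """

    points: np.ndarray
    centroid: np.ndarray
    grid: AngularGrid | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array of (x, y, z) coordinates")
        if self.grid is not None and self.points.shape[0] != self.grid.n_rays:
            raise ValueError("number of points must equal the number of grid rays")

    def as_vector(self) -> np.ndarray:
        """Flattened (x1, y1, z1, ..., xn, yn, zn) representation."""
        return self.points.reshape(-1)


def radial_resample(mask, grid: AngularGrid, step: float = 0.25) -> BoundaryPointList:
    """Sample a binary mask's boundary along the rays of an angular grid.

    Rays start at the foreground centroid; for each ray the farthest
    foreground-to-background transition of the trilinearly interpolated mask
    is recorded, with sub-voxel position from the 0.5-isolevel crossing.
    """
    from scipy.ndimage import map_coordinates

    arr = as_array(mask) > 0
    if not arr.any():
        raise ValueError("mask has no foreground")
    idx = np.argwhere(arr)
    centroid_zyx = idx.mean(axis=0)
    nearest = np.round(centroid_zyx).astype(int)
    if not arr[tuple(nearest)]:
        raise ValueError("foreground centroid lies in background; shape is not star-convex about its centroid")
    dirs_xyz = grid.directions()  # (n, 3)
    dirs_zyx = dirs_xyz[:, ::-1]
    t_max = float(np.linalg.norm(arr.shape)) + 1.0
    ts = np.arange(step, t_max, step)
    # sample positions: (n_rays, n_t, 3)
    pos = centroid_zyx[None, None, :] + ts[None, :, None] * dirs_zyx[:, None, :]
    vals = map_coordinates(
        arr.astype(np.float32), pos.reshape(-1, 3).T, order=1, mode="constant", cval=0.0
    ).reshape(grid.n_rays, ts.size)
    fg = vals >= 0.5
    n_rays, n_t = fg.shape
    any_fg = fg.any(axis=1)
    last = np.zeros(n_rays, dtype=int)
    last[any_fg] = n_t - 1 - np.argmax(fg[any_fg, ::-1], axis=1)
    v_in = vals[np.arange(n_rays), last]
    v_out = vals[np.arange(n_rays), np.minimum(last + 1, n_t - 1)]
    frac = np.where(v_in > v_out, (v_in - 0.5) / np.maximum(v_in - v_out, 1e-9), 0.5)
    t_bound = np.where(any_fg, ts[last] + step * np.clip(frac, 0.0, 1.0), step / 2.0)
    centroid_xyz = centroid_zyx[::-1]
    points = centroid_xyz[None, :] + t_bound[:, None] * dirs_xyz
    return BoundaryPointList(points=points, centroid=centroid_xyz, grid=grid)


# ---------------------------------------------------------------------------
# Statistical shape models
# ---------------------------------------------------------------------------

@dataclass
class ShapeModel:
    """PCA point-distribution model over aligned boundary vectors.

    ``mean`` is the arithmetic mean boundary vector; ``modes`` (n_modes, 3n)
    are orthonormal eigenvectors of the 1/(k-1)-normalized sample covariance;
    ``variances`` are the matching eigenvalues, sorted non-increasing.
    """

    mean: np.ndarray
    modes: np.ndarray
    variances: np.ndarray
    n_train: int
    grid: AngularGrid | None = None

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]

    def positive_modes(self, tol: float = 1e-12) -> int:
        scale = float(self.variances[0]) if self.variances.size else 0.0
        return int(np.sum(self.variances > tol * max(scale, 1.0)))


def fit_shape_model(shapes: list[BoundaryPointList]) -> ShapeModel:
    """Fit a statistical shape model to boundary lists on a common grid."""
    if len(shapes) < 2:
        raise ValueError("need at least 2 training shapes")
    vectors = [s.as_vector() for s in shapes]
    n = vectors[0].size
    if any(v.size != n for v in vectors):
        raise ValueError("all training shapes must have the same vector length")
    grids = {id(s.grid) for s in shapes if s.grid is not None}
    if len(grids) > 1:
        raise ValueError("all training shapes must share one AngularGrid")
    X = np.stack(vectors)  # (k, 3n)
    k = X.shape[0]
    mean = X.mean(axis=0)
    C = X - mean
    # SVD of the centered data matrix gives the covariance eigenpairs without
    # forming the 3n x 3n covariance.
    _, s, Vt = np.linalg.svd(C, full_matrices=False)
    variances = (s ** 2) / (k - 1)
    order = np.argsort(variances)[::-1]
    variances = variances[order]
    modes = Vt[order]
    return ShapeModel(mean=mean, modes=modes, variances=variances, n_train=k,
                      grid=shapes[0].grid)


def project_shape(model: ShapeModel, shape: BoundaryPointList) -> np.ndarray:
    """Mode coefficients ``b`` of a boundary shape: b = modes @ (p - mean)."""
    return model.modes @ (shape.as_vector() - model.mean)


def sample_shape(
    model: ShapeModel,
    n_modes: int,
    seed: int | None = None,
    b: np.ndarray | None = None,
    bound_scale: str = "lambda",
) -> BoundaryPointList:
    """Generate a new shape as mean plus a random combination of modes.

    Mode weights ``b_j`` are drawn uniformly from ``[-3*lambda_j, 3*lambda_j]``
    (``bound_scale='sqrt'`` uses ``3*sqrt(lambda_j)``, the conventional PCA
    band, instead). Pass ``b`` explicitly to bypass sampling (e.g. to
    reconstruct a training shape from its projection coefficients).
    """
    if not 1 <= n_modes <= model.positive_modes():
        raise ValueError(
            f"n_modes must be in [1, {model.positive_modes()}] (positive-variance modes)"
        )
    if b is None:
        rng = np.random.default_rng(seed)
        lam = model.variances[:n_modes]
        bound = 3.0 * (np.sqrt(lam) if bound_scale == "sqrt" else lam)
        b = rng.uniform(-bound, bound)
    else:
        b = np.asarray(b, dtype=float)
        if b.size != n_modes:
            raise ValueError("b must have n_modes entries")
    vec = model.mean + model.modes[:n_modes].T @ b
    points = vec.reshape(-1, 3)
    return BoundaryPointList(points=points, centroid=points.mean(axis=0), grid=model.grid)


# ---------------------------------------------------------------------------
# Boundary points -> voxels
# ---------------------------------------------------------------------------

def boundary_to_mask(points: BoundaryPointList | np.ndarray, grid_shape) -> LabelVolume:
    """Voxelize a boundary-point cloud via Delaunay tessellation.

    Voxel centers inside the Delaunay tessellation of the boundary points
    (i.e. their convex hull) become foreground. Raises on degenerate
    (coplanar) point sets.
    """
    pts = points.points if isinstance(points, BoundaryPointList) else np.asarray(points, float)
    if pts.shape[0] < 4:
        raise ValueError("need at least 4 boundary points")
    try:
        tri = Delaunay(pts)
    except QhullError as e:
        raise ValueError(f"degenerate (coplanar) boundary point set: {e}") from e
    grid_shape = tuple(int(s) for s in grid_shape)
    lo = np.maximum(np.floor(pts.min(axis=0)).astype(int), 0)          # (x, y, z)
    hi = np.minimum(np.ceil(pts.max(axis=0)).astype(int) + 1, np.array(grid_shape)[::-1])
    out = np.zeros(grid_shape, dtype=np.uint8)
    if np.any(hi <= lo):
        warnings.warn("boundary points lie entirely outside the grid")
        return LabelVolume(out, metadata={"truncated": True})
    xs, ys, zs = (np.arange(lo[i], hi[i]) for i in range(3))
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    q = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1).astype(float)
    inside = tri.find_simplex(q) >= 0
    out[gz.ravel()[inside], gy.ravel()[inside], gx.ravel()[inside]] = 1
    truncated = bool(np.any(pts.min(axis=0) < -0.5) or
                     np.any(pts.max(axis=0) > np.array(grid_shape)[::-1] - 0.5))
    return LabelVolume(out, metadata={"truncated": truncated})
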