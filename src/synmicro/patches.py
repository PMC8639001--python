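"""Patch extraction and seamless full-volume reassembly.

3D volumes are processed patch-wise (memory-bounded inference) and
reassembled without tiling artifacts by (1) cropping a margin ``d_crop``
from every patch side that does not touch the volume boundary, (2)
overlapping neighbouring cropped patches by ``d_overlap``, and (3) averaging
overlaps with a concentric weight map that down-weights voxels towards patch
faces.

All extents are in (z, y, x) axis order. The classical training/inference
patch of 128x128x64 (x, y, z) is therefore ``(64, 128, 128)`` here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .volumes import as_array

__all__ = [
    "PatchGridSpec",
    "random_origin",
    "random_patch",
    "concentric_weights",
    "tile_origins",
    "cut_volume",
    "assemble",
    "apply_patchwise",
]


@dataclass(frozen=True)
class PatchGridSpec:
    """Tiling geometry: patch extents, per-axis overlap and crop margins.

    ``stride = patch_size - 2*d_crop - d_overlap`` per axis and must be >= 1.
    Defaults mirror the reference setting: patches of 128x128x64 (x, y, z)
    with overlap and crop margins of (30, 30, 15), expressed in (z, y, x).
    """

    patch_size: tuple[int, int, int] = (64, 128, 128)
    d_overlap: tuple[int, int, int] = (15, 30, 30)
    d_crop: tuple[int, int, int] = (15, 30, 30)

    def __post_init__(self):
        for name in ("patch_size", "d_overlap", "d_crop"):
            object.__setattr__(self, name, tuple(int(v) for v in getattr(self, name)))
        if any(c < 0 for c in self.d_crop):
            raise ValueError("d_crop must be non-negative")
        if any(o >= p for o, p in zip(self.d_overlap, self.patch_size)):
            raise ValueError("d_overlap must be smaller than patch_size")
        if any(s < 1 for s in self.stride):
            raise ValueError(
                f"stride {self.stride} < 1; reduce d_crop/d_overlap for patch {self.patch_size}"
            )

    @property
    def stride(self) -> tuple[int, int, int]:
        return tuple(p - 2 * c - o
                     for p, c, o in zip(self.patch_size, self.d_crop, self.d_overlap))


def random_origin(shape, patch_size, rng: np.random.Generator) -> tuple[int, ...]:
    """Uniformly random valid patch origin in a volume of the given shape."""
    return tuple(int(rng.integers(0, s - p + 1)) for s, p in zip(shape, patch_size))


def random_patch(volumes, patch_size, seed: int):
    """Extract one identically-windowed random patch from aligned volumes.

    ``volumes`` is a single array or a sequence of aligned arrays (e.g. mask,
    positional map, image); the same uniformly random window is applied to
    all of them. Volumes smaller than the patch are reflect-padded first.
    Returns ``(origin, patches)`` with ``patches`` matching the input nesting.
    """
    single = not isinstance(volumes, (list, tuple))
    vols = [as_array(volumes)] if single else [as_array(v) for v in volumes]
    shape = vols[0].shape
    if any(v.shape != shape for v in vols):
        raise ValueError("aligned volumes must share one shape")
    patch_size = tuple(int(p) for p in patch_size)
    pad = [(0, max(0, p - s)) for p, s in zip(patch_size, shape)]
    if any(p[1] > 0 for p in pad):
        vols = [np.pad(v, pad, mode="reflect") for v in vols]
        shape = vols[0].shape
    rng = np.random.default_rng(seed)
    origin = random_origin(shape, patch_size, rng)
    window = tuple(slice(o, o + p) for o, p in zip(origin, patch_size))
    patches = [v[window].copy() for v in vols]
    return origin, (patches[0] if single else patches)


def concentric_weights(patch_size, eps: float = 0.05, profile: str = "linear") -> np.ndarray:
    """Strictly positive blending weights, maximal at the patch center.

    Separable product of per-axis symmetric ramps from ``eps`` at the faces
    to 1 at the center (``profile='gaussian'`` uses a Gaussian bump with the
    same floor). Corner weight is ``eps**3`` for the linear profile.
    """
    if not 0 < eps <= 1:
        raise ValueError("eps must be in (0, 1]")
    axes = []
    for n in patch_size:
        if n < 1:
            raise ValueError("patch extents must be positive")
        if n == 1:
            axes.append(np.ones(1))
            continue
        c = (n - 1) / 2.0
        u = np.abs(np.arange(n) - c) / c  # 0 at center, 1 at faces
        if profile == "linear":
            axes.append(1.0 - (1.0 - eps) * u)
        elif profile == "gaussian":
            g = np.exp(-4.0 * u ** 2)
            axes.append(eps + (1.0 - eps) * (g - g.min()) / (g.max() - g.min()))
        else:
            raise ValueError("profile must be 'linear' or 'gaussian'")
    return axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]


def tile_origins(out_shape, spec: PatchGridSpec) -> list[tuple[int, ...]]:
    """Patch origins covering a volume, stepping by the spec stride.

    The last tile of each axis is shifted inward so it ends exactly at the
    volume boundary (last-tile alignment); boundary-touching sides are not
    cropped during assembly, so no true boundary voxel is lost.
    """
    per_axis = []
    for dim, p, s in zip(out_shape, spec.patch_size, spec.stride):
        if dim < p:
            raise ValueError(f"volume extent {dim} smaller than patch extent {p}; pad first")
        xs = list(range(0, dim - p + 1, s))
        if xs[-1] != dim - p:
            xs.append(dim - p)
        per_axis.append(xs)
    return [tuple(o) for o in itertools.product(*per_axis)]


def cut_volume(volume, spec: PatchGridSpec) -> list[tuple[tuple[int, ...], np.ndarray]]:
    """Cut a volume into overlapping patches on the spec's tiling grid."""
    arr = as_array(volume)
    out = []
    for origin in tile_origins(arr.shape, spec):
        window = tuple(slice(o, o + p) for o, p in zip(origin, spec.patch_size))
        out.append((origin, arr[window].copy()))
    return out


def _crop_slices(origin, patch_shape, out_shape, d_crop):
    """Per-axis crop of d_crop, skipped on sides touching the volume boundary."""
    sl = []
    for o, p, dim, c in zip(origin, patch_shape, out_shape, d_crop):
        lo = 0 if o == 0 else c
        hi = p if o + p == dim else p - c
        if hi <= lo:
            raise ValueError("d_crop leaves an empty patch window")
        sl.append(slice(lo, hi))
    return tuple(sl)


def assemble(patches, spec: PatchGridSpec, out_shape, eps: float = 0.05,
             profile: str = "linear") -> np.ndarray:
    """Reassemble a full volume from (origin, patch) pairs.

    Each patch is cropped by ``d_crop`` (except on volume-boundary sides),
    then accumulated as a weighted average with the concentric weight map;
    output voxels are ``sum(w_i * p_i) / sum(w_i)`` over covering patches.
    Raises if any voxel remains uncovered, reporting the uncovered bounding
    box. Accumulation is commutative, so patch order does not matter.
    """
    out_shape = tuple(int(s) for s in out_shape)
    num = np.zeros(out_shape, dtype=np.float64)
    den = np.zeros(out_shape, dtype=np.float64)
    weights = concentric_weights(spec.patch_size, eps=eps, profile=profile)
    for origin, patch in patches:
        patch = as_array(patch)
        if patch.shape != spec.patch_size:
            raise ValueError(f"patch at {origin} has shape {patch.shape}, "
                             f"expected {spec.patch_size}")
        crop = _crop_slices(origin, patch.shape, out_shape, spec.d_crop)
        target = tuple(slice(o + c.start, o + c.stop) for o, c in zip(origin, crop))
        w = weights[crop]
        num[target] += w * patch[crop]
        den[target] += w
    if np.any(den == 0):
        missing = np.argwhere(den == 0)
        lo, hi = missing.min(axis=0), missing.max(axis=0)
        raise ValueError(f"coverage gap: uncovered bounding box {tuple(lo)}..{tuple(hi)}")
    return num / den


def apply_patchwise(fn, volumes, spec: PatchGridSpec, out_shape=None) -> np.ndarray:
    """Run ``fn(*patches) -> patch`` over the tiling of aligned volumes and
    reassemble the results (reflect-padding volumes smaller than the patch)."""
    vols = [as_array(v) for v in (volumes if isinstance(volumes, (list, tuple)) else [volumes])]
    shape = vols[0].shape
    pad = [(0, max(0, p - s)) for p, s in zip(spec.patch_size, shape)]
    padded = any(p[1] > 0 for p in pad)
    if padded:
        vols = [np.pad(v, pad, mode="reflect") for v in vols]
    work_shape = vols[0].shape
    outputs = []
    for origin in tile_origins(work_shape, spec):
        window = tuple(slice(o, o + p) for o, p in zip(origin, spec.patch_size))
        outputs.append((origin, fn(*[v[window] for v in vols])))
    res = assemble(outputs, spec, work_shape)
    if padded:
        res = res[tuple(slice(0, s) for s in shape)]
    if out_shape is not None and tuple(out_shape) != res.shape:
        raise ValueError("out_shape mismatch")
    return res
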