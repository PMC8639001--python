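"""Lightweight volume containers and seed bookkeeping.

All volumes in this package use axis order ``(z, y, x)`` with 0-based,
voxel-centered coordinates. Boundary points and other geometric quantities
that are exposed as ``(x, y, z)`` triples are converted explicitly at the
module boundaries (see :mod:`synmicro.shapes`).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LabelVolume",
    "IntensityVolume",
    "as_array",
    "voxel_size_of",
    "substream_seed",
]


@dataclass
class LabelVolume:
    """3D integer volume; 0 is background, positive integers are instances.

    ``voxel_size`` is the physical extent of one voxel per axis in (z, y, x)
    order (micrometres by convention); ``None`` means unknown/isotropic-1.
    Instance ids may be sparse (e.g. occluded nuclei); this is recorded in
    ``metadata['sparse_labels']`` when a producer knows it.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"LabelVolume must be 3D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            if np.issubdtype(self.data.dtype, np.bool_):
                self.data = self.data.astype(np.uint8)
            else:
                raise ValueError(f"LabelVolume requires integer voxels, got {self.data.dtype}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def labels(self) -> np.ndarray:
        """Sorted positive instance ids present in the volume."""
        u = np.unique(self.data)
        return u[u > 0]

    def __array__(self, dtype=None):
        return self.data if dtype is None else self.data.astype(dtype)


@dataclass
class IntensityVolume:
    """3D scalar volume of microscopy-like intensities in [0, 1]."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] | None = None
    original_range: tuple[float, float] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"IntensityVolume must be 3D, got shape {self.data.shape}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def __array__(self, dtype=None):
        return self.data if dtype is None else self.data.astype(dtype)


def as_array(volume) -> np.ndarray:
    """Coerce a LabelVolume/IntensityVolume/ndarray to a plain ndarray."""
    if isinstance(volume, (LabelVolume, IntensityVolume)):
        return volume.data
    return np.asarray(volume)


def voxel_size_of(volume) -> tuple[float, float, float] | None:
    if isinstance(volume, (LabelVolume, IntensityVolume)):
        return volume.voxel_size
    return None


def substream_seed(master_seed: int, *tags) -> int:
    """Derive a reproducible child seed (< 2**31) from a master seed and tags.

    Stages of the pipeline draw their randomness from named substreams so
    each stage is independently reproducible from the master seed alone.
    """
    key = ":".join(str(t) for t in (master_seed, *tags)).encode()
    return zlib.crc32(key) & 0x7FFFFFFF
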