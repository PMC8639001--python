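"""Volume I/O (multi-page TIFF and HDF5) and provenance records.

Axis order on disk and in memory is (z, y, x): TIFF pages are z-slices.
Voxel sizes are read from ImageJ-style TIFF metadata (``spacing`` +
resolution tags) or the ``element_size_um`` HDF5 attribute when present, and
written back the same way. Intensity volumes are rescaled to [0, 1] on read
when they exceed that range, with the original range recorded.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volumes import IntensityVolume, LabelVolume, as_array

__all__ = ["read_volume", "write_volume", "Provenance"]

_H5_DATASET = "volume"


def _is_hdf5(path: Path) -> bool:
    return path.suffix.lower() in (".h5", ".hdf5", ".hdf")


def read_volume(path, kind: str = "label"):
    """Read a 3D volume from multi-page TIFF or HDF5.

    ``kind='label'`` returns a :class:`LabelVolume` with integer voxels;
    ``kind='intensity'`` returns an :class:`IntensityVolume` rescaled to
    [0, 1] (original range recorded in ``original_range``). A 512x512 stack
    of 120 pages reads as shape (120, 512, 512).
    """
    if kind not in ("label", "intensity"):
        raise ValueError("kind must be 'label' or 'intensity'")
    path = Path(path)
    voxel_size = None
    if _is_hdf5(path):
        import h5py

        with h5py.File(path, "r") as f:
            name = _H5_DATASET if _H5_DATASET in f else next(iter(f.keys()))
            ds = f[name]
            data = ds[()]
            if "element_size_um" in ds.attrs:
                voxel_size = tuple(float(v) for v in ds.attrs["element_size_um"])
    else:
        import tifffile

        with tifffile.TiffFile(path) as tif:
            try:
                data = tif.asarray()
            except Exception as e:  # ragged/corrupt stacks
                raise ValueError(f"unreadable TIFF stack {path}: {e}") from e
            meta = tif.imagej_metadata or {}
            spacing = meta.get("spacing")
            page = tif.pages[0]
            xres = page.tags.get("XResolution")
            yres = page.tags.get("YResolution")
            if spacing is not None and xres is not None and yres is not None:
                vx = xres.value[1] / xres.value[0]
                vy = yres.value[1] / yres.value[0]
                voxel_size = (float(spacing), float(vy), float(vx))
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D stack in {path}, got shape {data.shape}")
    if kind == "label":
        if not np.issubdtype(data.dtype, np.integer):
            raise ValueError(f"label volume {path} has non-integer dtype {data.dtype}")
        return LabelVolume(data, voxel_size=voxel_size)
    data = data.astype(np.float32)
    lo, hi = float(data.min()), float(data.max())
    if lo < 0.0 or hi > 1.0:
        data = (data - lo) / (hi - lo) if hi > lo else np.zeros_like(data)
    return IntensityVolume(data, voxel_size=voxel_size, original_range=(lo, hi))


def write_volume(volume, path, intensity_as: str = "float32") -> Path:
    """Write a volume to TIFF or HDF5 (by file extension).

    Labels are stored as uint16, or uint32 automatically when ids exceed
    65535. Intensities are stored as float32, or rescaled to uint16 with
    ``intensity_as='uint16'``. TIFF and HDF5 writers produce voxel-identical
    data.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    voxel_size = getattr(volume, "voxel_size", None)
    data = as_array(volume)
    if isinstance(volume, LabelVolume) or np.issubdtype(data.dtype, np.integer):
        max_label = int(data.max(initial=0))
        if max_label > np.iinfo(np.uint32).max:
            raise ValueError(f"label {max_label} exceeds the uint32 range")
        dtype = np.uint16 if max_label <= np.iinfo(np.uint16).max else np.uint32
        out = data.astype(dtype)
    else:
        if intensity_as == "uint16":
            out = np.clip(np.asarray(data, np.float64), 0, 1)
            out = (out * np.iinfo(np.uint16).max).round().astype(np.uint16)
        elif intensity_as == "float32":
            out = data.astype(np.float32)
        else:
            raise ValueError("intensity_as must be 'float32' or 'uint16'")
    if _is_hdf5(path):
        import h5py

        with h5py.File(path, "w") as f:
            ds = f.create_dataset(_H5_DATASET, data=out, compression="gzip")
            if voxel_size is not None:
                ds.attrs["element_size_um"] = np.asarray(voxel_size, dtype=float)
    else:
        import tifffile

        kwargs = {"photometric": "minisblack"}
        if voxel_size is not None and out.dtype in (np.uint8, np.uint16, np.float32):
            vz, vy, vx = voxel_size
            kwargs.update({"imagej": True,
                           "resolution": (1.0 / vx, 1.0 / vy),
                           "metadata": {"spacing": vz, "unit": "um", "axes": "ZYX"}})
        tifffile.imwrite(path, out, **kwargs)
    return path


@dataclass
class Provenance:
    """Reproducibility record written next to every pipeline output.

    Rerunning with the recorded config and master seed reproduces all
    deterministic stages bitwise.
    """

    tool: str = "synmicro"
    version: str = "0.1.0"
    master_seed: int = 0
    config: dict = field(default_factory=dict)
    stage_seeds: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)
    created: str = field(default_factory=lambda: datetime.datetime.now().isoformat(timespec="seconds"))

    def add_checksum(self, name: str, volume) -> None:
        arr = np.ascontiguousarray(as_array(volume))
        self.checksums[name] = hashlib.sha256(arr.tobytes()).hexdigest()

    def write(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "tool": self.tool, "version": self.version,
            "master_seed": self.master_seed, "config": self.config,
            "stage_seeds": self.stage_seeds, "checksums": self.checksums,
            "created": self.created,
        }
        path.write_text(json.dumps(payload, indent=2, default=str))
        return path

    @classmethod
    def read(cls, path) -> "Provenance":
        d = json.loads(Path(path).read_text())
        return cls(tool=d["tool"], version=d["version"], master_seed=d["master_seed"],
                   config=d["config"], stage_seeds=d["stage_seeds"],
                   checksums=d["checksums"], created=d["created"])
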