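"""Volume, table and model file I/O plus tiling of large volumes.

Coordinate convention used throughout the package: 0-based voxel indices in
(x, y, z) order with half-open bounding boxes ``[min, max)``.  Files may store
their arrays z-major (TIFF pages are z slices); the in-memory contract is
always (x, y, z).

Physical voxel size is carried as explicit metadata: HDF5 attributes on the
dataset, or a JSON sidecar (``<stem>.json``) next to a TIFF stack.  When the
metadata is absent a default of 11.24 x 11.24 x 28 nm is assumed and a
warning is logged — this is the voxel size of serial block-face EM data this
detector was designed around.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("emsynapse")

#: default physical voxel size (x, y, z) in nm for SBEM cortex data
DEFAULT_VOXEL_SIZE_NM = (11.24, 11.24, 28.0)


class VolumeIOError(Exception):
    """Base class for volume I/O failures."""


class MissingFileError(VolumeIOError):
    """The requested path does not exist."""


class FormatError(VolumeIOError):
    """The stored dataset has an unexpected shape or dtype."""


class BoundingBoxError(VolumeIOError):
    """A requested bounding box exceeds the stored extent."""


@dataclass
class VoxelVolume:
    """Raw 8-bit EM intensities with physical metadata.

    ``data`` is indexed ``[x, y, z]``; ``origin_voxel`` is the global offset
    of ``data[0, 0, 0]``.
    """

    data: np.ndarray
    voxel_size_nm: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_NM
    origin_voxel: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"expected 3D data, got ndim={self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise FormatError(f"degenerate shape {self.data.shape}")
        if any(v <= 0 for v in self.voxel_size_nm):
            raise ValueError(f"voxel size must be positive, got {self.voxel_size_nm}")
        if self.data.size and (self.data.min() < 0 or self.data.max() > 255):
            raise ValueError("intensity values must lie within [0, 255]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)


@dataclass
class SegmentationVolume:
    """Integer label volume; 0 marks boundary / extracellular voxels."""

    labels: np.ndarray
    voxel_size_nm: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_NM
    origin_voxel: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise FormatError(f"expected 3D labels, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("segmentation labels must be integers")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("segmentation labels must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)


@dataclass
class TileGrid:
    """Partition of a volume into core regions with padded surrounds.

    Each tile is a pair of half-open boxes ``(core, padded)`` in global voxel
    coordinates, stored as ``((min_xyz, max_xyz), (min_xyz, max_xyz))``.  Core
    regions tile the volume exactly; padded regions extend each core by the
    overlap, clipped to the volume, so that translation-invariant filters can
    be evaluated per tile and cropped back to the core without border
    artifacts.
    """

    volume_shape: tuple[int, int, int]
    tile_shape: tuple[int, int, int]
    overlap: tuple[int, int, int]
    tiles: list[tuple[tuple, tuple]] = field(default_factory=list)


def make_tiles(volume_shape, tile_shape, overlap) -> TileGrid:
    """Tile a volume into non-overlapping cores with overlapping padding.

    The reference processing unit is a 548 x 548 x 268 voxel cuboid with
    72 / 72 / 24 voxel overlap, which guarantees that every perisynaptic
    subvolume plus the texture-filter reach fits inside a padded tile.
    """
    volume_shape = tuple(int(v) for v in volume_shape)
    tile_shape = tuple(int(v) for v in tile_shape)
    overlap = tuple(int(v) for v in overlap)
    if any(t <= 0 for t in tile_shape):
        raise ValueError(f"tile shape must be positive, got {tile_shape}")
    if any(o < 0 for o in overlap):
        raise ValueError(f"overlap must be non-negative, got {overlap}")
    if any(o >= t for o, t in zip(overlap, tile_shape)):
        raise ValueError("overlap must be smaller than the tile shape")

    starts = [list(range(0, v, t)) for v, t in zip(volume_shape, tile_shape)]
    tiles = []
    for x0 in starts[0]:
        for y0 in starts[1]:
            for z0 in starts[2]:
                cmin = (x0, y0, z0)
                cmax = tuple(
                    min(c + t, v) for c, t, v in zip(cmin, tile_shape, volume_shape)
                )
                pmin = tuple(max(c - o, 0) for c, o in zip(cmin, overlap))
                pmax = tuple(
                    min(c + o, v) for c, o, v in zip(cmax, overlap, volume_shape)
                )
                tiles.append(((cmin, cmax), (pmin, pmax)))
    return TileGrid(volume_shape, tile_shape, overlap, tiles)


# ---------------------------------------------------------------------------
# volume reading / writing
# ---------------------------------------------------------------------------


def _check_bbox(bbox, extent):
    bmin, bmax = bbox
    for lo, hi, n in zip(bmin, bmax, extent):
        if lo < 0 or hi > n or lo >= hi:
            raise BoundingBoxError(
                f"bounding box {bbox} out of range for extent {extent}"
            )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_volume(path, dataset_name="raw", bounding_box=None, *, segmentation=False):
    """Read a (sub)volume from an HDF5 dataset or a multi-page TIFF stack.

    ``bounding_box`` is ``((xmin, ymin, zmin), (xmax, ymax, zmax))``,
    half-open, in the file's global voxel coordinates; ``None`` reads the full
    extent.  Returns a :class:`VoxelVolume` (or :class:`SegmentationVolume`
    when ``segmentation`` is true) with ``origin_voxel`` set to the box
    minimum.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(str(path))
    voxel_size = None
    if path.suffix in (".h5", ".hdf5", ".hdf"):
        with h5py.File(path, "r") as f:
            if dataset_name not in f:
                raise FormatError(f"dataset {dataset_name!r} not in {path}")
            dset = f[dataset_name]
            if dset.ndim != 3:
                raise FormatError(f"dataset {dataset_name!r} is not 3D")
            # stored z-major (z, y, x); in-memory contract is (x, y, z)
            extent = dset.shape[::-1]
            if bounding_box is None:
                bounding_box = ((0, 0, 0), extent)
            _check_bbox(bounding_box, extent)
            (x0, y0, z0), (x1, y1, z1) = bounding_box
            data = np.asarray(dset[z0:z1, y0:y1, x0:x1]).transpose(2, 1, 0)
            if "voxel_size_nm" in dset.attrs:
                voxel_size = tuple(float(v) for v in dset.attrs["voxel_size_nm"])
    elif path.suffix in (".tif", ".tiff"):
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        extent = stack.shape[::-1]
        if bounding_box is None:
            bounding_box = ((0, 0, 0), extent)
        _check_bbox(bounding_box, extent)
        (x0, y0, z0), (x1, y1, z1) = bounding_box
        data = stack[z0:z1, y0:y1, x0:x1].transpose(2, 1, 0)
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            if "voxel_size_nm" in meta:
                voxel_size = tuple(float(v) for v in meta["voxel_size_nm"])
    else:
        raise FormatError(f"unsupported volume format: {path.suffix!r}")

    if voxel_size is None:
        voxel_size = DEFAULT_VOXEL_SIZE_NM
        logger.warning(
            "no voxel size metadata for %s; assuming %s nm", path, voxel_size
        )
    origin = tuple(int(v) for v in bounding_box[0])
    cls = SegmentationVolume if segmentation else VoxelVolume
    kwargs = {"voxel_size_nm": voxel_size, "origin_voxel": origin}
    return cls(data, **kwargs)


def write_volume(path, volume, dataset_name="raw"):
    """Write a volume to HDF5 or TIFF, storing voxel-size metadata."""
    path = Path(path)
    data = volume.labels if isinstance(volume, SegmentationVolume) else volume.data
    zyx = np.ascontiguousarray(np.transpose(data, (2, 1, 0)))
    if path.suffix in (".h5", ".hdf5", ".hdf"):
        with h5py.File(path, "a") as f:
            if dataset_name in f:
                del f[dataset_name]
            dset = f.create_dataset(dataset_name, data=zyx)
            dset.attrs["voxel_size_nm"] = list(volume.voxel_size_nm)
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, zyx)
        _sidecar_path(path).write_text(
            json.dumps({"voxel_size_nm": list(volume.voxel_size_nm)})
        )
    else:
        raise FormatError(f"unsupported volume format: {path.suffix!r}")


# ---------------------------------------------------------------------------
# tables and model files
# ---------------------------------------------------------------------------


def write_table(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise MissingFileError(str(path))
    return pd.read_csv(path)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def read_json(path):
    path = Path(path)
    if not path.exists():
        raise MissingFileError(str(path))
    return json.loads(path.read_text())
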