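"""Neurite interface extraction and perisynaptic subvolume definition.

An *interface* is a 26-connected component of the one-voxel segmentation
boundary (label 0) whose voxels see a given pair of segments in their
26-neighborhood.  Interfaces are the unit of synapse classification.  Around
each interface, six shell subvolumes are defined: the voxels of each adjacent
segment within 40, 80 and 160 nm (anisotropic Euclidean distance between
voxel centers) of any border voxel.  Together with the border itself this
yields 7 aggregation regions per interface.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_io import SegmentationVolume

logger = logging.getLogger("emsynapse")

#: all 26 neighbor offsets in 3D
NEIGHBOR_OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]

#: canonical subvolume order used everywhere downstream
SUBVOLUME_ORDER = [
    ("border", None),
    ("S1", 40.0),
    ("S2", 40.0),
    ("S1", 80.0),
    ("S2", 80.0),
    ("S1", 160.0),
    ("S2", 160.0),
]


@dataclass
class ExtractionConfig:
    """Parameters of interface extraction.

    ``min_border_voxels`` is the smallest component size kept; the production
    default of 151 discards components of 150 voxels or less.
    """

    min_border_voxels: int = 151
    distances_nm: tuple[float, ...] = (40.0, 80.0, 160.0)

    def __post_init__(self) -> None:
        d = self.distances_nm
        if any(x <= 0 for x in d) or any(a >= b for a, b in zip(d, d[1:])):
            raise ValueError("distances must be strictly increasing and positive")


@dataclass
class Interface:
    """A directed-classifiable contact between two segments.

    ``segments`` is stored canonically with ``id1 < id2``; direction is only
    introduced at feature-vector assembly.
    """

    id: int
    segments: tuple[int, int]
    border_voxels: np.ndarray  # (n, 3) int voxel coordinates
    centroid_nm: tuple[float, float, float]

    @property
    def n_border_voxels(self) -> int:
        return len(self.border_voxels)


@dataclass
class SubvolumeSet:
    """Border voxels plus the six distance shells of an interface."""

    border: np.ndarray
    shells: dict = field(default_factory=dict)  # (role, distance_nm) -> (n, 3) array

    def in_canonical_order(self):
        """Yield the 7 voxel sets in the canonical order."""
        for role, dist in SUBVOLUME_ORDER:
            if role == "border":
                yield self.border
            else:
                yield self.shells[(role, dist)]


def _neighbor_label_pairs(labels: np.ndarray, boundary_idx: np.ndarray) -> np.ndarray:
    """For each boundary voxel, the positive labels in its 26-neighborhood.

    Returns an (n, 26) array with 0 where the neighbor is outside the volume
    or itself boundary.
    """
    shape = labels.shape
    n = len(boundary_idx)
    out = np.zeros((n, len(NEIGHBOR_OFFSETS_26)), dtype=labels.dtype)
    for k, (dx, dy, dz) in enumerate(NEIGHBOR_OFFSETS_26):
        nb = boundary_idx + np.array([dx, dy, dz])
        valid = np.all((nb >= 0) & (nb < np.array(shape)), axis=1)
        v = nb[valid]
        out[valid, k] = labels[v[:, 0], v[:, 1], v[:, 2]]
    return out


def extract_interfaces(seg: SegmentationVolume, config: ExtractionConfig | None = None):
    """Extract all neurite-neurite interfaces from a segmentation.

    Boundary voxels (label 0) whose 26-neighborhood contains both labels of a
    segment pair are collected per unordered pair; 26-connected components of
    each pair's voxel set become separate interfaces; components smaller than
    ``config.min_border_voxels`` are discarded.
    """
    if config is None:
        config = ExtractionConfig()
    labels = seg.labels
    boundary_idx = np.argwhere(labels == 0)
    if len(boundary_idx) == 0:
        logger.warning("segmentation has no boundary (0) voxels; no interfaces")
        return []

    nb_labels = _neighbor_label_pairs(labels, boundary_idx)

    # per-voxel sets of distinct positive neighbor labels -> pair membership
    pair_voxels: dict[tuple[int, int], list[int]] = {}
    for i in range(len(boundary_idx)):
        uniq = np.unique(nb_labels[i])
        uniq = uniq[uniq > 0]
        if len(uniq) < 2:
            continue
        for a, b in itertools.combinations(uniq.tolist(), 2):
            pair_voxels.setdefault((int(a), int(b)), []).append(i)

    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    interfaces: list[Interface] = []
    vs = np.asarray(seg.voxel_size_nm, dtype=float)
    origin = np.asarray(seg.origin_voxel, dtype=float)
    next_id = 0
    for pair in sorted(pair_voxels):
        vox = boundary_idx[pair_voxels[pair]]
        lo = vox.min(axis=0)
        hi = vox.max(axis=0) + 1
        mask = np.zeros(tuple(hi - lo), dtype=bool)
        local = vox - lo
        mask[local[:, 0], local[:, 1], local[:, 2]] = True
        comp, n_comp = ndimage.label(mask, structure=structure)
        comp_of_voxel = comp[local[:, 0], local[:, 1], local[:, 2]]
        for c in range(1, n_comp + 1):
            member = vox[comp_of_voxel == c]
            if len(member) < config.min_border_voxels:
                continue
            centroid = (member.astype(float) + origin).mean(axis=0) * vs
            interfaces.append(
                Interface(
                    id=next_id,
                    segments=pair,
                    border_voxels=member,
                    centroid_nm=tuple(centroid),
                )
            )
            next_id += 1
    return interfaces


def compute_subvolumes(
    iface: Interface,
    seg: SegmentationVolume,
    voxel_size_nm=None,
    config: ExtractionConfig | None = None,
) -> SubvolumeSet:
    """Compute the 6 distance-shell subvolumes of an interface.

    ``shell(S, d)`` contains every voxel with label ``S`` whose center lies
    within Euclidean distance ``d`` (in nm, anisotropic) of some border voxel
    center.  Implemented with an anisotropic distance transform seeded at the
    border voxels, restricted to a local bounding box that covers the maximal
    shell distance.
    """
    if config is None:
        config = ExtractionConfig()
    if voxel_size_nm is None:
        voxel_size_nm = seg.voxel_size_nm
    vs = np.asarray(voxel_size_nm, dtype=float)
    labels = seg.labels
    shape = np.array(labels.shape)
    dmax = max(config.distances_nm)
    reach = np.ceil(dmax / vs).astype(int) + 1

    vox = iface.border_voxels
    lo = np.maximum(vox.min(axis=0) - reach, 0)
    hi = np.minimum(vox.max(axis=0) + 1 + reach, shape)
    sub = labels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    seed = np.ones(sub.shape, dtype=bool)
    local = vox - lo
    seed[local[:, 0], local[:, 1], local[:, 2]] = False
    dist = ndimage.distance_transform_edt(seed, sampling=vs)

    id1, id2 = iface.segments
    shells = {}
    for role, seg_id in (("S1", id1), ("S2", id2)):
        role_mask = sub == seg_id
        for d in config.distances_nm:
            sel = np.argwhere(role_mask & (dist <= d + 1e-9))
            shells[(role, float(d))] = sel + lo
    return SubvolumeSet(border=vox, shells=shells)


def interface_table(interfaces) -> pd.DataFrame:
    """Tabulate interfaces (id, segment pair, size, centroid in nm)."""
    rows = [
        {
            "id": i.id,
            "id1": i.segments[0],
            "id2": i.segments[1],
            "n_border_voxels": i.n_border_voxels,
            "centroid_x_nm": i.centroid_nm[0],
            "centroid_y_nm": i.centroid_nm[1],
            "centroid_z_nm": i.centroid_nm[2],
        }
        for i in interfaces
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "id",
            "id1",
            "id2",
            "n_border_voxels",
            "centroid_x_nm",
            "centroid_y_nm",
            "centroid_z_nm",
        ],
    )
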