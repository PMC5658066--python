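"""Seeded synthetic neuropil scenes with planted synapses and ground truth.

The generator emulates the image statistics the detector exploits, not
photorealism: space is partitioned into convex-ish processes (Voronoi cells
of seeded points under the anisotropic physical metric) separated by a
one-voxel dark boundary; at planted synaptic contacts the border band is
darkened (postsynaptic density), the presynaptic side within 160 nm
receives a high-variance dark speckle (vesicle cloud), and the postsynaptic
side is filled bright and smooth (spine lumen).  Elsewhere membranes are
plain.  Gaussian pixel noise is added and intensities clipped to [0, 255].

Everything is drawn from one seeded generator, so scenes are byte-identical
across runs for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .interfaces import ExtractionConfig, compute_subvolumes, extract_interfaces
from .volume_io import DEFAULT_VOXEL_SIZE_NM, SegmentationVolume, VoxelVolume


class SceneGenerationError(Exception):
    """The requested synapse density cannot be realized in the scene."""


@dataclass
class SceneConfig:
    """Study conditions of a synthetic scene.

    Defaults mirror cortical neuropil as seen by serial block-face EM:
    11.24 x 11.24 x 28 nm voxels and about one synapse per cubic micron.
    Intensity levels are 8-bit grayscale with membranes dark and cytosol
    mid-gray.
    """

    volume_shape: tuple[int, int, int] = (128, 128, 64)
    voxel_size_nm: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_NM
    n_processes: int = 15
    synapse_density: float = 1.0  # planted synapses per um^3
    vesicle_speckle: tuple[float, int] = (70.0, 2)  # (amplitude, grain voxels)
    psd_contrast: float = 40.0
    spine_lumen_level: float = 200.0
    membrane_dark_level: float = 60.0
    cytosol_level: float = 150.0
    noise_sd: float = 6.0
    plant_margin_nm: float = 250.0
    seed: int = 0
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)

    def __post_init__(self) -> None:
        if self.synapse_density < 0:
            raise ValueError("synapse density must be non-negative")
        for level in (self.spine_lumen_level, self.membrane_dark_level,
                      self.cytosol_level):
            if not 0 <= level <= 255:
                raise ValueError("intensity levels must lie in [0, 255]")

    @property
    def volume_um3(self) -> float:
        return float(np.prod(self.volume_shape)
                     * np.prod(self.voxel_size_nm) * 1e-9)


@dataclass
class PlantedSynapse:
    """Ground truth for one planted synaptic contact."""

    pre_segment: int
    post_segment: int
    border_voxels: np.ndarray
    interface_index: int


@dataclass
class GroundTruth:
    synapses: list[PlantedSynapse] = field(default_factory=list)


def _voronoi_segmentation(config: SceneConfig, rng) -> np.ndarray:
    """Partition the volume into nearest-seed cells (anisotropic metric)."""
    shape = config.volume_shape
    vs = np.asarray(config.voxel_size_nm)
    seeds = rng.uniform(0, 1, size=(config.n_processes, 3)) * np.asarray(shape)
    coords = [np.arange(s, dtype=np.float32) * v for s, v in zip(shape, vs)]
    best_d = np.full(shape, np.inf, dtype=np.float32)
    labels = np.zeros(shape, dtype=np.int32)
    for i, seed in enumerate(seeds):
        d = (
            (coords[0][:, None, None] - seed[0] * vs[0]) ** 2
            + (coords[1][None, :, None] - seed[1] * vs[1]) ** 2
            + (coords[2][None, None, :] - seed[2] * vs[2]) ** 2
        )
        closer = d < best_d
        best_d[closer] = d[closer]
        labels[closer] = i + 1
    return labels


def _one_voxel_boundary(labels: np.ndarray) -> np.ndarray:
    """Zero out one voxel layer wherever the label changes across a face.

    Only the voxel on the lower-index side of each face is cleared, so the
    boundary between two cells stays one voxel thin and every boundary voxel
    sees both adjacent labels in its 26-neighborhood.
    """
    seg = labels.copy()
    mask = np.zeros(labels.shape, dtype=bool)
    mask[:-1, :, :] |= labels[:-1, :, :] != labels[1:, :, :]
    mask[:, :-1, :] |= labels[:, :-1, :] != labels[:, 1:, :]
    mask[:, :, :-1] |= labels[:, :, :-1] != labels[:, :, 1:]
    seg[mask] = 0
    return seg


def _speckle_field(shape, grain: int, rng) -> np.ndarray:
    """Blocky binary speckle with the given grain size (voxels)."""
    coarse = tuple(int(np.ceil(s / grain)) for s in shape)
    blocks = rng.uniform(size=coarse) < 0.5
    field = np.kron(blocks, np.ones((grain, grain, grain), dtype=bool))
    return field[: shape[0], : shape[1], : shape[2]]


def _eligible_interfaces(interfaces, config: SceneConfig):
    """Interfaces far enough from the volume faces to plant a synapse on."""
    vs = np.asarray(config.voxel_size_nm)
    hi = (np.asarray(config.volume_shape) - 1) * vs
    margin = config.plant_margin_nm
    out = []
    for idx, iface in enumerate(interfaces):
        c = np.asarray(iface.centroid_nm)
        if np.all(c >= margin) and np.all(c <= hi - margin):
            out.append(idx)
    return out


def generate_scene(config: SceneConfig | None = None):
    """Generate one scene: raw volume, segmentation and ground truth."""
    if config is None:
        config = SceneConfig()
    if config.n_processes < 2:
        raise ValueError("a scene needs at least 2 processes")
    rng = np.random.default_rng(config.seed)

    labels = _voronoi_segmentation(config, rng)
    seg_arr = _one_voxel_boundary(labels)
    seg = SegmentationVolume(seg_arr, voxel_size_nm=config.voxel_size_nm)

    canvas = np.full(config.volume_shape, config.cytosol_level, dtype=np.float64)
    # slight per-process brightness variation so segments are not identical
    for pid in range(1, config.n_processes + 1):
        canvas[seg_arr == pid] += rng.uniform(-8.0, 8.0)
    canvas[seg_arr == 0] = config.membrane_dark_level

    interfaces = extract_interfaces(seg, config.extraction)
    eligible = _eligible_interfaces(interfaces, config)

    # bounded retries: a draw that exceeds the eligible contacts is re-drawn
    # (jittered through the same generator) before giving up
    n_planted = -1
    for _attempt in range(5):
        n_planted = int(rng.poisson(config.synapse_density * config.volume_um3))
        if n_planted <= len(eligible):
            break
    gt = GroundTruth()
    if n_planted > 0:
        if n_planted > len(eligible):
            raise SceneGenerationError(
                f"requested {n_planted} synapses but only {len(eligible)} "
                f"eligible interfaces exist"
            )
        chosen = rng.choice(np.array(eligible), size=n_planted, replace=False)
        amp, grain = config.vesicle_speckle
        speckle = _speckle_field(config.volume_shape, int(grain), rng)
        for idx in sorted(int(i) for i in chosen):
            iface = interfaces[idx]
            subvols = compute_subvolumes(iface, seg, config.voxel_size_nm,
                                         config.extraction)
            pre_role = "S1" if rng.uniform() < 0.5 else "S2"
            post_role = "S2" if pre_role == "S1" else "S1"
            pre_id = iface.segments[0] if pre_role == "S1" else iface.segments[1]
            post_id = iface.segments[1] if pre_role == "S1" else iface.segments[0]

            bv = iface.border_voxels
            canvas[bv[:, 0], bv[:, 1], bv[:, 2]] = max(
                config.membrane_dark_level - config.psd_contrast, 0.0)
            pre_vox = subvols.shells[(pre_role, 160.0)]
            pre_mask = speckle[pre_vox[:, 0], pre_vox[:, 1], pre_vox[:, 2]]
            dark = pre_vox[pre_mask]
            canvas[dark[:, 0], dark[:, 1], dark[:, 2]] = config.cytosol_level - amp
            post_vox = subvols.shells[(post_role, 160.0)]
            canvas[post_vox[:, 0], post_vox[:, 1], post_vox[:, 2]] = (
                config.spine_lumen_level)

            gt.synapses.append(PlantedSynapse(
                pre_segment=pre_id, post_segment=post_id,
                border_voxels=bv, interface_index=idx))

    canvas += rng.normal(0.0, config.noise_sd, size=config.volume_shape)
    raw = VoxelVolume(
        np.clip(np.round(canvas), 0, 255).astype(np.uint8),
        voxel_size_nm=config.voxel_size_nm,
    )
    return raw, seg, gt


def label_table(gt: GroundTruth, interfaces):
    """Raw annotations ``(interface_id, synaptic, direction)`` from ground truth.

    An interface is synaptic (with direction) iff its border voxels overlap a
    planted synapse's voxel set and it joins the synapse's segment pair (the
    second condition keeps interfaces of neighboring segment pairs, which
    share junction voxels with the synaptic border, non-synaptic).  A planted
    synapse matched by no interface indicates a generation bug and fails
    loudly.
    """
    planted = []
    for syn in gt.synapses:
        voxset = set(map(tuple, syn.border_voxels))
        planted.append((syn, voxset))

    matched = [False] * len(planted)
    annotations = []
    for iface in interfaces:
        voxset = set(map(tuple, iface.border_voxels))
        hit = None
        for k, (syn, svox) in enumerate(planted):
            if (set(iface.segments) == {syn.pre_segment, syn.post_segment}
                    and voxset & svox):
                hit = syn
                matched[k] = True
                break
        if hit is None:
            annotations.append((iface.id, False, None))
        else:
            direction = ("S1->S2" if hit.pre_segment == iface.segments[0]
                         else "S2->S1")
            annotations.append((iface.id, True, direction))
    if not all(matched):
        missing = [planted[k][0] for k, m in enumerate(matched) if not m]
        raise SceneGenerationError(
            f"{len(missing)} planted synapses match no extracted interface")
    return annotations
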