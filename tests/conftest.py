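"""Shared fixtures: tiny deterministic volumes and scenes."""

import numpy as np
import pytest

from emsynapse.interfaces import ExtractionConfig
from emsynapse.synthetic import SceneConfig, generate_scene
from emsynapse.volume_io import SegmentationVolume, VoxelVolume


@pytest.fixture
def planar_seg():
    """5x3x3 volume: segment 1 | one-voxel boundary at x=2 | segment 2."""
    labels = np.zeros((5, 3, 3), dtype=np.int32)
    labels[:2] = 1
    labels[3:] = 2
    return SegmentationVolume(labels, voxel_size_nm=(11.24, 11.24, 28.0))


def make_small_scene():
    """A small synthetic scene with at least one planted synapse."""
    cfg = SceneConfig(
        volume_shape=(64, 64, 32),
        n_processes=8,
        synapse_density=3.0,
        seed=5,
        extraction=ExtractionConfig(min_border_voxels=60),
    )
    raw, seg, gt = generate_scene(cfg)
    assert gt.synapses, "fixture scene must contain a planted synapse"
    return cfg, raw, seg, gt


@pytest.fixture
def small_scene():
    return make_small_scene()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_label_volume(rng, shape=(32, 32, 32), n_segments=4):
    """Random smooth-ish label volume with one-voxel boundaries."""
    seeds = rng.uniform(0, 1, size=(n_segments, 3)) * np.asarray(shape)
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    best = np.full(shape, np.inf)
    labels = np.zeros(shape, dtype=np.int32)
    for i, s in enumerate(seeds):
        d = sum((g - c) ** 2 for g, c in zip(grids, s))
        closer = d < best
        best[closer] = d[closer]
        labels[closer] = i + 1
    seg = labels.copy()
    mask = np.zeros(shape, dtype=bool)
    mask[:-1, :, :] |= labels[:-1] != labels[1:]
    mask[:, :-1, :] |= labels[:, :-1] != labels[:, 1:]
    mask[:, :, :-1] |= labels[:, :, :-1] != labels[:, :, 1:]
    seg[mask] = 0
    return seg


@pytest.fixture
def random_volume_16(rng):
    return VoxelVolume(rng.integers(0, 256, size=(16, 16, 16)).astype(np.uint8))
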