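"""Feature aggregation: 9 summary statistics x 7 subvolumes x 51 texture maps
plus 11 shape features, assembled into two directed 3224-entry vectors.

Layout
------
Texture block (3213 entries): index ``(map * 7 + subvolume) * 9 + statistic``
with subvolumes in the canonical order border, S1@40, S2@40, S1@80, S2@80,
S1@160, S2@160 and statistics in the order q0.25, median, q0.75, min, max,
mean, variance, skewness, kurtosis.

Shape block (11 entries, appended): voxel counts (border, S1@160, S2@160),
border sphere-equivalent diameter, the three border principal-axis lengths
(covariance eigenvalues, descending), the absolute scalar product of the
first principal components of the two 160 nm clouds, and convex-hull voxel
counts (border, S1@160, S2@160).

Conventions (fixed so results are bit-stable): quantiles interpolate
linearly between order statistics; variance is unbiased (n-1); skewness and
kurtosis are biased standardized moments with kurtosis non-excess (3 for a
Gaussian); constant samples have skewness = kurtosis = 0; an empty
subvolume contributes zeros for all 9 statistics (flagged in the log).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .interfaces import SUBVOLUME_ORDER, Interface, SubvolumeSet

logger = logging.getLogger("emsynapse")

N_STATS = 9
N_SUBVOLUMES = 7
N_TEXTURE_MAPS = 51
N_TEXTURE_FEATURES = N_TEXTURE_MAPS * N_SUBVOLUMES * N_STATS  # 3213
N_SHAPE_FEATURES = 11
N_FEATURES = N_TEXTURE_FEATURES + N_SHAPE_FEATURES  # 3224

STAT_NAMES = ("q25", "median", "q75", "min", "max", "mean",
              "variance", "skewness", "kurtosis")


@dataclass
class DirectedFeatureVector:
    """One of the two directed feature vectors of an interface."""

    values: np.ndarray
    direction: str  # "S1->S2" or "S2->S1"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} entries, got {self.values.shape}")


def _stats_matrix(vals: np.ndarray) -> np.ndarray:
    """Summary statistics along the last axis of ``vals`` (rows x samples).

    Returns an array of shape ``vals.shape[:-1] + (9,)``.
    """
    vals = np.asarray(vals, dtype=np.float64)
    n = vals.shape[-1]
    out = np.zeros(vals.shape[:-1] + (N_STATS,), dtype=np.float64)
    if n == 0:
        return out

    # quantiles by linear interpolation between order statistics; a single
    # multi-kth partition is O(n) instead of a full sort
    qpos = [q * (n - 1) for q in (0.25, 0.5, 0.75)]
    kth = sorted({0, n - 1} | {int(np.floor(p)) for p in qpos}
                 | {min(int(np.floor(p)) + 1, n - 1) for p in qpos})
    part = np.partition(vals, kth, axis=-1)
    for col, p in enumerate(qpos):
        lo = int(np.floor(p))
        frac = p - lo
        hi = min(lo + 1, n - 1)
        out[..., col] = part[..., lo] * (1.0 - frac) + part[..., hi] * frac
    out[..., 3] = part[..., 0]
    out[..., 4] = part[..., n - 1]

    mean = vals.mean(axis=-1)
    out[..., 5] = mean
    dev = vals - mean[..., None]
    d2 = dev * dev
    m2 = d2.mean(axis=-1)
    if n > 1:
        out[..., 6] = m2 * n / (n - 1)
    nz = m2 > 1e-300
    m3 = (d2 * dev).mean(axis=-1)
    m4 = (d2 * d2).mean(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        safe_m2 = np.where(nz, m2, 1.0)
        out[..., 7] = np.where(nz, m3 / safe_m2**1.5, 0.0)
        out[..., 8] = np.where(nz, m4 / safe_m2**2, 0.0)
    return out


def summary_statistics(samples) -> np.ndarray:
    """The 9 pooling statistics of a scalar sample (see module docstring)."""
    samples = np.asarray(samples, dtype=np.float64).ravel()
    return _stats_matrix(samples[None, :])[0]


def stack_maps(maps) -> np.ndarray:
    """Stack texture maps into a (51, X, Y, Z) array for fast gathering."""
    arrs = maps.maps if hasattr(maps, "maps") else maps
    return np.stack([np.asarray(a) for a in arrs], axis=0)


def texture_features(maps, subvols: SubvolumeSet) -> np.ndarray:
    """Pool every texture map over the 7 subvolumes: 51 x 7 x 9 = 3213 values."""
    stacked = maps if isinstance(maps, np.ndarray) else stack_maps(maps)
    n_maps = stacked.shape[0]
    blocks = np.zeros((n_maps, N_SUBVOLUMES, N_STATS), dtype=np.float64)
    for si, vox in enumerate(subvols.in_canonical_order()):
        if len(vox) == 0:
            logger.debug("empty subvolume %s; statistics set to 0",
                         SUBVOLUME_ORDER[si])
            continue
        vals = stacked[:, vox[:, 0], vox[:, 1], vox[:, 2]]
        blocks[:, si, :] = _stats_matrix(vals)
    return blocks.reshape(-1)


# ---------------------------------------------------------------------------
# shape features
# ---------------------------------------------------------------------------


def _principal_axes(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
    """Covariance eigenvalues (descending) and first principal component."""
    if len(coords) < 2:
        return np.zeros(3), None
    cov = np.cov(coords.astype(np.float64).T, ddof=1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w = w[order]
    v = v[:, order]
    if w[0] <= 1e-300:
        return np.zeros(3), None
    return w, v[:, 0]


def _hull_voxel_count(coords: np.ndarray) -> int:
    """Number of lattice voxels whose centers lie inside the convex hull.

    Degenerate clouds (fewer than 4 points, coplanar or collinear) fall back
    to the number of distinct member voxels, which is the hull content of a
    lower-dimensional point set sampled on the lattice.
    """
    coords = np.unique(coords, axis=0)
    if len(coords) < 4:
        return len(coords)
    try:
        hull = ConvexHull(coords.astype(np.float64))
    except QhullError:
        return len(coords)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    # half-space test x . a + b <= 0, resolved per (x, y) lattice column:
    # convexity makes the feasible z range an interval, so each facet only
    # tightens a lower or upper z bound (or vetoes the whole column)
    normals = hull.equations[:, :3]
    offsets = hull.equations[:, 3]
    tol = 1e-9
    gx, gy = np.meshgrid(np.arange(lo[0], hi[0] + 1),
                         np.arange(lo[1], hi[1] + 1), indexing="ij")
    cols = np.stack([gx.ravel(), gy.ravel()], axis=-1).astype(np.float64)
    rhs = -(cols @ normals[:, :2].T + offsets)  # (n_cols, n_facets)
    az = normals[:, 2]
    z_lo = np.full(len(cols), float(lo[2]))
    z_hi = np.full(len(cols), float(hi[2]))
    pos = az > tol
    neg = az < -tol
    flat = ~pos & ~neg
    if pos.any():
        z_hi = np.minimum(z_hi, np.min((rhs[:, pos] + tol) / az[pos], axis=1))
    if neg.any():
        z_lo = np.maximum(z_lo, np.max((rhs[:, neg] + tol) / az[neg], axis=1))
    feasible = np.ones(len(cols), dtype=bool)
    if flat.any():
        feasible &= np.all(rhs[:, flat] >= -tol, axis=1)
    count = np.floor(z_hi) - np.ceil(z_lo) + 1.0
    count = np.where(feasible, np.maximum(count, 0.0), 0.0)
    return int(count.sum())


def shape_features(iface: Interface, subvols: SubvolumeSet, voxel_size_nm) -> np.ndarray:
    """The 11 shape features of an interface (see module docstring for order)."""
    vs = np.asarray(voxel_size_nm, dtype=np.float64)
    border = subvols.border
    s1_160 = subvols.shells[("S1", 160.0)]
    s2_160 = subvols.shells[("S2", 160.0)]

    n_border = len(border)
    n_s1 = len(s1_160)
    n_s2 = len(s2_160)

    # sphere-equivalent diameter from the voxel count (voxel-based units)
    diameter = 2.0 * (3.0 * n_border / (4.0 * np.pi)) ** (1.0 / 3.0) if n_border else 0.0

    axes_border, _ = _principal_axes(border * vs)
    _, pc1 = _principal_axes(s1_160 * vs)
    _, pc2 = _principal_axes(s2_160 * vs)
    # absolute value makes the product invariant to the eigenvector sign choice
    axis_product = float(abs(np.dot(pc1, pc2))) if pc1 is not None and pc2 is not None else 0.0

    return np.array(
        [
            n_border,
            n_s1,
            n_s2,
            diameter,
            axes_border[0],
            axes_border[1],
            axes_border[2],
            axis_product,
            _hull_voxel_count(border),
            _hull_voxel_count(s1_160),
            _hull_voxel_count(s2_160),
        ],
        dtype=np.float64,
    )


# ---------------------------------------------------------------------------
# directed assembly
# ---------------------------------------------------------------------------

#: subvolume swap for direction reversal: border fixed, S1<->S2 per distance
_SUBVOL_SWAP = np.array([0, 2, 1, 4, 3, 6, 5])
#: shape-entry swap: voxel counts and hull counts of the two 160 nm clouds
_SHAPE_SWAP = np.array([0, 2, 1, 3, 4, 5, 6, 7, 8, 10, 9])


def swap_direction_permutation() -> np.ndarray:
    """The fixed permutation of all 3224 indices that reverses direction."""
    perm = np.empty(N_FEATURES, dtype=np.int64)
    tex = (
        np.arange(N_TEXTURE_MAPS)[:, None, None] * (N_SUBVOLUMES * N_STATS)
        + _SUBVOL_SWAP[None, :, None] * N_STATS
        + np.arange(N_STATS)[None, None, :]
    )
    perm[:N_TEXTURE_FEATURES] = tex.reshape(-1)
    perm[N_TEXTURE_FEATURES:] = N_TEXTURE_FEATURES + _SHAPE_SWAP
    return perm


_PERM = swap_direction_permutation()


def assemble_directed_vectors(texture: np.ndarray, shape: np.ndarray):
    """Assemble the forward (S1 presynaptic) and reverse directed vectors."""
    texture = np.asarray(texture, dtype=np.float64)
    shape = np.asarray(shape, dtype=np.float64)
    if texture.shape != (N_TEXTURE_FEATURES,):
        raise ValueError(f"expected {N_TEXTURE_FEATURES} texture values")
    if shape.shape != (N_SHAPE_FEATURES,):
        raise ValueError(f"expected {N_SHAPE_FEATURES} shape values")
    forward = np.concatenate([texture, shape])
    reverse = forward[_PERM]
    return (
        DirectedFeatureVector(forward, "S1->S2"),
        DirectedFeatureVector(reverse, "S2->S1"),
    )


def interface_feature_vectors(stacked_maps, iface, subvols, voxel_size_nm):
    """Convenience: texture + shape features to two directed vectors."""
    tex = texture_features(stacked_maps, subvols)
    shp = shape_features(iface, subvols, voxel_size_nm)
    return assemble_directed_vectors(tex, shp)


def save_feature_matrix(path, interface_ids, X_fwd, X_rev) -> None:
    """Persist directed feature matrices as HDF5 with a JSON layout manifest.

    Datasets: ``ids`` (n,), ``features`` (n, 2, 3224) with axis 1 indexing
    the direction (0 = S1->S2, 1 = S2->S1); attribute ``layout`` holds the
    index -> (map, subvolume, statistic) manifest.
    """
    import json

    import h5py

    X_fwd = np.asarray(X_fwd, dtype=np.float64)
    X_rev = np.asarray(X_rev, dtype=np.float64)
    stacked = np.stack([X_fwd, X_rev], axis=1)
    with h5py.File(path, "w") as f:
        f.create_dataset("ids", data=np.asarray(interface_ids, dtype=np.int64))
        dset = f.create_dataset("features", data=stacked)
        dset.attrs["layout"] = json.dumps(feature_layout())


def load_feature_matrix(path):
    """Read back ``(ids, X_fwd, X_rev, layout)`` written by
    :func:`save_feature_matrix`."""
    import json

    import h5py

    with h5py.File(path, "r") as f:
        ids = np.asarray(f["ids"])
        stacked = np.asarray(f["features"])
        layout = json.loads(f["features"].attrs["layout"])
    return ids, stacked[:, 0, :], stacked[:, 1, :], layout


def feature_layout() -> list[dict]:
    """Index -> (map, subvolume, statistic) manifest for all 3224 entries."""
    layout = []
    for m in range(N_TEXTURE_MAPS):
        for (role, dist) in SUBVOLUME_ORDER:
            for stat in STAT_NAMES:
                layout.append(
                    {"block": "texture", "map": m, "subvolume": role,
                     "distance_nm": dist, "statistic": stat}
                )
    shape_names = [
        "n_voxels_border", "n_voxels_s1_160", "n_voxels_s2_160",
        "diameter_border", "principal_axis_1", "principal_axis_2",
        "principal_axis_3", "principal_axis_product",
        "hull_border", "hull_s1_160", "hull_s2_160",
    ]
    layout.extend({"block": "shape", "name": n} for n in shape_names)
    return layout
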