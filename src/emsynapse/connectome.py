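"""Connectome construction and the pairwise connectivity error model.

From detected synaptic interfaces this module builds

* the **contactome** — total contact area between every pair of pre- and
  postsynaptic processes, synaptic or not;
* the **weighted connectome** — synapse counts per process pair, after
  single-linkage clustering of interface centroids (default cutoff 1500 nm;
  320.12 nm is the default when counting synapses volume-wide), so that
  large synapses split over several interfaces are counted once;
* the **binary connectome** — thresholded at gamma_nn synapses per pair
  (1 for excitatory, 2 for inhibitory presynaptic processes).

The analytic error model propagates single-synapse recall R_s and precision
P_s into neuron-to-neuron recall R_nn and precision P_nn:

    R_nn = sum_n P(Bin(n, R_s) >= gamma_nn) p(n)

with p(n) the distribution of synapses per connected pair (a point mass at
n = 6 for inhibitory connections; an empirical table with mean 4.3 for
excitatory ones), and

    P_nn = c_r R_nn / (c_r R_nn + (1 - c_r) P(Poi(lambda) >= gamma_nn)),
    lambda = (1 - P_s)/P_s * R_s * c_r * <n_syn>,

where c_r is the pairwise connectivity rate (0.2 excitatory, 0.6
inhibitory) and lambda the per-entry rate of false-positive synapses
scattered uniformly over the N^2 connectome entries.  The neuron count N
cancels, so P_nn is independent of connectome size.  Binomial and Poisson
tails are evaluated exactly (scipy survival functions), never by normal
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import binom, poisson

#: single-linkage cutoff for per-pair synapse merging in connectomes (nm)
CONNECTOME_CLUSTER_CUTOFF_NM = 1500.0
#: cutoff for volume-wide synapse counting (nm)
DENSITY_CLUSTER_CUTOFF_NM = 320.12

#: pairwise connectivity rates in cortex
CONNECTIVITY_RATE = {"exc": 0.2, "inh": 0.6}
#: mean synapses per connected pair
MEAN_SYNAPSES_PER_CONNECTION = {"exc": 4.3, "inh": 6.0}


@dataclass
class SynapseRecord:
    """One clustered synapse: its member interfaces and summed area."""

    pre: int
    post: int
    interface_ids: tuple
    centroid_nm: tuple
    area_um2: float


@dataclass
class WeightedConnectome:
    """Synapse counts per (pre, post) process pair with per-synapse records."""

    counts: dict = field(default_factory=dict)  # (pre, post) -> int
    synapses: list[SynapseRecord] = field(default_factory=list)

    def to_matrix(self, pre_ids=None, post_ids=None):
        if pre_ids is None:
            pre_ids = sorted({p for p, _ in self.counts})
        if post_ids is None:
            post_ids = sorted({q for _, q in self.counts})
        mat = np.zeros((len(pre_ids), len(post_ids)), dtype=np.int64)
        pre_index = {p: i for i, p in enumerate(pre_ids)}
        post_index = {q: j for j, q in enumerate(post_ids)}
        for (p, q), c in self.counts.items():
            mat[pre_index[p], post_index[q]] = c
        return mat, list(pre_ids), list(post_ids)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "pre": s.pre,
                "post": s.post,
                "n_interfaces": len(s.interface_ids),
                "centroid_x_nm": s.centroid_nm[0],
                "centroid_y_nm": s.centroid_nm[1],
                "centroid_z_nm": s.centroid_nm[2],
                "area_um2": s.area_um2,
            }
            for s in self.synapses
        ]
        return pd.DataFrame(
            rows, columns=["pre", "post", "n_interfaces", "centroid_x_nm",
                           "centroid_y_nm", "centroid_z_nm", "area_um2"])


# ---------------------------------------------------------------------------
# interface areas, contactome, ASI
# ---------------------------------------------------------------------------

_FACE_OFFSETS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def interface_area_um2(iface, seg, voxel_size_nm=None) -> float:
    """Physical area of an interface in square micrometers.

    Counts, over all border voxels, the exposed voxel faces toward each of
    the two adjacent segments, weights each face by its physical area and
    averages the two one-sided surfaces.  For a flat axis-aligned interface
    this reduces to face area x face count.
    """
    if voxel_size_nm is None:
        voxel_size_nm = seg.voxel_size_nm
    vs = np.asarray(voxel_size_nm, dtype=np.float64)
    face_area = {
        0: vs[1] * vs[2],
        1: vs[0] * vs[2],
        2: vs[0] * vs[1],
    }
    labels = seg.labels
    shape = np.array(labels.shape)
    id1, id2 = iface.segments
    total = 0.0
    for axis_offsets in _FACE_OFFSETS:
        axis = int(np.argmax(np.abs(axis_offsets)))
        nb = iface.border_voxels + np.array(axis_offsets)
        valid = np.all((nb >= 0) & (nb < shape), axis=1)
        v = nb[valid]
        lab = labels[v[:, 0], v[:, 1], v[:, 2]]
        total += face_area[axis] * float(np.sum((lab == id1) | (lab == id2)))
    return total / 2.0 * 1e-6  # nm^2 -> um^2


def asi_area(member_areas_um2) -> float:
    """Axon-spine interface area: sum of member interface areas (um^2)."""
    return float(np.sum(np.asarray(member_areas_um2, dtype=np.float64)))


def contactome(interface_pairs, areas_um2, process_of_segment=None):
    """Total contact area per (pre, post) process pair.

    ``interface_pairs``: iterable of (segment/process id1, id2) per
    interface; ``process_of_segment`` optionally maps segment ids to process
    ids — interfaces whose segments map to no process are skipped (counted in
    the returned ``skipped``).
    """
    totals: dict = {}
    skipped = 0
    for (a, b), area in zip(interface_pairs, areas_um2):
        if process_of_segment is not None:
            if a not in process_of_segment or b not in process_of_segment:
                skipped += 1
                continue
            a, b = process_of_segment[a], process_of_segment[b]
        totals[(a, b)] = totals.get((a, b), 0.0) + float(area)
    return totals, skipped


# ---------------------------------------------------------------------------
# synapse clustering
# ---------------------------------------------------------------------------


def _single_linkage_clusters(centroids_nm: np.ndarray, cutoff_nm: float):
    """Cluster ids (0-based) by single linkage with a distance cutoff.

    Equivalent to connected components of the graph joining centroids at
    distance <= cutoff.
    """
    n = len(centroids_nm)
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    Z = linkage(pdist(centroids_nm), method="single")
    return fcluster(Z, t=cutoff_nm, criterion="distance") - 1


def cluster_synapses(detections, cutoff_nm: float = CONNECTOME_CLUSTER_CUTOFF_NM):
    """Merge detected interfaces into synapses per process pair.

    ``detections``: iterable of dicts with keys ``pre``, ``post``,
    ``interface_id``, ``centroid_nm`` and optionally ``area_um2``.
    Interfaces between the same (pre, post) pair are single-linkage
    clustered on their centroids; each cluster becomes one synapse.
    """
    by_pair: dict = {}
    for det in detections:
        by_pair.setdefault((det["pre"], det["post"]), []).append(det)

    cw = WeightedConnectome()
    for (pre, post), members in sorted(by_pair.items()):
        cents = np.array([m["centroid_nm"] for m in members], dtype=np.float64)
        assign = _single_linkage_clusters(cents, cutoff_nm)
        for c in range(assign.max() + 1):
            idx = np.flatnonzero(assign == c)
            ifaces = tuple(sorted(members[i]["interface_id"] for i in idx))
            centroid = tuple(cents[idx].mean(axis=0))
            area = asi_area([members[i].get("area_um2", 0.0) for i in idx])
            cw.synapses.append(
                SynapseRecord(pre, post, ifaces, centroid, area))
            cw.counts[(pre, post)] = cw.counts.get((pre, post), 0) + 1
    return cw


def binarize(counts, gamma_nn):
    """Binary connectome: entry 1 iff synapse count >= gamma_nn.

    ``counts`` may be a matrix or a ``(pre, post) -> count`` mapping;
    ``gamma_nn`` an integer or a ``pre -> gamma`` mapping (per presynaptic
    type: 1 excitatory, 2 inhibitory).
    """
    if isinstance(counts, dict):
        out = {}
        for (p, q), c in counts.items():
            g = gamma_nn[p] if isinstance(gamma_nn, dict) else gamma_nn
            if g < 1:
                raise ValueError("gamma_nn must be >= 1")
            out[(p, q)] = int(c >= g)
        return out
    mat = np.asarray(counts)
    g = np.asarray(gamma_nn)
    if np.any(g < 1):
        raise ValueError("gamma_nn must be >= 1")
    if g.ndim == 1:
        return (mat >= g[:, None]).astype(np.int64)
    return (mat >= g).astype(np.int64)


# ---------------------------------------------------------------------------
# analytic neuron-to-neuron error model
# ---------------------------------------------------------------------------


def point_mass(n: int) -> dict:
    """Degenerate synapses-per-connection distribution (inhibitory default)."""
    return {int(n): 1.0}


def _validate_pn(p_n: dict):
    ns = np.array(sorted(p_n), dtype=np.int64)
    ps = np.array([p_n[int(n)] for n in ns], dtype=np.float64)
    if np.any(ns < 0) or np.any(ps < 0) or not np.isclose(ps.sum(), 1.0):
        raise ValueError("p_n must be a probability distribution over n >= 0")
    return ns, ps


def nn_recall(r_s: float, p_n: dict, gamma_nn: int) -> float:
    """Neuron-to-neuron recall R_nn = sum_n P(Bin(n, R_s) >= gamma) p(n)."""
    if not 0.0 <= r_s <= 1.0:
        raise ValueError("R_s must lie in [0, 1]")
    if gamma_nn < 1:
        raise ValueError("gamma_nn must be >= 1")
    ns, ps = _validate_pn(p_n)
    tail = binom.sf(gamma_nn - 1, ns, r_s)
    return float(np.sum(tail * ps))


def nn_precision(p_s: float, r_s: float, r_nn: float, c_r: float,
                 mean_n_syn: float, gamma_nn: int, n_neurons=None) -> float:
    """Neuron-to-neuron precision from the Poisson false-connection model.

    When ``n_neurons`` is given, the false-positive synapse count is routed
    through the explicit N^2-sized connectome; the result is identical for
    any N (the N^2 factors cancel).
    """
    if p_s <= 0 or p_s > 1:
        raise ValueError("P_s must lie in (0, 1]")
    if not 0 < c_r < 1:
        raise ValueError("c_r must lie in (0, 1)")
    if gamma_nn < 1:
        raise ValueError("gamma_nn must be >= 1")
    if n_neurons is None:
        lam = (1.0 - p_s) / p_s * r_s * c_r * mean_n_syn
    else:
        n_syn_total = float(n_neurons) ** 2 * c_r * mean_n_syn
        fp_s = (1.0 - p_s) / p_s * r_s * n_syn_total
        lam = fp_s / float(n_neurons) ** 2
    fp_tail = poisson.sf(gamma_nn - 1, lam)
    tp_nn = c_r * r_nn
    fp_nn = (1.0 - c_r) * fp_tail
    return float(tp_nn / (tp_nn + fp_nn))


@dataclass
class ConnectivityModel:
    """Bundled error-model inputs for one presynaptic type."""

    p_n: dict
    c_r: float
    mean_n_syn: float

    @classmethod
    def inhibitory(cls) -> "ConnectivityModel":
        return cls(p_n=point_mass(6), c_r=CONNECTIVITY_RATE["inh"],
                   mean_n_syn=MEAN_SYNAPSES_PER_CONNECTION["inh"])

    @classmethod
    def excitatory(cls, p_n: dict) -> "ConnectivityModel":
        """Excitatory model requires an empirical p(n) table (mean ~4.3)."""
        return cls(p_n=p_n, c_r=CONNECTIVITY_RATE["exc"],
                   mean_n_syn=MEAN_SYNAPSES_PER_CONNECTION["exc"])

    def evaluate(self, p_s: float, r_s: float, gamma_nn: int) -> dict:
        r_nn = nn_recall(r_s, self.p_n, gamma_nn)
        p_nn = nn_precision(p_s, r_s, r_nn, self.c_r, self.mean_n_syn, gamma_nn)
        return {"R_nn": r_nn, "P_nn": p_nn}


def round_percent(x: float, decimals: int = 1) -> float:
    """Round a fraction to percent, half away from zero (report convention)."""
    scaled = x * 100.0 * 10**decimals
    return float(np.floor(scaled + 0.5) / 10**decimals)
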