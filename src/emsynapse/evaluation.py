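"""Synapse-level evaluation: overlap matching of detections to ground truth
and precision/recall curves.

Matching rule: a ground-truth synapse counts as detected (TP) if at least
one interface overlapping it was detected; as missed (FN) if none was; a
detected interface overlapping no labeled synapse counts as one FP.  A
detected interface that overlaps a synapse never counts as FP, and multiple
detected interfaces on the same synapse do not inflate the TP count.

Interfaces near the evaluation-volume boundary can be excluded with a
physical margin (default 160 nm) so that every evaluated interface has its
full perisynaptic surround inside the volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GroundTruthSynapse:
    """A labeled synapse and the candidate interfaces overlapping it."""

    id: int
    interface_ids: frozenset
    synapse_class: str = "spine"  # "spine" | "shaft"
    direction: str | None = None

    def __post_init__(self) -> None:
        self.interface_ids = frozenset(int(i) for i in self.interface_ids)
        if not self.interface_ids:
            raise ValueError(f"synapse {self.id} overlaps no interface")


@dataclass
class PRCurve:
    """Precision/recall across thresholds with the raw counts."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    counts: list[tuple[int, int, int]] = field(default_factory=list)  # (TP, FP, FN)

    def to_frame(self) -> pd.DataFrame:
        tp, fp, fn = (np.array([c[i] for c in self.counts]) for i in range(3))
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "precision": self.precision,
                "recall": self.recall,
                "tp": tp,
                "fp": fp,
                "fn": fn,
            }
        )


def match_detections(detections, gt):
    """Count (TP, FN, FP) for a set of detected interface ids.

    ``detections``: iterable of interface ids; ``gt``: list of
    :class:`GroundTruthSynapse`.
    """
    det = {int(d) for d in detections}
    covered = set()
    tp = fn = 0
    for syn in gt:
        if det & syn.interface_ids:
            tp += 1
        else:
            fn += 1
        covered |= syn.interface_ids
    fp = len(det - covered)
    return tp, fn, fp


def precision_recall(tp: int, fn: int, fp: int):
    """P and R for the synaptic class; empty detection sets give P = 1."""
    precision = 1.0 if (tp + fp) == 0 else tp / (tp + fp)
    recall = 0.0 if (tp + fn) == 0 else tp / (tp + fn)
    return precision, recall


def pr_curve(scored_interfaces, gt, thresholds, synapse_class=None) -> PRCurve:
    """Sweep thresholds over max-direction interface scores.

    ``scored_interfaces``: mapping interface id -> score (already the max
    over the two directions).  ``synapse_class`` optionally restricts the
    ground truth to one class ("spine" or "shaft"); detections on synapses of
    the other class are then ignored entirely (neither TP nor FP).
    """
    ids = np.array(sorted(scored_interfaces), dtype=np.int64)
    scores = np.array([scored_interfaces[i] for i in ids], dtype=np.float64)

    if synapse_class is not None:
        keep = [s for s in gt if s.synapse_class == synapse_class]
        drop_ifaces = set().union(
            *(s.interface_ids for s in gt if s.synapse_class != synapse_class)
        ) if len(keep) < len(gt) else set()
        gt = keep
        mask = np.array([i not in drop_ifaces for i in ids])
        ids, scores = ids[mask], scores[mask]

    thresholds = np.asarray(thresholds, dtype=np.float64)
    precisions, recalls, counts = [], [], []
    for th in thresholds:
        det = ids[scores > th]
        tp, fn, fp = match_detections(det, gt)
        p, r = precision_recall(tp, fn, fp)
        precisions.append(p)
        recalls.append(r)
        counts.append((tp, fp, fn))
    return PRCurve(
        thresholds=thresholds,
        precision=np.array(precisions),
        recall=np.array(recalls),
        counts=counts,
    )


def exclude_border_interfaces(interfaces, volume_shape, voxel_size_nm,
                              margin_nm: float = 160.0):
    """Drop interfaces whose centroid is within ``margin_nm`` of the volume face.

    Mirrors the test-volume convention that evaluated interfaces must be
    fully contained, so their subvolumes are not clipped.
    """
    vs = np.asarray(voxel_size_nm, dtype=np.float64)
    hi = (np.asarray(volume_shape) - 1) * vs
    kept = []
    for iface in interfaces:
        c = np.asarray(iface.centroid_nm)
        if np.all(c >= margin_nm) and np.all(c <= hi - margin_nm):
            kept.append(iface)
    return kept
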