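"""Cost-weighted boosted decision stumps for directed interface classification.

The default learner is binary LogitBoost (Friedman, Hastie & Tibshirani 2000)
with depth-1 regression stumps: at every round, Newton working responses
``z = (y - p) / (p (1 - p))`` are fitted by the weighted least-squares stump
over all features, the additive score is updated with a learning rate, and
class probabilities are refreshed.  Numerical guards: working responses are
clamped at +-4 and probabilities at 1e-10.  The misclassification cost of the
synaptic class (default 100) is realized as a multiplicative prior weight on
synaptic observations, renormalized to sum 1.  The whole path is
deterministic: no subsampling is used.

An AdaBoost.M1 variant with classification stumps is retained as an option
(it was the historically first choice for this detector and is useful for
ablation), but LogitBoost is the default.

Each interface is scored in both pre-to-post directions; the larger of the
two scores decides synaptic/non-synaptic and the argmax decides direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import N_FEATURES

P_CLAMP = 1e-10
Z_CLAMP = 4.0
W_FLOOR = 1e-12


@dataclass
class ClassifierThresholds:
    """Score thresholds optimized for single-synapse vs connectome recovery."""

    theta_s_exc: float = -1.67
    theta_nn_exc: float = -0.08
    theta_s_inh: float = -2.06
    theta_nn_inh: float = -1.58


@dataclass
class TrainParams:
    n_learners: int = 1500
    learning_rate: float = 0.1
    cost_synaptic: float = 100.0
    algorithm: str = "logitboost"  # or "adaboostm1"
    seed: int = 0


@dataclass
class Stump:
    feature: int
    threshold: float
    left: float   # response when x[feature] <= threshold
    right: float

    def respond(self, X: np.ndarray) -> np.ndarray:
        return np.where(X[:, self.feature] <= self.threshold, self.left, self.right)


@dataclass
class StumpEnsemble:
    stumps: list[Stump] = field(default_factory=list)
    learning_rate: float = 0.1
    n_features: int = N_FEATURES
    gains: np.ndarray | None = None  # accumulated split gain per feature
    meta: dict = field(default_factory=dict)

    def score(self, X: np.ndarray) -> np.ndarray:
        """Additive stump score; higher = more synaptic."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature length {X.shape[1]} does not match model "
                f"({self.n_features})"
            )
        out = np.zeros(len(X))
        for st in self.stumps:
            out += self.learning_rate * st.respond(X)
        return out

    def to_json(self) -> dict:
        return {
            "learning_rate": self.learning_rate,
            "n_features": self.n_features,
            "stumps": [[s.feature, s.threshold, s.left, s.right]
                       for s in self.stumps],
            "gains": None if self.gains is None else self.gains.tolist(),
            "meta": self.meta,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "StumpEnsemble":
        ens = cls(
            stumps=[Stump(int(f), float(t), float(a), float(b))
                    for f, t, a, b in obj["stumps"]],
            learning_rate=float(obj["learning_rate"]),
            n_features=int(obj["n_features"]),
            meta=dict(obj.get("meta", {})),
        )
        if obj.get("gains") is not None:
            ens.gains = np.asarray(obj["gains"], dtype=np.float64)
        return ens


# ---------------------------------------------------------------------------
# label-set variants
# ---------------------------------------------------------------------------


@dataclass
class LabelSet:
    """Directed or undirected training labels.

    ``entries`` holds ``(interface_id, direction, synaptic)`` with direction
    ``"S1->S2"``, ``"S2->S1"`` or ``None`` (undirected variant).
    """

    entries: list[tuple]
    variant: str


def build_label_variant(raw_annotations, variant: str) -> LabelSet:
    """Expand annotator labels into the undirected/augmented/directed variant.

    ``raw_annotations``: iterable of ``(interface_id, synaptic, direction)``
    where ``direction`` is the true pre-to-post direction of a synapse
    (required for the directed variant).
    """
    if variant not in ("undirected", "augmented", "directed"):
        raise ValueError(f"unknown label variant {variant!r}")
    entries = []
    for iface_id, synaptic, direction in raw_annotations:
        if variant == "undirected":
            entries.append((iface_id, None, bool(synaptic)))
            continue
        if variant == "directed" and synaptic and direction not in ("S1->S2", "S2->S1"):
            raise ValueError(
                f"synaptic annotation for interface {iface_id} lacks a direction"
            )
        for d in ("S1->S2", "S2->S1"):
            if not synaptic:
                entries.append((iface_id, d, False))
            elif variant == "augmented":
                entries.append((iface_id, d, True))
            else:  # directed
                entries.append((iface_id, d, d == direction))
    return LabelSet(entries=entries, variant=variant)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _best_stump(Xs, order, can_split, w, z):
    """Weighted least-squares stump over all features.

    ``Xs``: per-column sorted feature values; ``order``: argsort indices;
    ``can_split``: where adjacent sorted values differ.  Returns
    (feature, threshold, left, right, gain) with gain the SSE reduction
    relative to the best constant fit.
    """
    wz = w * z
    W = np.take(w, order)
    WZ = np.take(wz, order)
    cum_w = np.cumsum(W, axis=0)[:-1]
    cum_wz = np.cumsum(WZ, axis=0)[:-1]
    tot_w = w.sum()
    tot_wz = wz.sum()
    right_w = np.maximum(tot_w - cum_w, W_FLOOR)
    left_w = np.maximum(cum_w, W_FLOOR)
    crit = cum_wz**2 / left_w + (tot_wz - cum_wz) ** 2 / right_w
    crit = np.where(can_split, crit, -np.inf)
    flat = int(np.argmax(crit))
    pos, feat = np.unravel_index(flat, crit.shape)
    base = tot_wz**2 / max(tot_w, W_FLOOR)
    gain = float(crit[pos, feat] - base)
    threshold = 0.5 * (Xs[pos, feat] + Xs[pos + 1, feat])
    left = float(cum_wz[pos, feat] / left_w[pos, feat])
    right = float((tot_wz - cum_wz[pos, feat]) / right_w[pos, feat])
    return int(feat), float(threshold), left, right, gain


def _presort(X):
    order = np.argsort(X, axis=0, kind="stable")
    Xs = np.take_along_axis(X, order, axis=0)
    can_split = Xs[1:] > Xs[:-1]
    return Xs, order, can_split


def train(X, y, params: TrainParams | None = None) -> StumpEnsemble:
    """Train the boosted stump ensemble on directed feature vectors.

    ``y`` is boolean (synaptic class = True).  Deterministic for fixed
    inputs and parameters.
    """
    if params is None:
        params = TrainParams()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=bool)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be (n, features) matching y")
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    if y.all() or (~y).all():
        raise ValueError("training requires both classes")

    n, n_feat = X.shape
    Xs, order, can_split = _presort(X)

    prior = np.where(y, params.cost_synaptic, 1.0)
    prior = prior / prior.sum()

    ens = StumpEnsemble(
        learning_rate=params.learning_rate,
        n_features=n_feat,
        gains=np.zeros(n_feat),
        meta={"algorithm": params.algorithm, "seed": params.seed,
              "cost_synaptic": params.cost_synaptic,
              "n_learners": params.n_learners},
    )

    if params.algorithm == "logitboost":
        _train_logitboost(ens, X, Xs, order, can_split, y, prior, params)
    elif params.algorithm == "adaboostm1":
        _train_adaboostm1(ens, X, Xs, order, can_split, y, prior, params)
    else:
        raise ValueError(f"unknown algorithm {params.algorithm!r}")
    return ens


def _train_logitboost(ens, X, Xs, order, can_split, y, prior, params):
    n = len(y)
    ybin = y.astype(np.float64)
    F = np.zeros(n)
    for _ in range(params.n_learners):
        p = 1.0 / (1.0 + np.exp(-2.0 * F))
        p = np.clip(p, P_CLAMP, 1.0 - P_CLAMP)
        pq = p * (1.0 - p)
        w = prior * pq
        w = np.maximum(w, W_FLOOR)
        z = np.clip((ybin - p) / pq, -Z_CLAMP, Z_CLAMP)
        feat, thr, left, right, gain = _best_stump(Xs, order, can_split, w, z)
        # Newton half-step folded into the stored responses
        left = float(np.clip(0.5 * left, -Z_CLAMP, Z_CLAMP))
        right = float(np.clip(0.5 * right, -Z_CLAMP, Z_CLAMP))
        st = Stump(feat, thr, left, right)
        ens.stumps.append(st)
        ens.gains[feat] += max(gain, 0.0)
        F += params.learning_rate * st.respond(X)


def _train_adaboostm1(ens, X, Xs, order, can_split, y, prior, params):
    """AdaBoost.M1 with classification stumps (responses are +-alpha)."""
    n = len(y)
    w = prior.copy()
    ysign = np.where(y, 1.0, -1.0)
    for _ in range(params.n_learners):
        w = w / w.sum()
        # fit LS stump to the signed labels: equivalent to minimizing
        # weighted misclassification over threshold/polarity
        feat, thr, left, right, gain = _best_stump(Xs, order, can_split, w, ysign)
        pred = np.where(X[:, feat] <= thr, np.sign(left) or 1.0, np.sign(right) or 1.0)
        err = float(np.sum(w * (pred != ysign)))
        err = min(max(err, 1e-10), 1 - 1e-10)
        alpha = 0.5 * np.log((1 - err) / err)
        st = Stump(feat, thr, float(alpha * (np.sign(left) or 1.0)),
                   float(alpha * (np.sign(right) or 1.0)))
        ens.stumps.append(st)
        ens.gains[feat] += max(gain, 0.0)
        w = w * np.exp(-ysign * st.respond(X))
        if err >= 0.5:
            break


# ---------------------------------------------------------------------------
# application
# ---------------------------------------------------------------------------


def score(model: StumpEnsemble, vectors) -> np.ndarray:
    """Score one or many directed feature vectors."""
    if hasattr(vectors, "values"):  # a single DirectedFeatureVector
        vectors = vectors.values[None, :]
    elif not isinstance(vectors, np.ndarray):
        vectors = np.array([getattr(v, "values", v) for v in vectors])
    return model.score(np.atleast_2d(vectors))


def classify_interface(score_fwd: float, score_rev: float, theta: float):
    """Combine the two directed scores: max over directions, then threshold.

    Returns ``None`` for non-synaptic, else ``(True, direction)`` with ties
    broken toward the forward direction.
    """
    if not (np.isfinite(score_fwd) and np.isfinite(score_rev)):
        raise ValueError("scores must be finite")
    m = max(score_fwd, score_rev)
    if m > theta:
        direction = "S1->S2" if score_fwd >= score_rev else "S2->S1"
        return (True, direction)
    return None


def feature_importance(model: StumpEnsemble):
    """Features ranked by accumulated split gain, descending.

    Features never used by any stump have importance 0.
    """
    gains = model.gains
    if gains is None:
        gains = np.zeros(model.n_features)
        for st in model.stumps:
            gains[st.feature] += 1.0
    order = np.argsort(-gains, kind="stable")
    return [(int(i), float(gains[i])) for i in order]


def validate_undirected(model: StumpEnsemble, X_fwd, X_rev, y_undirected, theta):
    """Undirected precision/recall with the either-direction (logical OR) rule.

    An interface counts as detected if either directed score exceeds
    ``theta``.  With no detections at all, precision is reported as 1.0 and
    flagged.
    """
    s_fwd = model.score(np.asarray(X_fwd, dtype=np.float64))
    s_rev = model.score(np.asarray(X_rev, dtype=np.float64))
    detected = (s_fwd > theta) | (s_rev > theta)
    y = np.asarray(y_undirected, dtype=bool)
    tp = int(np.sum(detected & y))
    fp = int(np.sum(detected & ~y))
    fn = int(np.sum(~detected & y))
    empty = (tp + fp) == 0
    precision = 1.0 if empty else tp / (tp + fp)
    recall = 0.0 if (tp + fn) == 0 else tp / (tp + fn)
    return {"precision": precision, "recall": recall, "tp": tp, "fp": fp,
            "fn": fn, "no_detections": empty}
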