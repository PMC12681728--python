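"""Axis-aligned recursive partitioning to re-derive decision thresholds.

The published rule has exactly one cut per laboratory feature (RDW and
glucose gap), which is what a depth-2 classification tree with Gini
impurity yields: a root split on the more informative feature and a
second-level split on the other.  Genotype-positive carriers are a ~10-15%
minority, so splits are scored with balanced class weights by default —
unweighted Gini on so skewed a prior favours trivial splits.

The split search is exhaustive over midpoints between consecutive sorted
unique feature values; ties in impurity decrease break toward the smaller
threshold, making the fit deterministic for a given input order and
configuration.  The learner reports thresholds for inspection; it does not
silently replace the published operating points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .classify import DecisionCriteria

__all__ = [
    "LearnerConfig",
    "Split",
    "PartitionModel",
    "LearnedRule",
    "DegenerateLabelsError",
    "best_split",
    "fit_partition",
    "learn_rule",
]


class DegenerateLabelsError(ValueError):
    """All labels belong to one class; no supervised split exists."""


@dataclass(frozen=True)
class LearnerConfig:
    max_depth: int = 2
    min_leaf: int = 20
    class_weight: str = "balanced"  # "balanced" or "uniform"

    def __post_init__(self):
        if self.max_depth < 1 or self.min_leaf < 1:
            raise ValueError("max_depth and min_leaf must be >= 1")
        if self.class_weight not in ("balanced", "uniform"):
            raise ValueError(f"unknown class_weight: {self.class_weight!r}")


@dataclass(frozen=True)
class Split:
    threshold: float
    direction: str  # side enriched for positives: "le" or "ge"
    impurity_decrease: float


def _sample_weights(labels: np.ndarray, class_weight: str) -> np.ndarray:
    if class_weight == "uniform":
        return np.ones(labels.shape, dtype=float)
    n = labels.size
    n_pos = int(labels.sum())
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        return np.ones(labels.shape, dtype=float)
    w = np.where(labels, n / (2.0 * n_pos), n / (2.0 * n_neg))
    return w


def _gini(w_pos: float, w_tot: float) -> float:
    if w_tot <= 0:
        return 0.0
    p = w_pos / w_tot
    return 2.0 * p * (1.0 - p)


def best_split(
    values,
    labels,
    sample_weight=None,
    min_leaf: int = 1,
) -> Optional[Split]:
    """Exhaustive weighted-Gini split search over candidate midpoints.

    Candidates are midpoints between consecutive sorted unique values; each
    side of an admissible split holds at least ``min_leaf`` samples.  Ties
    in impurity decrease break toward the smaller threshold.  Returns the
    best :class:`Split` (even at zero decrease — pruning is the caller's
    job) or ``None`` when no admissible candidate exists (constant
    feature, or min_leaf infeasible).
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    w = np.ones_like(x) if sample_weight is None else np.asarray(sample_weight, float)
    if x.size < 2:
        return None

    order = np.argsort(x, kind="stable")
    xs, ys, ws = x[order], y[order], w[order]
    # split after position i => left = xs[:i+1]; admissible where value changes
    boundary = np.nonzero(np.diff(xs) > 0)[0]
    if boundary.size == 0:
        return None
    n_left = boundary + 1
    ok = (n_left >= min_leaf) & (x.size - n_left >= min_leaf)
    boundary = boundary[ok]
    if boundary.size == 0:
        return None

    cw = np.cumsum(ws)
    cwp = np.cumsum(ws * ys)
    w_tot, wp_tot = cw[-1], cwp[-1]
    wl, wpl = cw[boundary], cwp[boundary]
    wr, wpr = w_tot - wl, wp_tot - wpl

    pl = np.divide(wpl, wl, out=np.zeros_like(wpl), where=wl > 0)
    pr = np.divide(wpr, wr, out=np.zeros_like(wpr), where=wr > 0)
    g_parent = _gini(wp_tot, w_tot)
    g_children = (wl * 2 * pl * (1 - pl) + wr * 2 * pr * (1 - pr)) / w_tot
    decrease = g_parent - g_children

    i = int(np.argmax(decrease))  # first max => smallest threshold on ties
    b = boundary[i]
    threshold = 0.5 * (xs[b] + xs[b + 1])
    direction = "le" if pl[i] >= pr[i] else "ge"
    return Split(
        threshold=float(threshold),
        direction=direction,
        impurity_decrease=float(decrease[i]),
    )


@dataclass
class _Node:
    feature: Optional[str] = None
    split: Optional[Split] = None
    left: Optional["_Node"] = None  # feature value <= threshold
    right: Optional["_Node"] = None
    pos_fraction: float = 0.0  # unweighted positive rate in this node


@dataclass
class PartitionModel:
    """A fitted depth-<=2 axis-aligned partition over (rdw, gg)."""

    root: _Node
    config: LearnerConfig
    features: tuple[str, str] = ("rdw", "gg")

    def score(self, rdw, gg) -> np.ndarray:
        """Leaf-wise training positive fraction for each sample.

        This is the natural continuous score of a recursive-partitioning
        model and is what the rank-based AUROC consumes.
        """
        r = np.asarray(rdw, dtype=float)
        g = np.asarray(gg, dtype=float)
        out = np.empty(r.shape, dtype=float)
        vals = {"rdw": r, "gg": g}
        for i in range(r.size):
            node = self.root
            while node.split is not None:
                v = vals[node.feature][i]
                node = node.left if v <= node.split.threshold else node.right
            out[i] = node.pos_fraction
        return out


@dataclass
class LearnedRule:
    """Thresholds extracted from a fitted partition, one per feature."""

    rdw_threshold: Optional[float]
    gg_threshold: Optional[float]
    directions: dict = field(default_factory=dict)
    impurity_decreases: dict = field(default_factory=dict)
    model: Optional[PartitionModel] = None

    def criteria(
        self, fallback: DecisionCriteria = DecisionCriteria()
    ) -> DecisionCriteria:
        """As decision criteria, filling any missing cut from ``fallback``."""
        return DecisionCriteria(
            rdw_threshold=(
                self.rdw_threshold if self.rdw_threshold is not None
                else fallback.rdw_threshold
            ),
            gg_threshold=(
                self.gg_threshold if self.gg_threshold is not None
                else fallback.gg_threshold
            ),
        )


def fit_partition(rdw, gg, labels, config: LearnerConfig = LearnerConfig()) -> PartitionModel:
    """Fit the depth-<=2 partition: root on the better feature, then the
    other feature within each child."""
    r = np.asarray(rdw, dtype=float)
    g = np.asarray(gg, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise DegenerateLabelsError("labels contain a single class")
    if y.size < 2 * config.min_leaf:
        raise ValueError(f"need at least {2 * config.min_leaf} samples")

    w = _sample_weights(y, config.class_weight)
    feats = {"rdw": r, "gg": g}

    def grow(idx: np.ndarray, allowed: tuple[str, ...], depth: int) -> _Node:
        node = _Node(pos_fraction=float(y[idx].mean()) if idx.size else 0.0)
        if depth >= config.max_depth or idx.size < 2 * config.min_leaf:
            return node
        best_name, best = None, None
        for name in allowed:
            s = best_split(feats[name][idx], y[idx], w[idx], min_leaf=config.min_leaf)
            if s is None:
                continue
            if best is None or s.impurity_decrease > best.impurity_decrease:
                best_name, best = name, s
        if best is None:
            return node
        node.feature, node.split = best_name, best
        mask = feats[best_name][idx] <= best.threshold
        other = tuple(n for n in allowed if n != best_name)
        node.left = grow(idx[mask], other, depth + 1)
        node.right = grow(idx[~mask], other, depth + 1)
        return node

    root = grow(np.arange(y.size), ("rdw", "gg"), 0)
    return PartitionModel(root=root, config=config)


def learn_rule(rdw, gg, labels, config: LearnerConfig = LearnerConfig()) -> LearnedRule:
    """One operating threshold per feature, from marginal root-level splits.

    Each feature's cut comes from an exhaustive balanced-Gini search over
    the full sample.  The cut for the root feature coincides with the
    fitted partition's root split; the other feature's cut is its own
    marginal split rather than a split conditioned inside a child node —
    conditioning on the first cut skews the class mix and drags the second
    threshold away from its population-level (Bayes axis) operating point,
    which is the quantity a published one-cut-per-lab rule states.  The
    depth-2 partition is still fitted and returned: it is the model whose
    leaf scores feed the AUROC.  Directions record which side of each cut
    is enriched for carriers ("le" for RDW, "ge" for glucose gap in the
    intended regime).
    """
    model = fit_partition(rdw, gg, labels, config)
    rule = LearnedRule(rdw_threshold=None, gg_threshold=None, model=model)
    y = np.asarray(labels, dtype=bool)
    w = _sample_weights(y, config.class_weight)
    for feature, values in (("rdw", rdw), ("gg", gg)):
        split = best_split(
            np.asarray(values, dtype=float), y, w, min_leaf=config.min_leaf
        )
        if split is None:
            continue
        key = "rdw_threshold" if feature == "rdw" else "gg_threshold"
        setattr(rule, key, split.threshold)
        rule.directions[feature] = split.direction
        rule.impurity_decreases[feature] = split.impurity_decrease
    return rule
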