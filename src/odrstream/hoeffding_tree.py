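"""Incremental decision-tree learning with Hoeffding-bound split control (ioVFDT).

A Hoeffding tree grows one leaf at a time from a stream: each leaf accumulates
sufficient statistics (class counts, per-class Gaussian summaries for numeric
attributes, value-by-class counts for nominal ones) and, every ``grace``
instances, attempts a split.  The best candidate attribute is adopted when its
information-gain advantage over the runner-up exceeds the Hoeffding bound

    eps = sqrt(R^2 * ln(1/delta) / (2 n)),

which guarantees with confidence 1 - delta that the observed gain ranking is
the true one.  Gains are measured in bits and normalized by log2(K) for K
classes so the bound's range assumption R = 1 holds.

The "incrementally optimized" variant adds adaptive tie-breaking: when the two
best candidates are within eps of each other, the split is forced anyway once
the current bound has fallen below the running mean of all bounds computed at
previous split attempts — near-ties on well-populated leaves are resolved
rather than deferred forever, keeping the tree compact without a hand-picked
tie threshold.  A fixed threshold mode (``tie_mode="fixed"``, split near-ties
when eps < tau) is provided for comparison.

Leaf prediction is, by default, an adaptive per-leaf choice between majority
class and naive Bayes (whichever has been more accurate at that leaf so far);
plain majority voting is available as ``leaf_prediction="majority"``.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .stream_io import ConfigError, Instance, StreamSchema

__all__ = [
    "hoeffding_bound",
    "entropy",
    "information_gain",
    "candidate_thresholds",
    "cost_balance",
    "GaussianStats",
    "LeafStats",
    "SplitCandidate",
    "HoeffdingTreeModel",
]

_SQRT2 = math.sqrt(2.0)


def hoeffding_bound(value_range: float, delta: float, n: int) -> float:
    """eps = sqrt(R^2 ln(1/delta) / (2n)): with confidence 1-delta the true mean
    of n iid observations with range R is within eps of the observed mean."""
    if value_range < 0:
        raise ValueError(f"value range R={value_range} must be >= 0")
    if not 0.0 < delta <= 1.0:
        raise ValueError(f"split confidence delta={delta} must be in (0, 1]")
    if n < 1:
        raise ValueError(f"sample count n={n} must be >= 1")
    return math.sqrt(value_range * value_range * math.log(1.0 / delta) / (2.0 * n))


def entropy(counts: Sequence[float]) -> float:
    """Shannon entropy in bits of a non-negative count vector."""
    total = float(sum(counts))
    if total <= 0.0:
        return 0.0
    h = 0.0
    for c in counts:
        if c > 0.0:
            p = c / total
            h -= p * math.log2(p)
    return h


class GaussianStats:
    """Running mean/variance (Welford) of one attribute for one class."""

    __slots__ = ("n", "mean", "_m2")

    def __init__(self, n: int = 0, mean: float = 0.0, m2: float = 0.0):
        self.n = n
        self.mean = mean
        self._m2 = m2

    def add(self, x: float) -> None:
        self.n += 1
        d = x - self.mean
        self.mean += d / self.n
        self._m2 += d * (x - self.mean)

    @property
    def variance(self) -> float:
        return self._m2 / (self.n - 1) if self.n > 1 else 0.0

    @property
    def std(self) -> float:
        return math.sqrt(self.variance)

    def cdf(self, t: float) -> float:
        """P(X <= t) under the fitted normal; degenerates to a step at the mean."""
        if self.n == 0:
            return 0.5
        sd = self.std
        if sd == 0.0:
            return 1.0 if self.mean <= t else 0.0
        return 0.5 * (1.0 + math.erf((t - self.mean) / (sd * _SQRT2)))

    def pdf(self, x: float) -> float:
        sd = self.std
        if sd == 0.0:
            return 1.0 if x == self.mean else 1e-12
        z = (x - self.mean) / sd
        return max(math.exp(-0.5 * z * z) / (sd * math.sqrt(2.0 * math.pi)), 1e-300)

    def to_dict(self) -> dict:
        return {"n": self.n, "mean": self.mean, "m2": self._m2}

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianStats":
        return cls(d["n"], d["mean"], d["m2"])


class LeafStats:
    """Sufficient statistics accumulated at one leaf."""

    __slots__ = ("class_counts", "numeric", "ranges", "nominal",
                 "n_since_attempt", "n_total")

    def __init__(self):
        self.class_counts: Dict[str, int] = {}
        self.numeric: Dict[int, Dict[str, GaussianStats]] = {}
        self.ranges: Dict[int, List[float]] = {}
        self.nominal: Dict[int, Dict[str, Dict[str, int]]] = {}
        self.n_since_attempt = 0
        self.n_total = 0

    def update(self, instance: Instance, schema: StreamSchema) -> None:
        label = instance.label
        self.class_counts[label] = self.class_counts.get(label, 0) + 1
        self.n_total += 1
        self.n_since_attempt += 1
        for ai, spec in enumerate(schema.attributes):
            v = instance.values[ai]
            if v is None:
                continue
            if spec.is_numeric:
                per_class = self.numeric.setdefault(ai, {})
                gs = per_class.get(label)
                if gs is None:
                    gs = per_class[label] = GaussianStats()
                gs.add(v)
                rng = self.ranges.get(ai)
                if rng is None:
                    self.ranges[ai] = [v, v]
                else:
                    if v < rng[0]:
                        rng[0] = v
                    if v > rng[1]:
                        rng[1] = v
            else:
                table = self.nominal.setdefault(ai, {})
                row = table.setdefault(v, {})
                row[label] = row.get(label, 0) + 1

    @property
    def n_classes_observed(self) -> int:
        return sum(1 for c in self.class_counts.values() if c > 0)


@dataclass
class SplitCandidate:
    """A proposed test on one attribute, with its information gain in bits."""

    attribute: int
    name: str
    kind: str                       # "numeric" or "nominal"
    gain: float
    threshold: Optional[float] = None
    values: Optional[tuple] = None  # nominal branch values, schema category order


def candidate_thresholds(stats: LeafStats, attribute: int, k: int = 10) -> List[float]:
    """k equally spaced thresholds strictly between the observed min and max."""
    if k < 1:
        raise ConfigError(f"threshold count k={k} must be >= 1")
    rng = stats.ranges.get(attribute)
    if rng is None or rng[0] == rng[1]:
        return []
    lo, hi = rng
    step = (hi - lo) / (k + 1)
    return [lo + i * step for i in range(1, k + 1)]


def information_gain(stats: LeafStats, candidate: SplitCandidate) -> float:
    """Entropy gain of a candidate split, from the leaf's sufficient statistics.

    Nominal: exact, from the value-by-class contingency table.  Numeric: the
    class-conditional Gaussian summaries provide the expected mass of each
    class on either side of the threshold.  Instances missing the attribute are
    excluded (gain is relative to the instances that observed it).  Clipped at 0.
    """
    if candidate.kind == "nominal":
        table = stats.nominal.get(candidate.attribute, {})
        branch_values = candidate.values or tuple(table.keys())
        parent: Dict[str, float] = {}
        branches = []
        for v in branch_values:
            row = table.get(v, {})
            branches.append(list(row.values()))
            for lbl, c in row.items():
                parent[lbl] = parent.get(lbl, 0) + c
        n = sum(parent.values())
        if n <= 0:
            return 0.0
        h_parent = entropy(list(parent.values()))
        h_children = sum((sum(b) / n) * entropy(b) for b in branches if b)
        return max(h_parent - h_children, 0.0)

    per_class = stats.numeric.get(candidate.attribute, {})
    t = candidate.threshold
    if t is None or not per_class:
        return 0.0
    left: List[float] = []
    right: List[float] = []
    parent_counts: List[float] = []
    for gs in per_class.values():
        mass_left = gs.n * gs.cdf(t)
        left.append(mass_left)
        right.append(gs.n - mass_left)
        parent_counts.append(float(gs.n))
    n = sum(parent_counts)
    if n <= 0:
        return 0.0
    n_left = sum(left)
    n_right = sum(right)
    h = entropy(parent_counts)
    if n_left > 0:
        h -= (n_left / n) * entropy(left)
    if n_right > 0:
        h -= (n_right / n) * entropy(right)
    return max(h, 0.0)


def cost_balance(accuracy: float, size: float, elapsed: float,
                 weights: Sequence[float],
                 size_range: Optional[Tuple[float, float]] = None,
                 time_range: Optional[Tuple[float, float]] = None) -> float:
    """Monitoring score balancing error, tree size and time; lower is better.

    Theta = w1*(1 - accuracy) + w2*norm(size) + w3*norm(elapsed), with size and
    elapsed min-max normalized over the supplied ranges (a missing or degenerate
    range contributes 0).  Weights must be non-negative and sum to 1, so
    Theta lies in [0, 1].  Reported in run summaries only; never fed back into
    learning.
    """
    if len(weights) != 3 or any(w < 0 for w in weights):
        raise ConfigError("weights must be three non-negative numbers")
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ConfigError(f"weights {tuple(weights)} must sum to 1")

    def norm(v: float, rng: Optional[Tuple[float, float]]) -> float:
        if rng is None:
            return 0.0
        lo, hi = rng
        if hi <= lo:
            return 0.0
        return min(max((v - lo) / (hi - lo), 0.0), 1.0)

    w1, w2, w3 = weights
    return w1 * (1.0 - accuracy) + w2 * norm(size, size_range) + w3 * norm(elapsed, time_range)


class _Leaf:
    __slots__ = ("stats", "fallback", "mc_correct", "nb_correct")

    def __init__(self, fallback: str):
        self.stats = LeafStats()
        self.fallback = fallback
        self.mc_correct = 0
        self.nb_correct = 0


class _Split:
    __slots__ = ("attribute", "name", "kind", "threshold", "branch_values",
                 "children", "branch_weights")

    def __init__(self, attribute, name, kind, threshold, branch_values,
                 children, branch_weights):
        self.attribute = attribute
        self.name = name
        self.kind = kind
        self.threshold = threshold
        self.branch_values = branch_values
        self.children = children
        self.branch_weights = branch_weights

    def route(self, value) -> int:
        """Child index for a value; missing or unseen values take the branch
        that received the most training mass (majority branch)."""
        if value is None:
            return self._majority_branch()
        if self.kind == "numeric":
            return 0 if value <= self.threshold else 1
        try:
            return self.branch_values.index(value)
        except ValueError:
            return self._majority_branch()

    def _majority_branch(self) -> int:
        best, best_w = 0, -1.0
        for i, w in enumerate(self.branch_weights):
            if w > best_w:
                best, best_w = i, w
        return best


class HoeffdingTreeModel:
    """Incremental Hoeffding tree with adaptive mean-of-bounds tie-breaking.

    Parameters
    ----------
    schema : StreamSchema
        Attribute/class declaration the instances conform to.
    delta : float
        Split confidence; the bound holds with probability 1 - delta.
    grace : int
        Instances a leaf accumulates between consecutive split attempts.
    n_thresholds : int
        Candidate thresholds per numeric attribute (equally spaced grid).
    tie_mode : {"adaptive", "fixed"}
        Near-tie policy: adaptive compares the current bound with the running
        mean of past bounds; fixed compares it with ``tie_tau``.
    leaf_prediction : {"majority", "nb_adaptive"}
        Leaf classification strategy.
    """

    def __init__(self, schema: StreamSchema, *, delta: float = 1e-7, grace: int = 200,
                 n_thresholds: int = 10, tie_mode: str = "adaptive",
                 tie_tau: float = 0.05, leaf_prediction: str = "nb_adaptive",
                 value_range: float = 1.0):
        if not 0.0 < delta <= 1.0:
            raise ConfigError(f"delta={delta} must be in (0, 1]")
        if grace < 1:
            raise ConfigError(f"grace={grace} must be >= 1")
        if tie_mode not in ("adaptive", "fixed"):
            raise ConfigError(f"unknown tie mode {tie_mode!r}")
        if leaf_prediction not in ("majority", "nb_adaptive"):
            raise ConfigError(f"unknown leaf prediction {leaf_prediction!r}")
        self.schema = schema
        self.delta = delta
        self.grace = grace
        self.n_thresholds = n_thresholds
        self.tie_mode = tie_mode
        self.tie_tau = tie_tau
        self.leaf_prediction = leaf_prediction
        self.value_range = value_range
        self.root = _Leaf(fallback=schema.class_labels[0])
        self.n_nodes = 1
        self.n_leaves = 1
        self.n_splits = 0
        self.n_trained = 0
        self._bound_sum = 0.0
        self._bound_count = 0
        self._gain_norm = math.log2(len(schema.class_labels)) if len(schema.class_labels) > 1 else 1.0

    # -- bookkeeping ---------------------------------------------------------

    @property
    def bound_history_mean(self) -> Optional[float]:
        """Running mean of the Hoeffding bounds computed at split attempts."""
        if self._bound_count == 0:
            return None
        return self._bound_sum / self._bound_count

    def tree_size(self) -> int:
        """Number of nodes (internal + leaves), by traversal."""

        def count(node) -> int:
            if isinstance(node, _Leaf):
                return 1
            return 1 + sum(count(c) for c in node.children)

        return count(self.root)

    # -- learning ------------------------------------------------------------

    def _route(self, instance: Instance):
        node = self.root
        parent = None
        slot = None
        while isinstance(node, _Split):
            parent, slot = node, node.route(instance.values[node.attribute])
            node = node.children[slot]
        return node, parent, slot

    def learn_one(self, instance: Instance) -> "HoeffdingTreeModel":
        """Route the instance to its leaf, update statistics, maybe split."""
        if len(instance.values) != self.schema.n_attributes:
            raise TypeError(
                f"instance has {len(instance.values)} values, schema declares "
                f"{self.schema.n_attributes} attributes")
        if instance.label not in self.schema.class_labels:
            raise TypeError(f"label {instance.label!r} not in schema classes")
        leaf, parent, slot = self._route(instance)
        if self.leaf_prediction == "nb_adaptive" and leaf.stats.n_total > 0:
            mc = self._majority_label(leaf)
            nb = self._nb_label(leaf, instance)
            if mc == instance.label:
                leaf.mc_correct += 1
            if nb == instance.label:
                leaf.nb_correct += 1
        leaf.stats.update(instance, self.schema)
        self.n_trained += 1
        if (leaf.stats.n_since_attempt >= self.grace
                and leaf.stats.n_classes_observed >= 2):
            self._attempt_split(leaf, parent, slot)
        return self

    def _class_mean_thresholds(self, stats: LeafStats, attribute: int) -> List[float]:
        """Midpoints between adjacent class-conditional means.

        The equal-spacing grid is anchored on the observed min/max, which a
        single extreme value can stretch far beyond the data bulk; midpoints
        of class means stay inside the bulk, so concept boundaries remain
        reachable even on contaminated leaves.
        """
        rng = stats.ranges.get(attribute)
        if rng is None or rng[0] == rng[1]:
            return []
        means = sorted(gs.mean for gs in stats.numeric.get(attribute, {}).values()
                       if gs.n > 0)
        out = []
        for a, b in zip(means, means[1:]):
            t = 0.5 * (a + b)
            if rng[0] < t < rng[1]:
                out.append(t)
        return out

    def _candidates(self, stats: LeafStats) -> List[SplitCandidate]:
        out: List[SplitCandidate] = []
        for ai, spec in enumerate(self.schema.attributes):
            if spec.is_numeric:
                best = None
                thresholds = candidate_thresholds(stats, ai, self.n_thresholds)
                thresholds += self._class_mean_thresholds(stats, ai)
                for t in thresholds:
                    cand = SplitCandidate(ai, spec.name, "numeric", 0.0, threshold=t)
                    cand.gain = information_gain(stats, cand)
                    if best is None or cand.gain > best.gain:
                        best = cand
                if best is not None:
                    out.append(best)
            else:
                table = stats.nominal.get(ai, {})
                observed = tuple(v for v in spec.categories if v in table)
                if len(observed) >= 2:
                    cand = SplitCandidate(ai, spec.name, "nominal", 0.0, values=observed)
                    cand.gain = information_gain(stats, cand)
                    out.append(cand)
        return out

    def _attempt_split(self, leaf: _Leaf, parent, slot) -> bool:
        """One split attempt: rank candidates, apply the bound and tie rules.

        The bound eps is computed from the leaf's total count and recorded in
        the model-wide running mean whether or not a split happens; near-ties
        consult the mean of *previous* attempts.
        """
        stats = leaf.stats
        candidates = self._candidates(stats)
        eps = hoeffding_bound(self.value_range, self.delta, stats.n_total)
        prev_mean = self.bound_history_mean
        split_done = False
        if candidates:
            best = candidates[0]
            second_gain = 0.0
            for cand in candidates[1:]:
                if cand.gain > best.gain:
                    second_gain = best.gain
                    best = cand
                elif cand.gain > second_gain:
                    second_gain = cand.gain
            g1 = best.gain / self._gain_norm
            g2 = second_gain / self._gain_norm
            if g1 > 0.0:
                if g1 - g2 > eps:
                    split_done = True
                elif self.tie_mode == "adaptive":
                    split_done = prev_mean is not None and eps < prev_mean
                else:
                    split_done = eps < self.tie_tau
            if split_done:
                self._realize_split(leaf, parent, slot, best)
        self._bound_sum += eps
        self._bound_count += 1
        if not split_done:
            stats.n_since_attempt = 0
        return split_done

    def _realize_split(self, leaf: _Leaf, parent, slot, cand: SplitCandidate) -> None:
        stats = leaf.stats
        labels = self.schema.class_labels
        parent_majority = self._majority_label(leaf)
        if cand.kind == "numeric":
            per_class = stats.numeric.get(cand.attribute, {})
            branch_dists = [[], []]
            for lbl in labels:
                gs = per_class.get(lbl)
                if gs is None:
                    branch_dists[0].append(0.0)
                    branch_dists[1].append(0.0)
                else:
                    mass_left = gs.n * gs.cdf(cand.threshold)
                    branch_dists[0].append(mass_left)
                    branch_dists[1].append(gs.n - mass_left)
            branch_values = None
        else:
            table = stats.nominal.get(cand.attribute, {})
            branch_values = cand.values
            branch_dists = []
            for v in branch_values:
                row = table.get(v, {})
                branch_dists.append([float(row.get(lbl, 0)) for lbl in labels])

        children = []
        weights = []
        for dist in branch_dists:
            total = sum(dist)
            if total > 0:
                best_i = max(range(len(labels)), key=lambda i: (dist[i], -i))
                fallback = labels[best_i]
            else:
                fallback = parent_majority
            children.append(_Leaf(fallback=fallback))
            weights.append(total)

        node = _Split(cand.attribute, cand.name, cand.kind, cand.threshold,
                      branch_values, children, weights)
        if parent is None:
            self.root = node
        else:
            parent.children[slot] = node
        self.n_splits += 1
        self.n_leaves += len(children) - 1
        self.n_nodes += len(children)

    # -- prediction ----------------------------------------------------------

    def _majority_label(self, leaf: _Leaf) -> str:
        counts = leaf.stats.class_counts
        if not counts or leaf.stats.n_total == 0:
            return leaf.fallback
        best, best_c = None, -1
        for lbl in self.schema.class_labels:  # schema order breaks ties
            c = counts.get(lbl, 0)
            if c > best_c:
                best, best_c = lbl, c
        return best

    def _nb_label(self, leaf: _Leaf, instance: Instance) -> str:
        scores = self._nb_scores(leaf, instance)
        best, best_s = None, -math.inf
        for lbl in self.schema.class_labels:
            s = scores[lbl]
            if s > best_s:
                best, best_s = lbl, s
        return best

    def _nb_scores(self, leaf: _Leaf, instance: Instance) -> Dict[str, float]:
        stats = leaf.stats
        n = max(stats.n_total, 1)
        scores = {}
        for lbl in self.schema.class_labels:
            prior = (stats.class_counts.get(lbl, 0) + 1.0) / (n + len(self.schema.class_labels))
            s = math.log(prior)
            for ai, spec in enumerate(self.schema.attributes):
                v = instance.values[ai]
                if v is None:
                    continue
                if spec.is_numeric:
                    gs = stats.numeric.get(ai, {}).get(lbl)
                    if gs is not None and gs.n > 0:
                        s += math.log(gs.pdf(v))
                else:
                    table = stats.nominal.get(ai, {})
                    row = table.get(v, {})
                    n_c = stats.class_counts.get(lbl, 0)
                    s += math.log((row.get(lbl, 0) + 1.0) / (n_c + len(spec.categories)))
            scores[lbl] = s
        return scores

    def predict_proba(self, instance: Instance) -> Dict[str, float]:
        leaf, _, _ = self._route(instance)
        labels = self.schema.class_labels
        if leaf.stats.n_total == 0:
            return {lbl: 1.0 / len(labels) for lbl in labels}
        if self.leaf_prediction == "nb_adaptive" and leaf.nb_correct > leaf.mc_correct:
            log_scores = self._nb_scores(leaf, instance)
            mx = max(log_scores.values())
            raw = {lbl: math.exp(s - mx) for lbl, s in log_scores.items()}
        else:
            raw = {lbl: float(leaf.stats.class_counts.get(lbl, 0)) for lbl in labels}
        total = sum(raw.values())
        if total <= 0:
            return {lbl: 1.0 / len(labels) for lbl in labels}
        return {lbl: raw[lbl] / total for lbl in labels}

    def predict_one(self, instance: Instance) -> str:
        leaf, _, _ = self._route(instance)
        if leaf.stats.n_total == 0:
            return leaf.fallback
        if self.leaf_prediction == "nb_adaptive" and leaf.nb_correct > leaf.mc_correct:
            return self._nb_label(leaf, instance)
        return self._majority_label(leaf)

    def clone(self) -> "HoeffdingTreeModel":
        """Deep copy (used for re-learning trials)."""
        return copy.deepcopy(self)

    # -- serialization -------------------------------------------------------

    def _node_to_dict(self, node) -> dict:
        if isinstance(node, _Leaf):
            s = node.stats
            return {
                "type": "leaf",
                "fallback": node.fallback,
                "mc_correct": node.mc_correct,
                "nb_correct": node.nb_correct,
                "class_counts": dict(sorted(s.class_counts.items())),
                "n_total": s.n_total,
                "n_since_attempt": s.n_since_attempt,
                "numeric": {str(ai): {lbl: gs.to_dict() for lbl, gs in sorted(d.items())}
                            for ai, d in sorted(s.numeric.items())},
                "ranges": {str(ai): list(r) for ai, r in sorted(s.ranges.items())},
                "nominal": {str(ai): {v: dict(sorted(row.items()))
                                      for v, row in sorted(t.items())}
                            for ai, t in sorted(s.nominal.items())},
            }
        return {
            "type": "split",
            "attribute": node.attribute,
            "name": node.name,
            "kind": node.kind,
            "threshold": node.threshold,
            "branch_values": list(node.branch_values) if node.branch_values else None,
            "branch_weights": list(node.branch_weights),
            "children": [self._node_to_dict(c) for c in node.children],
        }

    def _node_from_dict(self, d):
        if d["type"] == "leaf":
            leaf = _Leaf(fallback=d["fallback"])
            leaf.mc_correct = d["mc_correct"]
            leaf.nb_correct = d["nb_correct"]
            s = leaf.stats
            s.class_counts = dict(d["class_counts"])
            s.n_total = d["n_total"]
            s.n_since_attempt = d["n_since_attempt"]
            s.numeric = {int(ai): {lbl: GaussianStats.from_dict(g) for lbl, g in dd.items()}
                         for ai, dd in d["numeric"].items()}
            s.ranges = {int(ai): list(r) for ai, r in d["ranges"].items()}
            s.nominal = {int(ai): {v: dict(row) for v, row in t.items()}
                         for ai, t in d["nominal"].items()}
            return leaf
        children = [self._node_from_dict(c) for c in d["children"]]
        return _Split(d["attribute"], d["name"], d["kind"], d["threshold"],
                      tuple(d["branch_values"]) if d["branch_values"] else None,
                      children, list(d["branch_weights"]))

    def to_dict(self) -> dict:
        return {
            "delta": self.delta,
            "grace": self.grace,
            "n_thresholds": self.n_thresholds,
            "tie_mode": self.tie_mode,
            "tie_tau": self.tie_tau,
            "leaf_prediction": self.leaf_prediction,
            "value_range": self.value_range,
            "n_nodes": self.n_nodes,
            "n_leaves": self.n_leaves,
            "n_splits": self.n_splits,
            "n_trained": self.n_trained,
            "bound_sum": self._bound_sum,
            "bound_count": self._bound_count,
            "root": self._node_to_dict(self.root),
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, schema: StreamSchema, d: dict) -> "HoeffdingTreeModel":
        model = cls(schema, delta=d["delta"], grace=d["grace"],
                    n_thresholds=d["n_thresholds"], tie_mode=d["tie_mode"],
                    tie_tau=d["tie_tau"], leaf_prediction=d["leaf_prediction"],
                    value_range=d["value_range"])
        model.n_nodes = d["n_nodes"]
        model.n_leaves = d["n_leaves"]
        model.n_splits = d["n_splits"]
        model.n_trained = d["n_trained"]
        model._bound_sum = d["bound_sum"]
        model._bound_count = d["bound_count"]
        model.root = model._node_from_dict(d["root"])
        return model
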