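"""Synthetic labeled streams with ground-truth outlier flags.

The generator emulates the two kinds of abnormality the pipeline must tell
apart.  Base instances have uniform[0,1] numeric attributes labeled by a fixed
random decision-tree concept, so every clean attribute has known quartiles
(Q1 = 0.25, Q3 = 0.75, IQR = 0.5) and outlier magnitudes can be calibrated
exactly.  On top of that:

* **point noise** — a fraction of instances get one attribute replaced by a
  value ``magnitude`` IQRs beyond the clean quartiles (random side), optionally
  with the label flipped to a random other class: isolated corruption a robust
  learner should discard;
* **a rare group** — a tight coherent cluster far outside the clean range with
  its own dedicated class: repeated meaningful abnormality (the rare-disease
  scenario) a robust learner should retain.

All randomness derives from the config seed; the same config reproduces the
same stream byte for byte.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Set, Tuple, Union

import numpy as np

from .stream_io import AttributeSpec, ConfigError, Instance, StreamSchema

__all__ = [
    "SynthConfig",
    "Concept",
    "make_concept",
    "generate_stream",
    "truth_confusion",
    "write_truth_csv",
]

RARE_CLASS = "rare"

#: clean marginals of uniform[0,1] attributes — used for magnitude calibration
CLEAN_Q1 = 0.25
CLEAN_Q3 = 0.75
CLEAN_IQR = 0.5

#: rare-cluster location: every attribute near this center, far below the
#: lower fence for any beta up to ~5 (0.25 - 5*0.5 = -2.25 > -3 + jitter)
RARE_CENTER = -3.0
RARE_SPREAD = 0.05


@dataclass
class SynthConfig:
    """Generator settings; defaults give a clean, learnable 4-class stream."""

    n_attributes: int = 10
    n_classes: int = 4
    concept_depth: int = 3
    n_instances: int = 20000
    noise_rate: float = 0.0
    outlier_magnitude: float = 10.0
    label_flip_on_noise: bool = True
    rare_group_rate: float = 0.0
    seed: int = 0

    def validate(self) -> "SynthConfig":
        if self.n_attributes < 1:
            raise ConfigError("need at least one attribute")
        if self.n_classes < 2:
            raise ConfigError("need at least two classes")
        if self.concept_depth < 1:
            raise ConfigError(f"concept depth {self.concept_depth} must be >= 1")
        if self.n_instances < 1:
            raise ConfigError("need at least one instance")
        for name in ("noise_rate", "rare_group_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.noise_rate + self.rare_group_rate > 0.5:
            raise ConfigError("noise_rate + rare_group_rate must be <= 0.5")
        if self.outlier_magnitude <= 0:
            raise ConfigError("outlier magnitude must be > 0")
        return self

    def as_dict(self) -> dict:
        return asdict(self)


class Concept:
    """A fixed random decision tree over uniform[0,1] attributes.

    Nodes are nested dicts {attr, threshold, left, right}; leaves are class
    labels.  Thresholds are drawn from (0.25, 0.75) so both branches stay
    well populated.
    """

    def __init__(self, root, labels: Tuple[str, ...]):
        self.root = root
        self.labels = labels

    def classify(self, x: Sequence[float]) -> str:
        node = self.root
        while isinstance(node, dict):
            node = node["left"] if x[node["attr"]] <= node["threshold"] else node["right"]
        return node


def make_concept(n_attributes: int, n_classes: int, depth: int, seed: int) -> Concept:
    """Deterministic random-tree concept; every leaf is assigned a class so
    that all classes appear (labels cycled over a shuffled leaf order)."""
    if n_classes < 2:
        raise ConfigError("need at least two classes")
    if depth < 1:
        raise ConfigError(f"concept depth {depth} must be >= 1")
    rng = np.random.default_rng(seed)
    labels = tuple(f"c{i}" for i in range(n_classes))

    def build(d: int):
        if d == 0:
            return None  # placeholder, filled below
        return {
            "attr": int(rng.integers(0, n_attributes)),
            "threshold": float(rng.uniform(0.25, 0.75)),
            "left": build(d - 1),
            "right": build(d - 1),
        }

    root = build(depth)
    # collect leaf slots in deterministic (left-to-right) order
    slots: List[Tuple[dict, str]] = []

    def walk(node):
        for side in ("left", "right"):
            if node[side] is None:
                slots.append((node, side))
            else:
                walk(node[side])

    walk(root)
    order = rng.permutation(len(slots))
    for rank, slot_i in enumerate(order):
        node, side = slots[int(slot_i)]
        node[side] = labels[rank % n_classes]
    return Concept(root, labels)


def _schema_for(config: SynthConfig) -> StreamSchema:
    attrs = tuple(AttributeSpec(f"a{i}", "numeric") for i in range(config.n_attributes))
    classes = [f"c{i}" for i in range(config.n_classes)]
    if config.rare_group_rate > 0:
        classes.append(RARE_CLASS)
    return StreamSchema(attrs, AttributeSpec("class", "nominal", tuple(classes)))


def generate_stream(config: SynthConfig) -> Tuple[StreamSchema, List[Instance]]:
    """Generate the full stream with truth flags.

    Exactly ``round(noise_rate * n)`` instances are corrupted (one attribute
    each) and ``round(rare_group_rate * n)`` replaced by rare-cluster members;
    the affected stream positions are a seeded random choice.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    concept = make_concept(config.n_attributes, config.n_classes,
                           config.concept_depth, config.seed)
    schema = _schema_for(config)
    n, p = config.n_instances, config.n_attributes
    X = rng.random((n, p))
    labels = [concept.classify(X[i]) for i in range(n)]

    n_noise = int(round(config.noise_rate * n))
    n_rare = int(round(config.rare_group_rate * n))
    special = rng.permutation(n)[: n_noise + n_rare]
    noise_idx: Set[int] = set(int(i) for i in special[:n_noise])
    rare_idx: Set[int] = set(int(i) for i in special[n_noise:])

    class_labels = [f"c{i}" for i in range(config.n_classes)]
    instances: List[Instance] = []
    for i in range(n):
        values = X[i]
        label = labels[i]
        truth_outlier = False
        truth_group = False
        if i in noise_idx:
            j = int(rng.integers(0, p))
            if rng.random() < 0.5:
                values = values.copy()
                values[j] = CLEAN_Q3 + config.outlier_magnitude * CLEAN_IQR
            else:
                values = values.copy()
                values[j] = CLEAN_Q1 - config.outlier_magnitude * CLEAN_IQR
            truth_outlier = True
            if config.label_flip_on_noise:
                others = [c for c in class_labels if c != label]
                label = others[int(rng.integers(0, len(others)))]
        elif i in rare_idx:
            values = RARE_CENTER + RARE_SPREAD * rng.standard_normal(p)
            label = RARE_CLASS
            truth_outlier = True
            truth_group = True
        instances.append(Instance(
            values=tuple(float(v) for v in values),
            label=label,
            index=i,
            truth_outlier=truth_outlier,
            truth_group=truth_group,
        ))
    return schema, instances


def truth_confusion(detected, stream: Sequence[Instance]) -> dict:
    """Precision/recall of detected outliers against the stream's truth flags.

    ``detected`` may be OutlierRecords (their ``stream_index`` is used) or a
    collection of stream indices.  With zero detections precision is reported
    as 1.0 and flagged (``zero_detections``).
    """
    if any(inst.truth_outlier is None for inst in stream):
        raise ValueError("stream carries no ground-truth outlier flags")
    detected_idx: Set[int] = set()
    for d in detected:
        detected_idx.add(d.stream_index if hasattr(d, "stream_index") else int(d))
    truth_idx = {inst.index for inst in stream if inst.truth_outlier}
    tp = len(detected_idx & truth_idx)
    zero = len(detected_idx) == 0
    precision = 1.0 if zero else tp / len(detected_idx)
    recall = 1.0 if not truth_idx else tp / len(truth_idx)
    return {
        "precision": precision,
        "recall": recall,
        "n_detected": len(detected_idx),
        "n_truth": len(truth_idx),
        "zero_detections": zero,
    }


def write_truth_csv(path, stream: Sequence[Instance]) -> int:
    """Sidecar CSV of truth flags (index, truth_outlier, truth_group, label)."""
    n = 0
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "truth_outlier", "truth_group", "label"])
        for inst in stream:
            writer.writerow([
                inst.index,
                int(bool(inst.truth_outlier)),
                int(bool(inst.truth_group)),
                inst.label,
            ])
            n += 1
    return n
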