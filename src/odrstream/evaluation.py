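"""Prequential (interleaved test-then-train) metric accounting.

Every clean instance is first scored against the current model, then used to
train it; the running confusion matrix yields accuracy and Cohen's kappa
(chance-corrected agreement), reported per window and cumulatively.  Kappa
values are mapped onto the conventional qualitative agreement bands
(Slight / Fair / Moderate / Substantial / Almost perfect).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "kappa",
    "kappa_band",
    "WindowRecord",
    "PrequentialReport",
    "summarize",
]


class ConfusionMatrix:
    """k x k contingency of (truth row, prediction column) counts."""

    def __init__(self, labels):
        self.labels = tuple(labels)
        self._index = {lbl: i for i, lbl in enumerate(self.labels)}
        self.counts = np.zeros((len(self.labels), len(self.labels)), dtype=np.int64)

    def update(self, truth: str, predicted: str) -> "ConfusionMatrix":
        try:
            i = self._index[truth]
            j = self._index[predicted]
        except KeyError as exc:
            raise ValueError(f"label {exc.args[0]!r} not in schema classes {self.labels}") from None
        self.counts[i, j] += 1
        return self

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def correct(self) -> int:
        return int(np.trace(self.counts))

    @property
    def tested(self) -> bool:
        return self.total > 0

    @property
    def accuracy(self) -> float:
        """Fraction of correct predictions; 0.0 before any test (flagged by
        the ``tested`` property)."""
        t = self.total
        return self.correct / t if t else 0.0

    def copy(self) -> "ConfusionMatrix":
        cm = ConfusionMatrix(self.labels)
        cm.counts = self.counts.copy()
        return cm


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa (p_o - p_e) / (1 - p_e).

    Degenerate case p_e = 1 (all mass in a single truth/prediction cell pair):
    defined as 1.0 if agreement is perfect, else 0.0.
    """
    total = cm.total
    if total < 1:
        raise ValueError("kappa of an empty confusion matrix")
    p_o = cm.correct / total
    rows = cm.counts.sum(axis=1).astype(float)
    cols = cm.counts.sum(axis=0).astype(float)
    p_e = float(np.dot(rows, cols)) / (total * total)
    if p_e >= 1.0 - 1e-15:
        return 1.0 if p_o >= 1.0 - 1e-15 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


_BANDS = [
    (20.0, "Slight"),
    (40.0, "Fair"),
    (60.0, "Moderate"),
    (80.0, "Substantial"),
    (100.0, "Almost perfect"),
]


def kappa_band(k: float) -> str:
    """Qualitative label for a kappa value in [-1, 1].

    Bands are half-open on their upper bound: kappa*100 <= 20 is Slight,
    (20, 40] Fair, (40, 60] Moderate, (60, 80] Substantial, (80, 100]
    Almost perfect; negative kappa maps to Slight.
    """
    if not -1.0 <= k <= 1.0:
        raise ValueError(f"kappa={k} outside [-1, 1]")
    pct = k * 100.0
    for upper, name in _BANDS:
        if pct <= upper:
            return name
    return _BANDS[-1][1]


@dataclass
class WindowRecord:
    """Metrics snapshot at the end of one window (accuracy/kappa cumulative)."""

    start: int
    mode: str
    n_outliers: int
    accuracy: float
    kappa: float
    tree_size: int

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class PrequentialReport:
    """Full run report: config echo, per-window trace, final metrics.

    ``timing`` carries wall-clock ODR costs (t_odr_a, t_odr_r, total seconds)
    and is the only non-deterministic part; ``to_json(include_timing=False)``
    serializes the reproducible core.
    """

    config: dict
    windows: List[WindowRecord]
    final_accuracy: float
    final_kappa: float
    final_kappa_band: str
    tree_size: int
    n_instances: int
    n_tested: int
    n_trained_clean: int
    n_retained: int
    n_removed: int
    n_outliers_total: int
    timing: Dict[str, float] = field(default_factory=dict)

    def to_dict(self, include_timing: bool = True) -> dict:
        d = {
            "config": self.config,
            "windows": [w.as_dict() for w in self.windows],
            "final": {
                "accuracy": self.final_accuracy,
                "kappa": self.final_kappa,
                "kappa_band": self.final_kappa_band,
                "tree_size": self.tree_size,
                "n_instances": self.n_instances,
                "n_tested": self.n_tested,
                "n_trained_clean": self.n_trained_clean,
                "n_retained": self.n_retained,
                "n_removed": self.n_removed,
                "n_outliers_total": self.n_outliers_total,
            },
        }
        if include_timing:
            d["timing"] = self.timing
        return d

    def to_json(self, include_timing: bool = True) -> str:
        return json.dumps(self.to_dict(include_timing=include_timing),
                          sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PrequentialReport":
        d = json.loads(text)
        final = d["final"]
        return cls(
            config=d["config"],
            windows=[WindowRecord(**w) for w in d["windows"]],
            final_accuracy=final["accuracy"],
            final_kappa=final["kappa"],
            final_kappa_band=final["kappa_band"],
            tree_size=final["tree_size"],
            n_instances=final["n_instances"],
            n_tested=final["n_tested"],
            n_trained_clean=final["n_trained_clean"],
            n_retained=final["n_retained"],
            n_removed=final["n_removed"],
            n_outliers_total=final["n_outliers_total"],
            timing=d.get("timing", {}),
        )


def summarize(trace: List[WindowRecord], cm: ConfusionMatrix, model, config: dict,
              counts: Optional[dict] = None,
              timing: Optional[dict] = None) -> PrequentialReport:
    """Assemble the final report from the window trace and cumulative matrix."""
    if not trace:
        raise ValueError("cannot summarize an empty trace")
    counts = counts or {}
    final_kappa = kappa(cm) if cm.tested else 0.0
    return PrequentialReport(
        config=dict(config),
        windows=list(trace),
        final_accuracy=cm.accuracy,
        final_kappa=final_kappa,
        final_kappa_band=kappa_band(final_kappa),
        tree_size=model.tree_size(),
        n_instances=counts.get("n_instances", cm.total),
        n_tested=cm.total,
        n_trained_clean=counts.get("n_trained_clean", cm.total),
        n_retained=counts.get("n_retained", 0),
        n_removed=counts.get("n_removed", 0),
        n_outliers_total=counts.get("n_outliers_total", 0),
        timing=dict(timing or {}),
    )
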