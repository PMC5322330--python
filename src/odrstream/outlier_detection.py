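"""Per-window interquartile-range outlier detection (the ODR-A path).

For every numeric attribute of a window the empirical quartiles Q1 and Q3 are
estimated from the non-missing values, and Tukey fences ``[Q1 - beta*IQR,
Q3 + beta*IQR]`` are drawn with tolerance factor ``beta``.  An instance is
flagged as an outlier when at least one attribute value lies strictly outside
its fences (rule ``"any"``), or when the violating fraction of usable
attributes exceeds ``tau`` (rule ``"fraction"``).  Flagged instances become
:class:`OutlierRecord` objects whose disposition is decided by :func:`disposition`:
groups smaller than ``lof_min`` are treated as noise and moved to the
misclassified database, larger groups are retained as a candidate rare-event
group for the re-learning check.

The quantile estimator is linear interpolation of order statistics (numpy's
default, the common "type 7" convention); alternatives are exposed through
``method``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .stream_io import ConfigError, Instance, StreamSchema, Window

__all__ = [
    "QuartileSummary",
    "OutlierRecord",
    "MisclassifiedDB",
    "empirical_quantile",
    "quartile_summary",
    "detect_outliers",
    "disposition",
]

#: disposition states, in transition order
PENDING = "pending"
REMOVED_TO_DB = "removed_to_db"
RETAINED_GROUP = "retained_group"
RELEARNED_NOISE = "relearned_noise"
RELEARNED_KEPT = "relearned_kept"

_QUANTILE_METHODS = ("linear", "lower", "nearest")


@dataclass(frozen=True)
class QuartileSummary:
    """Quartiles, IQR and beta-fences of one numeric attribute over one window."""

    attribute: str
    q1: float
    q3: float
    iqr: float
    beta: float
    lower_fence: float
    upper_fence: float
    n_used: int
    usable: bool = True


@dataclass
class OutlierRecord:
    """One flagged instance and what ultimately happened to it."""

    instance: Instance
    window_start: int
    stream_index: int
    violating_attributes: tuple
    disposition: str = PENDING


class MisclassifiedDB:
    """Append-only store of outliers judged to be noise, plus a clean reservoir.

    ``records`` accumulates :class:`OutlierRecord` objects (never mutated except
    for their disposition field); ``negatives`` is a bounded reservoir sample of
    clean instances used as the "normal" class when training ODR-R rules.
    """

    def __init__(self, cap: int = 5000, rng: Optional[np.random.Generator] = None):
        if cap < 1:
            raise ConfigError("reservoir cap must be >= 1")
        self.records: list = []
        self.negatives: list = []
        self.cap = cap
        self._rng = rng if rng is not None else np.random.default_rng(0)
        self._n_clean_seen = 0

    def add_records(self, records: Iterable[OutlierRecord]) -> None:
        self.records.extend(records)

    def add_clean(self, instance: Instance) -> None:
        """Standard reservoir sampling: every clean instance seen so far has
        equal probability cap/n of being in the reservoir."""
        self._n_clean_seen += 1
        if len(self.negatives) < self.cap:
            self.negatives.append(instance)
        else:
            j = int(self._rng.integers(0, self._n_clean_seen))
            if j < self.cap:
                self.negatives[j] = instance

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_negatives(self) -> int:
        return len(self.negatives)


def empirical_quantile(values: Sequence[float], p: float, method: str = "linear") -> float:
    """Inverse empirical CDF of ``values`` at probability ``p``.

    With sorted order statistics x_(1..n) and position h = p*(n-1), the
    ``linear`` method returns x_(floor(h)+1) + (h - floor(h)) * (x_(floor(h)+2)
    - x_(floor(h)+1)); p=0 gives the minimum and p=1 the maximum.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability p={p} outside [0, 1]")
    if method not in _QUANTILE_METHODS:
        raise ConfigError(f"unknown quantile method {method!r}; choose from {_QUANTILE_METHODS}")
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("empirical_quantile of empty (or all-missing) data")
    return float(np.quantile(arr, p, method=method))


def quartile_summary(window: Window, attribute: str, beta: float, schema: StreamSchema,
                     method: str = "linear") -> QuartileSummary:
    """Q1/Q3/IQR and standard fences for one numeric attribute of a window.

    An all-missing attribute yields a degenerate summary with ``usable=False``
    (NaN statistics); a nominal attribute is a type error.
    """
    if beta < 0:
        raise ConfigError(f"beta={beta} must be >= 0")
    ai = schema.attribute_index(attribute)
    spec = schema.attributes[ai]
    if not spec.is_numeric:
        raise TypeError(f"attribute {attribute!r} is nominal; fences need numeric values")
    vals = [inst.values[ai] for inst in window.instances if inst.values[ai] is not None]
    if not vals:
        nan = float("nan")
        return QuartileSummary(attribute, nan, nan, nan, beta, nan, nan, 0, usable=False)
    q1 = empirical_quantile(vals, 0.25, method=method)
    q3 = empirical_quantile(vals, 0.75, method=method)
    iqr = q3 - q1
    return QuartileSummary(
        attribute=attribute,
        q1=q1,
        q3=q3,
        iqr=iqr,
        beta=beta,
        lower_fence=q1 - beta * iqr,
        upper_fence=q3 + beta * iqr,
        n_used=len(vals),
    )


def detect_outliers(window: Window, beta: float, schema: StreamSchema, *,
                    rule: str = "any", tau: float = 0.5,
                    fence_dialect: str = "standard", method: str = "linear"):
    """Split a window into clean instances and outlier records.

    Returns ``(clean, outliers, summaries)``.  ``clean`` and the instances
    behind ``outliers`` partition the window.  Boundary values (exactly on a
    fence) are clean; comparisons are strict.

    ``fence_dialect="standard"`` uses Tukey fences [Q1 - beta*IQR, Q3 + beta*IQR].
    ``fence_dialect="paper"`` applies the verbatim printed comparisons
    (value < Q1 + beta*IQR or value > Q3 + beta*IQR), kept only for audit.
    """
    if window.length < 4:
        raise ConfigError(f"window of length {window.length} < 4 cannot support quartiles")
    if beta < 0:
        raise ConfigError(f"beta={beta} must be >= 0")
    if rule not in ("any", "fraction"):
        raise ConfigError(f"unknown outlier rule {rule!r}")
    if fence_dialect not in ("standard", "paper"):
        raise ConfigError(f"unknown fence dialect {fence_dialect!r}")
    numeric = [(i, schema.attributes[i].name) for i in schema.numeric_indices]
    if not numeric:
        raise ConfigError("stream has no numeric attributes; IQR detection inapplicable")

    summaries = []
    fences = {}  # attr index -> (lower, upper)
    for ai, name in numeric:
        s = quartile_summary(window, name, beta, schema, method=method)
        summaries.append(s)
        if not s.usable:
            continue
        if fence_dialect == "paper":
            fences[ai] = (s.q1 + beta * s.iqr, s.q3 + beta * s.iqr)
        else:
            fences[ai] = (s.lower_fence, s.upper_fence)

    clean: list = []
    outliers: list = []
    for inst in window.instances:
        violating = []
        n_usable = 0
        for ai, name in numeric:
            if ai not in fences:
                continue
            v = inst.values[ai]
            if v is None:
                continue
            n_usable += 1
            lo, hi = fences[ai]
            if v < lo or v > hi:
                violating.append(name)
        if rule == "any":
            is_outlier = bool(violating)
        else:
            is_outlier = n_usable > 0 and (len(violating) / n_usable) > tau
        if is_outlier:
            outliers.append(OutlierRecord(
                instance=inst,
                window_start=window.start_index,
                stream_index=inst.index,
                violating_attributes=tuple(violating),
            ))
        else:
            clean.append(inst)
    return clean, outliers, summaries


def disposition(outliers: Sequence[OutlierRecord], lof_min: int,
                db: MisclassifiedDB) -> None:
    """Decide the fate of one window's outlier set by its size.

    Fewer than ``lof_min`` records: each is marked ``removed_to_db`` and
    appended to the misclassified database (excluded from training).
    ``lof_min`` or more: each is marked ``retained_group`` — a candidate
    rare-event group queued for the re-learning check (a tie |O| == lof_min
    favors keeping data).
    """
    if lof_min < 1:
        raise ConfigError(f"lof_min={lof_min} must be >= 1")
    if not outliers:
        return
    if len(outliers) < lof_min:
        for rec in outliers:
            rec.disposition = REMOVED_TO_DB
        db.add_records(outliers)
    else:
        for rec in outliers:
            rec.disposition = RETAINED_GROUP
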