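"""The ODR-ioVFDT feedback loop: per-window outlier handling around the learner.

Each window is processed in one of two modes, chosen by the running
prequential accuracy:

* **ODR-A** (active) — while ``Acc_cur < Acc_min`` (and always until ODR-R rules
  exist): interquartile-range fences flag outliers directly.
* **ODR-R** (rules) — once accuracy is satisfactory: a binary incremental tree,
  trained on the misclassified database (outliers) against a reservoir of clean
  instances (normals), filters the window instead.

Flagged instances in a window form a set O.  ``|O| < lof_min`` means isolated
noise: the records go to the misclassified database and are never trained.
``|O| >= lof_min`` means a candidate rare-event group: a deep copy of the
learner is evaluated on the group prequentially (test-then-train).  If the
group is self-consistent enough that the copy's error on it stays below the
current error on clean data, the copy — which has now learned the group —
replaces the live learner (``relearned_kept``); otherwise the group is noise
(``relearned_noise``) and joins the misclassified database.  Clean instances
are always prequentially tested then trained.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from typing import Iterable, List, Optional, Tuple

import numpy as np

from .evaluation import ConfusionMatrix, PrequentialReport, WindowRecord, kappa, summarize
from .hoeffding_tree import HoeffdingTreeModel
from .outlier_detection import (
    MisclassifiedDB,
    OutlierRecord,
    RELEARNED_KEPT,
    RELEARNED_NOISE,
    REMOVED_TO_DB,
    RETAINED_GROUP,
    detect_outliers,
    disposition,
)
from .stream_io import (
    AttributeSpec,
    ConfigError,
    Instance,
    StreamSchema,
    Window,
    sliding_windows,
)

__all__ = [
    "RunConfig",
    "ControllerState",
    "train_odr_rules",
    "apply_odr_rules",
    "relearn_outliers",
    "process_window",
    "run_stream",
]

logger = logging.getLogger("odrstream")

MODE_A = "ODR_A"
MODE_R = "ODR_R"
MODE_OFF = "OFF"

RULE_ATTRIBUTE = "<rule>"
_ODR_CLASS = ("normal", "outlier")


@dataclass
class RunConfig:
    """All knobs of one run, echoed verbatim into the report.

    beta is the fence tolerance factor; omega the window length (step m
    defaults to omega, i.e. non-overlapping windows); lof_min the smallest
    outlier set treated as a candidate rare group; acc_min the accuracy
    threshold switching ODR-A to ODR-R (err_max = 1 - acc_min).  delta and
    grace are the Hoeffding-tree split confidence and grace period.
    """

    beta: float = 3.0
    omega: int = 1000
    m: Optional[int] = None
    lof_min: int = 10
    acc_min: float = 0.75
    delta: float = 1e-7
    grace: int = 200
    n_thresholds: int = 10
    tie_mode: str = "adaptive"
    tie_tau: float = 0.05
    leaf_prediction: str = "nb_adaptive"
    fence_dialect: str = "standard"
    rule: str = "any"
    rule_tau: float = 0.5
    quantile_method: str = "linear"
    reservoir_cap: int = 5000
    n_min_rules: int = 20
    odr_r_grace: int = 25
    odr_r_skill_min: float = 0.9
    odr_enabled: bool = True
    seed: int = 0

    def validate(self) -> "RunConfig":
        if self.beta < 0:
            raise ConfigError(f"beta={self.beta} must be >= 0")
        if self.omega < 4:
            raise ConfigError(f"omega={self.omega} must be >= 4")
        step = self.m if self.m is not None else self.omega
        if not 1 <= step <= self.omega:
            raise ConfigError(f"m={step} must satisfy 1 <= m <= omega")
        if self.lof_min < 1:
            raise ConfigError(f"lof_min={self.lof_min} must be >= 1")
        if not 0.0 <= self.acc_min <= 1.0:
            raise ConfigError(f"acc_min={self.acc_min} must be in [0, 1]")
        if not 0.0 < self.delta <= 1.0:
            raise ConfigError(f"delta={self.delta} must be in (0, 1]")
        if self.grace < 1 or self.odr_r_grace < 1:
            raise ConfigError("grace periods must be >= 1")
        if self.n_min_rules < 1:
            raise ConfigError("n_min_rules must be >= 1")
        return self

    @property
    def step(self) -> int:
        return self.m if self.m is not None else self.omega

    @property
    def err_max(self) -> float:
        return 1.0 - self.acc_min

    def as_dict(self) -> dict:
        return asdict(self)

    def make_learner(self, schema: StreamSchema) -> HoeffdingTreeModel:
        return HoeffdingTreeModel(
            schema,
            delta=self.delta,
            grace=self.grace,
            n_thresholds=self.n_thresholds,
            tie_mode=self.tie_mode,
            tie_tau=self.tie_tau,
            leaf_prediction=self.leaf_prediction,
        )


@dataclass
class ControllerState:
    """Mutable controller bookkeeping carried across windows."""

    db: MisclassifiedDB
    acc_min: float
    mode: str = MODE_A
    odr_r_model: Optional[HoeffdingTreeModel] = None
    t_odr_a: float = 0.0
    t_odr_r: float = 0.0
    n_windows: int = 0
    n_instances: int = 0
    n_trained_clean: int = 0
    n_retained: int = 0
    n_removed: int = 0
    n_outliers_total: int = 0
    n_kept_groups: int = 0
    n_noise_groups: int = 0

    @property
    def err_max(self) -> float:
        return 1.0 - self.acc_min

    @property
    def t_odr(self) -> float:
        return self.t_odr_a + self.t_odr_r


def _binary_schema(schema: StreamSchema) -> StreamSchema:
    return StreamSchema(
        schema.attributes,
        AttributeSpec("__odr__", "nominal", _ODR_CLASS),
    )


def train_odr_rules(db: MisclassifiedDB, schema: StreamSchema, config: RunConfig,
                    rng: np.random.Generator) -> Optional[HoeffdingTreeModel]:
    """Train the binary outlier/normal rule model from the misclassified db.

    Positives are the db records (label "outlier"), negatives an equal number
    of reservoir-sampled clean instances (label "normal"); training order is a
    seeded interleaving.  Returns None (the absent-model signal: the controller
    stays in ODR-A) when either side has fewer than ``n_min_rules`` instances,
    or when the trained model cannot reproduce the separation of its own
    training data (in-sample balanced accuracy below ``odr_r_skill_min``) — a
    rule set that replaces a working fence detector must at least recover the
    separations it was shown.
    """
    n_pos = db.n_records
    if n_pos < config.n_min_rules or db.n_negatives < config.n_min_rules:
        return None
    n_neg = min(db.n_negatives, n_pos)
    neg_idx = rng.permutation(db.n_negatives)[:n_neg]
    examples: List[Instance] = []
    for rec in db.records:
        examples.append(Instance(values=rec.instance.values, label="outlier"))
    for i in neg_idx:
        inst = db.negatives[int(i)]
        examples.append(Instance(values=inst.values, label="normal"))
    order = rng.permutation(len(examples))
    model = HoeffdingTreeModel(
        _binary_schema(schema),
        delta=config.delta,
        grace=config.odr_r_grace,
        n_thresholds=config.n_thresholds,
        tie_mode=config.tie_mode,
        tie_tau=config.tie_tau,
        leaf_prediction="majority",
    )
    for i in order:
        model.learn_one(examples[int(i)])
    # in-sample skill gate
    hits = {"outlier": 0, "normal": 0}
    totals = {"outlier": 0, "normal": 0}
    for ex in examples:
        totals[ex.label] += 1
        if model.predict_one(ex) == ex.label:
            hits[ex.label] += 1
    balanced = 0.5 * (hits["outlier"] / max(totals["outlier"], 1)
                      + hits["normal"] / max(totals["normal"], 1))
    if balanced < config.odr_r_skill_min:
        return None
    return model


def apply_odr_rules(model: HoeffdingTreeModel, window: Window,
                    schema: StreamSchema) -> Tuple[list, list]:
    """Filter a window with the learned ODR-R model.

    Instances predicted "outlier" become OutlierRecords (violating attribute
    recorded as the pseudo-name "<rule>"); the usual size-based disposition
    applies afterwards.
    """
    clean: List[Instance] = []
    outliers: List[OutlierRecord] = []
    for inst in window.instances:
        probe = Instance(values=inst.values, label=_ODR_CLASS[0])
        if model.predict_one(probe) == "outlier":
            outliers.append(OutlierRecord(
                instance=inst,
                window_start=window.start_index,
                stream_index=inst.index,
                violating_attributes=(RULE_ATTRIBUTE,),
            ))
        else:
            clean.append(inst)
    if not clean:
        logger.warning("ODR-R flagged every instance of window at %d", window.start_index)
    return clean, outliers


def relearn_outliers(learner: HoeffdingTreeModel, records, err_cur: float):
    """Noise-vs-worthwhile test for a retained outlier group.

    A deep copy of the learner is first trained on the group, then re-scored
    on it; ``Err_re`` is the resulting error rate — a measure of how learnable
    / self-consistent the group is.  A coherent rare group (repeated abnormal
    records with a consistent label) becomes predictable after one pass, so
    Err_re collapses; corrupted instances with arbitrary labels do not.
    ``Err_re >= err_cur`` (the current error on clean data, inclusive) marks
    the group as noise and the copy is discarded; ``Err_re < err_cur`` marks
    it worthwhile and the group-trained copy becomes the live learner.

    Returns ``(disposition, learner, err_re)``.
    """
    if not records:
        raise ValueError("relearn_outliers needs a non-empty group")
    trial = learner.clone()
    for rec in records:
        trial.learn_one(rec.instance)
    errors = sum(1 for rec in records
                 if trial.predict_one(rec.instance) != rec.instance.label)
    err_re = errors / len(records)
    if err_re >= err_cur:
        for rec in records:
            rec.disposition = RELEARNED_NOISE
        return RELEARNED_NOISE, learner, err_re
    for rec in records:
        rec.disposition = RELEARNED_KEPT
    return RELEARNED_KEPT, trial, err_re


def process_window(state: ControllerState, window: Window,
                   learner: HoeffdingTreeModel, schema: StreamSchema,
                   config: RunConfig, cm: ConfusionMatrix,
                   rng: np.random.Generator
                   ) -> Tuple[HoeffdingTreeModel, WindowRecord]:
    """Run the full ODR-ioVFDT loop over one window; returns the (possibly
    replaced) learner and the window's metrics record."""
    state.n_windows += 1
    state.n_instances += window.length

    if not config.odr_enabled:
        mode = MODE_OFF
        clean = list(window.instances)
        outliers: List[OutlierRecord] = []
    else:
        want_rules = cm.tested and cm.accuracy >= config.acc_min
        if want_rules and state.odr_r_model is not None:
            mode = MODE_R
            t0 = time.perf_counter()
            clean, outliers = apply_odr_rules(state.odr_r_model, window, schema)
            state.t_odr_r += time.perf_counter() - t0
        else:
            if want_rules:
                logger.info("window %d: accuracy %.3f >= acc_min but no ODR-R model; "
                            "falling back to ODR-A", window.start_index, cm.accuracy)
            mode = MODE_A
            t0 = time.perf_counter()
            clean, outliers, _ = detect_outliers(
                window, config.beta, schema,
                rule=config.rule, tau=config.rule_tau,
                fence_dialect=config.fence_dialect,
                method=config.quantile_method,
            )
            state.t_odr_a += time.perf_counter() - t0
        disposition(outliers, config.lof_min, state.db)
        for inst in clean:
            state.db.add_clean(inst)

    state.n_outliers_total += len(outliers)

    # prequential test-then-train over the clean instances
    win_correct = 0
    for inst in clean:
        pred = learner.predict_one(inst)
        cm.update(inst.label, pred)
        if pred == inst.label:
            win_correct += 1
        learner.learn_one(inst)
    state.n_trained_clean += len(clean)
    if not clean:
        logger.warning("window at %d has zero clean instances; nothing trained",
                       window.start_index)
        err_cur = 1.0 - cm.accuracy if cm.tested else 1.0
    else:
        err_cur = 1.0 - win_correct / len(clean)

    retained = [r for r in outliers if r.disposition == RETAINED_GROUP]
    state.n_removed += sum(1 for r in outliers if r.disposition == REMOVED_TO_DB)
    if retained:
        state.n_retained += len(retained)
        t0 = time.perf_counter()
        verdict, learner, _err_re = relearn_outliers(learner, retained, err_cur)
        dt = time.perf_counter() - t0
        if mode == MODE_R:
            state.t_odr_r += dt
        else:
            state.t_odr_a += dt
        if verdict == RELEARNED_NOISE:
            state.db.add_records(retained)
            state.n_noise_groups += 1
        else:
            state.n_kept_groups += 1

    # keep the rule model in sync while actively collecting outliers
    if config.odr_enabled and mode == MODE_A:
        t0 = time.perf_counter()
        new_rules = train_odr_rules(state.db, schema, config, rng)
        state.t_odr_r += time.perf_counter() - t0
        if new_rules is not None:
            state.odr_r_model = new_rules

    state.mode = mode
    record = WindowRecord(
        start=window.start_index,
        mode=mode,
        n_outliers=len(outliers),
        accuracy=cm.accuracy,
        kappa=kappa(cm) if cm.tested else 0.0,
        tree_size=learner.tree_size(),
    )
    return learner, record


def run_stream(schema: StreamSchema, stream: Iterable[Instance], config: RunConfig
               ) -> Tuple[PrequentialReport, HoeffdingTreeModel, ControllerState]:
    """Top-level orchestration: windows -> per-window processing -> report.

    Fully deterministic given the config seed, except for the wall-clock
    timing section of the report.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    db = MisclassifiedDB(cap=config.reservoir_cap, rng=rng)
    state = ControllerState(db=db, acc_min=config.acc_min)
    learner = config.make_learner(schema)
    cm = ConfusionMatrix(schema.class_labels)
    trace: List[WindowRecord] = []
    t_start = time.perf_counter()
    for window in sliding_windows(stream, config.omega, config.step):
        try:
            learner, record = process_window(state, window, learner, schema, config, cm, rng)
        except Exception as exc:
            raise RuntimeError(
                f"failure while processing window starting at {window.start_index}: {exc}"
            ) from exc
        trace.append(record)
    elapsed = time.perf_counter() - t_start
    if not trace:
        raise ConfigError("stream produced no windows (shorter than 4 instances?)")
    counts = {
        "n_instances": state.n_instances,
        "n_trained_clean": state.n_trained_clean,
        "n_retained": state.n_retained,
        "n_removed": state.n_removed,
        "n_outliers_total": state.n_outliers_total,
    }
    timing = {
        "t_odr_a": state.t_odr_a,
        "t_odr_r": state.t_odr_r,
        "t_odr": state.t_odr,
        "elapsed": elapsed,
    }
    report = summarize(trace, cm, learner, config.as_dict(), counts, timing)
    return report, learner, state
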