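# Methods

This note records the model, the defaults and the design choices behind
`odrstream`, at the level of detail a maintainer (or skeptical user) needs to
interpret results produced with it.

## Problem setting

A labeled tabular stream arrives continuously; records may be corrupted by
transmission or measurement error (point outliers with unreliable labels), or
may form small coherent groups of genuinely abnormal cases that deserve their
own decision path. Training on the former degrades an incremental classifier;
discarding the latter blinds it. The pipeline couples three components: an
incremental Hoeffding-tree learner, a per-window interquartile-range outlier
detector, and a feedback controller that disposes of detected outliers as
noise or as a worthwhile rare group.

## The learner (ioVFDT)

A Hoeffding tree grows from a stream without storing instances. Each leaf
keeps sufficient statistics: class counts, per-(attribute, class) running
Gaussian summaries (Welford mean/variance) with observed min/max, and
value-by-class counts for nominal attributes.

**Split rule.** Every `grace` instances at a leaf (default 200, the common
MOA default), candidate splits are ranked by information gain in bits,
normalized by log₂(K) for K classes so gains live in [0, 1] and the Hoeffding
bound ε = √(R² ln(1/δ) / 2n) applies with R = 1 (δ = 10⁻⁷). The best
candidate is adopted when its normalized advantage over the runner-up exceeds
ε computed at the leaf's total count.

**Adaptive tie-breaking.** When the top candidates are within ε of each other
(two near-equally-good attributes would otherwise deadlock indefinitely), the
split is forced once the current ε falls below the running mean of the ε
values recorded at all previous split attempts, model-wide. The mean is
updated on *every* attempt, split or not; the first attempt can never
tie-split (no history yet). Exact gain ties resolve to the lowest schema
attribute index. A fixed-threshold tie mode (`tie_mode="fixed"`, ε < τ with
τ = 0.05) is provided for comparison.

**Numeric split candidates.** For each numeric attribute the model evaluates
(a) `n_thresholds` = 10 equally spaced points strictly between the leaf's
observed min and max, and (b) midpoints between adjacent class-conditional
means. The second family matters under contamination: a single extreme value
stretches the min/max grid so far that no grid point falls inside the data
bulk, leaving concept boundaries unreachable; class-mean midpoints are robust
to range poisoning because a bounded fraction of extreme values moves a class
mean only slightly. Branch class masses for a threshold t come from the
class-conditional Gaussian CDFs (a zero-variance summary degenerates to a
step at its mean). Nominal attributes split multiway over observed values;
their gains are exact (contingency-table entropy).

**Prediction.** Leaves predict by an adaptive per-leaf choice between
majority class and naive Bayes (`leaf_prediction="nb_adaptive"`, the MOA
default): both predictors are scored on each training instance before it
updates the leaf, and whichever has been more accurate at that leaf answers
queries. This matters for rare groups: a small coherent cluster can never
flip the majority count of a well-populated leaf, but its Gaussian likelihood
dominates immediately. Plain majority voting is available; ties break to
schema class order, an empty leaf answers with the fallback label projected
from its parent split (schema-first class for an empty model). Missing values
route down the branch that received the most training mass.

**Monitoring.** `cost_balance` reports a weighted sum of (1 − accuracy) and
min-max-normalized tree size and elapsed time — a convenience score for
comparing runs. It never feeds back into learning.

## The detector (ODR-A)

Streams are cut into windows of ω = 1000 instances (the length used
throughout; quartiles need at least 4). The step m defaults to ω
(non-overlapping); overlap is supported but windows then share instances and
per-run accounting counts each occurrence. A trailing remainder shorter than
4 is merged into the final window, which may therefore hold up to ω + 3
instances.

Per numeric attribute and window, the empirical quartiles come from linear
interpolation of order statistics (the "type 7" convention; `lower` and
`nearest` variants are exposed), and the Tukey fences are
[Q1 − β·IQR, Q3 + β·IQR]. An instance is flagged when at least one attribute
value lies *strictly* outside its fences (boundary values are clean); a
fraction rule (violating share of usable attributes > τ) is available for
high-dimensional streams. Flagging is invariant to per-attribute translation
and positive scaling, and the flagged set shrinks monotonically in β. The
class label never participates in fence computation (that would leak the
target into preprocessing). Missing values are excluded from quartiles and
cannot violate a fence; an all-missing attribute yields an unusable summary
that is skipped.

A `fence_dialect="paper"` flag applies a raised lower bound (Q1 + β·IQR)
instead of the Tukey lower fence. It flags part of the interquartile bulk and
exists only so that audits can reproduce the verbatim printed comparison; the
standard dialect is the default and the only one used in tests.

## The controller (ODR-A / ODR-R and the feedback loop)

Mode is chosen at each window boundary from the cumulative prequential
accuracy: below Acc_min (default 0.75; Err_max = 1 − Acc_min) the active
fence detector runs (ODR-A); at or above it, a learned rule model filters the
window instead (ODR-R), falling back to ODR-A with a log notice when no rule
model exists. Accuracy bootstraps at 0, so the first windows always run
ODR-A.

**Misclassified database.** Outlier records judged noise accumulate in an
append-only database, alongside a seeded reservoir sample (cap 5000) of clean
instances. The ODR-R model is a binary incremental tree (outlier vs normal)
trained on the database's records against an equal number of reservoir
negatives, with a shorter grace period (25) suited to the small training set.
It is retrained at every ODR-A window and must pass two gates before being
adopted: at least `n_min_rules` = 20 instances per side, and in-sample
balanced accuracy ≥ 0.9 — a rule set replacing a working fence detector must
at least reproduce the separations it was shown. An unskilled model returns
the absent-model signal and the controller stays in ODR-A. (Without this
gate, an overfit early rule model was observed to flag entire windows as
outliers and starve the learner for the rest of the run.)

**Disposition.** A window's outlier set O with |O| < LOF_min (default 10 per
1000-instance window) is isolated noise: removed to the database, excluded
from training and testing. |O| ≥ LOF_min (ties retain: equality favors
keeping data) marks a candidate rare-event group.

**Re-learning.** Each retained group is tested immediately: a deep copy of
the live learner is trained on the group, then re-scored on it, giving
Err_re — a measure of the group's self-consistency. A coherent rare group
(repeated similar records, consistent label) becomes predictable after one
pass, so Err_re collapses toward 0; corrupted records with arbitrary labels
do not. The verdict compares against Err_cur, the prequential error on the
*current window's clean instances* (the matching error estimate from the same
data period): Err_re ≥ Err_cur (inclusive) ⇒ noise, copy discarded, records
appended to the database; Err_re < Err_cur ⇒ worthwhile, the group-trained
copy becomes the live learner. The live learner is therefore never
contaminated by a group later judged noise. Clean instances are always
prequentially tested then trained; a window with zero clean instances trains
nothing and logs a warning.

A known bias of the resubstitution step: a very large inconsistent group
(several grace periods long) could trigger splits that partially fit its own
noise and understate Err_re. At the window sizes and contamination rates the
pipeline targets (groups of tens of instances), no split can occur during the
trial pass and the measure is conservative.

## Evaluation

Prequential (interleaved test-then-train) accounting over the clean
instances: a k×k confusion matrix updated per test, accuracy = trace/total
(reported as 0 with a `tested=False` flag before any test), Cohen's
κ = (p_o − p_e)/(1 − p_e) with the degenerate p_e = 1 case defined as 1 for
perfect agreement and 0 otherwise. κ·100 maps to qualitative bands, half-open
on the upper bound: ≤ 20 Slight (including negative κ), (20, 40] Fair,
(40, 60] Moderate, (60, 80] Substantial, (80, 100] Almost perfect. Reports
carry the config echo, one record per window (cumulative accuracy/κ, mode,
|O|, tree size) and finals. Wall-clock ODR timings (t_ODR-A, t_ODR-R, their
sum) are reported but excluded from the deterministic serialization
(`to_json(include_timing=False)`, CLI `--no-timing`): every other byte of the
report is a pure function of config + seed.

## Synthetic streams

The generator emulates the two abnormality types against a known clean
background. Base instances have i.i.d. uniform[0, 1] attributes labeled by a
fixed random decision tree (depth 3 over 10 attributes, 4 classes by
default; thresholds drawn in (0.25, 0.75) so branches stay populated, leaf
labels cycled over a shuffled leaf order so every class occurs). Uniform
marginals make calibration exact: Q1 = 0.25, Q3 = 0.75, IQR = 0.5, and —
because the support is bounded — β ≥ 1 fences flag essentially nothing on
clean data (no-harm comparisons are exact).

*Point noise*: exactly round(rate·n) instances get one randomly chosen
attribute replaced by Q3 + magnitude·IQR or Q1 − magnitude·IQR (random
side); optionally the label is flipped to a random other class. Replacement
(not perturbation) keeps ground truth unambiguous. *Rare group*: round(rate·n)
instances are replaced by members of a tight cluster (attribute values
N(−3, 0.05²), beyond the β = 5 lower fence) carrying a dedicated class label.
Affected stream positions are a seeded random choice; the same config + seed
reproduces the stream byte for byte.

What the generator does *not* emulate — and what passing tests therefore do
not certify for real data: correlated attributes, nominal predictive
attributes in the concept, concept drift, heavy-tailed clean marginals
(which produce fence false positives at small β), structured missingness,
and class imbalance in the clean background.

## Benchmark conditions and problem sizes

The property suite and `scripts/acceptance.py` use: contaminated benchmark
n = 20,000 instances, ω = 1000, 5% noise at magnitude 10 with label flips,
β = 3, LOF_min = 10, Acc_min = 0.75, judged over 10 seeds; no-harm and
rare-group benchmarks n = 10,000 (rare rate 2%); the β sweep uses magnitude 4
so the 1..5 fence widening produces graded counts rather than a flat line.
Oracle checks (quantile/fence equivalence, batch entropy gains, κ closed
form) are exact to floating-point tolerance against independently coded
references.

## Known limitations

- The Gaussian numeric observer underestimates gains on heavily contaminated
  leaves (inflated variances smear branch masses); detection upstream is what
  keeps the learner's statistics clean.
- ODR-R rules are axis-parallel over raw attributes; an outlier pattern
  spread thinly across many attributes (one extreme attribute per record)
  needs substantial database growth before the rule tree can represent it.
  The skill gate keeps fences active until then.
- No concept-drift adaptation, leaf deactivation or memory-bounded leaf
  management; streams are assumed stationary at desk scale.
- Timing fields are hardware-dependent and never asserted.
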