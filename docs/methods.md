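# Methods

## Problem and data model

The package quantifies plank (prone-bridge) technique from five body-worn
IMUs (occiput, C7, T3, sacrum, right radius), each reporting Euler angles,
acceleration, angular velocity and magnetic field on three axes: 60 channels
sampled at 60 Hz for 10 s, i.e. a 600 × 60 matrix per trial.  Seven technique
labels are distinguished: the acceptable form PC and six deviations (HTFN,
HTBN, HC, HTB, HD, BC — head forward/back at the neck, hands close, pelvis
tilted back, hip dropped, back convex).

### Stable-window features

A subject getting into and out of position produces transients at the edges
of the trial; the middle is near-stationary.  Each channel is therefore
reduced to its mean over the closed window t ∈ [181, 420] (the 4th–7th
second, exactly 240 samples):

    X_{k,j} = (1/240) · Σ_{t=181}^{420} x_{t,j}^{(k)}

Both endpoints are inclusive — the divisor 240 = 420 − 181 + 1 forces this
reading.  A fractional mode ([0.3·T]+1 .. [0.7·T]) generalises the window to
other trial lengths and reproduces [181, 420] at T = 600.

On top of the 60 base features, nine engineered cross-sensor features take
the pairwise maximum of a channel with same-measurement/axis channels of
other sensors — `max(Euler-Z-S5, ·)` over S1–S4, `max(Acc-X-S3, ·)` over
S2/S4/S5, `max(Mag-Z-S3, ·)` over S2/S4.  They capture relative sensor
relationships (e.g. which of two spine sensors sits higher) that single
channels miss.  Only the pairwise max family is implemented; other combiners
(min, difference) are out of scope.

## The cascade

Classification is a binary tree that peels off one technique per node.

**Threshold root.**  HTBN is perfectly separated by a single feature
(Euler-Y-S1): the fitted threshold is the midpoint between the maximum of
the HTBN training values and the minimum of everything else, and fitting
fails loudly (`SeparabilityError`) if the classes overlap — the rule
presupposes perfect separation, so silently fitting a bad threshold would be
worse than an error.  In `threshold_first="auto"` mode all (feature, class)
pairs are scanned for perfect separation and the pair with the largest
margin standardized by the pooled within-class spread wins (raw gap breaks
exact ties, which matters in noise-free data where every within-class spread
is zero).

**Two-stage nodes.**  Each subsequent node N_i separating technique d1 from
the remaining set D2 runs:

1. *Aberrance filter F_i.*  For each of a small set of filtered variables,
   the node stores the D2 training values as an empirical reference.  An
   incoming observation gets an empirical p-value per variable; if any
   p < α (default 0.05) the observation is declared an extreme aberrant
   execution and labelled d1 immediately, short-circuiting the forest.
2. *Random forest RF_i.*  A binary d1-vs-rest forest over all available
   features (60 base + 9 engineered), 500 trees, √p features per split,
   unlimited depth, seeded.  scikit-learn provides the forest; everything
   around it is this package's code.

Filtered variables per node default to the reference sets: none at the HTFN
node, Gyr-Z-S3 at the HTB node, {Euler-Z-S3, Acc-X-S4} at the BC node, the
four `max(Euler-Z-S5, ·)` features at the HC node, and
{Euler-Z-S3, three `max(Acc-X-S3, ·)`, two `max(Mag-Z-S3, ·)`} at the HD
node.  An `"auto"` mode selects them from data: a candidate is kept iff it
flags at least one d1 training observation while flagging at most
⌊α·|D2|⌋ D2 training observations.

**Node order.**  Either explicit (default: HTFN, HTB, BC, HC, HD after the
HTBN root, ending at the PC leaf) or greedy: at each node every remaining
technique is tried as d1 and scored by the combined two-stage accuracy on
training rows, where filter-flagged rows count as claimed-d1 and the rest
are scored by the forest's out-of-bag vote.  Resubstitution accuracy is
degenerate here (forests memorise 100% of small training sets), and OOB is
the standard internal estimate that costs no extra split; k-fold CV would
be the obvious alternative but adds a nested split for no benefit at these
sample sizes.

**Prediction.**  Root threshold first; then at each node filter → forest;
if the final node rejects its technique the observation is labelled PC.
When a model needs an engineered `max(A, B)` feature that the incoming
table lacks, it is recomputed on the fly from the base channels rather than
erroring.

### Empirical p-values: the correction choice

`empirical_p_value` supports two conventions.  With the add-one correction
(its default), p_left = (#{v ≤ x}+1)/(m+1), p_right = (#{v ≥ x}+1)/(m+1),
two-sided p = min(1, 2·min(p_left, p_right)) — never exactly 0.  The
*filters*, however, default to the uncorrected empirical proportion
(#{...}/m).  The reason is arithmetic: the last two nodes have only m = 30
and m = 15 D2 training values, where the add-one two-sided minimum
2/(m+1) already exceeds α = 0.05, so a corrected filter could never flag
anything there and the two-stage procedure would silently degenerate to a
plain forest at exactly the nodes where filtering matters.  The uncorrected
tail p-value reaches 0 for an observation beyond the whole reference, which
is precisely the "extremely aberrant" event the filter is built to catch.
Sidedness defaults to two-sided (conservative; nothing in the problem
singles out a tail).

**Training-time interaction.**  Rows flagged by a node's filter during
training are excluded from that node's forest training set by default
(`exclude_flagged=False` restores them): extreme executions sit in awkward
regions of feature space and are already handled by the short-circuit.  If
exclusion would leave a single class, the forest falls back to all rows.

Note one deliberate consequence of the any-variable rule: with several
filtered variables and small references, a non-aberrant observation has a
non-trivial chance of landing beyond a whole reference on some variable
(~12% per variable at m = 15), so the last node trades specificity for
sensitivity.  This is inherent to the method, not a bug; disable filters or
reduce α to move along that trade-off.

## Evaluation protocol

Per technique, ⌊0.8·n⌋ subjects train and the rest test (19 → 15/4); the
whole cascade is refitted on each of 50 independent stratified splits, with
per-repetition RNG streams derived from (master seed, repetition index).
At node i, D1 is the node's technique and D2 the techniques still in play
by *true* label (so n1/n2 are fixed per node, 15/90 … 15/15 on training
splits); a `routed_metrics` flag instead scores only rows the fitted
cascade actually routes to the node.  From the counts n_ij (classified as
D_i, truly D_j): accuracy (n11+n22)/total, sensitivity n11/(n11+n21),
specificity n22/(n12+n22).  Zero-denominator metrics are reported as
missing, never coerced to 0, and excluded from means.  Aggregation is mean
and SD (ddof = 1) over repetitions; a single-repetition report carries a
caveat flag and SD 0.  Variable importance is the forest's impurity-based
mean decrease in Gini, normalised to sum 1 as scikit-learn reports it
(ranking is unaffected).

## Synthetic study generator

No public recording of this protocol exists, so the generator emulates the
statistical structure the cascade exploits.  Per channel j, subject k,
technique c:

    x_t = μ_{c,j} + b_{k,j} + r_t + ε_t

* b ~ N(0, subject_sd²) — subject-level offset (anatomy, sensor placement);
* ε ~ N(0, noise_sd²) i.i.d. — within-trial sampling noise; an AR(1)
  option with the same stationary variance exists behind `ar1_phi` but is
  off by default (channels are generated independently; no inter-channel
  covariance);
* r_t — deterministic linear ramp of amplitude `transient_amp` falling to 0
  over the first 180 timestamps and rising again over the last 180, so the
  stable window is untouched and windowing demonstrably matters.

Defaults: 19 subjects per technique, T = 600, subject_sd = 0.5,
noise_sd = 2.0, transient_amp = 5 (unitless signal units; feature-level
combined SD s = √(0.5² + 2²/240) ≈ 0.52).  Class structure: each deviation
is offset from PC by 4·s on three designated channels in the sensor region
that deviation plausibly disturbs (neck deviations on S1–S2 Euler channels,
hands-close on S5, pelvis/back on S4); HD is offset on its five designated
channels (Euler-Z-S3, Acc-X-S3/S4, Mag-Z-S3/S4).  HTBN's Euler-Y-S1 mean
additionally sits below every other class by `htbn_margin` (10) plus 6·s,
guaranteeing the threshold root.  Magnetometer and Euler-Z baselines differ
per sensor so max-features are non-degenerate.

With the default `hd_overlap=True`, the HD offset is reduced to 1.5·s — HD
and PC genuinely overlap — and 8 of the 19 HD subjects (deterministically
the first ids, exposed via `extreme_hd_subjects`) form an extreme component
shifted a further 8·s on the HD channels: the cases a tail filter should
catch, and the regime in which the filter ablation is meaningful.
`hd_overlap=False` separates HD like every other deviation (no extreme
component); that configuration backs the parameter-recovery check (every
node's mean test sensitivity ≥ 0.90 over 50 splits).

What passing on this generator does **not** show: robustness to
inter-channel correlation, non-Gaussian subject effects, drift within the
stable window, or sensor-mount differences — all absent by construction.
Thresholds fitted here (e.g. the Euler-Y-S1 cut) are specific to the
generator's scale, as any mount-specific threshold would be, and are never
hard-coded.

## Numerical and interface choices

* Channel order is fixed: sensor-major (S1..S5), then measurement
  (Euler, Acc, Gyr, Mag), then axis (X, Y, Z); names are
  `Measurement-Axis-Sensor` and round-trip through parse/format.
* Timestamps are 1-based inclusive throughout.
* Models persist as a single version-stamped JSON file embedding each
  decision tree's node table and leaf values; loading rebuilds native
  scikit-learn trees, so saved and loaded models predict identically at
  label level.  A truncated/foreign file or a different scikit-learn
  version raises `ModelVersionError` rather than guessing.
* Raw trials and feature tables are plain CSV (long or wide dialect);
  engineered column names keep their `max(A, B)` form verbatim.
* All randomness flows from explicit seeds; identical configs produce
  bit-identical datasets, models and reports.

## Problem sizes used in the shipped checks

The repeated-evaluation checks and the acceptance script run the full
protocol — 19 subjects × 7 techniques, 50 repetitions, 500-tree forests,
explicit reference order (a greedy search multiplies fitting cost ~4× for
identical structure on this generator and is exercised on small problems
instead).  Unit tests that only need a fitted object use 5 subjects per
technique and 15–200 trees.

## Known limitations

* The greedy order search scores candidates out-of-bag; with very small
  node samples OOB votes are noisy and the chosen order can vary between
  seeds on weakly separated data.
* The aberrance filter's false-flag rate at the last node is structural
  (see above); reported specificity there should be read with that in mind.
* `confusion_at_node` with chain membership evaluates each node on all rows
  of its true-label classes, including rows an earlier node would have
  absorbed; the routed alternative conditions on the fitted cascade and
  yields variable n1/n2.
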