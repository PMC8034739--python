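# Methods

## The measurement model

The atomic observation is a 60-second epoch carrying one METs estimate.
Wear-time behavior is classified purely by METs cut-points: sedentary
≤ 1.5, light > 1.5 to < 3.0, MVPA ≥ 3.0. Posture is not observed, so
"sedentary" here means low-energy wear time, and very static standing is
indistinguishable from sitting — a known device limitation that this
package inherits by design.

### Non-wear detection

Non-wear is inferred, not recorded: a window of at least 60 consecutive
epochs in which every epoch is ≤ 1.0 METs and at most two epochs exceed
0.9 METs (the "limited movement" allowance) is non-wear; an epoch above
1.0 METs always terminates a candidate window. The allowance is counted
per window, not per interruption — the stricter of the two possible
readings — and tolerated epochs are part of the marked interval.

The detector marks the union of all qualifying windows. Implementation
note: that union equals the union of qualifying windows of length
exactly 60, because any subwindow of a qualifying window inherits both
the ≤ 1.0 cap and the ≤ 2 allowance bound. The production scan walks
maximal runs of ≤ 1.0-METs epochs with a two-pointer over allowance
positions (O(n)); the test oracle independently enumerates length-60
windows. Consequences verified by property tests: every maximal marked
run is ≥ 60 epochs, and lowering any epoch to ≤ 0.9 METs can only grow
the non-wear mask.

### Windows, validity, eligibility

All metrics are computed on wear epochs in [06:00, 24:00), split into
morning [06:00, 12:00), afternoon [12:00, 18:00) and evening
[18:00, 24:00); an epoch belongs to the window containing its start
timestamp. Epochs before 06:00 participate in non-wear detection (a
sleep block can anchor a non-wear run) but never in metrics. The 10-h
valid-day wear rule is evaluated on 06:00–24:00 wear; whether the
original rule used full-day wear is not determinable, and the choice is
recorded here rather than made configurable silently. A sedentary break
is a wear-SB epoch immediately followed by a wear-non-SB epoch;
transitions into non-wear are not breaks, and the break belongs to the
period containing the non-SB epoch. Scopes with zero wear yield missing
(not zero) percentages; zero sedentary minutes yield a missing break
rate, excluded from group means.

## Variation-level features

The feature of day type *d* and period *p* is
100 · SB%_{dp} / SB%_{d}: sedentary share of wear in the period,
relative to the whole day. The ratio cancels participant-specific wear
patterns (late risers lose morning wear, not morning features).

Aggregation across days uses pooled minutes by default: sum wear and
sedentary minutes over contributing days, then take ratios. Period
numerators pool over period-valid days; the whole-day denominator pools
the same period-valid days, which makes the wear-weighted mean of the
three features within a day type *exactly* 100 (an algebraic identity,
asserted to 1e-9). Day-type summaries used for profiling pool whole-day
quantities over all valid days, matching how group means are usually
reported. The alternative convention — average per-day ratios — is
implemented behind `convention="daily_mean"`; it weights a 4-hour day
equally with a 14-hour day and breaks the identity, so it is not the
default. Features are not standardized before clustering: all six share
the ~100% scale.

## Two-step clustering

Ward's method (classical minimum-variance agglomeration; merge costs
are within-SS increments, computed as h²/2 from the Lance–Williams
distances) builds the dendrogram. Heights are non-decreasing and
telescope to the total sum of squares (asserted at 1e-6 relative).

The number of clusters is chosen by the largest relative gap
height(k−1)/height(k) between successive merge costs within [2, 8] —
the numeric analogue of eyeballing the dendrogram for the last cheap
merge; ties break to the smaller k, and a degenerate tree (all-zero
heights) returns k_min with a warning. The rule is overridable (`--k`),
which matters in practice: on mixtures parameterized from the published
typology profiles, where two of the four components are separated
mainly along one dimension, the dominant dendrogram gap is frequently
the 2-cluster cut, and the rule selects k = 4 in only a minority of
simulated cohorts. This is a property of the gap heuristic on
overlapping mixtures, not of the Ward tree.

k-means refinement is a deterministic Lloyd iteration seeded with the
means of the k Ward clusters: assign to the nearest centroid (Euclidean;
ties to the lowest cluster index), recompute means, stop when
assignments are unchanged (≤ 100 iterations). A cluster emptied during
iteration is re-seeded with the point farthest from its current
centroid. There is no stochastic initialization anywhere in the
pipeline; the only randomness in the package lives in the synthetic
generators. On well-separated data the Ward partition is already a
fixed point (verified); on small clusterable instances the two-step
within-SS matches exhaustive best-partition search ≥ 95% of the time
(Ward+Lloyd is a heuristic, and on pure noise its local optima miss the
global 2-partition optimum in roughly a quarter of instances — the
property is asserted where cluster structure exists, which is the
regime the method is for).

For recovery experiments, clusters are matched to reference archetypes
by exhaustively minimizing the summed centroid–archetype distance over
all k! assignments (k ≤ 8).

## Profiling statistics

One-way ANOVA is the classical F = MSB/MSW with (k−1, N−k) degrees of
freedom; post hoc comparisons are two-sided t tests on the pooled MSW
with df = N−k, p multiplied by k(k−1)/2 and capped at 1 (the
pooled-variance Bonferroni convention of mainstream statistical
packages). `anova_from_summary` reproduces the identical F from group
means/SDs/sizes (SSB from means, SSW = Σ(n−1)s²) — useful for
verifying printed summary tables — and round-trips against the raw-data
ANOVA to 1e-9.

The χ² test is plain Pearson without continuity correction; adjusted
standardized residuals are (O−E)/√(E(1−row/N)(1−col/N)) with |r| > 1.96
flagged. No small-expected-cell correction is applied: the published
participant-characteristics p-values (0.019, 0.016, 0.002, 0.894, and
the 3.08 residual) reproduce exactly under plain Pearson even though one
table contains an expected cell below 5. No multiplicity control is
applied across variables, only Bonferroni within a variable's pairwise
comparisons. Formatting follows the field convention: percentages to
1 d.p., p to 3 d.p., "<0.001" below 0.0005.

## The synthetic cohort generator

The generator encodes the study design: 229 participants, mixture
weights 107/61/19/42 over four archetypes, a 7-day protocol (5 workdays
+ 2 non-workdays), wake windows ~06:30–23:00 (truncated-normal start/end
clipped to [06:00, 24:00), SDs 30/40 min), and Poisson device-off gaps
(0.3/day, 75 min — long enough for the detector to find).

Each archetype is a map (day type × period) → target sedentary fraction
of wear, with a between-person SD. The four defaults are parameterized
from the published cluster profiles: variation-level means and SDs per
period (the one period per day type whose mean is not printed is
recovered from the constraint that the three period means average to
~100; its SD is the mean of the two printed SDs), scaled by the
published whole-day SB%-of-wear per day type. The feature-level
generator draws the six features independently per dimension from
normals with the archetype's implied means/SDs (the same numbers the
sedentary-fraction targets imply, by construction).

The epoch-level generator alternates sedentary and active bouts as a
two-state minute-resolution Markov chain (geometric bouts — the
discrete memoryless analogue of exponential bout lengths, giving the
closed-form stationary sedentary fraction L_sed/(L_sed+L_act)). Per
period the bout-length pair is scaled to hit the participant's target
fraction exactly while keeping the archetype's cycle length
(sedentary + active bout means, defaults ~6–7.5 and ~4–4.7 min,
matched to published break rates of 8–10/sedentary-hour); where a bout
mean would fall below one minute, both are inflated together so the
ratio — and hence the stationary fraction — is preserved. Sedentary wear
epochs emit METs in (1.02, 1.5] — strictly above the non-wear allowance
band, so worn time is identifiable from the stream; active epochs emit
(1.55, 2.95) or ≥ 3.0 with the archetype's MVPA share; device-off and
sleep minutes emit ≤ 0.9. Each participant gets an independent RNG
stream keyed by (seed, participant index), so enlarging a cohort never
reshuffles existing participants and fixed seeds give bit-identical
output.

What the generator does *not* emulate: raw tri-axial accelerations and
the device's METs regression, posture, circadian METs drift within a
period, day-to-day habit correlation beyond the participant-level
propensities, and item-level questionnaire responses. Passing tests
therefore demonstrate that the pipeline recovers structure that is
present in the stated form — period-wise stationary sedentary
propensities — not that real cohorts satisfy that form.

## Problem sizes and numerical choices

Recovery experiments use cohorts of n = 229 over 20 seeds
(feature-level) and single cohorts of 42 / 19 participants
(epoch-level), the sizes of the groups they emulate; with the published
between-person SDs, the cohort mean of a variation-level feature at
n = 19 carries a seed-to-seed SD of ~3.5 points, which bounds how
tightly epoch-pipeline fidelity can be asserted. Exact identities are
asserted at 1e-9 (feature normalization, ANOVA round trip), structural
identities at 1e-6 relative (Ward telescoping), and printed statistics
at their printed precision. Degenerate inputs are handled explicitly:
all-identical rows give zero-height trees (k selection warns and
returns k_min), zero-wear scopes give missing values, zero-margin
contingency tables and single-level covariates are errors/skips with
logs, and sedentary targets of exactly 0 or 1 are rejected as
degenerate chains.

## Known limitations

* k selection by the relative-gap rule is unreliable when mixture
  components overlap along few dimensions (see above); fixing k from
  substantive knowledge is the supported path.
* The epoch generator's cohort-mean variation levels carry a small
  upward ratio bias (~1–2 points at the published noise levels) because
  the feature is a ratio of noisy pooled quantities.
* SPSS's exact Ward and k-means update order are not reproducible
  bit-for-bit; equivalence is asserted at the level of invariants
  (merge-cost oracle, fixed-point, recovery), not implementation.
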