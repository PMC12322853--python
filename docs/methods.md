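# Methods

This note documents the models, numerical choices and design decisions
behind `pymacbeth`, and what the synthetic-data experiments do and do not
demonstrate.

## The MACBETH elicitation LP

A judgment matrix holds, for item pairs `(i, j)` with `i` not less
attractive than `j`, one of seven semantic categories: 0 (no difference)
through 6 (extreme difference). The engine searches for item values
`v_i ≥ 0` and category thresholds `t_1 < … < t_6` satisfying

- `t_1 ≥ δ` and `t_{k+1} ≥ t_k + δ` with spacing `δ = 1`;
- category `k ∈ 1..5` on `(i, j)`: `t_k ≤ v_i − v_j ≤ t_{k+1} − δ`;
- category 6: `v_i − v_j ≥ t_6`;
- category 0: `v_i = v_j` (indifference is exact equality on a cardinal
  scale, the classic MACBETH reading).

*Consistency* is feasibility of this system (solved with HiGHS via
`scipy.optimize.linprog`). Because only inequalities with a free global
scale are involved, the particular value of `δ` is immaterial to
feasibility; it only fixes the units of the raw solution.

*Canonical solution.* The system usually has infinitely many solutions, so
the derived scale is pinned down in stages: first minimize the maximum
item value, then lexicographically minimize the item values (in item
order) and finally the thresholds. Each stage locks the previous optimum
with an upper bound at `optimum + 1e-6`; the slack must exceed the
solver's feasibility tolerance (1e-7) or later stages become spuriously
infeasible. The final solution is rounded to 6 decimals to snap off that
slack; canonical solutions of integer-structured systems are integral in
practice, so the rounding is exact there. The result is deterministic:
repeated calls return bitwise-identical scales.

*Anchoring.* `derive_scale(matrix, top, bottom)` affinely maps the raw
solution so `top → 100` and `bottom → 0` (thresholds are difference
quantities and are scaled, not shifted). The anchors must be admissible:
`top` may not be judged less attractive than any item, `bottom` not more
attractive than any item, and their derived values must differ. Values of
unanchored items are clamped into `[0, 100]`; with admissible anchors the
clamp only removes numerical noise. Equality and anchor checks use a
tolerance of 1e-9 on the 0–100 scale.

*Inconsistency witness.* When infeasible, every judgment's constraints are
relaxed by a shared non-negative slack and total slack is minimized; the
judgment with the largest slack is removed and the loop repeats until the
remainder is feasible. The removed set is the witness. This greedy
primal-slack procedure is a heuristic — the exact minimum-cardinality
witness is combinatorial — but it always terminates with a repairable
diagnosis, and removing a judgment can never create a new inconsistency.

*Missing judgments* are simply unconstrained pairs; complete matrices are
not required.

## Performance reference levels

For a numeric criterion with observed comparator performances, the five
levels are, writing `lo`/`hi`/`med` for the minimum, maximum and median:

- harm criteria (lower performance better): `L1..L5 = (0.8·lo, lo, med,
  hi, 1.2·hi)`;
- benefit criteria: `(1.2·hi, hi, med, lo, 0.8·lo)`.

Conventions where the rule under-determines the answer: the median of an
even-sized sample is the midpoint of the two central order statistics
(continuous levels are preferable for interpolation breakpoints); if the
median coincides with an extreme (heavily skewed samples) `L3` is moved to
the range midpoint to keep the levels strictly ordered. A zero-width range
is a degeneracy error — five distinct levels cannot exist. The ±20 %
bracketing reads "20 % beyond the extreme" multiplicatively (`0.8·lo`,
`1.2·hi`), the only reading that brackets the data; it consequently fails
to produce strictly ordered levels when an extreme is 0 or negative, and
the constructor rejects such inputs rather than silently bending the rule.
Categorical criteria (dosage and administration; number of alternative
medicines) do not use this rule: their five levels are enumerated category
labels supplied in configuration.

## Value functions, weights, scoring

A numeric value function is the piecewise-linear interpolant through the
five `(level, scale value)` breakpoints with `v(L1) = 100`, `v(L5) = 0`
and weakly monotone values. Performance outside `[L5, L1]` is **clamped**
to 0/100 rather than extrapolated: the function is only elicited over the
reference range, and clamping keeps every overall score in `[0, 100]`.
Categorical functions are explicit category → value maps.

Swing weights come from a MACBETH scale over `n + 1` hypothetical
alternatives: one per criterion at its upper level with all others lower,
plus an all-lower baseline fixed at scale value 0 (the standard reference
profile). The weight of criterion `j` is proportional to its swing's scale
value and normalized to sum to one. Scaling all raw scale values leaves
the weights unchanged. For stakeholder groups, scales and weights are
derived per stakeholder and arithmetically averaged afterwards.

The additive model then scores a therapy as `Σ_j w_j v_j(x_j)`.

## The packaged lymphoma framework

The packaged model carries the nine published mean stakeholder weights
(stored as basis points of 1 so they sum to exactly 1 after
normalization). Only one value-function fact is published: the mPFS
segment `v = 1.58·x + 20.75` around 25.7 months. The packaged mPFS
function places that exact line on the 20–30 month segment (52.35 value
points at 20 months, 68.15 at 30); the outer breakpoints are configuration,
flagged as such, and every other value function is flagged `placeholder`
— plausible reference levels with equally spaced values, intended to be
replaced by re-elicitation. Direction conventions: mortality of disease is
treated as a benefit-direction severity criterion (treating a deadlier
disease contributes more value); this is a packaging choice, not a
published fact.

The criteria-selection replay ships the 25 candidate criteria in their
published importance ranking. Per-rater scores were never published, so
the attached mean scores are synthetic, linearly spaced so that exactly
the first 18 clear the 3.5 threshold; the replay demonstrates the
selection *procedure* and its published outcome (18 retained, 9 final),
not the survey data. The filter excludes scores `≤ 3.5` (boundary
inclusive on the exclusion side).

## Inter-rater reliability

The ICC is computed from the two-way ANOVA mean squares with items as
targets and raters as the second factor, in the two-way random-effects,
absolute-agreement form: `ICC(A,k) = (MSR − MSE) / (MSR + (MSC − MSE)/n)`
for the average of `k` raters (the panel-level figure reported by
default), with `ICC(A,1)` behind a flag. This form fits the design —
every rater rates every item, raters are a sample, and systematic rater
disagreement should count against reliability. Confidence intervals use
the McGraw–Wong F construction with Satterthwaite degrees of freedom,
stepped up to the average-measures form via Spearman–Brown. A panel with
no between-item variance raises a degeneracy error; a perfectly agreeing
panel returns estimate 1 with a collapsed interval. Interpretation bands:
below 0.4 poor, above 0.75 good, otherwise moderate.

## Synthetic data: what it emulates and what it does not

`generate_consistent_judgments` bins true value differences with fixed
thresholds (default: seven equal categories over a 0–100 span) to emulate
a perfectly coherent stakeholder; `perturb_judgments` moves each judgment
±1 category with probability `p`, the minimal ordinal error model;
`generate_rater_panel` adds iid Gaussian noise to true item means (no
systematic rater effects); `generate_performance_table` draws uniform
performances. All generators are seeded and byte-reproducible.

One constraint is inherent: two *distinct* true values closer than the
first threshold would bin as "no difference", and since indifference means
exact equality on a cardinal scale, such a matrix can be inconsistent
(the tied pair relates differently to third items). The generator
therefore rejects truths with `0 < |Δv| < t_1`; tie items exactly or
separate them by at least one category width.

Passing tests on these generators show that the engines invert their own
noise-free generative model and degrade monotonically under ordinal noise.
They do not show that real stakeholder panels are well described by
independent ±1 category errors, that real rater noise is homoscedastic
Gaussian without rater main effects, or that real drug performances are
uniform — so quantitative error rates on synthetic panels should not be
read as forecasts for field elicitations.

## Problem sizes and tolerances in the test suite

The oracle-equivalence check compares LP feasibility against exhaustive
enumeration (integer value grids 0..24, greedily constructed unit-spaced
integer thresholds — an exact search for matrices of up to four items) on
5000 sampled matrices. Weight recovery uses 500 perturbation seeds per
flip probability (0, 0.2, 0.5), repairing inconsistent matrices by
removing the witness before re-deriving. ICC calibration uses 1000
replicates of 5-rater × 50-item panels; the acceptance band of 0.01
around the theoretical ICC covers Monte-Carlo error plus the O(1/n)
small-sample bias of the ratio-of-mean-squares estimator. Weight-sum and
additivity identities are checked to 1e-9; scale equalities to 1e-6
(the lexicographic lock slack bounds attainable precision).

## Known limitations

- The witness set is greedy-minimal, not provably minimum-cardinality.
- The canonical LP objective is this package's choice for determinism;
  other MACBETH implementations may return different (equally valid)
  representative scales, so derived values should be compared across tools
  only up to the feasibility bands, not digit for digit.
- The reference-level rule assumes strictly positive observed ranges.
- The packaged model's placeholder value functions make absolute overall
  scores illustrative only; rankings driven mostly by mPFS and the weights
  are meaningful, full valuations require re-elicitation.
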