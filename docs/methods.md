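# Methods

This note documents the model implemented by `qbe`, the parameter choices
that matter, the numerical conventions, and the limits of what the bundled
tests demonstrate.

## The scoring model

An evidence item is the scored residue of a (phenomenon, observation,
argument) triple: the free-text argument itself is out of scope, only its
ordinal assessment is stored.

* **A-score** — argument quality, four ordinals:
  `rejected < coherent_untestable < coherent_testable < accepted`.
  `rejected` is modelled as a real ordinal that is filtered at
  quantification time, not at parse time, so datasets can archive rejected
  claims and re-score them later (e.g. after engaging the original
  authors, or when a new paradigm makes a previously untestable claim
  testable). Rejected items are skipped silently and counted in a log line.
* **R-score** — replication robustness, three ordinals by default
  (`low < medium < high`); any number ≥ 2 of ordered labels is supported
  structurally.

Count matrices are oriented rows = R-score (high, medium, low
top-to-bottom), columns = A-score (accepted, coherent_testable,
coherent_untestable left-to-right). `expand_matrix` inverts `count_matrix`
with deterministic phenomenon labels `<theory>_<a>_<r>_<index>`, so a
published count table is a complete, reproducible input.

## From ordinals to numbers: anchored sweeps

Ordinal scores become numeric values via anchored scales. Both default
scales run 1–10 (A-values in percent, R-values in hundredths): the lowest
non-rejected ordinal is pinned to the anchor minimum, the highest to the
anchor maximum. The value of a middle ordinal is deliberately never fixed.
Instead the quantification enumerates **every** strictly increasing integer
assignment from the open anchor interval — with one middle per scale that
is {2, ..., 9}, i.e. 8 assignments per scale and an 8 × 8 = 64-point grid;
with m middles on a span s it is C(s−1, m) assignments (two middle ordinals
on 1–10 give C(8,2) = 28). Refusing to pick a middle value is the method's
answer to arbitrariness: no individual's weighting enters the comparison.

## The updating mechanism

Each theory starts from the uniform prior π = 1/`theory_count`. The default
`theory_count` of 25 is a deliberately conservative count of viable
contemporary theories, giving π = 0.04; the exact value is inconsequential
for comparisons as long as every theory shares it (multiplicative
posteriors are exactly linear in the prior — a tested invariant). For each
grid point, the update is folded over the non-rejected items in input
order:

* **multiplicative** (default): `p' = p · (1 + a/100) / (1 − r/100)` with
  `a` the item's A-value and `1 − r/100` the marginal. The fold is a
  commutative product, so posteriors are order-invariant and equal
  `prior · Π_cells ((1 + a/100)/(1 − r/100))^count` — the closed form used
  as the test oracle. The cumulative multiplication favours theories with
  many items; this bias is inherent to the mechanism and documented rather
  than corrected.
* **additive**: `p' = (p + a/100) / (1 − r/100)`. Only the likelihood
  operation changes; whether the additive variant should also divide by the
  marginal is genuinely open, and retaining the division was the design
  choice here so the two mechanisms differ in exactly one operation.
  Additive updating is order-dependent; items are processed in input order.

The rule is Bayes-*inspired* bookkeeping, not a normatively correct
posterior: nothing forces the result to stay in (0, 1). Per a strict
reading of the scaling constraint, bounds are checked after **every step**,
not only at the end. The default `bound_policy="warn"` records violations
and continues (so comparisons stay computable), `"error"` aborts with the
offending assignment and step index, `"ignore"` records nothing.
Posteriors are accumulated in double precision; at these magnitudes
(≤ 40 factors of at most 1.1/0.9) no log-space accumulation is needed.

## Comparison statistics

Grid summaries per theory: arithmetic mean and **n−1 sample SD** (the
sample-variance convention is what reproduces the published demonstration
SDs; the population convention does not). Cross-theory:

* **Ratio matrix** — pairwise ratios of *unrounded* means, diagonal
  undefined. The published demonstration table mixes rounded and unrounded
  inputs across cells; unrounded is used throughout for internal
  consistency, which reproduces the A/B cell at 4 d.p. and the remaining
  cells at 3 d.p.
* **Z-scores** — each theory's mean against a pool, default every grid
  posterior of every theory pooled (`all_posteriors`), optionally the
  theory means themselves (`theory_means`, which centres the z-scores to
  zero).
* **Welch t-tests** — unequal-variance t on the grids (scipy), one- or
  two-tailed. *Caveat*: the 64 grid points are a deterministic sensitivity
  sweep, not independent draws, so p-values are descriptive summaries of
  grid separation, not sampling probabilities. No multiple-testing
  correction is applied across pairs.
* **AUC** — trapezoid area under the ascending sorted-posterior curve over
  the unit interval, `(v₁/2 + v₂ + ... + v_{n−1} + v_n/2)/(n−1)`. It
  differs from the mean by at most `(v_max − v_min)/(2(n−1))`. Finer
  integral-based refinements are out of scope.

Comparison refuses to mix posterior sets whose configuration hashes differ,
so theories quantified under different mechanisms, priors or scales can
never be compared silently.

## Synthetic data generator

No complete scored compilations of real evidence exist yet, so
demonstrations run on synthetic fields. Per theory the generator draws an
item count uniformly from [20, 40] and each item's scores independently
from categorical weights. The default weights are the pooled empirical
score frequencies of the four bundled demonstration matrices —
a = (0.06, 0.45, 0.49) over (accepted, coherent_testable,
coherent_untestable) and r = (0.15, 0.50, 0.35) over (high, medium, low) —
so the highest ordinal is the rarest, reflecting that knock-down evidence
is currently scarce. A master seed with a per-theory sub-stream
(`default_rng([seed, index])`) makes each theory individually reproducible
and prefix-stable when the field grows.

What the generator does **not** emulate: correlations between A- and
R-scores, theory-specific score profiles, replication counts, or argument
text. Passing tests on generated fields therefore demonstrate numerical
correctness and pipeline robustness, not that the method discriminates
real theories.

## Calibration of R-score ordinals

The number of R-score ordinals and their thresholds can be mined from a
corpus of per-phenomenon replication counts instead of being decreed. In
one dimension the optimal within-SS partition is contiguous on the sorted
values, so `cluster_1d` computes the **global optimum by dynamic
programming** (vectorised O(k n²)) — deliberately replacing Lloyd-style
k-means, whose initialisation arbitrariness is precisely the concern the
calibration exists to remove. Thresholds are placed at the midpoint between
adjacent cluster extremes; a count equal to a threshold belongs to the
upper ordinal (half-open convention).

The cluster count is selected by a BIC-style Gaussian score: per-cluster
means and mixing proportions with a shared variance W/(n−k), penalised by
2k·ln n (the criterion family behind x-means). The score is
scale-equivariant, so rescaling the counts never changes the chosen k. A
zero within-SS (every cluster a single distinct value) is floored at a
scale-proportional epsilon to keep the score finite. The selection
criterion is one reasonable choice among several; the published sketch
commits to none.

## Problem sizes and determinism

The demonstration reproduction (4 theories × 64 grid points × ≤ 26 items)
runs in milliseconds. The test suite's heavier components are sized to stay
statistically meaningful at small cost: the generator's distributional
check uses 10,000 items (chi-square at α = 0.001), the clustering
parameter-recovery check uses 200 seeded trials of 3 clumps × 25 points at
10-SD separation, and the DP-optimality check compares against a few
thousand random contiguous partitions. Every stochastic component is
seeded; `(seed, config)` fully determines all outputs, and run manifests
record config hashes and input digests so identical manifests imply
identical results.

## Known limitations

* The updating rule is a proof-of-concept bookkeeping device; its absolute
  posteriors have no calibrated probabilistic interpretation — only the
  *comparison* between theories sharing a configuration is meaningful.
* A-score assignment itself is a human judgement; the package stores and
  propagates scores, it cannot audit them.
* The additive mechanism's marginal treatment and the cluster-selection
  criterion are documented design choices, selectable but not settled.
* Extension scales (e.g. physical/functional closeness, distribution of a
  phenomenon across subjects) are structurally supported via additional
  `OrdinalScale`s but no semantics are provided for them.
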