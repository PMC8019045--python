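# Methods

This note documents the models and conventions implemented in `multisoc`,
the design of the synthetic-society generator, the numerical choices, and
what the test suite does and does not demonstrate about real field data.

## Association indices

A scan's *presence set* is the focal unit plus its recorded associates;
presence means membership of the focal-centered aggregation at scan time,
and associations are never chained across scans. For a dyad (A, B) over a
set of scans, N_AB counts scans containing both, N_A-only and N_B-only
scans containing exactly one. The simple association index is

    AI = N_AB / (N_AB + N_A-only + N_B-only),

i.e. joint sightings over the *union* of sightings. Two denominator
conventions circulate for this index: the union above, and the raw sum
N_AB / (N_A + N_B), which counts joint scans twice and caps the index at
0.5. Only the union form satisfies the usual anchors (1 = always
together, 0 = never together), so it is the default; the raw-sum form is
available via `simple_ai(..., denominator="sum")` for sensitivity
analysis.

A dyad whose members were never sighted has no data: its AI is flagged
undefined (NaN), treated as 0 when building trees and networks (absence
of evidence of association), but excluded from CV computations (absence
of data is not evidence of identical association). Unit identifiers are
case-sensitive opaque strings. The 2-hour scan-interval independence rule
is the collector's responsibility; the reader only warns when two scans
of the same focal sit closer than 2 h.

## Clan clustering

Agglomerative clustering runs directly on the similarity (AI) scale: the
most-similar pair of clusters merges and the merge height is that
similarity, so the field-standard clan cut (AI ≥ 0.05) applies directly
to merge heights. Cluster-to-cluster similarity follows the linkage rule
(average = size-weighted mean, complete = least-similar cross pair,
single = most-similar cross pair). Ward's method uses the Lance–Williams
recurrence on d = 1 − AI without checking Euclidean embeddability — the
common practice in this literature's toolchains — and its heights map
back as 1 − d, which can leave the similarity scale for late merges;
Ward trees are therefore compared by CCC but the 0.05 cut is only
meaningful on the similarity-scale linkages. Merge-order ties break on
the lexicographically smallest cluster-name pair, making trees
deterministic.

The cophenetic correlation coefficient is the Pearson correlation between
observed dyadic AIs and cophenetic *similarities* (the height of the
dyad's lowest common merge) over defined dyads; correlating similarities
with similarities keeps the sign positive for a good fit. Linkage
selection evaluates all four linkages and takes the highest CCC, ties
resolving in the fixed order average, Ward, complete, single.

`compare_partitions` reports the adjusted Rand index over shared units
plus a minimal set of "moved" units, found by greedily removing the unit
with the most pairwise co-membership disagreements until the partitions
agree — so a single unit that switched clans is reported alone rather
than dragging its former clanmates into the list.

## Preferred/avoided association

The test statistic is the coefficient of variation of the defined dyadic
AIs (population SD over mean by default; the sample-SD variant is an
option). The null is generated by Bejder-style sequential data-stream
swaps: pick two scans, pick one associate from each such that neither
already occurs in the other scan's presence set, and exchange them.
Every accepted swap preserves the number of scans, each scan's group
size, and each unit's total sighting count; focal units never leave their
own follows. After 1,000 accepted burn-in swaps, one permuted dataset is
taken every 100 accepted swaps (both configurable). The p-value is
right-tailed with the add-one estimator (k + 1)/(n + 1): high observed CV
relative to the swap null indicates preferred/avoided companionship.

Swaps are unconstrained across days by default. A within-day constraint
(`constraint="day"`) exists for designs that sample several groups per
day, but under a one-focal-unit-per-day design all of a day's scans share
the focal, so within-day swaps merely shuffle one focal's associates
among that day's scans and leave dyadic preference essentially intact (on
clan-structured simulations the CV moves by < 1% after 1,000 such swaps);
that null would have no power by construction.

A node-label scheme (joint row/column permutation of unit labels over the
association matrix) is also provided. The global CV depends only on the
multiset of dyad values and is invariant under relabelling, so with the
default statistic this scheme returns p = 1 by construction; it is
intended for label-dependent statistics supplied via the `statistic` hook
(e.g. `within_partition_statistic`, the within-minus-between clan mean AI
for a candidate partition).

The chance-encounter band for windowed edge density runs the same swap
chain within each window and takes the 2.5th–97.5th percentiles of
permuted density; observed density above the band indicates more
connected aggregation than chance encounter under preserved
gregariousness.

## Temporal networks

Windows are half-open `[start, start + window_days)` tiles shifted by
`shift_days` (both default 31), with incomplete trailing windows dropped;
over the emulated 624-day study span (2017-08-28 to 2019-05-13) this
yields exactly 20 networks. Edge presence means AI > 0 (a configurable
threshold exists); degree, edge density and the clustering coefficient
use the binarized graph — the clustering coefficient is global
transitivity, 3 × triangles / connected triples, with a weighted
(geometric-mean) variant as an option — while strength sums raw AI
weights. Cosine similarity between two networks is the normalized dot
product of edge-weight vectors over the union of their dyads (zero-weight
padding is a no-op), 0 when either network is empty, clipped to [0, 1]
with float noise rounded at 1e-12 so identical networks give exactly 1.

Bootstrap uncertainty resamples a window's scans with replacement,
rebuilds the network, and reports the 95% highest-density interval over
(default) 100 replicates. Note that presence-type statistics such as edge
density are biased low under scan resampling (a bootstrap replicate
misses ~1/e of the distinct scans, dropping rarely-realized dyads), so in
saturated windows the interval can sit below the point estimate — the
interval describes resampling variability, not a debiased estimate.

Window-size selection formalizes "maximize variability in edge density":
for each candidate size, signal = variance of density across windows,
noise = mean within-window bootstrap variance; the candidate maximizing
signal/noise wins, ties toward the smallest candidate (a raw-variance
criterion is available).

## Ecological covariates and models

The food availability index for a month and plant-part group is
Σ_species (mean phenology score of that species' surveyed trees, 0–4) ×
(species basal area, m²). "Fruit" pools ripe and unripe fruit with equal
weight; "young_leaf" uses young leaves only. A species-month with no
records is flagged missing and contributes 0 with a warning — the
additive index treats it like a non-bearing tree — rather than
propagating missingness. Covariates are z-scored with the population SD
over analyzed months; pairwise predictor correlations above |r| = 0.7
trigger a multicollinearity warning.

The network-level model is y_t = β₀ + X_t β + ε_t with stationary AR1
errors ε_t = φ ε_{t−1} + η_t, η ~ N(0, σ²), fit by exact Gaussian ML:
given φ the data are whitened (first row scaled by √(1−φ²), the rest
quasi-differenced), β and σ² solve in closed form, and the concentrated
likelihood is optimized over φ ∈ (−0.999, 0.999). With φ = 0 the fit *is*
OLS; the statsmodels ARIMA(1,0,0)-with-exogenous fit maximizes the same
likelihood and serves as an independent cross-check in the tests. An
optional ridge penalty on the slopes (iterated to the MAP under
independent N(0, 1/λ) slope priors on the standardized predictors)
provides the shrinkage a weakly-informative-prior Bayesian fit would;
estimation here is ML throughout, not MCMC.

The node-level model adds a unit random intercept, b_i ~ N(0, τ²), with
each unit's residual series independently AR1 (correlation φ^|t₁−t₂| on
window indices, so gaps decay correctly). The likelihood is profiled over
β by GLS and optimized over (atanh φ, log τ, log σ) with Nelder–Mead;
coefficient CIs come from the GLS covariance at the optimum, and the
reported "error" is that ML standard error. Units with fewer than 3
usable rows are dropped with a warning; windows with undefined metrics
drop listwise.

R² is var(fitted)/(var(fitted) + var(residual)) on the fixed-effect fit
(the Gelman variance-explained definition), with a percentile interval
from 200 parametric-bootstrap refits simulating from the fitted
generative process.

## Dispersal analysis

The dispersal month is the calendar month holding the most days of the
inclusive last-seen/first-seen range, ties to the earlier month (so a
range shrunk within the winning month never changes the assignment).
Monthly male transfer counts (females excluded, each male of a parallel
transfer counted) are correlated with each ecological series by Spearman
rho on mid-ranks; the two-sided p is the add-one fraction of Monte-Carlo
permutations with |rho| at least the observed — appropriate because
zero-transfer months tie heavily. Bonferroni over the three predictors
gives the display threshold α = 0.05/3 → 0.017.

Post-dispersal association: for each dyadic event (parallel transfers
collapse to one event) and offset month 1–3, the dyad's AI in the offset
month is compared against baseline AIs — for each involved unit, its AI
(evaluated in the same offset month) with every third unit it associated
with (AI > 0) during the transfer month; the control *set* is fixed at
the transfer month and reused across offsets. The one-sample Wilcoxon
signed-rank test (one-sided: dyad higher) is exact — full enumeration of
sign assignments — up to 15 non-zero differences, and uses the
tie-corrected, continuity-corrected normal approximation above that.
Offsets beyond the data, empty control sets, and all-zero differences are
flagged rather than tested.

## The synthetic-society generator

The generator emulates the sampling design the pipeline consumes: one
focal unit per day in round-robin, 5 scans/day at 2 h spacing from 07:00,
and for each non-focal unit an independent Bernoulli draw

    p = logistic(β₀ + β_clan·[same clan] + β_fruit·z(fruit)
                 + β_bond·2^(−Δdays / half-life)),

where the bond term applies to dyads linked by a dispersal Δ days
earlier. Dispersal counts per month are Poisson with expectation
rate·exp(coef·z(fruit)); origins and destinations are uniform over
distinct pairs and date ranges span ≤ 14 days. Ecological series are
sinusoids with two peaks per year (two rainy seasons) plus relative
Gaussian noise, clipped at zero, with per-series phase offsets (fruit 0,
young leaf +2, rain +4 months) so the three covariates are only
moderately correlated (|r| ≈ 0.5 before noise) — staggered phenology, not
a single shared cycle. Phenology tables are emitted as Binomial(4, q)
scores per tree with q proportional to the target series, so the FAI
reconstructed downstream tracks the intended series linearly (covariates
are z-scored, so only proportionality matters).

Default study conditions: two clans of six units, 624 days (21 months),
β₀ = −3 (cross-clan association p ≈ 0.047), β_clan = 2 (within-clan
p ≈ 0.27), β_fruit = 0.5, bond half-life 45 days, dispersal rate
0.4/month (≈ 9–10 males over 21 months) with fruit coefficient 1.5.
Presets pin the regimes the analyses are validated on:

- `nabugabo_like`: 13 units — two 6-unit clans plus a one-unit "clan"
  that models a loosely attached all-male unit — over the 21-month span.
- `strong_clan`: β₀ = −4, β_clan = 2, 150 days. The lower baseline keeps
  mean cross-clan AI (≈ 0.02) clearly below the 0.05 clan cut; at
  β₀ = −3 cross-clan AI (≈ 0.04) sits on the cut boundary and the
  dendrogram cut would not reflect a society whose clans resolve at that
  threshold.
- `null_society`: all structure effects zero, β₀ = −1 for realistic
  group sizes — the type-I-error regime.
- `bond_preset`: β₀ = −5, β_clan = 3, β_bond = 10, one cross-clan
  dispersal mid-way through 7 months. The half-life fixes the
  month-to-month bond decay at ×0.63, so the dyad's elevation can only
  return to baseline by month 3 if the control pool is tight: the sharp
  society makes chance cross-clan controls rare, the month-3 logit bump
  (β_bond × 0.24 ≈ 2.4) lands near the clan effect — ordinary clan-level
  association — while month 2 sits ≈ 1.4 logits above it. This is the
  calibrated regime in which elevated association is detectable at
  offsets 1–2 and gone by offset 3.

What the generator does *not* emulate: explicit 50 m spatial geometry
(association is pairwise-independent Bernoulli, not spatial aggregation,
which under-disperses group sizes relative to true spatial clustering),
within-unit individual behavior, observation gaps (every day is a follow
day, unlike real fieldwork's 243 observation days over the span), female
dispersal, and unit fission/formation. Passing tests therefore show the
*methods* behave correctly — calibrated nulls, recoverable known
structure, nominal interval coverage — under the stated generative
assumptions; they do not certify effect sizes or significance patterns in
any real dataset.

## Numerical conventions and degenerate inputs

- Population SD throughout (CV, z-scores) unless a `ddof`/option says
  otherwise; conventions are fixed and documented rather than inferred.
- Add-one permutation p-values, so p ∈ {1/(n+1), …, 1}; permuted values
  tie with the observed at 1e-12 tolerance.
- Undefined quantities (never-sighted dyads, zero-variance CCC inputs,
  transitivity without connected triples, bands in scan-less windows) are
  NaN flags, not exceptions; genuinely impossible requests (CV of a
  zero-mean matrix, Spearman on constant series) raise `ValueError`.
- All randomness flows through one integer seed per run; stage streams
  derive via a seed sequence keyed by a stable stream label, so stages
  are independent yet reproducible (byte-identical outputs under a fixed
  seed).
- Sizes used by the validation suite: type-I calibration on 200 seeds ×
  1,000 permutations of a 6-unit/60-day null society; clan recovery on
  100 seeds of the 12-unit/150-day strong-clan preset; AR1 coverage on
  500 series of length 100; post-dispersal pattern on 100 seeds of the
  bond preset; dispersal seasonality on 500 replicates of 24 months.

## Known limitations

- Ward heights can leave the [0, 1] similarity scale; the 0.05 clan cut
  is interpreted on similarity-scale linkages (average by default).
- Sequential-swap permutation samples are serially correlated; the
  add-one p-value over thinned samples is standard practice and
  calibrates well in our tests, but samples are not independent draws.
- The node-level AR1 model assumes a shared φ across units and
  stationarity within units.
- The Bayesian machinery of common field workflows (posterior intervals,
  convergence diagnostics) is deliberately replaced by ML point estimates
  with observed-information CIs and an optional ridge/MAP variant; at
  these data sizes the surfaces agree closely but are not identical.
- The scan bootstrap's downward bias on presence-type statistics (see
  above) is inherent to resampling scans; intervals for density in
  near-saturated windows should be read accordingly.
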