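# Methods

This note records the model as implemented, the defaults and why they are
what they are, and the choices made where the design was genuinely open.

## Cortical sheet and growth layouts

The sheet is a rectangle tiled by identical square areas of side `a = 1`
length unit. Somata are dimensionless points on a cell-centred r×c grid
inside their area, with (r, c) the factor pair of the soma count closest to
square (r ≤ c; a prime count degenerates to one row). An area at density
tier t of n_t tiers holds `round(ρ_t · a²)` somata, with densities ramping
linearly from `density_min` (default 100/unit²) to
`density_fold × density_min` (default fold 5, matching the roughly
five-fold empirical span of cortical neuron density). Absolute densities
are arbitrary units; 100–500 somata per area keeps per-area axon counts in
the hundreds while one simulation instance of the largest layout (162
areas, 64 200 neurons) runs in about a second.

Growth-event bookkeeping differs by mode, reverse-engineered so that the
final area counts come out right for every layout:

* **1D modes** — origin areas pre-exist at t = 0 (one per origin per row)
  and are *not* a growth event; each event inserts one new column per side
  per origin block (two rows move together in the 2-rows mode). Final
  count: `rows × origins × (1 + 2·events)`.
* **2D mode** — the sheet starts empty; event 1 places one origin area per
  origin and each later event adds a complete square ring around each
  origin block. Final count: `origins × (2·(events−1)+1)²`.

Multi-origin 2D blocks sit on a line (2 origins) or a 2×2 grid (4
origins); blocks stay contiguous and push each other apart symmetrically as
rings accrete. Density tiers equal the creation generation (1D: origin
tier 0 plus one tier per event, so 7 tiers at 6 events; 2D: one tier per
event). The inverse set maps creation order onto the ramp descending; the
radial and static sets reuse the realistic final arrangement; the random
set permutes the realistic per-area density multiset with the instance RNG
(a permutation, not i.i.d. resampling, so total neuron counts match the
realistic counterpart exactly).

Growth events are spaced evenly over the first third of the simulated
duration, the last landing exactly at `floor(T/3)`, leaving two thirds of
the run for connection formation by the full complement of neurons. A
static sheet fires its single (no-op) event at t = 1. Radial growth adds
`ceil(max complement / events)` somata per event to every unfinished area,
activating grid positions in a seeded random order to stay spatially
uniform; sparser areas therefore finish earlier.

Re-layout after an event pins the sheet's lower-left corner at the origin
and logs one rigid displacement vector per pre-existing area. For planar
layouts pairwise centroid distances between pre-existing areas are
non-decreasing across events (strictly increasing across origin-block
boundaries, constant within a block).

## Axon dynamics

One terminal per neuron, starting on its soma. Per step, every unoccupied
terminal extends by `step_length` at a uniform random angle; positions are
mirrored back at the current sheet rectangle (reflecting boundaries keep
axons in tissue; the alternative, absorbing or periodic edges, has no
biological reading here). A terminal becomes eligible the first time it
lies outside its parent area and stays eligible (after re-entry it may
synapse onto its parent area's somata — the area-level analyses exclude
the diagonal regardless; its own soma is always excluded). An eligible
terminal within `contact_radius` of a candidate soma targets the nearest
one (exact ties broken uniformly at random) and with probability 0.9 forms
a synapse: it relocates onto the soma and stops. A failed draw blacklists
nothing; the terminal may retry after moving. Growth events shift every
terminal by the displacement of the area containing it (point-in-cell
lookup against the pre-event layout), which keeps occupied terminals
coincident with their targets. New neurons instantiate their terminals the
moment their soma appears.

All stochastic draws of an instance — angles, tie-breaks, acceptance,
radial fill order, random-set density permutation — come from a single
`numpy.random.default_rng(seed)` in a fixed order, so (layout, params,
seed) reproduces bit-identical synapse tables. Neighbour queries use a
k-d tree over soma positions, rebuilt only at growth events (somata are
static in between); this is a performance device, not a model change.

## Calibration

The paper-level criteria are: ≥99.9% of terminals occupied at simulation
end, and median interareal connectivity of the 1D layouts inside the
empirically reported 39–66% band. `calibrate()` grid-searches
(step_length, contact_radius, total_steps) per growth mode on pilot
instances; the pilot set deliberately contains the least-connected family
member (`inverse-1D-2row-2or`) so the whole mode lands in the band. The
shipped defaults produced by this search are

| mode | step_length | contact_radius | total_steps |
|------|-------------|----------------|-------------|
| 1D   | 0.8         | 0.012          | 360         |
| 2D   | 1.6         | 0.008          | 360         |

in sheet length units (one area side = 1). The 2D mode needs a longer
step and tighter radius because diffusion must cover a two-dimensional
sheet of up to 18 × 9 areas. With these values the realistic 1D layout
reaches ~0.6 fraction connected and the realistic 2D two-origin layout
~0.6, with occupancy ≥ 0.999 across seeds.

## Analysis battery

* **Binned relative frequency** — present/(present+absent) per bin over
  ordered off-diagonal pairs; 10 equal-width bins for distance, one bin
  per distinct value for |Δρ| (≤10). Empty bins are dropped before
  correlating and the retained bin count is recorded.
* **Spearman correlations** — average ranks for ties; for ≤9 bins the
  two-sided p-value is the exact permutation probability
  P(|ρ_perm| ≥ |ρ_obs|) over all n! rankings, whose discreteness matters:
  a perfect monotone relation over 4 tiers cannot beat p = 2/24 = 0.083,
  over 5 tiers it reaches 2/120 = 0.0167. Above 9 points the t
  approximation is used. Fewer than 3 finite points or zero rank variance
  yields an undefined-result marker.
* **Sign test** — left-tailed test that the per-instance p-values' median
  is below α = 0.05, as a continuity-corrected normal approximation on the
  count of values above α; 100 values below α give z = −9.9,
  p = Φ(−9.9) = 2.08e−23.
* **Logistic models** — unregularized maximum likelihood (statsmodels) on
  z-scored predictors (sample SD, matching the convention in which
  {1,2,3} → {−1,0,1}); four predictor sets (constant-only, +distance,
  +|Δρ|, +both). The null log-likelihood uses the closed form
  n·(q·ln q + (1−q)·ln(1−q)). McFadden's pseudo-R² is 1 − LL_model/LL_null;
  the bare ratio is available behind `printed_formula=True` for auditing
  against sources that print the statistic without the "1 −" (the
  conventional interpretation bands — 0.10 moderate, 0.15 adequate,
  0.20 very high — presuppose the standard form). Perfect separation is
  caught and flagged with a capped-iteration fallback fit.
* **Degree** — afferent + efferent binary connections per area, correlated
  with density.

Connectomes are kept directed; analyses needing symmetry use the symmetric
measures (|Δρ|, centroid distance) over ordered pairs, consistent with
directed tract-tracing tables.

## Classification of empirical-format data

The classifier is scikit-learn's linear-kernel `SVC` with
`class_weight="balanced"` (misclassification weights inversely
proportional to class frequencies, implementing uniform class priors) and
Platt sigmoid calibration of the decision score fitted on the training
data — the standard score-to-posterior construction; the exact calibration
of the original tooling is not recoverable, and sigmoid calibration is the
assumption made here. Features (simulated and empirical) are z-scored per
dataset with their own mean and SD. Dual thresholds at ten levels
0.750–0.975 in steps of 0.025 label pairs present/absent/unclassified;
accuracy and J are computed over classified pairs only, and thresholds at
which a metric is undefined are dropped from the instance mean (an
instance where no threshold classifies anything is recorded as missing and
excluded from layout medians). Permutation nulls permute the empirical
truth labels 100 times, fit a normal, and report a two-tailed z-test
p-value; per instance the median p over thresholds is kept, and per layout
a left-tailed sign test checks whether those medians sit below 0.05. The
two-tailed z-test is kept as such (the observed z is positive whenever the
test is significant in practice, which justifies the better-than-chance
reading without re-interpreting the test as one-sided).

The origin-count comparison is a three-way main-effects OLS ANOVA
(species × growth mode × origins) — no interactions, so the full balanced
design of 1800 rows leaves 1794 error degrees of freedom — with estimated
marginal means per origin level and pairwise z-tests on their differences
using the model covariance, Bonferroni-corrected at α = 0.05/3.

## Synthetic empirical fixtures

Real macaque (1128 directed pairs; |log density ratio|, Euclidean
distance) and cat (954 pairs; |cortical type difference| ≤ 7, border
distance) connectivity tables are not redistributable, so tests and
examples use synthetic stand-ins of the same shape (`fixtures.py`; the
datasets label themselves `synthetic-*`). Areas receive differentiation
levels (uniform log-densities spanning a five-fold ratio, or 8 ordinal
types) and uniform planar positions; ordered pairs inherit |Δ level| and
Euclidean distance, and existence is Bernoulli with logit
`b0 − atp·z(diff) − dd·z(dist)`, b0 solved so the expected rate matches the
configured base rate (default 0.55/0.60, inside the empirically reported
50–77%). Default coefficients atp = dd = 1 per SD give binned existence
frequencies that fall clearly in both measures — the qualitative ATP
signature — without being deterministic. What passing tests show is that
the pipeline detects this structure when present and reports chance when
labels are permuted; they cannot show how well the simulation predicts the
*real* macaque or cat data, which would require the original tables and
the original (unpublished) parameter calibration.

## Problem sizes and determinism of the shipped analyses

Cross-instance statistics in the tests and the acceptance script use 11
seeded instances per layout (5 for auxiliary contrasts) rather than 100,
and the acceptance script evaluates the representative layouts rather than
all 21; the full 100-instance, 21-layout campaign is available through
`run_campaign` / `corticodev campaign` (roughly an hour of CPU time).
Instance i of a campaign always receives seed `base_seed + i`. Medians of
Spearman correlations over ≥11 instances are stable to the reported
precision; stochastic quantities (connectivity fractions, occupancy) vary
by well under a percentage point across seeds at the shipped densities.

## Known limitations

Single hemisphere, ipsilateral connections only; one axon terminal per
neuron; no pruning, waiting periods, laminar structure, activity-dependent
remodelling, or cortical folding; Euclidean distance on a flat sheet
stands in for tract lengths. Connection existence is binary throughout —
axon counts are kept, but weighted analyses are out of scope. Absolute
neuron totals are arbitrary-unit choices, so published per-layout neuron
totals that depend on unpublished absolute densities are not reproduced,
only the density *structure* (five-fold span, tier counts, multiset
identities across sets) is.
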