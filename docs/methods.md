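# Methods notes

This note records the statistical conventions, numerical choices and known
limitations behind `pollinet`. Formulas are in the README; here the emphasis
is on *why* each convention was chosen where more than one defensible option
exists.

## Strength construction

**Weekly weighting.** The unit of aggregation is the survey week: encounter
frequency is encounters per open surveyed flower per week, and each weekly
frequency is multiplied by that week's plot-level flower abundance before
summing. This corrects jointly for uneven sampling effort across plants and
for within-season turnover in bloom. Sub-weekly structure (time of day,
individual observation bouts) is assumed to have been aggregated away before
the data reach the pipeline. An encounter in a week with no positive
surveyed-flower count for that plant is a hard error, not a silent drop: it
indicates inconsistent survey tables.

**Visits per encounter.** The per-interaction mean is a plain arithmetic
mean over 4-minute follows, pooled across years without year weighting.
The imputation hierarchy (observed → donor → expert → excluded) is strict
and data-driven only at the first step; donor and expert assignments encode
expert judgment ("functionally similar species", "large-flowered plants are
worked one flower at a time by beetles") and therefore live in a YAML
configuration, never in code. A donor must itself have an observed estimate
on the same plant, or the configuration is rejected. Interactions resolved
as *excluded* are removed from **both** networks so that every comparison
operates on identical link sets. The count of estimates backed by ≥ 5
follows is reported as a reliability diagnostic but never used as a filter.

**Scale.** Only the relative scale of flower abundance matters for d′, H2′,
evenness, generality and push–pull (all are invariant to multiplying a
matrix by a positive constant; this is property-tested). Raw strengths and
their regressions do depend on whether abundance enters as flowers/m² or as
a transect total; the pipeline takes whatever the `flower_abundance` column
contains and documents this as the caller's choice of units.

## Metric dialects

Two descriptors have incompatible published dialects; both are implemented
and flag-selectable, with these defaults:

- **wNODF pair rule** — default `fill`: a row (column) pair contributes only
  if the upper line has strictly larger *binary fill*; this matches the
  widely used R implementation (`vegan::nestednodf(weighted=TRUE)`, the
  engine behind the `bipartite` package's value), and the implementation is
  pinned to it by a frozen oracle value on a 4×4 integer matrix. The
  alternative `margin` rule gates on strictly larger marginal totals. Under
  either rule ties score zero, which makes the sort order of tied lines
  irrelevant — hence no tie-breaking policy can affect the result.
- **Interaction evenness denominator** — default `all` (ln of rows×columns,
  all potential links); `realized` (ln of the number of observed links) is
  available. The `all` dialect is the stricter of the two and the one most
  common in visitation-network studies.

## Continuous entropy bounds

Strengths are real-valued after abundance weighting, so the integer-count
randomizations used by some reference implementations to standardize d′ and
H2′ are undefined here. Both indices use continuous-marginal bounds instead:

- d′: upper bound `d_max = ln(m / A_i)`; lower bound 0 (allocation
  proportional to availability). d′ values are therefore comparable between
  the two strength measures — which is the only comparison the pipeline
  makes — but not numerically identical to integer-mode implementations.
- H2′: `H2max` is the entropy of the independence allocation
  `A_i·A_j / m` (the maximum-entropy coupling of the margins); `H2min` is
  the entropy of a greedy concentration allocation (repeatedly place
  `min(remaining row, remaining column)` in the cell of the currently
  largest remaining margins — each step exhausts a row or column, so at most
  R+C−1 cells fill). The greedy allocation is a standard heuristic for the
  minimum-entropy transportation problem; the exact minimum is NP-hard, and
  the ordering `H2min ≤ H2 ≤ H2max` is asserted property-wise on random
  matrices. Both indices are clamped to [0, 1] to absorb float spill at the
  boundaries.

Degenerate inputs are errors, not NaNs: H2′ on a 1×1 network ("degenerate
marginals"), wNODF and evenness on a single-cell network. The one exception
is d′ for a species facing a single-species opposite level (`d_max = 0`),
which is defined as 0 and logged, since it can arise mid-bootstrap on
legitimate data.

## Regressions

All fits are ordinary least squares via statsmodels. Transforms follow the
normalizing conventions for these quantities: species strengths log–log,
plant d′ arcsin(√·) on both axes, ratios of change log (strength) or √
(d′), floral display always log. The slope-vs-1 test is a two-sided *t*
with n−2 df; an exact fit (slope SE at float-noise level) degenerates to
p = 1 for slope 1 and p = 0 otherwise. Both R² and adjusted R² are always
reported; for small n they differ materially and published single "R²"
values are often the adjusted one, so tests target the explicitly named
field. Plants whose encounter-based value is zero cannot form a change
ratio and are dropped from ratio regressions with a logged warning.

## Bootstrap comparison

Replicates draw ⌊fraction·N⌋ encounter events **without replacement** (a
subsample of the observed pool, not a resample; a `replace=True` flag gives
the bootstrap-proper alternative). Sampled events keep their week labels and
the complete flower-survey table is reused, so the rebuilt networks pass
through exactly the same weekly-weighting machinery as the original
(`reweight_weekly=False` builds replicates from raw counts instead).
Replicates in which either trophic level collapses below two species are
redrawn and counted; exceeding 1000 redraws aborts with an error naming the
fraction. Paired *t*-tests are two-sided with no multiple-testing
correction (the comparisons are reported raw, as is conventional for this
design). With fraction 1.0 every replicate equals the original network
exactly; constant descriptor series short-circuit the mean/SD computation so
this degeneracy is bit-exact, and the paired test reports p = 1 for
identically zero differences. Identical seed and inputs give bit-identical
output.

## Synthetic generator

The generator emulates the structure the analysis assumes: ~19 plants × ~122
pollinator morphotypes in eight functional groups (roster proportions
39 bees : 27 beetles : 20 flies : 15 butterflies : 9 wasps : 8 ants :
3 true bugs : 1 grasshopper), a 14-week season with contiguous triangular
bloom windows, log-normal floral displays (μ = 2.96, σ = 1.81 on the log
scale), and a display–visits log–log line (slope 0.28, intercept 0.17,
residual SD 0.52) — display and visit parameters estimated from the bundled
19-plant field summary. Preferences are Dirichlet rows (concentration 0.02)
over a shared heavy-tailed activity profile, which yields a few dominant
pollinators, plant-level effective partner numbers near 4, and grand totals
on the order of 4×10³ encounters per season — the scale of a full field
campaign. Encounter and follow counts are negative binomial (Poisson and
deterministic variants selectable; dispersion 0 means "rounded mean", the
no-sampling-noise limit used by calibration tests). Visit counts are shifted
negative binomial, `1 + NB(μ−1)`: support ≥ 1 with mean exactly μ, which the
slope-recovery tests rely on; this replaces rejection-sampled zero
truncation, whose mean exceeds μ. One scenario seed is split into three
child streams (community, encounters, follows) via `numpy` generator
spawning.

What the generator does **not** emulate: taxonomic identity and phylogenetic
signal in preferences, within-day survey structure, year-to-year turnover,
observer error in morphotype assignment, and pollination function (pollen
transfer). Passing tests therefore demonstrate that the pipeline's
machinery is correct and that its statistical behavior is as designed under
a realistic data-generating process — not that any particular field system
satisfies the generator's assumptions.

## Problem sizes in tests

The test suite runs field-size (19×122) scenarios only where the check is
about field-scale behavior (slope recovery, scale anchors, ratio–display
correlation); structural and bootstrap-contract tests use smaller
communities (4–6 plants, 6–12 pollinators) and 10–60 replicates, which
exercise identical code paths at a fraction of the cost. Exhaustive oracle
sweeps cover all 3×3 matrices with entries in {0, 1, 2} and full margins.

## Known limitations

- The 4-minute truncation of follows biases `v_ij` low for pollinators that
  work a plant for longer (notably beetles); this is a property of the data
  collection design, documented but not modeled.
- d′ and H2′ values are tied to the continuous-bound convention above;
  do not mix them numerically with integer-mode values from other software.
- Mean/SD bootstrap summaries assume descriptor distributions across
  replicates are roughly symmetric; at very small fractions on small
  communities the redraw rule truncates the lower tail.
- The mixed-model question of among-plant differences in visits per
  encounter (plant as fixed factor, pollinator group as random factor) is
  outside the package's scope; it is a routine off-the-shelf fit on
  per-observation data the pipeline does not require.
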