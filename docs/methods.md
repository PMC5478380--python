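# Methods

This note documents the models and procedures implemented in `nestnet`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data validation does and does not
establish.

## Spatial networks

Breeding-season association is inferred from nest-site geometry alone:
two breeders are "associated" when their occupied nestboxes are spatially
close. Two operationalisations are provided.

**k nearest neighbours.** Each breeder is linked to the `k` same-sex
breeders at smallest Euclidean nestbox distance (`k` in {3, 5, 7} by
convention; default 5). Nearest-neighbourhood is asymmetric, so the graph
is directed; in practice 70–80% of links are reciprocal at these
densities. Distance ties — possible on gridded synthetic layouts — are
broken by the smaller box id, which keeps construction deterministic.
Searches run within one sex only: male and female networks are built and
analysed independently, and a missing partner id simply removes that bird
from its own sex's network.

**Thiessen polygons.** Each occupied box gets its Voronoi cell, an
idealised territory; breeders whose cells share a boundary segment of
*positive length* are linked (point contact, as at the centre of four
boxes on a square, does not count — this resolves cocircular
degeneracies deterministically). Cells on the hull are unbounded, so the
tessellation is clipped to a window: by default the bounding box of the
occupied boxes padded by 50 m, overridable with any polygon (including
disjoint multi-part windows, in which case adjacency cannot cross the
gap). Implementation: points are mirrored across the window's bounding
box sides before tessellating, which bounds every real cell exactly at
the window boundary; candidate neighbour pairs come from Voronoi ridges
and are confirmed on the clipped cells, so clipping can remove but never
invent adjacency. Collinear configurations are rejected explicitly.

**Edge weights.** Weighted networks use `e_ij = 1/ln(d)`. The weight is
undefined at `d = 1` m and negative below, so distances are clamped at
`d_min = 2` m (with a log message); real nestboxes are tens of metres
apart, so the clamp is inert on realistic data and merely makes the
function total. Binary networks use weight 1.

**Typed restriction.** Assortment is computable only for scored birds.
By default networks are built over *all* breeders and then restricted to
typed nodes (`construct_then_restrict`): an untyped bird still occupies
space and shapes its neighbours' neighbourhoods. The alternative
(`restrict_then_construct`) runs the k-NN search among typed birds only.
Both orders are exposed because published descriptions of the procedure
are ambiguous; link counts differ between them, conclusions in our
simulations do not.

## Assortativity

For a directed weighted edge list with weights `w_ij` and trait `x`,

r = [ Σw x_s x_t / W − (Σw x_s / W)(Σw x_t / W) ] / (σ_s σ_t),

the w-weighted Pearson correlation between source-end and target-end
trait values, with σ computed separately for each end. On a symmetric
edge list this reduces to the classical undirected continuous-trait
coefficient; undirected networks therefore contribute each edge in both
directions, and binary networks are the `w = 1` special case (verified to
machine precision). The coefficient is invariant under any non-zero
affine transform of the trait and under rescaling of all weights.

A zero-variance end (e.g. all scores equal after a permutation of a tiny
network) makes r undefined. This is raised as an error, never returned
as NaN, so that permutation loops must handle and tally such replicates
explicitly.

**Jackknife SE.** `se² = Σ_e (r_{−e} − r)²` over leave-one-out units:
the directed edge for k-NN networks, the dyad (both directions) for
undirected ones — the unit choice is a documented convention, since
either is defensible. Units whose removal leaves r undefined are skipped
and counted. The computation uses leave-one-out sufficient statistics,
so it is O(m) rather than O(m²).

**Across-year combination.** Multi-season results are combined as the
link-count-weighted mean of yearly coefficients (`combine_years`); the
same weighting is applied replicate-by-replicate to the null, and the
combined link count reported is the plain mean of the yearly counts
(which is why combined link counts are fractional).

## Permutation inference

The null model shuffles the observed score multiset uniformly across a
network's nodes, leaving topology and weights untouched — appropriate
when the network itself is known with certainty, as it is here (nestbox
occupancy is censused, not sampled). Shuffling is *within year*; each
year gets an independent RNG substream spawned from the master seed, so
results are independent of evaluation order. The permutation engine is
vectorised (a permutation matrix of scores hits precomputed edge-index
arrays), which makes 1000 replicates on a few-hundred-edge network a
millisecond-scale operation and the 500-dataset calibration study cheap.

P values use the add-one convention: `p_upper = (1 + #{null ≥ r_obs}) /
(1 + N)`, analogously for the lower tail, two-sided `min(1, 2·min(p_u,
p_l))`. This never returns 0 from finite permutations and is mildly
conservative. Two-sided is the default — published tables in this
literature report large P for observed values *above* the null mean,
which a pure upper-tail convention cannot produce — and the tail is
configurable. Whether the observed value should also be injected into
the null set is left to the caller (it is not, by default; the add-one
correction plays the equivalent role).

**Duplicate-dyad deletion.** Birds breeding in several seasons can form
the same dyad repeatedly, pseudoreplicating the combined analysis. With
`dedupe=True`, before each replicate every dyad occurring in more than
one year is kept in exactly one uniformly chosen year and removed (both
directions) elsewhere; link counts are recomputed per replicate. The
observed statistic under deletion is reported as the mean over the same
deletion draws — which is why deduplicated observed values and link
counts are also fractional.

## Environmental checks

**Nestbox repeatability.** If personality were anchored to sites (habitat
quality), box identity would explain score variance across occupant-
years. The estimand is the intraclass correlation from unbalanced
one-way ANOVA variance components: `ICC = σ²_box / (σ²_box + σ²_res)`
with `σ²_box = (MSB − MSW)/n₀`, truncated at 0, on scores centred within
sex. Because a bird reusing a box contributes pseudo-replicated rows,
each of `n_subsamples` (default 1000) subsamples keeps one uniformly
chosen year per (bird, box) pair; the estimate is the subsample mean and
the interval its 2.5/97.5 percentiles. That interval reflects
subsampling uncertainty only — it is *not* a confidence interval for the
ICC and is not comparable to model-based posterior intervals.

**Strength–personality.** Node strength (summed incident edge weights,
counting in- plus out-edges) proxies local breeding density. The slope
of strength on score, both centred within year (year as a blocking
factor), is tested by permuting scores within years. This, like the
repeatability check, replaces a Bayesian mixed-model formulation with a
frequentist equivalent targeting the same estimand — a deliberate
design choice to keep the package dependency-light and the inference
exactly reproducible.

## Synthetic woodlands

The generator emulates a mid-sized, well-monitored deciduous woodland:

| parameter | default | meaning |
|---|---|---|
| `n_boxes` | 320 | nestboxes, sequential inhibition placement |
| `window` | 850 × 600 m | study plot (~51 ha) |
| `min_spacing` | 30 m | minimum box spacing |
| `n_years` | 6 | breeding seasons |
| `occupancy` | 0.33 | boxes occupied per year |
| `return_rate` | 0.45 | adult survival/return per year |
| `site_fidelity` | 0.8 | P(returning bird reuses its box if free) |
| `typed_fraction` | 0.45 | breeders with a known score (per sex) |
| `rho` | 0.5 | spatial-assortment strength in [0, 1] |
| `length_scale` | 150 m | correlation range of the spatial field |
| `score_mean`, `score_sd` | 0, 1 | marginal score distribution |

Defaults mirror the focal region of the long-running great tit study
system this methodology comes from: ~100 pairs per season in ~50 ha with
roughly half of breeders assayed; occupancy, return and fidelity are set
to round field values for such populations.

Scores are `mean + sd·(√rho·f(pos) + √(1−rho)·ε)` where `f` is a
unit-variance Gaussian random field with exponential correlation
`exp(−d/length_scale)` — chosen because it is positive definite in 2-D
with a single range parameter — realised exactly by Cholesky
factorisation at the box positions, and `ε` is iid standard normal. The
marginal is `Normal(mean, sd²)` for every `rho`, so `rho` moves spatial
structure without moving the trait distribution. A bird's score is fixed
at first settlement and persists (personality is repeatable); untyped
birds' scores are retained in a ground-truth side table so
typed-fraction experiments can compare subsample estimates against the
full-population value.

Demography: males define the occupied box set (survivors re-settle —
previous box with probability `site_fidelity` if free, else the nearest
free box, ties by box id; recruits fill to exactly
`round(occupancy·n_boxes)` boxes), then females settle into those boxes
by the same rules. Settlement order is sorted bird id, so the whole
simulation is byte-reproducible from the seed.

**What the generator does *not* emulate.** There is no habitat-quality
covariate, no density dependence, no assortative mate choice and no
behavioural settlement mechanism: spatial personality structure is
imposed directly by the field. Consequently a passing calibration or
recovery study shows that the *statistics* behave correctly under a
known spatial-mixing model, not that real birds sort by the same
mechanism. One useful side effect: because the field is anchored to
sites, the nestbox-repeatability check responds strongly to `rho > 0`
synthetic data (scores really are site-correlated there), while on
`rho = 0` data it is calibrated near zero — the two regimes bracket the
field situations the check is designed to separate.

## Validation design

The suite validates three layers:

1. **Arithmetic fixtures** — the packaged published summary tables: all
   24 typed-breeder proportions recompute exactly at half-up 3-decimal
   rounding, and effect sizes recompute from printed observed/permuted
   values (exactly on the internally consistent rows; two printed rows
   differ by one unit in the last digit due to source-side rounding of
   unprinted full-precision values).
2. **Oracles** — plain-loop brute-force reimplementations of
   assortativity, the jackknife and the k-NN scan, exhaustive
   enumeration of the 24-assignment permutation null on a 4-node path,
   and exhaustive 4-node graph sweeps.
3. **Operating characteristics** — with spatially unstructured scores
   (`rho = 0`, 60 typed males, weighted 5-NN, 1000 permutations, 500
   datasets) the two-sided rejection rate at α = 0.05 must fall in the
   exact binomial 95% interval [0.033, 0.071]; mean observed assortment
   must increase strictly over `rho ∈ {0, 0.3, 0.6, 0.9}` (50 paired
   replicates per level, common seeds across levels to cancel woodland
   noise); and at `rho = 0.9` the test must reject towards positive
   assortment in a clear majority of 200 replicates.

Study sizes (60–100 males, single seasons, 500/200/50 replicates) are
chosen as the smallest designs at which these properties are sharp; they
complete in a few minutes on one CPU.

## Known limitations

- The edge-jackknife SE is a convention; node-jackknife SEs would differ
  on small networks.
- The Thiessen construction assumes contiguous, non-overlapping
  territories; in dense clusters real territorial interaction reaches
  past shared boundaries, which is exactly why the k-NN view can detect
  structure the polygon view misses.
- The subsampling interval for repeatability understates total
  uncertainty (no sampling variance of the variance components).
- No spatially restricted permutation null is provided (all node
  permutations are exchangeable); for traits with strong environmental
  gradients a distance-restricted null would be the next step.
- Degree-preserving edge-swap nulls are out of scope by design: node
  permutation is the appropriate null when the network is a census.
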