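# Methods

## The estimator

A respondent's residence is known only to a region (a ZIP-code-like
unit). The region is partitioned into blocks, each with population counts
by demographic stratum (sex × age bracket). Writing `c_i` for the count
of the respondent's stratum in block `i`, the estimator draws

    n i.i.d. blocks,  P(block i) = c_i / Σ_j c_j      (n = 30 by default)

with replacement (implemented as inverse-CDF lookups on the cumulative
weights — mathematically identical to a draw-and-replace loop). Each draw
contributes the road-network distance from that block's centroid to the
nearest facility; the nearest facility may differ across draws. The
summary is the median of the n distances bounded by order statistics:
with n = 30 and ranks (2, 29) the closed interval contains at least 28 of
the 30 sampled distances — the "93%" interval (28/30 ≈ 93.3%). Closed-
interval inclusion is used under ties; on grid geographies, where many
sampled distances tie exactly, the realized coverage can therefore exceed
28/30 (the acceptance run reports ≈99%). Each respondent is re-sampled
independently even when regions are shared: the target of inference is
the distance a given person on a given occasion would travel, not a fixed
regional property.

The median for the even default n is the midpoint of the 15th and 16th
order statistics (the midpoint convention; for odd n the middle order
statistic). CI ranks are stored explicitly, not derived from the nominal
0.93: there is no formula that uniquely recovers (2, 29) from a
confidence level, so non-default sample sizes require explicit ranks.

`exact_distribution` enumerates the same weighted distance distribution
deterministically (one weight–distance pair per block; the weighted
median is the smallest distance whose cumulative weight reaches 0.5, the
minimizer of the weighted sum of absolute deviations). It is the limit
the sampler converges to and serves as the internal oracle: at sample
size 5001 the sampled median equals the enumerated weighted median
whenever the latter is unique with cumulative-weight margin ≥ 0.05.

## Age brackets

Demographic counts come in census-style age brackets (single years exist
only at 20 and 21), so a respondent's exact age is mapped to its bracket
before weighting. The bracket table is configurable
(`BracketTable`); the default is the standard census layout covering ages
0–120. An empty stratum (nobody of the respondent's age and sex in the
whole region) makes sampling impossible and excludes the respondent with
reason `zero_stratum`; missing fields and unresolvable region codes are
the other two reason codes. An age outside the bracket table is coded
`missing_fields` (an invalid field).

## Distances

The road network is a weighted undirected graph with lengths in miles.
Arbitrary points are snapped to the nearest node (ties to the lowest node
id) and the straight-line access leg is added on each side:

    d(a, b) = access(a) + dijkstra(snap(a), snap(b)) + access(b)

with `d(a, a) = 0` for identical points and `inf` for disconnected pairs.
Nearest-node snapping with an explicit access leg is the single largest
deliberate simplification relative to a full GIS network-analyst
toolchain; it is transparent, reproducible, and keeps distances symmetric
and metric. One-way streets, turn penalties and travel-time costing are
out of scope. Unreachable draws are an error by default
(`unreachable_policy="error"`), because silently dropping draws would
change what the order-statistic ranks mean; `drop_and_warn` literally
drops them with a warning, leaving the caller to supply ranks consistent
with the reduced sample. Cohort runs precompute one single-source
Dijkstra per facility and memoize each block's nearest-facility result,
so a run costs O(unique blocks), not O(draws).

## Comparators

- **Region centroid**: network distance from the region polygon's
  geometric (land-area) centroid to the nearest facility.
- **Population center**: the same from the region's most populated place
  (ties to the lowest place id). Facilities known only by a PO-box region
  are themselves geocoded to that region's population center, which is
  what creates exact-zero B-type distances when a respondent's region
  hosts such a facility.

Both are deterministic per region. The comparison reports, per method:
range/median/mean (sample SD)/quartiles (linear-interpolation convention;
the quartile convention is a documented choice), OLS of the sampled
median on the comparator (slope, intercept, R²), and the mean signed
error (comparator − sampled median; positive = overestimation), which the
regression coefficients alone cannot express.

## Synthetic geography

The generator emulates the study landscape rather than any real state:
square regions of square blocks on a road lattice, laid out on a grid.
Design choices, made once:

- **Scale defaults** mirror the motivating study: 218 regions vs 28
  facilities (≈ 8:1), 1467 respondents, women aged 18–44, with region
  populations of 200–2000 split equally across the sixteen F/M brackets
  spanning 18–44. Block side (`grid_spacing`) is 2 miles, giving regions
  4–8 miles across and cohort distances in the 0–60 mile range.
- **Spatial concentration** `c ∈ [0, 1]` allocates block population
  shares `(1−c)/n_blocks + c·1[center block]`; counts are one multinomial
  draw per region. The default 0.4 puts just under half a region's
  population in its largest place; `c = 1` realizes the fully
  concentrated regime (the population center is then the median location
  no matter where it sits), `c = 0` the uniform one.
- **Roads run through block centers**, not block corners: roads serve
  inhabited blocks, so block centroids and places sit on-network while
  the land-area centroid of a region may not — as in real geography,
  where an areal centroid can fall in a lake or a field. Edge lengths
  equal the node spacing exactly, keeping shortest paths analytically
  checkable. (With corner nodes instead, every block-centroid query would
  carry a constant off-network access leg that region centroids often
  avoid, distorting the method comparison with a pure snapping artifact.)
- **Facility placement** defaults to `at_population_centers` (the PO-box
  geocoding regime, which applied to half the motivating study's
  facilities); `random` and `offset_from_centers` are available.
- Respondent regions are drawn proportional to female stratum totals;
  every tenth region carries an alias code exercising the crosswalk.

What the generator does **not** emulate: realistic region topology,
distance-decay settlement patterns, multi-modal road hierarchies,
demographic correlation between neighboring regions, temporal population
change. Passing tests therefore demonstrate the estimator's internal
correctness and its qualitative bias regimes, not quantitative agreement
with any real geography.

## Bias-direction check

With facilities at population centers, the population-center geocode
under-estimates (its point is by construction at or near facilities,
and exactly at them in host regions) and the land-area centroid
over-estimates (it ignores where people cluster). The packaged check runs
20 seeded scenarios of 40 regions, 5 facilities (the ≈8:1 ratio) and 150
respondents — sized to keep the whole suite fast — and applies a sign
test (binomial, α = 0.05) to the per-scenario mean signed errors. The
direction is scenario-conditional, not universal: with facilities placed
away from settlements the population-center geocode can lose its
advantage.

## Determinism

All randomness flows from one master seed through named substreams
(`rng_stream(master_seed, key)`, SHA-256 keyed): each respondent draws
from `respondent/<id>`, the generator from `synthetic/geography` and
`synthetic/respondents`. Identical config + seed reproduce byte-identical
output files end-to-end. Weight vectors must sum to 1 within 1e-12
(counts are integers, so exactness is expected); the last cumulative
weight is clamped to exactly 1 to guard the inverse-CDF lookup.

## Problem sizes

The default test suite runs in a few seconds: the structural and
determinism checks use 6–8-region scenarios, the oracle-convergence check
20 qualifying regions at 5001 draws, the shortest-path oracle 200 random
graphs of ≤ 8 nodes, and the bias check 20 scenario seeds as above. The
acceptance script runs the full 218-region, 1467-respondent default in a
few seconds as well.
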