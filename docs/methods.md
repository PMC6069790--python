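# Methods

## The problem and the model

A person record carries demographics (sex, race/ethnicity group, age) and
a location known only at a coarse census unit. Geoimputation proposes a
fine-scale coordinate using block-level census counts. The demographic
category space is the SF1-style tabulation: 2 sexes × 9 race groups × 23
age ranges = 414 categories; ages resolve into right-open ranges
([0,5), [5,10), …, [80,85), [85,∞)). The central quantity is the block
weight for a record's category,

    w(b) = count_b[cat] / total_unit[cat],

which is a probability distribution over the unit's blocks whenever the
unit total is positive. The four strategies (S1 random-in-unit, S2
random-in-matching-blocks, S3 maximum-weight centroid, S4 weighted mean
centroid) are defined in the README; S3/S4 return an *unimputable* status
— a value, not an exception — when the unit total is zero, because the
study design requires counting such records.

All coordinates are planar meters in an already-projected equal-area
frame. The loaders validate a `crs_units: "m"` tag and the package does no
geodesic computation or reprojection; error distances are therefore plain
Euclidean distances in meters.

## Design choices where the design was open

* **Category ordering** is sex-major, then race, then age bin. Arbitrary
  but fixed; serialized count tables use label triples, never the index.
* **S2 sampling law.** "Random within matching blocks" does not pin down
  the block-choice law. The default picks a matching block with
  probability proportional to its *area*, then uniform within it — i.e.
  uniform over the union of matching blocks, keeping S2 a purely spatial
  randomizer in contrast to the demographically deterministic S3/S4. A
  population-proportional switch (`s2_weighting="population"`) is exposed
  but off by default.
* **S2 fallback.** When no block matches, S2 imputes over the whole unit
  (S1 behavior) and sets `fallback_used=True`, so both accountings — "S2
  always succeeds" and "S2 failed like S3/S4" — are recoverable from the
  output.
* **S3 tie-break** is by ascending block id: determinism is required for
  testability and the maximum is otherwise not unique.
* **S4 summation** runs over all member blocks; zero-weight blocks
  contribute nothing, so this equals the sum over matching blocks only.
* **Randomness.** One master seed; each (record, strategy, replicate)
  triple derives its own substream via a content-based key (CRC-32 of the
  record id plus strategy and replicate indices fed to NumPy's
  `SeedSequence`). Results are therefore independent of batch order and of
  which other strategies run.
* **Random point in polygon** uses bounding-box rejection sampling in
  fixed batches of 64 with a 10,000-attempt cap, making draws bit-for-bit
  reproducible per seed. The cap only binds for pathologically thin
  polygons (it raises a `SamplingError`).
* **Quartiles** use linear interpolation (NumPy's default); the SE of a
  stratum is the sample SD over √n and is reported missing (not zero) for
  n = 1. Unimputable rows are excluded from error summaries and counted in
  a companion table.
* **Density bins** are right-open decades [10ᵏ, 10ᵏ⁺¹) of the coarse
  unit's population density (people/km², unit population over unit area),
  with optional clipping of extreme decades into end bins.
* **Reporting age groups** for stratified summaries default to the five
  bins <20, 20–49, 50–64, 65–84, ≥85 — a record-side reporting
  stratification configured independently of the 23 census ranges.
* **Multiple imputation** averages per record first, then per stratum,
  and refuses deterministic strategies (their replicates are identical).
  In single-run mode, replicate 1 is what gets scored.
* **IDW surface** defaults: power 2, all-samples neighborhood, exact-hit
  rule at 10⁻⁹ m. Per-tract aggregation reports the maximum member error
  and drops tracts with fewer than 0.001 imputed records per km².
* **Race vocabulary.** Source datasets rarely use the census tabulation
  labels; readers accept a user-supplied race-mapping table rather than
  hard-coding any correspondence.

## The synthetic world

The generator produces worlds with the features that drive geoimputation
accuracy, not cartographic realism:

* **Geometry.** Square block groups on a grid, each an s × s grid of
  square blocks; tracts are contiguous column strips of groups and
  counties strips of tracts. Rectangles keep containment, area and
  centroid arithmetic exact and the full validation suite cheap. Group
  side length shrinks geometrically across columns so the
  largest/smallest block-area ratio equals `density_gradient` exactly.
* **Population.** Total population is split across the nine race groups
  (treated as disjoint strata with fixed shares — a simplification of the
  overlapping census iterations), each race is spread over blocks by a
  symmetric Dirichlet draw (`clustering_concentration` < 1 concentrates a
  race into few blocks, emulating residential segregation), and each
  block's race total is split over sex × age cells with equal sexes and
  width-proportional ages. Every split is multinomial, so totals are
  conserved exactly. Expected population per group is flat, so density
  scales inversely with group area and the gradient spans
  `density_gradient` in expectation.
* **Records** draw a home block proportional to population, a category
  proportional to the block's counts, an age uniform in the category's
  range (85+ treated as 85–99), and a true point uniform in the block.
  Every pristine record therefore matches at least its own block, and all
  four strategies succeed on pristine samples.
* **Unmatchable records.** `make_unmatchable(f)` switches the race of
  ⌈f·n⌉ randomly chosen records to one with zero population in their
  block group (for their sex and age range), reproducing the net effect
  of temporal mismatch and misclassification in real linkages — only the
  net effect, not the mechanisms.

Presets: `uniform` (16 groups, no gradient, evenly spread races; 2,000
records), `clustered_minorities` (100 groups, minority concentrations
0.05–0.3 vs 10 for the majority groups, 200,000 people, 6,000 records),
`density_gradient` (64 groups, 10⁴ area gradient giving block-group
densities from ≈9 to ≈10⁵ people/km², 5,000 records). These values are
fixed: they are the stated world the property tests run against.

**What a green test establishes.** The generator's worlds are rectangular,
single-state, temporally static, and cluster races by a one-parameter
Dirichlet law. Green tests establish that the pipeline's arithmetic and
contracts are right and that the qualitative phenomena (method ordering
S4 ≤ S3 ≤ S2 ≤ S1, density drop-off, minority-clustering advantage,
coarsening penalty) emerge under the stated conditions. They do not
establish the magnitudes real registry data would produce — real census
geographies have irregular shapes, correlated demographics and temporal
drift the generator does not emulate.

## Numerical notes

* Weight normalization holds to 1e-12; S4 agrees with a brute-force
  Σ wᵢcᵢ oracle to 1e-9 m; summary statistics agree with brute-force
  recomputation to 1e-12.
* Block containment within its group is checked with a 1e-6 m buffer;
  within-group block overlap is rejected above 1e-6 km².
* Point location resolves boundary points to the lowest block id among
  touching blocks.
* Degenerate inputs: zero-area polygons raise a geometry error; empty
  strata are never emitted; densities must be strictly positive to bin.

## Known limitations

* Only rectangular synthetic geographies are generated; irregular
  real-world unit shapes (and their centroid-outside-polygon cases) are
  exercised only through hand-built test fixtures.
* No significance testing between strategies is provided — summaries
  report means ± SE and leave inference to the user.
* Shapefile input is not supported; GeoJSON (with a meters units tag) is
  the canonical geography format.
* The imputation loop is per-record Python; it is comfortable at 10⁵
  record-strategy-replicate rows, not engineered for millions.
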