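# geoimpute

Demographically weighted **geoimputation**: assigning a coordinate to a
person record whose location is known only at a coarse census unit (block
group, tract or county), using block-level demographic counts — and a full
framework for evaluating how accurate such assignments are.

## Who this is for

Spatial epidemiologists and health-GIS analysts routinely receive records
with degraded location information (ZIP code, census unit) because exact
addresses are protected. Geoimputation recovers a plausible fine-scale
coordinate from ancillary census data, and the error this introduces
depends strongly on the demographics of the person and the population
density of the area. This package implements four standard strategies, a
synthetic census-like world generator with known ground truth, and the
error-distance evaluation machinery to quantify those dependencies.

## The strategies

A record resolves to one of the 414 census demographic categories
(2 sexes × 9 race/ethnicity groups × 23 age ranges). For a block *b* in
the searched unit, its **weight** for a category is its share of the
unit's population in that category:

```
w(b) = count_b[sex, race, age-range] / total_unit[sex, race, age-range]
```

| | Strategy | Rule |
|---|---|---|
| S1 | random in unit | uniform random point anywhere in the coarse unit |
| S2 | random in matching blocks | uniform random point over the union of blocks with w(b) > 0 |
| S3 | maximum-weight centroid | centroid of the block with the largest w(b) (deterministic; prone to artificial clustering) |
| S4 | weighted mean centroid | Σ_b w(b) · centroid(b) (deterministic, essentially collision-free) |

S3 and S4 are *unimputable* for a record whose category has zero
population in the searched unit; S2 then falls back to S1 behavior with a
flag. Accuracy is the planar Euclidean **error distance** in meters
between the true and imputed coordinates (all geometry is in a projected
equal-area frame; the package validates a meters units tag and never does
geodesic math).

## Worked example

```python
from geoimpute import GeoimputationStudy

study = GeoimputationStudy.from_preset("clustered_minorities",
                                       n_replicates=10)
res = study.fit(seed=1)
print(res.summary())
```

```
Geoimputation study results
==================================================================
records: 6000    strategies: S1, S2, S3, S4    replicates: 10
coarse level: block_group    seed: 1
------------------------------------------------------------------
error distance (m)
strategy     n     mean_m       se_m      min_m       q1_m   median_m       q3_m      max_m
      S1 60000      313.8        0.8        0.8      169.4      274.4      418.3     1328.3
      S2 60000      271.4        0.8        0.5      114.4      227.1      378.6     1277.5
      S3  6000      230.2        2.6        3.0       66.0      173.7      338.9     1134.7
      S4  6000      195.8        1.6        1.7      103.2      171.4      261.9      896.0
------------------------------------------------------------------
imputable fraction: S1=1.000  S2=1.000  S3=1.000  S4=1.000
```

Reading the table: 6,000 synthetic records were degraded to their block
group and re-located by each strategy (stochastic strategies 10×). The
weighted-mean-centroid strategy (S4, mean error 196 m) beats the
maximum-weight centroid (S3, 230 m), which beats random-in-matching-blocks
(S2, 271 m), which beats fully random (S1, 314 m) — demographic
information pays, and deterministic use of it pays more. Further slices:

```python
res.density_summary()          # accuracy by population-density decade
res.summary_frame(["strategy", "race", "sex"])
res.multiple_imputation()      # replicate-averaged S1/S2 means
res.sensitivity()              # block group vs tract vs county
res.tract_max_error("S4")      # worst error per tract (sparse tracts dropped)
res.idw_surface("S4")          # inverse-distance-weighted accuracy surface
```

The same pipeline is scriptable from the shell:

```bash
geoimpute simulate --preset density_gradient --seed 42 --out work/
geoimpute impute --geography work/geography.geojson --counts work/counts.csv \
    --records work/records.csv --strategies s1,s2,s3,s4 \
    --replicates 10 --seed 42 --out work/imputed.csv
geoimpute evaluate --imputed work/imputed.csv --records work/records.csv \
    --geography work/geography.geojson --counts work/counts.csv \
    --by strategy,density_bin --out work/summary.csv
```

## Synthetic worlds

Real ground-truth datasets for this problem are restricted-access, so the
package ships a generator of census-like worlds with known true
coordinates: nested rectangular block/block-group/tract/county
tessellations, a population-density gradient (block size shrinking up to
10⁴-fold), Dirichlet-controlled spatial clustering per race group, and an
optional fraction of records made demographically unmatchable. Presets:
`uniform`, `clustered_minorities`, `density_gradient`. Everything is
exactly reproducible per seed; see `docs/methods.md` for what the
generator does and does not emulate.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the headline study from scratch: it generates the
clustered-minorities scenario for the given seed, imputes all records with
all four strategies (10 replicates for S1/S2), and prints the per-strategy
and per-density-bin error-distance tables before writing the results file.
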