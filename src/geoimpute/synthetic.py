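"""Synthetic census-like worlds: geography, counts, and record populations.

Real studies of geoimputation accuracy need ground truth — records whose
true coordinate is known — which real registries only provide under
restricted access.  This module generates small worlds with the features
that drive the method's behavior:

* a nested block / block-group / tract / county hierarchy (rectangular
  tessellation: block groups on a grid, each subdivided into an s x s grid
  of blocks; tracts and counties are contiguous column strips of groups);
* a population-density gradient along the x-axis, realized by shrinking
  block-group side lengths geometrically so the largest/smallest block-area
  ratio equals ``density_gradient`` exactly while expected population per
  group stays flat (small blocks <=> high density, as in real urban cores);
* per-race spatial clustering via a symmetric Dirichlet allocation of each
  race's population over blocks — a low concentration parameter piles a
  race into few blocks (segregated minorities), a high one spreads it
  evenly;
* records sampled proportionally to population, each with a known true
  point uniform in its home block, so every pristine record has at least
  one matching block (its own) and all four strategies are feasible;
* an optional fraction of records whose race is switched to one absent
  from their block group, reproducing the real-world accounting in which
  a few percent of records cannot be imputed by the demographic strategies.

Everything is exactly reproducible per seed, and total population is
conserved exactly (all allocations are multinomial splits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import shapely

from .errors import ConfigError, SamplingError
from .geography import CensusBlock, CensusGeography, PersonRecord
from .geometry import random_point_in_polygon
from .schema import DemographicSchema

__all__ = [
    "ScenarioConfig",
    "generate_geography",
    "assign_population",
    "sample_records",
    "make_unmatchable",
    "generate_scenario",
    "PRESETS",
    "preset",
    "gini",
]

#: Disjoint synthetic population shares for the nine default race groups.
#: (In real SF1 the Hispanic/not-Hispanic iterations overlap the race-alone
#: ones; the generator treats all nine as disjoint strata for simplicity.)
DEFAULT_RACE_SHARES = (0.30, 0.12, 0.01, 0.04, 0.005, 0.05, 0.03, 0.28, 0.165)

#: Age profile proportional to bin width (the open 85+ bin counted as 15
#: years), i.e. a flat pyramid. Coarse but adequate: strategies depend on
#: counts per category, not on pyramid realism.
_LAST_BIN_WIDTH_YEARS = 15


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic world.

    Parameters
    ----------
    n_block_groups
        Number of block groups, laid out on a near-square grid.
    blocks_per_group
        Blocks per group; must be a perfect square (s x s sub-grid).
    base_block_size_m
        Side of a block in the *widest* (lowest-density) column, meters.
    density_gradient
        Ratio of largest to smallest block area across the x-axis
        (>= 1; 1 means no gradient).
    clustering_concentration
        Symmetric Dirichlet concentration per race, as a mapping from race
        label to a positive float, or a single float applied to all races.
        Low values (<1) concentrate a race into few blocks.
    total_population
        Total people across all blocks; conserved exactly.
    n_records
        Person records to sample.
    unmatchable_fraction
        Fraction of records whose race is switched to one with zero
        population in their block group (in [0, 1)).
    seed
        Master seed; every random stage derives its stream from it.
    tract_cols, county_tracts
        Hierarchy shape: group-grid columns per tract strip, and tract
        strips per county.
    """

    n_block_groups: int = 16
    blocks_per_group: int = 16
    base_block_size_m: float = 250.0
    density_gradient: float = 1.0
    clustering_concentration: float | dict[str, float] = 50.0
    total_population: int = 50_000
    n_records: int = 2_000
    unmatchable_fraction: float = 0.0
    seed: int = 0
    tract_cols: int = 2
    county_tracts: int = 2
    race_shares: tuple[float, ...] = DEFAULT_RACE_SHARES
    schema: DemographicSchema = field(default_factory=DemographicSchema)

    def __post_init__(self):
        if self.n_block_groups < 1 or self.blocks_per_group < 1:
            raise ConfigError("n_block_groups and blocks_per_group must be >= 1")
        s = math.isqrt(self.blocks_per_group)
        if s * s != self.blocks_per_group:
            raise ConfigError(
                f"blocks_per_group must be a perfect square for a grid "
                f"factorization, got {self.blocks_per_group}"
            )
        if self.density_gradient < 1.0:
            raise ConfigError("density_gradient must be >= 1")
        if not 0.0 <= self.unmatchable_fraction < 1.0:
            raise ConfigError("unmatchable_fraction must be in [0, 1)")
        if self.total_population < 1:
            raise ConfigError("total_population must be positive")
        if self.n_records < 0:
            raise ConfigError("n_records must be >= 0")
        if len(self.race_shares) != self.schema.n_races:
            raise ConfigError("race_shares length must equal number of races")
        if self.tract_cols < 1 or self.county_tracts < 1:
            raise ConfigError("tract_cols and county_tracts must be >= 1")

    def concentration_for(self, race_label: str) -> float:
        c = self.clustering_concentration
        if isinstance(c, dict):
            value = c.get(race_label)
            if value is None:
                raise ConfigError(f"no concentration for race {race_label!r}")
        else:
            value = float(c)
        if value <= 0:
            raise ConfigError(f"concentration must be positive, got {value}")
        return value


def _grid_shape(n: int) -> tuple[int, int]:
    """Factor n as (columns, rows) with columns >= rows, columns minimal."""
    gy = max(d for d in range(1, math.isqrt(n) + 1) if n % d == 0)
    return n // gy, gy


def generate_geography(config: ScenarioConfig) -> CensusGeography:
    """Build the rectangular tessellation (counts all zero).

    Block groups occupy a gx x gy grid of columns; every group is a square
    split into an s x s grid of square blocks.  Group (and block) *area*
    shrinks geometrically across columns so the largest/smallest block-area
    ratio equals ``density_gradient`` exactly — both dimensions scale by
    its square root, keeping blocks square (as in real geographies, where
    dense urban blocks are small in every direction, not slivers).  Columns
    stack their gy groups from y = 0, so the overall outline is ragged;
    nothing downstream needs a rectangular extent.  The construction is
    fully deterministic (the seed only drives population and records).
    """
    gx, gy = _grid_shape(config.n_block_groups)
    s = math.isqrt(config.blocks_per_group)
    base = config.base_block_size_m
    if gx > 1:
        r = config.density_gradient ** (-0.5 / (gx - 1))
        col_sides = [s * base * r**j for j in range(gx)]
    else:
        col_sides = [s * base]
    x_edges = np.concatenate([[0.0], np.cumsum(col_sides)])
    schema = config.schema

    n_tracts_x = math.ceil(gx / config.tract_cols)
    blocks: list[CensusBlock] = []
    zero = np.zeros(schema.n_categories, dtype=np.int64)
    for c in range(gx):
        tract_strip = c // config.tract_cols
        county_strip = tract_strip // config.county_tracts
        side = col_sides[c]
        for rrow in range(gy):
            gid = f"g{c:03d}x{rrow:03d}"
            tid = f"t{tract_strip:03d}"
            cid = f"c{county_strip:03d}"
            gx0, gx1 = x_edges[c], x_edges[c + 1]
            gy0 = rrow * side
            bw = (gx1 - gx0) / s
            bh = side / s
            for i in range(s):
                for j in range(s):
                    poly = shapely.box(
                        gx0 + i * bw, gy0 + j * bh,
                        gx0 + (i + 1) * bw, gy0 + (j + 1) * bh,
                    )
                    blocks.append(
                        CensusBlock(
                            block_id=f"{gid}_b{i:02d}x{j:02d}",
                            block_group_id=gid,
                            tract_id=tid,
                            county_id=cid,
                            polygon=poly,
                            counts=zero.copy(),
                        )
                    )
    # constructed on an exact grid: skip the O(n^2) overlap validation
    return CensusGeography(schema, blocks, validate=False)


def _age_profile(schema: DemographicSchema) -> np.ndarray:
    edges = np.asarray(schema.age_bin_edges, dtype=float)
    widths = np.diff(np.append(edges, edges[-1] + _LAST_BIN_WIDTH_YEARS))
    return widths / widths.sum()


def assign_population(
    geography: CensusGeography, config: ScenarioConfig
) -> CensusGeography:
    """Fill per-block category counts (in place; also returned).

    Population splits race-wise by ``race_shares`` (multinomial), then each
    race spreads over blocks via a symmetric Dirichlet draw with that
    race's concentration, then within each block over sex x age cells
    (equal sexes, width-proportional ages).  Every split is multinomial,
    so the total is conserved exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    schema = geography.schema
    block_ids = sorted(geography.blocks)
    n_blocks = len(block_ids)
    age_p = _age_profile(schema)
    sex_p = np.full(schema.n_sexes, 1.0 / schema.n_sexes)
    cell_p = np.outer(sex_p, age_p).ravel()  # sex-major, length 2*23

    race_totals = rng.multinomial(config.total_population,
                                  np.asarray(config.race_shares))
    n_age = schema.n_age_bins
    n_races = schema.n_races
    for ri, race in enumerate(schema.race_labels):
        conc = config.concentration_for(race)
        shares = rng.dirichlet(np.full(n_blocks, conc))
        per_block = rng.multinomial(race_totals[ri], shares)
        for bi in np.flatnonzero(per_block):
            cells = rng.multinomial(per_block[bi], cell_p)
            counts = geography.blocks[block_ids[bi]].counts
            for si in range(schema.n_sexes):
                base = (si * n_races + ri) * n_age
                counts[base:base + n_age] += cells[si * n_age:(si + 1) * n_age]
    # invalidate cached unit totals
    geography._unit_counts.clear()
    return geography


def sample_records(
    geography: CensusGeography, config: ScenarioConfig
) -> list[PersonRecord]:
    """Sample person records from the populated geography.

    Each record draws a home block proportional to block population, a
    demographic category proportional to that block's category counts, an
    exact age uniform within the category's age bin, and a true point
    uniform in the block.  The coarse unit is the block's group, so every
    pristine record matches at least its own block.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    schema = geography.schema
    block_ids = sorted(geography.blocks)
    pops = np.array([geography.blocks[b].counts.sum() for b in block_ids],
                    dtype=float)
    total = pops.sum()
    if total <= 0:
        raise SamplingError("cannot sample records: total population is zero")
    if config.n_records == 0:
        return []

    block_idx = rng.choice(len(block_ids), size=config.n_records, p=pops / total)
    cum_cache: dict[int, np.ndarray] = {}
    edges = schema.age_bin_edges
    records: list[PersonRecord] = []
    for i in range(config.n_records):
        bi = int(block_idx[i])
        block = geography.blocks[block_ids[bi]]
        cum = cum_cache.get(bi)
        if cum is None:
            cum = np.cumsum(block.counts).astype(float)
            cum /= cum[-1]
            cum_cache[bi] = cum
        cat = int(np.searchsorted(cum, rng.random(), side="right"))
        ai = cat % schema.n_age_bins
        rest = cat // schema.n_age_bins
        ri = rest % schema.n_races
        si = rest // schema.n_races
        lo = edges[ai]
        hi = (edges[ai + 1] if ai + 1 < len(edges)
              else edges[-1] + _LAST_BIN_WIDTH_YEARS)
        age = int(rng.integers(lo, hi))
        x, y = random_point_in_polygon(block.polygon, rng)
        records.append(
            PersonRecord(
                record_id=f"r{i:06d}",
                sex=schema.sex_labels[si],
                race=schema.race_labels[ri],
                age_years=age,
                coarse_unit_id=block.block_group_id,
                coarse_level="block_group",
                true_location=(x, y),
            )
        )
    return records


def make_unmatchable(
    records: list[PersonRecord],
    geography: CensusGeography,
    fraction: float,
    rng: np.random.Generator,
) -> list[PersonRecord]:
    """Return a copy of ``records`` in which ceil(fraction * n) records have
    their race switched to one with zero population in their block group
    (for their sex and age bin), so the demographic strategies see no
    matching block for them.

    Records are visited in a seeded random order and skipped when no such
    race exists; the altered count falls short of the target only if the
    whole population runs out of feasible records.
    """
    if not 0.0 <= fraction < 1.0:
        raise ConfigError("fraction must be in [0, 1)")
    out = [replace(r) for r in records]
    target = math.ceil(fraction * len(out))
    if target == 0:
        return out
    schema = geography.schema
    altered = 0
    for idx in rng.permutation(len(out)):
        if altered >= target:
            break
        rec = out[idx]
        totals = geography.unit_counts("block_group", rec.coarse_unit_id)
        candidates = []
        for race in schema.race_labels:
            if race == rec.race:
                continue
            cat = schema.category_index(rec.sex, race, rec.age_years)
            if totals[cat] == 0:
                candidates.append(race)
        if not candidates:
            continue
        rec.race = candidates[int(rng.integers(len(candidates)))]
        altered += 1
    return out


def generate_scenario(
    config: ScenarioConfig,
) -> tuple[CensusGeography, list[PersonRecord]]:
    """Geography + population + records (+ unmatchable injection) in one call."""
    geography = assign_population(generate_geography(config), config)
    records = sample_records(geography, config)
    if config.unmatchable_fraction > 0:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
        records = make_unmatchable(
            records, geography, config.unmatchable_fraction, rng
        )
    return geography, records


# ----------------------------------------------------------------------
# presets
# ----------------------------------------------------------------------
def _clustered_concentrations() -> dict[str, float]:
    """Majority races spread out; minorities concentrated in few blocks."""
    from .schema import SF1_RACES
    conc = {
        SF1_RACES[0]: 10.0,   # White alone
        SF1_RACES[1]: 0.20,   # Black
        SF1_RACES[2]: 0.05,   # AIAN
        SF1_RACES[3]: 0.10,   # Asian
        SF1_RACES[4]: 0.05,   # NHPI
        SF1_RACES[5]: 0.20,   # Some Other Race
        SF1_RACES[6]: 0.30,   # Two or More
        SF1_RACES[7]: 0.30,   # Hispanic or Latino
        SF1_RACES[8]: 10.0,   # White, not Hispanic
    }
    return conc


PRESETS: dict[str, ScenarioConfig] = {
    # demographically uniform, no gradient: baseline where all strategies
    # face the same search space
    "uniform": ScenarioConfig(
        n_block_groups=16,
        blocks_per_group=16,
        base_block_size_m=250.0,
        density_gradient=1.0,
        clustering_concentration=50.0,
        total_population=40_000,
        n_records=2_000,
        seed=0,
    ),
    # segregated minorities: the regime where demographic weighting pays off
    "clustered_minorities": ScenarioConfig(
        n_block_groups=100,
        blocks_per_group=16,
        base_block_size_m=250.0,
        density_gradient=10.0,
        clustering_concentration=_clustered_concentrations(),
        total_population=200_000,
        n_records=6_000,
        seed=0,
    ),
    # four-decade density gradient: block areas (hence unit sizes and error
    # scales) shrink 10^4-fold across the x-axis
    "density_gradient": ScenarioConfig(
        n_block_groups=64,
        blocks_per_group=16,
        base_block_size_m=4000.0,
        density_gradient=1.0e4,
        clustering_concentration=5.0,
        total_population=150_000,
        n_records=5_000,
        seed=0,
    ),
}


def preset(name: str, **overrides) -> ScenarioConfig:
    """A copy of a named preset, optionally with fields overridden."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise ConfigError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return replace(base, **overrides) if overrides else base


# ----------------------------------------------------------------------
# diagnostics
# ----------------------------------------------------------------------
def gini(shares: np.ndarray) -> float:
    """Gini coefficient of a non-negative share vector (0 = perfectly even,
    -> 1 = fully concentrated); used to quantify spatial clustering."""
    x = np.sort(np.asarray(shares, dtype=float))
    if x.sum() == 0:
        return 0.0
    n = x.size
    cum = np.cumsum(x)
    return float((n + 1 - 2 * (cum / cum[-1]).sum()) / n)
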