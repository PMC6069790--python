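"""The four geoimputation strategies, plus batch orchestration.

A record is known only at a coarse unit (block group by default, tract or
county in sensitivity analyses).  Each strategy proposes a coordinate:

S1  random point in the whole coarse unit — the fully uninformed baseline;
S2  random point uniform over the union of *matching* blocks (blocks with a
    positive count for the record's demographic category): a matching block
    is chosen with probability proportional to its area, then a uniform
    point is drawn inside it;
S3  centroid of the block with the maximum demographic weight
    w(b) = count_b[cat] / total_unit[cat] (ties broken by ascending block
    id); deterministic, hence prone to artificial clustering — all records
    of one (unit, category) map to the same point;
S4  weighted mean of block centroids, Sum_b w(b) * centroid(b): a
    population-informed mean position, deterministic but essentially
    collision-free across categories.

S3/S4 are *unimputable* when the unit total for the category is zero.  S2
then falls back to S1 behavior with ``fallback_used=True`` (the choice is
flagged so either accounting can be reproduced).

Randomness: every (record, strategy, replicate) triple gets its own
substream derived from the master seed by stable hashing, so results never
depend on batch order or on which other strategies run.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .geography import CensusGeography, PersonRecord
from .geometry import polygon_centroid, random_point_in_polygon

Strategy = Literal["S1", "S2", "S3", "S4"]
STRATEGIES: tuple[Strategy, ...] = ("S1", "S2", "S3", "S4")
STOCHASTIC: frozenset = frozenset({"S1", "S2"})
DETERMINISTIC: frozenset = frozenset({"S3", "S4"})

IMPUTED = "imputed"
UNIMPUTABLE = "unimputable"


@dataclass(frozen=True)
class ImputedPoint:
    """One strategy's estimate (or unimputable marker) for one record."""

    record_id: str
    strategy: Strategy
    replicate: int
    location: Optional[tuple[float, float]]
    status: str
    fallback_used: bool = False

    def __post_init__(self):
        if (self.location is None) != (self.status == UNIMPUTABLE):
            raise ValueError("location must be present iff status is imputed")


def record_rng(seed: int, record_id: str, strategy: str,
               replicate: int) -> np.random.Generator:
    """Substream for one (record, strategy, replicate): stable under batch
    reordering because the stream key is content-derived (CRC-32 of the
    record id), not positional."""
    key = zlib.crc32(record_id.encode())
    scode = STRATEGIES.index(strategy)
    return np.random.default_rng(
        np.random.SeedSequence([seed, key, scode, replicate])
    )


def _category(geography: CensusGeography, record: PersonRecord) -> int:
    return geography.schema.category_index(
        record.sex, record.race, record.age_years
    )


# ----------------------------------------------------------------------
# single-record strategies
# ----------------------------------------------------------------------
def impute_s1(
    record: PersonRecord,
    geography: CensusGeography,
    rng: np.random.Generator,
    replicate: int = 1,
) -> ImputedPoint:
    """Uniform random point in the record's whole coarse unit."""
    poly = geography.unit_polygon(record.coarse_level, record.coarse_unit_id)
    pt = random_point_in_polygon(poly, rng)
    return ImputedPoint(record.record_id, "S1", replicate, pt, IMPUTED)


def impute_s2(
    record: PersonRecord,
    geography: CensusGeography,
    rng: np.random.Generator,
    replicate: int = 1,
    weighting: Literal["area", "population"] = "area",
) -> ImputedPoint:
    """Uniform random point over the union of matching blocks.

    A block is chosen with probability proportional to its area (uniform
    over the union) or, with ``weighting='population'``, proportional to
    its count for the record's category.  With no matching block the
    strategy falls back to the whole unit (S1 behavior) and flags it.
    """
    cat = _category(geography, record)
    match = geography.matching_blocks(
        record.coarse_unit_id, cat, record.coarse_level
    )
    if not match:
        poly = geography.unit_polygon(record.coarse_level, record.coarse_unit_id)
        pt = random_point_in_polygon(poly, rng)
        return ImputedPoint(record.record_id, "S2", replicate, pt, IMPUTED,
                            fallback_used=True)
    if weighting == "area":
        w = np.array([geography.blocks[b].polygon.area for b in match])
    elif weighting == "population":
        w = np.array(
            [float(geography.blocks[b].counts[cat]) for b in match]
        )
    else:
        raise ConfigError(f"unknown S2 weighting {weighting!r}")
    choice = match[int(rng.choice(len(match), p=w / w.sum()))]
    pt = random_point_in_polygon(geography.blocks[choice].polygon, rng)
    return ImputedPoint(record.record_id, "S2", replicate, pt, IMPUTED)


def impute_s3(
    record: PersonRecord, geography: CensusGeography
) -> ImputedPoint:
    """Centroid of the block with the maximum demographic weight."""
    cat = _category(geography, record)
    unit = record.coarse_unit_id
    level = record.coarse_level
    total = geography.unit_counts(level, unit)[cat]
    if total == 0:
        return ImputedPoint(record.record_id, "S3", 1, None, UNIMPUTABLE)
    best_id, best_count = None, -1
    for bid in geography.member_blocks(level, unit):  # ascending id: tie-break
        c = int(geography.blocks[bid].counts[cat])
        if c > best_count:
            best_id, best_count = bid, c
    return ImputedPoint(
        record.record_id, "S3", 1,
        polygon_centroid(geography.blocks[best_id].polygon), IMPUTED,
    )


def impute_s4(
    record: PersonRecord, geography: CensusGeography
) -> ImputedPoint:
    """Weighted mean of block centroids, weights = demographic weights.

    Blocks with zero count contribute nothing, so the sum over all member
    blocks equals the sum over matching blocks; the result lies in the
    convex hull of the matching-block centroids.
    """
    cat = _category(geography, record)
    unit = record.coarse_unit_id
    level = record.coarse_level
    total = float(geography.unit_counts(level, unit)[cat])
    if total == 0:
        return ImputedPoint(record.record_id, "S4", 1, None, UNIMPUTABLE)
    x = y = 0.0
    for bid in geography.member_blocks(level, unit):
        c = float(geography.blocks[bid].counts[cat])
        if c == 0.0:
            continue
        cx, cy = polygon_centroid(geography.blocks[bid].polygon)
        x += (c / total) * cx
        y += (c / total) * cy
    return ImputedPoint(record.record_id, "S4", 1, (x, y), IMPUTED)


# ----------------------------------------------------------------------
# batch orchestration
# ----------------------------------------------------------------------
IMPUTED_COLUMNS = ["record_id", "strategy", "replicate", "x", "y", "status",
                   "fallback_used"]


def impute_batch(
    records: Sequence[PersonRecord],
    geography: CensusGeography,
    strategies: Iterable[str] = STRATEGIES,
    n_replicates: int = 1,
    seed: int = 0,
    s2_weighting: Literal["area", "population"] = "area",
) -> pd.DataFrame:
    """Impute every record with every requested strategy.

    Stochastic strategies (S1, S2) produce ``n_replicates`` rows per
    record; deterministic ones (S3, S4) one row.  Per-record failures are
    collected into an ``errors`` attribute on the returned frame rather
    than aborting the batch.

    Returns a DataFrame with columns
    ``record_id, strategy, replicate, x, y, status, fallback_used``
    (x/y are NaN on unimputable rows).
    """
    strategies = tuple(strategies)
    unknown = set(strategies) - set(STRATEGIES)
    if unknown:
        raise ConfigError(f"unknown strategies: {sorted(unknown)}")
    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")

    rows: list[tuple] = []
    failures: list[tuple[str, str, str]] = []
    for rec in records:
        for strat in strategies:
            reps = n_replicates if strat in STOCHASTIC else 1
            for rep in range(1, reps + 1):
                try:
                    if strat == "S1":
                        rng = record_rng(seed, rec.record_id, strat, rep)
                        ip = impute_s1(rec, geography, rng, rep)
                    elif strat == "S2":
                        rng = record_rng(seed, rec.record_id, strat, rep)
                        ip = impute_s2(rec, geography, rng, rep,
                                       weighting=s2_weighting)
                    elif strat == "S3":
                        ip = impute_s3(rec, geography)
                    else:
                        ip = impute_s4(rec, geography)
                except Exception as exc:  # aggregate, don't abort the batch
                    failures.append((rec.record_id, strat, str(exc)))
                    continue
                x, y = ip.location if ip.location is not None else (np.nan, np.nan)
                rows.append((ip.record_id, ip.strategy, ip.replicate, x, y,
                             ip.status, ip.fallback_used))
    table = pd.DataFrame(rows, columns=IMPUTED_COLUMNS)
    table.attrs["errors"] = failures
    return table
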