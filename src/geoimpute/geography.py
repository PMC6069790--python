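"""Nested census geography with per-block demographic counts.

The hierarchy is the US census one: blocks nest in block groups, block
groups in tracts, tracts in counties.  Each block carries an integer count
vector over the demographic categories of a :class:`~geoimpute.schema.DemographicSchema`.

The central quantity is the *block weight*: a block's share of the searched
unit's population for one demographic category,

    w(b) = count_b[category] / total_unit[category],

the basis of the deterministic imputation strategies.  A category whose unit
total is zero yields a *no-match* signal (``None``), not an exception —
downstream strategies must count those records as unimputable rather than
fail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

from .errors import LookupIdError, ValidationError
from .geometry import validate_polygon
from .schema import DemographicSchema

CoarseLevel = Literal["block_group", "tract", "county"]

#: Coarse levels from finest to coarsest.
LEVELS: tuple[CoarseLevel, ...] = ("block_group", "tract", "county")

#: Containment tolerance for block-in-group checks, meters.
CONTAINMENT_TOL_M = 1e-6

#: Pairwise block overlap tolerance, m^2 (1e-6 km^2).
OVERLAP_TOL_M2 = 1e-6 * 1e6


@dataclass
class CensusBlock:
    """One census block: the smallest unit, carrying the count vector."""

    block_id: str
    block_group_id: str
    tract_id: str
    county_id: str
    polygon: BaseGeometry
    counts: np.ndarray  # int vector, length n_categories

    def unit_id(self, level: CoarseLevel) -> str:
        if level == "block_group":
            return self.block_group_id
        if level == "tract":
            return self.tract_id
        if level == "county":
            return self.county_id
        raise LookupIdError(f"unknown level {level!r}")


@dataclass
class PersonRecord:
    """A person with demographics, a coarse-unit assignment and (for
    evaluation only) a known true coordinate in planar meters."""

    record_id: str
    sex: str
    race: str
    age_years: int
    coarse_unit_id: str
    coarse_level: CoarseLevel = "block_group"
    true_location: Optional[tuple[float, float]] = None


class CensusGeography:
    """A validated collection of census blocks with nesting maps, cached
    unit polygons/totals, and point location.

    Parameters
    ----------
    schema
        The demographic category space the count vectors index.
    blocks
        The member blocks; ids must be unique.
    crs_units
        Units tag of the coordinate frame; must be ``"m"`` (planar meters).
        The package never reprojects — feed it already-projected data.
    validate
        Run the full structural validation (geometry validity, nesting
        consistency, containment, non-overlap).  On by default; generators
        that construct geographies known-correct may skip it.
    """

    def __init__(
        self,
        schema: DemographicSchema,
        blocks: Iterable[CensusBlock],
        crs_units: str = "m",
        validate: bool = True,
    ):
        if crs_units != "m":
            raise ValidationError(
                f"coordinate units must be planar meters ('m'), got {crs_units!r}"
            )
        self.schema = schema
        self.crs_units = crs_units
        self.blocks: dict[str, CensusBlock] = {}
        for b in blocks:
            if b.block_id in self.blocks:
                raise ValidationError(f"duplicate block id {b.block_id!r}")
            b.counts = np.asarray(b.counts, dtype=np.int64)
            if b.counts.shape != (schema.n_categories,):
                raise ValidationError(
                    f"block {b.block_id!r}: counts length {b.counts.shape} "
                    f"!= n_categories {schema.n_categories}"
                )
            self.blocks[b.block_id] = b
        if not self.blocks:
            raise ValidationError("geography has no blocks")

        # membership maps, finest-to-coarsest
        self._members: dict[CoarseLevel, dict[str, list[str]]] = {}
        for level in LEVELS:
            members: dict[str, list[str]] = {}
            for b in self.blocks.values():
                members.setdefault(b.unit_id(level), []).append(b.block_id)
            for ids in members.values():
                ids.sort()
            self._members[level] = members

        # caches
        self._unit_polygon: dict[tuple[CoarseLevel, str], BaseGeometry] = {}
        self._unit_counts: dict[tuple[CoarseLevel, str], np.ndarray] = {}
        self._tree: STRtree | None = None
        self._tree_ids: list[str] = []

        if validate:
            self.validate()

    # ------------------------------------------------------------------
    # structure & validation
    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Enforce the structural invariants; raise ValidationError."""
        for b in self.blocks.values():
            validate_polygon(b.polygon, context=f"block {b.block_id}")
            if (b.counts < 0).any():
                raise ValidationError(f"block {b.block_id!r}: negative counts")
        # nesting consistency: all blocks of a group share tract and county
        for gid, bids in self._members["block_group"].items():
            tracts = {self.blocks[b].tract_id for b in bids}
            counties = {self.blocks[b].county_id for b in bids}
            if len(tracts) != 1 or len(counties) != 1:
                raise ValidationError(
                    f"block group {gid!r} spans multiple tracts/counties"
                )
        for tid, bids in self._members["tract"].items():
            counties = {self.blocks[b].county_id for b in bids}
            if len(counties) != 1:
                raise ValidationError(f"tract {tid!r} spans multiple counties")
        # containment: block within its group (buffered tolerance)
        for gid, bids in self._members["block_group"].items():
            gpoly = self.unit_polygon("block_group", gid)
            buffered = gpoly.buffer(CONTAINMENT_TOL_M)
            for bid in bids:
                if not buffered.contains(self.blocks[bid].polygon):
                    raise ValidationError(
                        f"block {bid!r} not contained in its group {gid!r}"
                    )
        # pairwise non-overlap of block interiors within each group
        for gid, bids in self._members["block_group"].items():
            polys = [self.blocks[b].polygon for b in bids]
            tree = STRtree(polys)
            for i, p in enumerate(polys):
                for j in tree.query(p, predicate="intersects"):
                    if j <= i:
                        continue
                    inter = p.intersection(polys[j])
                    if inter.area >= OVERLAP_TOL_M2:
                        raise ValidationError(
                            f"blocks {bids[i]!r} and {bids[int(j)]!r} overlap "
                            f"by {inter.area:.3g} m^2"
                        )

    # ------------------------------------------------------------------
    # lookups
    # ------------------------------------------------------------------
    def block(self, block_id: str) -> CensusBlock:
        try:
            return self.blocks[block_id]
        except KeyError:
            raise LookupIdError(f"unknown block id {block_id!r}") from None

    def unit_ids(self, level: CoarseLevel) -> list[str]:
        self._check_level(level)
        return sorted(self._members[level])

    def member_blocks(self, level: CoarseLevel, unit_id: str) -> list[str]:
        """Block ids of a unit, in ascending id order."""
        self._check_level(level)
        try:
            return self._members[level][unit_id]
        except KeyError:
            raise LookupIdError(f"unknown {level} id {unit_id!r}") from None

    def unit_polygon(self, level: CoarseLevel, unit_id: str) -> BaseGeometry:
        key = (level, unit_id)
        poly = self._unit_polygon.get(key)
        if poly is None:
            bids = self.member_blocks(level, unit_id)
            poly = shapely.union_all([self.blocks[b].polygon for b in bids])
            self._unit_polygon[key] = poly
        return poly

    def unit_counts(self, level: CoarseLevel, unit_id: str) -> np.ndarray:
        """Category totals of a unit = sum over member-block count vectors."""
        key = (level, unit_id)
        tot = self._unit_counts.get(key)
        if tot is None:
            bids = self.member_blocks(level, unit_id)
            tot = np.sum([self.blocks[b].counts for b in bids], axis=0)
            self._unit_counts[key] = tot
        return tot

    def unit_population(self, level: CoarseLevel, unit_id: str) -> int:
        return int(self.unit_counts(level, unit_id).sum())

    def unit_area_km2(self, level: CoarseLevel, unit_id: str) -> float:
        return self.unit_polygon(level, unit_id).area / 1e6

    def unit_density_per_km2(self, level: CoarseLevel, unit_id: str) -> float:
        """Population density = unit population / unit area (people/km^2)."""
        return self.unit_population(level, unit_id) / self.unit_area_km2(level, unit_id)

    def parent_unit(self, unit_id: str, from_level: CoarseLevel,
                    to_level: CoarseLevel) -> str:
        """The unit at ``to_level`` containing a unit at ``from_level``."""
        bid = self.member_blocks(from_level, unit_id)[0]
        return self.blocks[bid].unit_id(to_level)

    def _check_level(self, level: str) -> None:
        if level not in LEVELS:
            raise LookupIdError(
                f"unknown level {level!r}; expected one of {LEVELS}"
            )

    # ------------------------------------------------------------------
    # point location
    # ------------------------------------------------------------------
    def locate_block(self, x: float, y: float) -> str:
        """Id of the block containing (x, y); boundary points resolve to the
        lowest block id among touchers.  Raises LookupIdError if outside."""
        if self._tree is None:
            self._tree_ids = sorted(self.blocks)
            self._tree = STRtree([self.blocks[b].polygon for b in self._tree_ids])
        pt = shapely.points(x, y)
        hits = self._tree.query(pt, predicate="intersects")
        if len(hits) == 0:
            raise LookupIdError(f"point ({x}, {y}) lies outside every block")
        return min(self._tree_ids[int(i)] for i in hits)

    # ------------------------------------------------------------------
    # demographic weights
    # ------------------------------------------------------------------
    def block_weight(
        self, block_id: str, category: int, level: CoarseLevel = "block_group"
    ) -> Optional[float]:
        """The block's share of the searched unit's population for one
        demographic category; ``None`` (no-match) when the unit total is 0.

        Over all member blocks of the unit, weights sum to 1 whenever the
        unit total is positive.
        """
        b = self.block(block_id)
        self._check_category(category)
        total = self.unit_counts(level, b.unit_id(level))[category]
        if total == 0:
            return None
        return float(b.counts[category]) / float(total)

    def matching_blocks(
        self, unit_id: str, category: int, level: CoarseLevel = "block_group"
    ) -> list[str]:
        """Member blocks of a unit with a positive count for the category,
        ascending by block id."""
        self._check_category(category)
        return [
            b for b in self.member_blocks(level, unit_id)
            if self.blocks[b].counts[category] > 0
        ]

    def _check_category(self, category: int) -> None:
        if not 0 <= category < self.schema.n_categories:
            raise LookupIdError(f"category index {category} out of range")


# functional aliases matching the operation-style surface -----------------

def block_weight(geography: CensusGeography, block_id: str, category: int,
                 level: CoarseLevel = "block_group") -> Optional[float]:
    return geography.block_weight(block_id, category, level)


def matching_blocks(geography: CensusGeography, unit_id: str, category: int,
                    level: CoarseLevel = "block_group") -> list[str]:
    return geography.matching_blocks(unit_id, category, level)
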