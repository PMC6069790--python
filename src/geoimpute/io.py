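"""Reading and writing the package's file formats.

* Geography: GeoJSON — one feature per census block, properties carrying
  block / block_group / tract / county ids and a top-level ``crs_units``
  tag that must be ``"m"`` (planar meters; the package never reprojects).
* Counts: long-format CSV ``block_id, sex, race, age_bin, count`` (age_bin
  is the left edge of the census age range).  Long format is diff-able and
  schema-agnostic, unlike 414 wide columns.
* Records: CSV ``record_id, sex, race, age_years, x, y, coarse_unit_id,
  coarse_level`` (x/y optional — present only for evaluation data).
* Imputed points: the CSV emitted by
  :func:`geoimpute.strategies.impute_batch`.

Every writer's output is re-parseable by the matching reader (closed
round-trip), and loaders enforce the full set of structural invariants,
naming the offending feature in the error.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape

from .errors import ValidationError
from .geography import (LEVELS, CensusBlock, CensusGeography, PersonRecord)
from .schema import DemographicSchema, apply_race_mapping

RECORD_COLUMNS = ["record_id", "sex", "race", "age_years", "x", "y",
                  "coarse_unit_id", "coarse_level"]


# ----------------------------------------------------------------------
# geography
# ----------------------------------------------------------------------
def write_geography(
    geography: CensusGeography,
    geojson_path: str | Path,
    counts_path: str | Path,
) -> None:
    """Write a geography as GeoJSON (geometry + ids) and a long counts CSV.

    Zero counts are omitted from the CSV; readers treat absent rows as 0.
    """
    features = []
    for bid in sorted(geography.blocks):
        b = geography.blocks[bid]
        features.append({
            "type": "Feature",
            "properties": {
                "block_id": b.block_id,
                "block_group_id": b.block_group_id,
                "tract_id": b.tract_id,
                "county_id": b.county_id,
            },
            "geometry": geom_mapping(b.polygon),
        })
    doc = {"type": "FeatureCollection", "crs_units": geography.crs_units,
           "features": features}
    Path(geojson_path).write_text(json.dumps(doc))

    schema = geography.schema
    rows = []
    for bid in sorted(geography.blocks):
        counts = geography.blocks[bid].counts
        for cat in np.flatnonzero(counts):
            sex, race, ai = _triple_for(schema, int(cat))
            rows.append((bid, sex, race, schema.age_bin_edges[ai],
                         int(counts[cat])))
    pd.DataFrame(
        rows, columns=["block_id", "sex", "race", "age_bin", "count"]
    ).to_csv(counts_path, index=False)


def _triple_for(schema: DemographicSchema, cat: int) -> tuple[str, str, int]:
    ai = cat % schema.n_age_bins
    rest = cat // schema.n_age_bins
    return (schema.sex_labels[rest // schema.n_races],
            schema.race_labels[rest % schema.n_races], ai)


def read_geography(
    geojson_path: str | Path,
    counts_path: str | Path,
    schema: DemographicSchema | None = None,
    validate: bool = True,
) -> CensusGeography:
    """Load and fully validate a geography from GeoJSON + counts CSV.

    Raises :class:`ValidationError` naming the offending feature for
    missing id attributes, invalid polygons, a non-meter units tag, or
    counts rows referencing unknown blocks or labels.
    """
    schema = schema or DemographicSchema()
    doc = json.loads(Path(geojson_path).read_text())
    units = doc.get("crs_units", None)
    if units != "m":
        raise ValidationError(
            f"geography units tag must be 'm' (planar meters), got {units!r}"
        )
    blocks: list[CensusBlock] = []
    for feat in doc.get("features", []):
        props = feat.get("properties", {})
        missing = [k for k in ("block_id", "block_group_id", "tract_id",
                               "county_id") if k not in props]
        if missing:
            raise ValidationError(
                f"feature missing attributes {missing}: {props!r}"
            )
        poly = geom_shape(feat["geometry"])
        if not poly.is_valid:
            raise ValidationError(
                f"block {props['block_id']!r}: invalid polygon "
                f"({shapely.is_valid_reason(poly)})"
            )
        blocks.append(CensusBlock(
            block_id=str(props["block_id"]),
            block_group_id=str(props["block_group_id"]),
            tract_id=str(props["tract_id"]),
            county_id=str(props["county_id"]),
            polygon=poly,
            counts=np.zeros(schema.n_categories, dtype=np.int64),
        ))
    geography = CensusGeography(schema, blocks, validate=validate)

    edge_index = {e: i for i, e in enumerate(schema.age_bin_edges)}
    counts_df = pd.read_csv(counts_path)
    need = {"block_id", "sex", "race", "age_bin", "count"}
    if not need <= set(counts_df.columns):
        raise ValidationError(
            f"counts CSV must have columns {sorted(need)}, "
            f"got {list(counts_df.columns)}"
        )
    for row in counts_df.itertuples(index=False):
        bid = str(row.block_id)
        if bid not in geography.blocks:
            raise ValidationError(f"counts row for unknown block_id {bid!r}")
        ai = edge_index.get(int(row.age_bin))
        if ai is None:
            raise ValidationError(
                f"counts row for block {bid!r}: unknown age_bin "
                f"{row.age_bin!r} (expected a schema bin edge)"
            )
        # resolve labels through the schema (raises on unknown labels)
        cat = schema.category_index(str(row.sex), str(row.race),
                                    schema.age_bin_edges[ai])
        count = int(row.count)
        if count < 0:
            raise ValidationError(f"counts row for block {bid!r}: "
                                  f"negative count {count}")
        geography.blocks[bid].counts[cat] += count
    geography._unit_counts.clear()
    return geography


# ----------------------------------------------------------------------
# records
# ----------------------------------------------------------------------
def write_records(records: Sequence[PersonRecord],
                  path: str | Path) -> None:
    rows = []
    for r in records:
        x, y = r.true_location if r.true_location is not None else (np.nan,
                                                                    np.nan)
        rows.append((r.record_id, r.sex, r.race, r.age_years, x, y,
                     r.coarse_unit_id, r.coarse_level))
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, index=False)


def read_records(
    path: str | Path,
    race_mapping: Mapping[str, str] | None = None,
) -> list[PersonRecord]:
    """Load person records; ``race_mapping`` translates a source race
    vocabulary into the schema's labels (e.g. registry 'White' with unknown
    ethnicity to 'White alone')."""
    df = pd.read_csv(path)
    missing = set(RECORD_COLUMNS) - set(df.columns) - {"x", "y"}
    if missing:
        raise ValidationError(f"records CSV missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        loc = None
        x = getattr(row, "x", math.nan)
        y = getattr(row, "y", math.nan)
        if not (pd.isna(x) or pd.isna(y)):
            loc = (float(x), float(y))
        level = str(row.coarse_level)
        if level not in LEVELS:
            raise ValidationError(
                f"record {row.record_id!r}: unknown coarse_level {level!r}"
            )
        out.append(PersonRecord(
            record_id=str(row.record_id),
            sex=str(row.sex),
            race=apply_race_mapping(str(row.race), dict(race_mapping)
                                    if race_mapping else None),
            age_years=int(row.age_years),
            coarse_unit_id=str(row.coarse_unit_id),
            coarse_level=level,
            true_location=loc,
        ))
    return out


# ----------------------------------------------------------------------
# imputed points
# ----------------------------------------------------------------------
def write_imputed(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_imputed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"record_id", "strategy", "replicate", "x", "y", "status",
            "fallback_used"}
    if not need <= set(df.columns):
        raise ValidationError(
            f"imputed CSV must have columns {sorted(need)}"
        )
    df["record_id"] = df["record_id"].astype(str)
    return df
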