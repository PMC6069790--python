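"""Error-distance evaluation of imputation strategies.

The evaluation loop is: take records with known true coordinates, *coarsen*
them (pretend only the block group / tract / county is known), impute with
each strategy, and score the planar Euclidean distance between the true and
imputed points.  Error distances are then summarized by strategy and by
demographic or geographic strata:

* race / sex / reporting age group (coarser than the 23 census age ranges);
* population-density decade bins of the coarse unit (people/km^2, log10
  scale), where accuracy varies by orders of magnitude;
* multiple-imputation replicates of the stochastic strategies (per-record
  mean first, then stratum mean);
* coarse-level sensitivity (block group vs tract vs county);
* per-tract maxima and an inverse-distance-weighted accuracy surface.

Records the demographic strategies cannot impute (no matching population)
are excluded from error summaries but always counted in a companion table.
Quartiles use linear interpolation; the SE of a single-observation stratum
is reported as missing, never zero.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ScoringError, ValidationError
from .geography import LEVELS, CensusGeography, CoarseLevel, PersonRecord
from .geometry import euclidean_distance
from .strategies import (DETERMINISTIC, IMPUTED, STOCHASTIC, STRATEGIES,
                         UNIMPUTABLE, impute_batch)

#: Default record-side reporting age bins: <20, 20-49, 50-64, 65-84, 85+.
AGE_REPORT_EDGES = (0, 20, 50, 65, 85)

SUMMARY_STATS = ["n", "mean_m", "se_m", "min_m", "q1_m", "median_m", "q3_m",
                 "max_m"]


def age_report_label(age_years: int,
                     edges: Sequence[int] = AGE_REPORT_EDGES) -> str:
    """Reporting age-group label for an age, right-open bins, last open."""
    edges = tuple(edges)
    if age_years < edges[1]:
        return f"<{edges[1]}"
    for lo, hi in zip(edges[1:], edges[2:]):
        if lo <= age_years < hi:
            return f"{lo}-{hi - 1}"
    return f">={edges[-1]}"


# ----------------------------------------------------------------------
# coarsening and scoring
# ----------------------------------------------------------------------
def coarsen(
    records: Sequence[PersonRecord],
    geography: CensusGeography,
    level: CoarseLevel,
) -> list[PersonRecord]:
    """Degrade each record's location knowledge to a coarse unit.

    The containing block is found from the true coordinate and the record's
    coarse assignment replaced by that block's unit at ``level``; the true
    location is retained for scoring only.  Idempotent for a given level.
    """
    if level not in LEVELS:
        raise ConfigError(f"unknown level {level!r}; expected one of {LEVELS}")
    out = []
    for rec in records:
        if rec.true_location is None:
            raise ScoringError(
                f"record {rec.record_id!r} has no true location to coarsen from"
            )
        bid = geography.locate_block(*rec.true_location)
        unit = geography.blocks[bid].unit_id(level)
        out.append(replace(rec, coarse_unit_id=unit, coarse_level=level))
    return out


def error_distance(true_pt: tuple[float, float] | None,
                   imputed_pt: tuple[float, float]) -> float:
    """Planar Euclidean distance in meters between true and imputed points."""
    if true_pt is None:
        raise ScoringError("record has no true location; cannot score")
    return euclidean_distance(true_pt, imputed_pt)


def compute_errors(
    records: Sequence[PersonRecord],
    imputed: pd.DataFrame,
    geography: CensusGeography,
    age_report_edges: Sequence[int] = AGE_REPORT_EDGES,
) -> pd.DataFrame:
    """Join imputed points to records and compute per-row error distances.

    Returns one row per imputed-table row with columns
    ``record_id, strategy, replicate, status, fallback_used, error_m,
    sex, race, age_group, unit_id, tract_id, density_per_km2``;
    ``error_m`` is NaN on unimputable rows.  ``unit_id`` is the coarse
    unit searched (the block group in the main analysis) and the density is
    that unit's population over its area in km^2.
    """
    rec_index: dict[str, PersonRecord] = {}
    rows = []
    for rec in records:
        if rec.record_id in rec_index:
            raise ValidationError(f"duplicate record id {rec.record_id!r}")
        rec_index[rec.record_id] = rec
        if rec.true_location is None:
            raise ScoringError(
                f"record {rec.record_id!r} has no true location; cannot score"
            )
        bid = geography.locate_block(*rec.true_location)
        rows.append((
            rec.record_id, rec.sex, rec.race,
            age_report_label(rec.age_years, age_report_edges),
            rec.coarse_unit_id,
            geography.blocks[bid].tract_id,
            geography.unit_density_per_km2(rec.coarse_level,
                                           rec.coarse_unit_id),
            rec.true_location[0], rec.true_location[1],
        ))
    rec_df = pd.DataFrame(
        rows, columns=["record_id", "sex", "race", "age_group", "unit_id",
                       "tract_id", "density_per_km2", "_tx", "_ty"],
    )
    missing = set(imputed["record_id"]) - set(rec_df["record_id"])
    if missing:
        raise ValidationError(
            f"imputed table references unknown records: {sorted(missing)[:5]}"
        )
    df = imputed.merge(rec_df, on="record_id", how="left")
    df["error_m"] = np.hypot(df["x"] - df["_tx"], df["y"] - df["_ty"])
    return df.drop(columns=["_tx", "_ty"])


# ----------------------------------------------------------------------
# summaries
# ----------------------------------------------------------------------
VALID_KEYS = ("strategy", "race", "age_group", "sex", "density_bin",
              "density_decade", "unit_id", "tract_id", "level", "replicate")


def stratified_summary(
    errors: pd.DataFrame,
    keys: Iterable[str] = ("strategy",),
) -> pd.DataFrame:
    """Five-number summary + mean and SE of error distance per stratum.

    One row per observed key combination (empty strata are never emitted);
    quartiles use linear interpolation; ``se_m`` is the sample SD over
    sqrt(n) and missing when n = 1.  Unimputable rows are excluded here and
    counted in :func:`unimputable_counts`.
    """
    keys = list(keys)
    unknown = set(keys) - set(VALID_KEYS)
    if unknown:
        raise ConfigError(f"unknown stratification keys: {sorted(unknown)}")
    if errors.empty:
        raise ConfigError("empty error table")
    scored = errors[errors["status"] == IMPUTED]

    def agg(g: pd.Series) -> pd.Series:
        v = g.to_numpy(dtype=float)
        n = v.size
        return pd.Series({
            "n": n,
            "mean_m": v.mean(),
            "se_m": (v.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
            "min_m": v.min(),
            "q1_m": np.quantile(v, 0.25),
            "median_m": np.quantile(v, 0.5),
            "q3_m": np.quantile(v, 0.75),
            "max_m": v.max(),
        })

    out = (scored.groupby(keys, observed=True, sort=True)["error_m"]
           .apply(agg).unstack().reset_index())
    out["n"] = out["n"].astype(int)
    return out[keys + SUMMARY_STATS]


def unimputable_counts(errors: pd.DataFrame) -> pd.DataFrame:
    """Companion table: per-strategy counts of records the strategy could
    not impute (distinct records, not replicate rows)."""
    out = []
    for strat, g in errors.groupby("strategy", sort=True):
        bad = g.loc[g["status"] == UNIMPUTABLE, "record_id"].nunique()
        out.append((strat, g["record_id"].nunique(), bad))
    return pd.DataFrame(out, columns=["strategy", "n_records", "n_unimputable"])


def imputable_fraction(imputed: pd.DataFrame) -> pd.Series:
    """Per-strategy fraction of records successfully imputed."""
    if imputed.empty:
        raise ConfigError("empty imputed table")
    frac = {}
    for strat, g in imputed.groupby("strategy", sort=True):
        ok = g.loc[g["status"] == IMPUTED, "record_id"].nunique()
        frac[strat] = ok / g["record_id"].nunique()
    return pd.Series(frac, name="imputable_fraction")


# ----------------------------------------------------------------------
# density binning
# ----------------------------------------------------------------------
def density_bin_label(density_per_km2: float) -> tuple[int, str]:
    """(decade, label) for a positive density: decade k means density in
    [10^k, 10^(k+1)), right-open."""
    if not density_per_km2 > 0:
        raise ValidationError(
            f"density must be positive, got {density_per_km2}"
        )
    k = int(np.floor(np.log10(density_per_km2)))
    # guard against log10 rounding at exact powers of ten
    if density_per_km2 < 10.0 ** k:
        k -= 1
    elif density_per_km2 >= 10.0 ** (k + 1):
        k += 1
    return k, f"[{10.0 ** k:g}, {10.0 ** (k + 1):g})"


def assign_density_bins(
    errors: pd.DataFrame,
    min_decade: int | None = None,
    max_decade: int | None = None,
) -> pd.DataFrame:
    """Add ``density_decade`` and ``density_bin`` columns (decade bins of
    the coarse unit's population density).  Rows outside the optional
    [min_decade, max_decade] truncation are clipped into the end bins."""
    out = errors.copy()
    decades, labels = [], []
    for d in out["density_per_km2"]:
        k, _ = density_bin_label(float(d))
        if min_decade is not None:
            k = max(k, min_decade)
        if max_decade is not None:
            k = min(k, max_decade)
        decades.append(k)
        labels.append(f"[{10.0 ** k:g}, {10.0 ** (k + 1):g})")
    out["density_decade"] = decades
    out["density_bin"] = labels
    return out


def density_bins(
    errors: pd.DataFrame,
    min_decade: int | None = None,
    max_decade: int | None = None,
) -> pd.DataFrame:
    """Per-strategy, per-density-decade error summary, ascending decade."""
    binned = assign_density_bins(errors, min_decade, max_decade)
    out = stratified_summary(binned, ["strategy", "density_decade",
                                      "density_bin"])
    return out.sort_values(["strategy", "density_decade"]).reset_index(drop=True)


# ----------------------------------------------------------------------
# multiple imputation
# ----------------------------------------------------------------------
def multiple_imputation_summary(
    errors: pd.DataFrame,
    keys: Iterable[str] = ("strategy",),
) -> pd.DataFrame:
    """Replicate-averaged error summary for stochastic strategies.

    Per-record mean error across replicates first, then stratum mean of
    those per-record means (with SE over records); plus the between-
    replicate spread — the SD across replicates of replicate-wise stratum
    means.  Raises :class:`ScoringError` if a deterministic strategy is
    present (replicates of a deterministic method are all identical, so
    the summary would be meaningless) or if fewer than 2 replicates exist.
    """
    keys = list(keys)
    present = set(errors["strategy"].unique())
    det = present & DETERMINISTIC
    if det:
        raise ScoringError(
            f"multiple imputation is undefined for deterministic strategies "
            f"{sorted(det)}; they yield the same point every replicate"
        )
    scored = errors[errors["status"] == IMPUTED]
    if scored.groupby("strategy")["replicate"].nunique().min() < 2:
        raise ScoringError("multiple imputation needs >= 2 replicates")

    per_record = (scored.groupby(keys + ["record_id"], observed=True)
                  ["error_m"].mean().reset_index())
    rep_stratum = (scored.groupby(keys + ["replicate"], observed=True)
                   ["error_m"].mean())
    rows = []
    for kv, g in per_record.groupby(keys, observed=True, sort=True):
        kv = kv if isinstance(kv, tuple) else (kv,)
        v = g["error_m"].to_numpy()
        rep_means = rep_stratum.loc[kv].to_numpy()
        rows.append((*kv, v.size, v.mean(),
                     v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else np.nan,
                     rep_means.std(ddof=1) if rep_means.size > 1 else np.nan))
    return pd.DataFrame(
        rows, columns=keys + ["n_records", "mean_m", "se_m",
                              "between_replicate_sd_m"],
    )


# ----------------------------------------------------------------------
# sensitivity across spatial units
# ----------------------------------------------------------------------
def sensitivity_by_level(
    records: Sequence[PersonRecord],
    geography: CensusGeography,
    levels: Sequence[CoarseLevel] = LEVELS,
    strategies: Sequence[str] = STRATEGIES,
    n_replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the full coarsen -> impute -> score loop at each spatial level.

    The same master seed is reused at every level so differences reflect
    the coarsening alone.  Returns the concatenated error tables with a
    ``level`` column (summarize with :func:`stratified_summary` or
    :func:`density_bins`).
    """
    frames = []
    for level in levels:
        coarse = coarsen(records, geography, level)
        imputed = impute_batch(coarse, geography, strategies,
                               n_replicates=n_replicates, seed=seed)
        errs = compute_errors(coarse, imputed, geography)
        errs.insert(0, "level", level)
        frames.append(errs)
    return pd.concat(frames, ignore_index=True)


# ----------------------------------------------------------------------
# accuracy across geography
# ----------------------------------------------------------------------
def tract_accuracy_aggregation(
    errors: pd.DataFrame,
    geography: CensusGeography,
    min_records_per_km2: float = 0.001,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-tract maximum error distance, with sparse tracts removed.

    A tract whose imputed-record density (records per km^2 of tract area)
    falls below ``min_records_per_km2`` is dropped as unreliable and listed
    in the second return value.
    """
    scored = errors[errors["status"] == IMPUTED]
    rows, dropped = [], []
    for tid, g in scored.groupby("tract_id", sort=True):
        n = g["record_id"].nunique()
        area = geography.unit_area_km2("tract", tid)
        if n / area < min_records_per_km2:
            dropped.append(tid)
            continue
        rows.append((tid, n, area, float(g["error_m"].max())))
    for tid in geography.unit_ids("tract"):
        if tid not in set(scored["tract_id"]):
            dropped.append(tid)
    kept = pd.DataFrame(
        rows, columns=["tract_id", "n_records", "area_km2", "max_error_m"]
    )
    return kept, sorted(set(dropped))


def idw_interpolate(
    sample_xy: np.ndarray,
    sample_values: np.ndarray,
    grid_x: np.ndarray,
    grid_y: np.ndarray,
    power: float = 2.0,
) -> np.ndarray:
    """Inverse-distance-weighted interpolation onto a rectilinear grid.

    Every grid node value is ``sum(w_i v_i) / sum(w_i)`` with
    ``w_i = d_i**(-power)`` over *all* samples; a node within 1e-9 m of a
    sample takes that sample's value exactly.  The output is bounded by
    the sample min/max.  Returns an array of shape (len(grid_y),
    len(grid_x)).
    """
    xy = np.atleast_2d(np.asarray(sample_xy, dtype=float))
    v = np.asarray(sample_values, dtype=float)
    if xy.shape[0] == 0:
        raise ConfigError("idw_interpolate needs at least one sample point")
    if xy.shape[0] != v.size:
        raise ConfigError("sample_xy and sample_values length mismatch")
    if not power > 0:
        raise ConfigError("power must be positive")
    gx, gy = np.meshgrid(np.asarray(grid_x, float), np.asarray(grid_y, float))
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    d = np.sqrt(((pts[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2))
    exact = d < 1e-9
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    out = np.empty(pts.shape[0])
    hit_rows = exact.any(axis=1)
    out[hit_rows] = v[np.argmax(exact[hit_rows], axis=1)]
    rest = ~hit_rows
    out[rest] = (w[rest] * v).sum(axis=1) / w[rest].sum(axis=1)
    return out.reshape(gy.shape)
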