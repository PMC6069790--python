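"""Study-level front door: a model object over records + geography whose
``fit`` runs the coarsen -> impute -> score loop and returns a results
object carrying the error table, summaries and diagnostics.

    >>> from geoimpute import GeoimputationStudy
    >>> study = GeoimputationStudy.from_preset("clustered_minorities",
    ...                                        n_replicates=10)
    >>> res = study.fit(seed=42)
    >>> print(res.summary())            # per-strategy error-distance table
    >>> res.density_summary()           # decade-binned accuracy
    >>> res.imputable_fraction()        # per-strategy coverage

The model holds the inputs and configuration; every number lives on the
results object.  Refitting with another seed re-imputes from scratch.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import evaluation as ev
from .errors import ConfigError
from .geography import LEVELS, CensusGeography, CoarseLevel, PersonRecord
from .strategies import (STOCHASTIC, STRATEGIES, impute_batch)


class GeoimputationStudy:
    """An imputation-accuracy study over ground-truth records.

    Parameters
    ----------
    records
        Person records with known true coordinates.
    geography
        The census geography (blocks + counts) the strategies search.
    strategies
        Subset of ``("S1", "S2", "S3", "S4")``.
    n_replicates
        Replicates for the stochastic strategies (S1/S2); deterministic
        strategies always run once.
    coarse_level
        The unit the records are degraded to before imputation
        (``block_group`` for the main analysis; ``tract``/``county`` for
        sensitivity runs).
    age_report_edges
        Reporting age-group edges for stratified summaries.
    s2_weighting
        Block-choice law for S2: ``"area"`` (uniform over the union of
        matching blocks, the default) or ``"population"``.
    """

    def __init__(
        self,
        records: Sequence[PersonRecord],
        geography: CensusGeography,
        strategies: Sequence[str] = STRATEGIES,
        n_replicates: int = 1,
        coarse_level: CoarseLevel = "block_group",
        age_report_edges: Sequence[int] = ev.AGE_REPORT_EDGES,
        s2_weighting: str = "area",
    ):
        if not records:
            raise ConfigError("study needs at least one record")
        if coarse_level not in LEVELS:
            raise ConfigError(f"unknown coarse_level {coarse_level!r}")
        self.records = list(records)
        self.geography = geography
        self.strategies = tuple(strategies)
        self.n_replicates = int(n_replicates)
        self.coarse_level = coarse_level
        self.age_report_edges = tuple(age_report_edges)
        self.s2_weighting = s2_weighting

    # -- constructors --------------------------------------------------
    @classmethod
    def from_files(cls, geojson_path, counts_path, records_path,
                   race_mapping=None, **kwargs) -> "GeoimputationStudy":
        from .io import read_geography, read_records
        geography = read_geography(geojson_path, counts_path)
        records = read_records(records_path, race_mapping=race_mapping)
        return cls(records, geography, **kwargs)

    @classmethod
    def from_preset(cls, name: str, scenario_overrides: dict | None = None,
                    **kwargs) -> "GeoimputationStudy":
        """Build a study on a named synthetic preset scenario."""
        from .synthetic import generate_scenario, preset
        geography, records = generate_scenario(
            preset(name, **(scenario_overrides or {}))
        )
        return cls(records, geography, **kwargs)

    # -- fitting -------------------------------------------------------
    def fit(self, seed: int = 0) -> "StudyResults":
        """Coarsen, impute every record with every strategy, and score."""
        coarse = ev.coarsen(self.records, self.geography, self.coarse_level)
        imputed = impute_batch(
            coarse, self.geography, self.strategies,
            n_replicates=self.n_replicates, seed=seed,
            s2_weighting=self.s2_weighting,
        )
        errors = ev.compute_errors(coarse, imputed, self.geography,
                                   self.age_report_edges)
        return StudyResults(self, coarse, imputed, errors, seed)


class StudyResults:
    """Fitted results: imputed points, per-row error distances, summaries.

    Attributes
    ----------
    imputed : DataFrame
        One row per (record, strategy, replicate) with the imputed point.
    errors : DataFrame
        The imputed table joined to record strata with ``error_m`` filled.
    seed : int
        The master seed the fit used.
    """

    def __init__(self, model: GeoimputationStudy,
                 records: list[PersonRecord],
                 imputed: pd.DataFrame, errors: pd.DataFrame, seed: int):
        self.model = model
        self.records = records
        self.imputed = imputed
        self.errors = errors
        self.seed = seed

    # -- summaries -----------------------------------------------------
    def summary_frame(self, by: Iterable[str] = ("strategy",)) -> pd.DataFrame:
        """Stratified five-number + mean/SE summary of error distances."""
        return ev.stratified_summary(self.errors, by)

    def summary(self) -> str:
        """Human-readable per-strategy report."""
        df = self.summary_frame(["strategy"])
        frac = self.imputable_fraction()
        lines = [
            "Geoimputation study results",
            "=" * 66,
            f"records: {len(self.records)}    "
            f"strategies: {', '.join(self.model.strategies)}    "
            f"replicates: {self.model.n_replicates}",
            f"coarse level: {self.model.coarse_level}    seed: {self.seed}",
            "-" * 66,
            "error distance (m)",
            df.to_string(index=False,
                         float_format=lambda v: f"{v:10.1f}"),
            "-" * 66,
            "imputable fraction: "
            + "  ".join(f"{s}={frac[s]:.3f}" for s in frac.index),
        ]
        return "\n".join(lines)

    def imputable_fraction(self) -> pd.Series:
        return ev.imputable_fraction(self.imputed)

    def unimputable_counts(self) -> pd.DataFrame:
        return ev.unimputable_counts(self.errors)

    def density_summary(self, min_decade: int | None = None,
                        max_decade: int | None = None) -> pd.DataFrame:
        """Per-strategy accuracy across population-density decade bins."""
        return ev.density_bins(self.errors, min_decade, max_decade)

    def multiple_imputation(
        self, by: Iterable[str] = ("strategy",)
    ) -> pd.DataFrame:
        """Replicate-averaged summary for the stochastic strategies only."""
        stoch = self.errors[self.errors["strategy"].isin(STOCHASTIC)]
        return ev.multiple_imputation_summary(stoch, list(by))

    def sensitivity(self, levels: Sequence[CoarseLevel] = LEVELS,
                    ) -> pd.DataFrame:
        """Re-run the study at several coarse levels with the same seed;
        returns the concatenated error tables with a ``level`` column."""
        return ev.sensitivity_by_level(
            self.model.records, self.model.geography, levels,
            self.model.strategies, self.model.n_replicates, self.seed,
        )

    def tract_max_error(self, strategy: str = "S4",
                        min_records_per_km2: float = 0.001):
        """Per-tract maximum error for one strategy (sparse tracts dropped)."""
        errs = self.errors[self.errors["strategy"] == strategy]
        return ev.tract_accuracy_aggregation(
            errs, self.model.geography, min_records_per_km2
        )

    def idw_surface(self, strategy: str = "S4", nx: int = 50, ny: int = 50,
                    power: float = 2.0):
        """Accuracy surface: IDW interpolation of per-record mean error at
        the true locations, onto an nx x ny grid over the geography bounds.

        Returns ``(grid_x, grid_y, grid)`` with grid shape (ny, nx).
        """
        errs = self.errors[(self.errors["strategy"] == strategy)
                           & (self.errors["status"] == "imputed")]
        if errs.empty:
            raise ConfigError(f"no imputed rows for strategy {strategy!r}")
        per_rec = errs.groupby("record_id")["error_m"].mean()
        locs = {r.record_id: r.true_location for r in self.records}
        xy = np.array([locs[rid] for rid in per_rec.index])
        minx = min(b.polygon.bounds[0]
                   for b in self.model.geography.blocks.values())
        maxx = max(b.polygon.bounds[2]
                   for b in self.model.geography.blocks.values())
        miny = min(b.polygon.bounds[1]
                   for b in self.model.geography.blocks.values())
        maxy = max(b.polygon.bounds[3]
                   for b in self.model.geography.blocks.values())
        grid_x = np.linspace(minx, maxx, nx)
        grid_y = np.linspace(miny, maxy, ny)
        grid = ev.idw_interpolate(xy, per_rec.to_numpy(), grid_x, grid_y,
                                  power=power)
        return grid_x, grid_y, grid

    # -- plotting ------------------------------------------------------
    def plot_strategy_boxplot(self, ax=None):
        """Box-and-whisker plot of error distance per strategy."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        scored = self.errors[self.errors["status"] == "imputed"]
        groups = [g["error_m"].to_numpy()
                  for _, g in scored.groupby("strategy", sort=True)]
        labels = sorted(scored["strategy"].unique())
        ax.boxplot(groups, tick_labels=labels, showfliers=False)
        ax.set_ylabel("error distance (m)")
        ax.set_xlabel("strategy")
        return ax
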