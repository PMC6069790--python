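"""Evaluation framework: coarsening, scoring, summaries, IDW."""

import numpy as np
import pandas as pd
import pytest

from geoimpute import PersonRecord, impute_batch
from geoimpute.errors import ConfigError, ScoringError, ValidationError
from geoimpute.evaluation import (age_report_label, assign_density_bins,
                                  coarsen, compute_errors, density_bin_label,
                                  density_bins, error_distance,
                                  idw_interpolate, imputable_fraction,
                                  multiple_imputation_summary,
                                  stratified_summary,
                                  tract_accuracy_aggregation,
                                  unimputable_counts)


class TestCoarsen:
    def test_block_group_level_matches_home_group(self, uniform_scenario):
        geography, records = uniform_scenario
        out = coarsen(records[:100], geography, "block_group")
        for rec in out:
            bid = geography.locate_block(*rec.true_location)
            assert rec.coarse_unit_id == geography.blocks[bid].block_group_id
            assert rec.coarse_level == "block_group"

    def test_county_level_on_single_county(self, mini_geography,
                                           uniform_scenario):
        geography, records = uniform_scenario
        out = coarsen(records[:50], geography, "county")
        assert len({r.coarse_unit_id for r in out}) \
            == len(geography.unit_ids("county"))

    def test_idempotence(self, uniform_scenario):
        geography, records = uniform_scenario
        once = coarsen(records[:50], geography, "tract")
        twice = coarsen(once, geography, "tract")
        assert once == twice

    def test_missing_true_location_raises(self, mini_geography):
        rec = PersonRecord("r", "Male", "RaceA", 10, "gA")
        with pytest.raises(ScoringError):
            coarsen([rec], mini_geography, "tract")

    def test_unknown_level_raises(self, uniform_scenario):
        geography, records = uniform_scenario
        with pytest.raises(ConfigError):
            coarsen(records[:1], geography, "zipcode")


class TestErrorDistance:
    def test_three_four_five(self):
        assert error_distance((0, 0), (3, 4)) == 5.0

    def test_identical_points_zero(self):
        assert error_distance((2.5, -1), (2.5, -1)) == 0.0

    def test_translation_invariance(self):
        a, b, v = (1.0, 2.0), (4.0, 6.0), (123.4, -56.7)
        assert error_distance(a, b) == pytest.approx(
            error_distance((a[0] + v[0], a[1] + v[1]),
                           (b[0] + v[0], b[1] + v[1])))

    def test_missing_true_point_raises(self):
        with pytest.raises(ScoringError):
            error_distance(None, (0, 0))


def _errors_frame(values, strategy="S1", **cols):
    n = len(values)
    base = dict(
        record_id=[f"r{i}" for i in range(n)], strategy=strategy,
        replicate=1, status="imputed", fallback_used=False,
        error_m=values, sex="Male", race="X", age_group="<20",
        unit_id="g", tract_id="t", density_per_km2=100.0,
    )
    base.update(cols)
    return pd.DataFrame(base)


class TestStratifiedSummary:
    def test_quartiles_linear_interpolation(self):
        out = stratified_summary(_errors_frame([1, 2, 3, 4, 5]), ["strategy"])
        row = out.iloc[0]
        assert (row["median_m"], row["q1_m"], row["q3_m"]) == (3, 2, 4)
        assert (row["min_m"], row["max_m"]) == (1, 5)

    def test_single_observation_se_is_missing_not_zero(self):
        out = stratified_summary(_errors_frame([7.0]), ["strategy"])
        assert np.isnan(out.iloc[0]["se_m"])
        assert out.iloc[0]["n"] == 1

    def test_mean_matches_brute_force_on_fixture(self):
        rng = np.random.default_rng(0)
        v = rng.exponential(500, size=100)
        out = stratified_summary(_errors_frame(v), ["strategy"])
        assert abs(out.iloc[0]["mean_m"] - v.sum() / 100) < 1e-12
        assert abs(out.iloc[0]["se_m"]
                   - np.std(v, ddof=1) / 10) < 1e-12

    def test_unimputable_rows_excluded_but_counted(self):
        df = _errors_frame([1, 2, 3, 4])
        df.loc[2:, "status"] = "unimputable"
        df.loc[2:, "error_m"] = np.nan
        out = stratified_summary(df, ["strategy"])
        assert out.iloc[0]["n"] == 2
        comp = unimputable_counts(df)
        assert comp.iloc[0]["n_unimputable"] == 2

    def test_empty_table_and_bad_keys_raise(self):
        with pytest.raises(ConfigError):
            stratified_summary(_errors_frame([]), ["strategy"])
        with pytest.raises(ConfigError):
            stratified_summary(_errors_frame([1.0]), ["shoe_size"])


class TestDensityBins:
    @pytest.mark.parametrize("density,decade", [
        (50, 1), (100, 2), (99.9999, 1), (0.05, -2), (1, 0), (10_000, 4),
    ])
    def test_decade_assignment_right_open(self, density, decade):
        k, label = density_bin_label(density)
        assert k == decade
        assert label.startswith(f"[{10.0 ** decade:g},")

    def test_zero_or_negative_density_rejected(self):
        for bad in (0.0, -5.0):
            with pytest.raises(ValidationError):
                density_bin_label(bad)

    def test_bins_partition_rows(self):
        rng = np.random.default_rng(1)
        df = _errors_frame(rng.exponential(100, 200),
                           density_per_km2=rng.uniform(0.1, 5000, 200))
        out = density_bins(df)
        assert out["n"].sum() == 200

    def test_truncation_clips_into_end_bins(self):
        df = _errors_frame([1.0, 2.0, 3.0],
                           density_per_km2=[0.5, 50, 5e6])
        binned = assign_density_bins(df, min_decade=0, max_decade=3)
        assert binned["density_decade"].tolist() == [0, 1, 3]


class TestMultipleImputation:
    def test_per_record_mean_then_stratum_mean(self):
        df = pd.concat([
            _errors_frame([10.0, 30.0], replicate=1),
            _errors_frame([20.0, 50.0], replicate=2),
        ])
        out = multiple_imputation_summary(df, ["strategy"])
        # record means are (15, 40) -> stratum mean 27.5
        assert out.iloc[0]["mean_m"] == pytest.approx(27.5)
        assert out.iloc[0]["n_records"] == 2

    def test_deterministic_strategy_rejected(self):
        df = _errors_frame([1.0, 2.0], strategy="S3")
        with pytest.raises(ScoringError, match="deterministic"):
            multiple_imputation_summary(df)

    def test_single_replicate_rejected(self):
        with pytest.raises(ScoringError, match="replicates"):
            multiple_imputation_summary(_errors_frame([1.0, 2.0]))


class TestTractAggregation:
    def test_max_per_tract_and_drops(self, uniform_scenario):
        geography, records = uniform_scenario
        recs = records[:300]
        imputed = impute_batch(recs, geography, strategies=("S4",), seed=0)
        errors = compute_errors(recs, imputed, geography)
        kept, dropped = tract_accuracy_aggregation(errors, geography,
                                                   min_records_per_km2=0.001)
        for row in kept.itertuples():
            sub = errors[errors["tract_id"] == row.tract_id]
            assert row.max_error_m == sub["error_m"].max()

    def test_threshold_zero_drops_only_empty_tracts(self, uniform_scenario):
        geography, records = uniform_scenario
        recs = records[:50]
        imputed = impute_batch(recs, geography, strategies=("S4",), seed=0)
        errors = compute_errors(recs, imputed, geography)
        kept, dropped = tract_accuracy_aggregation(errors, geography, 0.0)
        assert set(kept["tract_id"]) == set(errors["tract_id"].unique())
        kept_hi, _ = tract_accuracy_aggregation(errors, geography, 1e9)
        assert kept_hi.empty

    def test_sparse_tract_dropped_and_listed(self, uniform_scenario):
        geography, records = uniform_scenario
        recs = records[:20]
        imputed = impute_batch(recs, geography, strategies=("S4",), seed=0)
        errors = compute_errors(recs, imputed, geography)
        # threshold above every tract's record density: all dropped
        kept, dropped = tract_accuracy_aggregation(errors, geography, 1e9)
        assert set(dropped) == set(geography.unit_ids("tract"))


class TestIDW:
    def test_single_sample_constant_grid(self):
        grid = idw_interpolate(np.array([[5.0, 5.0]]), np.array([42.0]),
                               np.linspace(0, 10, 4), np.linspace(0, 10, 3))
        assert grid.shape == (3, 4)
        assert (grid == 42.0).all()

    def test_exact_hit_returns_sample_value(self):
        xy = np.array([[0.0, 0.0], [10.0, 0.0]])
        grid = idw_interpolate(xy, np.array([1.0, 9.0]),
                               np.array([0.0, 5.0, 10.0]), np.array([0.0]))
        assert grid[0, 0] == 1.0
        assert grid[0, 2] == 9.0
        assert 1.0 < grid[0, 1] < 9.0

    def test_matches_brute_force_double_loop(self):
        """5 samples, 3x3 grid, vs an index-by-index reimplementation."""
        rng = np.random.default_rng(2)
        xy = rng.uniform(0, 100, size=(5, 2))
        v = rng.uniform(0, 1000, size=5)
        gx = np.linspace(0, 100, 3)
        gy = np.linspace(0, 100, 3)
        grid = idw_interpolate(xy, v, gx, gy, power=2.0)
        for iy, y in enumerate(gy):
            for ix, x in enumerate(gx):
                d = np.sqrt((xy[:, 0] - x) ** 2 + (xy[:, 1] - y) ** 2)
                w = d ** -2.0
                assert abs(grid[iy, ix] - (w * v).sum() / w.sum()) < 1e-9

    def test_output_bounded_by_sample_range(self):
        rng = np.random.default_rng(3)
        xy = rng.uniform(0, 50, size=(20, 2))
        v = rng.uniform(100, 900, size=20)
        grid = idw_interpolate(xy, v, np.linspace(-10, 60, 15),
                               np.linspace(-10, 60, 15))
        assert grid.min() >= v.min() - 1e-9
        assert grid.max() <= v.max() + 1e-9

    def test_invalid_inputs(self):
        with pytest.raises(ConfigError):
            idw_interpolate(np.empty((0, 2)), np.array([]),
                            np.array([0.0]), np.array([0.0]))
        with pytest.raises(ConfigError):
            idw_interpolate(np.array([[0, 0]]), np.array([1.0]),
                            np.array([0.0]), np.array([0.0]), power=0)


class TestImputableFraction:
    def test_arithmetic(self):
        df = _errors_frame([1.0] * 10, strategy="S3")
        df.loc[:1, "status"] = "unimputable"
        assert imputable_fraction(df)["S3"] == pytest.approx(0.8)

    def test_pristine_sample_fully_imputable(self, uniform_scenario):
        geography, records = uniform_scenario
        table = impute_batch(records[:200], geography, seed=0)
        assert (imputable_fraction(table) == 1.0).all()


def test_age_report_labels():
    assert age_report_label(5) == "<20"
    assert age_report_label(20) == "20-49"
    assert age_report_label(64) == "50-64"
    assert age_report_label(84) == "65-84"
    assert age_report_label(85) == ">=85"
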