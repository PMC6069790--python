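"""The four imputation strategies: contracts, oracles, batch behavior."""

import numpy as np
import pytest
import shapely

from geoimpute import (PersonRecord, impute_batch, impute_s1, impute_s2,
                       impute_s3, impute_s4)
from geoimpute.errors import ConfigError
from geoimpute.geometry import polygon_centroid
from geoimpute.strategies import record_rng
from geoimpute.synthetic import make_unmatchable


def _rec(rid="r0", sex="Male", race="RaceA", age=20, unit="gA"):
    return PersonRecord(record_id=rid, sex=sex, race=race, age_years=age,
                        coarse_unit_id=unit, coarse_level="block_group")


class TestS1:
    def test_point_inside_coarse_unit(self, mini_geography):
        rng = np.random.default_rng(0)
        ip = impute_s1(_rec(), mini_geography, rng)
        poly = mini_geography.unit_polygon("block_group", "gA")
        assert shapely.contains_xy(poly, *ip.location)
        assert ip.status == "imputed"

    def test_same_seed_same_point(self, mini_geography):
        a = impute_s1(_rec(), mini_geography, np.random.default_rng(4))
        b = impute_s1(_rec(), mini_geography, np.random.default_rng(4))
        assert a.location == b.location

    def test_hit_frequencies_proportional_to_area(self, mini_geography):
        """gA is four equal-area blocks; 10,000 S1 draws should hit each
        block a quarter of the time within 3 sigma binomial bounds."""
        rng = np.random.default_rng(8)
        hits = {b: 0 for b in mini_geography.member_blocks("block_group", "gA")}
        for _ in range(10_000):
            ip = impute_s1(_rec(), mini_geography, rng)
            hits[mini_geography.locate_block(*ip.location)] += 1
        p = 0.25
        bound = 3 * np.sqrt(10_000 * p * (1 - p))
        for b, h in hits.items():
            assert abs(h - 10_000 * p) <= bound


class TestS2:
    def test_single_matching_block_containment(self, mini_geography):
        # category (Male, RaceB, 40+) in gB matches only b1
        rec = _rec(sex="Male", race="RaceB", age=50, unit="gB")
        cat = mini_geography.schema.category_index("Male", "RaceB", 50)
        assert mini_geography.matching_blocks("gB", cat) == ["b1"]
        ip = impute_s2(rec, mini_geography, np.random.default_rng(1))
        assert shapely.contains_xy(mini_geography.blocks["b1"].polygon,
                                   *ip.location)
        assert not ip.fallback_used

    def test_no_match_falls_back_to_unit_with_flag(self, mini_geography):
        rec = _rec(sex="Female", race="RaceA", age=50, unit="gA")  # cat 5
        ip = impute_s2(rec, mini_geography, np.random.default_rng(2))
        assert ip.fallback_used
        assert ip.status == "imputed"
        poly = mini_geography.unit_polygon("block_group", "gA")
        assert shapely.contains_xy(poly, *ip.location)

    def test_equal_area_matches_split_evenly(self, mini_geography):
        """Two equal-area matching blocks (a0, a1 for category 0): 10,000
        draws split 50/50 within 3 sigma."""
        rng = np.random.default_rng(3)
        rec = _rec()  # category 0 in gA -> matches a0, a1
        in_a0 = 0
        for _ in range(10_000):
            ip = impute_s2(rec, mini_geography, rng)
            in_a0 += mini_geography.locate_block(*ip.location) == "a0"
        assert abs(in_a0 - 5_000) <= 3 * np.sqrt(10_000 * 0.25)

    def test_population_weighting_switch(self, mini_geography):
        """With population weighting, block choice follows counts (3 vs 9),
        not areas (equal)."""
        rng = np.random.default_rng(6)
        in_a0 = 0
        for _ in range(4_000):
            ip = impute_s2(_rec(), mini_geography, rng,
                           weighting="population")
            in_a0 += mini_geography.locate_block(*ip.location) == "a0"
        expect = 4_000 * 0.25  # weight 3/12
        assert abs(in_a0 - expect) <= 3 * np.sqrt(4_000 * 0.25 * 0.75)


class TestS3:
    def test_argmax_weight_centroid(self, mini_geography):
        # weights (0.25, 0.75) over (a0, a1) -> centroid of a1
        ip = impute_s3(_rec(), mini_geography)
        assert ip.location == polygon_centroid(
            mini_geography.blocks["a1"].polygon)

    def test_zero_total_is_unimputable(self, mini_geography):
        rec = _rec(sex="Female", race="RaceA", age=50)  # category 5, empty
        ip = impute_s3(rec, mini_geography)
        assert ip.status == "unimputable"
        assert ip.location is None

    def test_artificial_clustering_same_category_same_point(
            self, mini_geography):
        a = impute_s3(_rec(rid="x"), mini_geography)
        b = impute_s3(_rec(rid="y"), mini_geography)
        assert a.location == b.location

    def test_tie_break_by_ascending_block_id(self, mini_schema):
        """Equal counts in two blocks: the lower block id wins."""
        from geoimpute import CensusBlock, CensusGeography
        counts = np.zeros(mini_schema.n_categories, dtype=np.int64)
        counts[0] = 5
        blocks = [
            CensusBlock("z1", "g", "t", "c", shapely.box(0, 0, 10, 10),
                        counts.copy()),
            CensusBlock("a9", "g", "t", "c", shapely.box(10, 0, 20, 10),
                        counts.copy()),
        ]
        g = CensusGeography(mini_schema, blocks)
        ip = impute_s3(_rec(unit="g"), g)
        assert ip.location == polygon_centroid(g.blocks["a9"].polygon)


class TestS4:
    def test_weighted_average_of_centroids(self, mini_geography):
        # centroids a0=(50,50), a1=(150,50); weights 0.25/0.75
        ip = impute_s4(_rec(), mini_geography)
        assert ip.location[0] == pytest.approx(0.25 * 50 + 0.75 * 150)
        assert ip.location[1] == pytest.approx(50.0)

    def test_single_matching_block_coincides_with_s3(self, mini_geography):
        rec = _rec(sex="Male", race="RaceB", age=50, unit="gB")
        assert impute_s4(rec, mini_geography).location == \
            impute_s3(rec, mini_geography).location

    def test_zero_total_is_unimputable(self, mini_geography):
        rec = _rec(sex="Female", race="RaceA", age=50)
        assert impute_s4(rec, mini_geography).status == "unimputable"

    def test_matches_brute_force_oracle(self, uniform_scenario):
        """S4 equals an independent sum(w_i * c_i) computed straight from
        counts and centroids, within 1e-9 m, on 200 synthetic records."""
        geography, records = uniform_scenario
        for rec in records[:200]:
            ip = impute_s4(rec, geography)
            cat = geography.schema.category_index(rec.sex, rec.race,
                                                  rec.age_years)
            bids = geography.member_blocks("block_group", rec.coarse_unit_id)
            cs = np.array([float(geography.blocks[b].counts[cat])
                           for b in bids])
            cents = np.array([polygon_centroid(geography.blocks[b].polygon)
                              for b in bids])
            expect = (cs[:, None] * cents).sum(axis=0) / cs.sum()
            assert abs(ip.location[0] - expect[0]) < 1e-9
            assert abs(ip.location[1] - expect[1]) < 1e-9

    def test_output_in_convex_hull_of_matching_centroids(
            self, uniform_scenario):
        geography, records = uniform_scenario
        for rec in records[:200]:
            ip = impute_s4(rec, geography)
            cat = geography.schema.category_index(rec.sex, rec.race,
                                                  rec.age_years)
            match = geography.matching_blocks(rec.coarse_unit_id, cat)
            hull = shapely.MultiPoint(
                [polygon_centroid(geography.blocks[b].polygon)
                 for b in match]).convex_hull
            assert hull.buffer(1e-6).contains(shapely.Point(ip.location))


class TestBatch:
    def test_row_counting(self, mini_geography):
        recs = [_rec(rid=f"r{i}") for i in range(10)]
        table = impute_batch(recs, mini_geography, n_replicates=10, seed=1)
        # 10 records x (2 stochastic x 10 reps + 2 deterministic x 1)
        assert len(table) == 220
        assert table.groupby("strategy").size().to_dict() \
            == {"S1": 100, "S2": 100, "S3": 10, "S4": 10}

    def test_same_master_seed_identical_table(self, mini_geography):
        recs = [_rec(rid=f"r{i}") for i in range(5)]
        t1 = impute_batch(recs, mini_geography, n_replicates=3, seed=9)
        t2 = impute_batch(recs, mini_geography, n_replicates=3, seed=9)
        assert t1.equals(t2)

    def test_results_independent_of_batch_order(self, mini_geography):
        recs = [_rec(rid=f"r{i}") for i in range(6)]
        t_fwd = impute_batch(recs, mini_geography, n_replicates=2, seed=9)
        t_rev = impute_batch(recs[::-1], mini_geography, n_replicates=2,
                             seed=9)
        key = ["record_id", "strategy", "replicate"]
        fwd = t_fwd.sort_values(key).reset_index(drop=True)
        rev = t_rev.sort_values(key).reset_index(drop=True)
        assert fwd.equals(rev)

    def test_unmatchable_records_unimputable_only_for_s3_s4(
            self, uniform_scenario):
        geography, records = uniform_scenario
        subset = make_unmatchable(records[:100], geography, 0.2,
                                  np.random.default_rng(5))
        table = impute_batch(subset, geography, n_replicates=2, seed=0)
        bad = table[table["status"] == "unimputable"]
        assert set(bad["strategy"]) == {"S3", "S4"}
        assert bad.groupby("strategy")["record_id"].nunique().eq(20).all()
        s2 = table[table["strategy"] == "S2"]
        assert s2[s2["fallback_used"]]["record_id"].nunique() == 20

    def test_invalid_arguments(self, mini_geography):
        with pytest.raises(ConfigError):
            impute_batch([_rec()], mini_geography, strategies=("S9",))
        with pytest.raises(ConfigError):
            impute_batch([_rec()], mini_geography, n_replicates=0)


def test_record_rng_streams_are_distinct():
    draws = {
        (rid, strat, rep): record_rng(1, rid, strat, rep).random()
        for rid in ("a", "b") for strat in ("S1", "S2") for rep in (1, 2)
    }
    assert len(set(draws.values())) == len(draws)
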