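"""Shared fixtures.

Heavy scenario runs (thousands of records, 10 replicates) are session-scoped
so the acceptance-style tests share one fit instead of re-imputing per test.
The hand-built mini geography uses a reduced 2 x 2 x 2 schema so expected
weights stay hand-checkable.
"""

import numpy as np
import pytest
import shapely

from geoimpute import (CensusBlock, CensusGeography, DemographicSchema,
                       GeoimputationStudy, PersonRecord)
from geoimpute.synthetic import generate_scenario, preset

MASTER_SEED = 1234


@pytest.fixture(scope="session")
def mini_schema():
    return DemographicSchema(
        sex_labels=("Male", "Female"),
        race_labels=("RaceA", "RaceB"),
        age_bin_edges=(0, 40),
    )


def _block(schema, bid, gid, tid, cid, x0, y0, side, counts):
    vec = np.zeros(schema.n_categories, dtype=np.int64)
    for cat, n in counts.items():
        vec[cat] = n
    return CensusBlock(
        block_id=bid, block_group_id=gid, tract_id=tid, county_id=cid,
        polygon=shapely.box(x0, y0, x0 + side, y0 + side), counts=vec,
    )


@pytest.fixture(scope="session")
def mini_geography(mini_schema):
    """Two block groups of four 100 m blocks each, two tracts, one county.

    Category 0 = (Male, RaceA, [0,40)).  Group gA counts for category 0:
    blocks a0..a3 = (3, 9, 0, 0) -> weights (0.25, 0.75, 0, 0).
    Category 5 has zero population everywhere in gA (no-match case).
    """
    s = mini_schema
    blocks = [
        _block(s, "a0", "gA", "tA", "c0", 0, 0, 100, {0: 3, 1: 5}),
        _block(s, "a1", "gA", "tA", "c0", 100, 0, 100, {0: 9, 2: 4}),
        _block(s, "a2", "gA", "tA", "c0", 0, 100, 100, {1: 2}),
        _block(s, "a3", "gA", "tA", "c0", 100, 100, 100, {2: 1}),
        _block(s, "b0", "gB", "tB", "c0", 200, 0, 100, {0: 7, 5: 2}),
        _block(s, "b1", "gB", "tB", "c0", 300, 0, 100, {3: 6}),
        _block(s, "b2", "gB", "tB", "c0", 200, 100, 100, {0: 1}),
        _block(s, "b3", "gB", "tB", "c0", 300, 100, 100, {4: 8}),
    ]
    return CensusGeography(s, blocks)


@pytest.fixture(scope="session")
def uniform_scenario():
    return generate_scenario(preset("uniform", seed=MASTER_SEED))


@pytest.fixture(scope="session")
def clustered_scenario():
    return generate_scenario(preset("clustered_minorities", seed=MASTER_SEED))


@pytest.fixture(scope="session")
def density_scenario():
    return generate_scenario(preset("density_gradient", seed=MASTER_SEED))


@pytest.fixture(scope="session")
def clustered_fit(clustered_scenario):
    """The main multi-replicate study run on the clustered preset."""
    geography, records = clustered_scenario
    study = GeoimputationStudy(records, geography, n_replicates=10)
    return study.fit(seed=MASTER_SEED)


@pytest.fixture(scope="session")
def density_fit(density_scenario):
    geography, records = density_scenario
    study = GeoimputationStudy(records, geography)
    return study.fit(seed=MASTER_SEED)
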