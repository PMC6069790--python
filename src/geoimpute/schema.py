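"""The demographic category space: sex x race x age range.

Census SF1 block counts are tabulated by sex (2), race/ethnicity group (9
tabulation groups) and age range (23 ranges), giving 2 x 9 x 23 = 414
distinct demographic categories.  Every block carries an integer count
vector over these categories, and every person record resolves to exactly
one category, which drives the demographically weighted strategies.

Category ordering is sex-major, then race, then age bin::

    index = sex_i * (n_race * n_age) + race_i * n_age + age_bin_i

The ordering is arbitrary but fixed; all serialized count tables use the
label triple, not the index, so the convention is internal.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Sequence

from .errors import CategoryResolutionError, ValidationError

#: SF1-style sex labels.
SF1_SEXES = ("Male", "Female")

#: The nine SF1 race/ethnicity tabulation groups (iterations A-I).
SF1_RACES = (
    "White alone",
    "Black or African American alone",
    "American Indian and Alaska Native alone",
    "Asian alone",
    "Native Hawaiian and Other Pacific Islander alone",
    "Some Other Race alone",
    "Two or More Races",
    "Hispanic or Latino",
    "White alone, not Hispanic or Latino",
)

#: Left edges of the 23 SF1 age ranges (years); the last range is open-ended
#: (85+).  Bins are right-open: [0,5), [5,10), ..., [80,85), [85, inf).
SF1_AGE_EDGES = (
    0, 5, 10, 15, 18, 20, 21, 22, 25, 30, 35, 40,
    45, 50, 55, 60, 62, 65, 67, 70, 75, 80, 85,
)


@dataclass(frozen=True)
class DemographicSchema:
    """The sex x race x age-range category space.

    Parameters
    ----------
    sex_labels, race_labels
        Ordered label sequences; order fixes the category indexing.
    age_bin_edges
        Strictly increasing left edges of right-open age bins, in years.
        The last bin is open-ended, so ``len(age_bin_edges)`` bins exist.
        The first edge must be 0 so every non-negative age falls in a bin.
    """

    sex_labels: tuple[str, ...] = SF1_SEXES
    race_labels: tuple[str, ...] = SF1_RACES
    age_bin_edges: tuple[int, ...] = SF1_AGE_EDGES

    _sex_index: dict = field(init=False, repr=False, compare=False)
    _race_index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "sex_labels", tuple(self.sex_labels))
        object.__setattr__(self, "race_labels", tuple(self.race_labels))
        object.__setattr__(self, "age_bin_edges", tuple(self.age_bin_edges))
        edges = self.age_bin_edges
        if len(edges) == 0 or edges[0] != 0:
            raise ValidationError("age_bin_edges must start at 0")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValidationError("age_bin_edges must be strictly increasing")
        if len(set(self.sex_labels)) != len(self.sex_labels):
            raise ValidationError("duplicate sex labels")
        if len(set(self.race_labels)) != len(self.race_labels):
            raise ValidationError("duplicate race labels")
        object.__setattr__(
            self, "_sex_index", {s: i for i, s in enumerate(self.sex_labels)}
        )
        object.__setattr__(
            self, "_race_index", {r: i for i, r in enumerate(self.race_labels)}
        )

    # -- cardinalities -------------------------------------------------
    @property
    def n_sexes(self) -> int:
        return len(self.sex_labels)

    @property
    def n_races(self) -> int:
        return len(self.race_labels)

    @property
    def n_age_bins(self) -> int:
        return len(self.age_bin_edges)

    @property
    def n_categories(self) -> int:
        """Total number of demographic categories (414 for the default)."""
        return self.n_sexes * self.n_races * self.n_age_bins

    # -- resolution ----------------------------------------------------
    def age_bin(self, age_years: int) -> int:
        """Index of the right-open age bin containing ``age_years``."""
        if age_years < 0:
            raise CategoryResolutionError("age", age_years)
        return bisect.bisect_right(self.age_bin_edges, age_years) - 1

    def age_bin_label(self, bin_index: int) -> str:
        """Human-readable label for an age bin, e.g. ``'70-74'`` or ``'85+'``."""
        lo = self.age_bin_edges[bin_index]
        if bin_index == self.n_age_bins - 1:
            return f"{lo}+"
        hi = self.age_bin_edges[bin_index + 1] - 1
        return str(lo) if hi == lo else f"{lo}-{hi}"

    def category_index(self, sex: str, race: str, age_years: int) -> int:
        """Map (sex, race, age) to the stable category index.

        Bijective over (sex, race, age-bin) triples; raises
        :class:`CategoryResolutionError` for labels outside the schema, so
        registry race vocabularies must be mapped to census ones first
        (see :meth:`apply_race_mapping`).
        """
        try:
            si = self._sex_index[sex]
        except KeyError:
            raise CategoryResolutionError("sex", sex) from None
        try:
            ri = self._race_index[race]
        except KeyError:
            raise CategoryResolutionError("race", race) from None
        ai = self.age_bin(age_years)
        return (si * self.n_races + ri) * self.n_age_bins + ai

    def category_triple(self, index: int) -> tuple[str, str, str]:
        """Inverse of :meth:`category_index` up to the age bin:
        returns (sex, race, age-bin label)."""
        if not 0 <= index < self.n_categories:
            raise CategoryResolutionError("category index", index)
        ai = index % self.n_age_bins
        rest = index // self.n_age_bins
        ri = rest % self.n_races
        si = rest // self.n_races
        return self.sex_labels[si], self.race_labels[ri], self.age_bin_label(ai)

    def iter_triples(self):
        """All (sex, race, age-bin-index) triples in index order."""
        for si, sex in enumerate(self.sex_labels):
            for ri, race in enumerate(self.race_labels):
                for ai in range(self.n_age_bins):
                    yield sex, race, ai


def apply_race_mapping(race: str, mapping: dict[str, str] | None) -> str:
    """Translate a source-vocabulary race label to a schema label.

    Registry data often uses a different race vocabulary than the census
    tabulation groups (e.g. a registry 'white, unknown ethnicity' mapping to
    'White alone', and 'white Hispanic' to 'Hispanic or Latino').  The
    mapping is user-supplied, never hard-coded; labels absent from the
    mapping pass through unchanged.
    """
    if mapping is None:
        return race
    return mapping.get(race, race)


def category_index(schema: DemographicSchema, sex: str, race: str,
                   age_years: int) -> int:
    """Functional alias for :meth:`DemographicSchema.category_index`."""
    return schema.category_index(sex, race, age_years)
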