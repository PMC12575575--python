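"""Shared vocabulary: land classes, fertility classes, species, event types.

Fertility classes follow the Finnish site-type ordering from most to least
productive: herb-rich > mesic > sub-xeric > xeric.  Several rules key off
this ordering (e.g. harvest-export duration is 6 years on mesic-or-better
peat sites and 4 years on sub-xeric-or-poorer ones), so an explicit rank is
provided.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .errors import ConfigurationError


class LandClass(enum.StrEnum):
    MINERAL = "mineral"
    DRAINED_PEAT = "drained_peat"
    UNDRAINED_PEAT = "undrained_peat"
    NONFOREST = "nonforest"


class Fertility(enum.StrEnum):
    HERB_RICH = "herb_rich"
    MESIC = "mesic"
    SUB_XERIC = "sub_xeric"
    XERIC = "xeric"


#: productivity rank, 0 = most fertile
FERTILITY_RANK = {
    Fertility.HERB_RICH: 0,
    Fertility.MESIC: 1,
    Fertility.SUB_XERIC: 2,
    Fertility.XERIC: 3,
}


class Species(enum.StrEnum):
    PINE = "pine"
    SPRUCE = "spruce"
    BIRCH = "birch"
    MIXED = "mixed"


class Origin(enum.StrEnum):
    PLANTED = "planted"
    SEEDED = "seeded"
    NATURAL = "natural"


class EventType(enum.StrEnum):
    CLEAR_CUT = "clear_cut"
    SEED_TREE_FELLING = "seed_tree_felling"
    THINNING_BELOW = "thinning_below"
    THINNING_ABOVE = "thinning_above"
    CCF_HARVEST = "ccf_harvest"
    SITE_PREPARATION = "site_preparation"
    PLANTING = "planting"
    SEEDING = "seeding"
    TENDING = "tending"
    FERTILIZATION_MINERAL_N = "fertilization_mineral_N"
    FERTILIZATION_PEAT_ASH = "fertilization_peat_ash"
    DNM = "dnm"


#: events that remove stem volume
HARVEST_EVENTS = frozenset(
    {
        EventType.CLEAR_CUT,
        EventType.SEED_TREE_FELLING,
        EventType.THINNING_BELOW,
        EventType.THINNING_ABOVE,
        EventType.CCF_HARVEST,
    }
)

#: final fellings that terminate an even-aged rotation
FINAL_FELLINGS = frozenset({EventType.CLEAR_CUT, EventType.SEED_TREE_FELLING})


class Management(enum.StrEnum):
    """Forest-management system."""

    RF = "RF"  # rotation forestry per current recommendations
    ERP = "ERP"  # extended rotation period (mineral soils only)
    CCF = "CCF"  # continuous cover forestry
    NONE = "none"  # no forestry operations


class Protection(enum.StrEnum):
    """Water-protection practice applied in a scenario (one at a time)."""

    NONE = "none"
    PONDS = "ponds"
    DAMS = "dams"
    WETLANDS = "wetlands"
    RIPARIAN = "riparian"


class Nutrient(enum.StrEnum):
    N = "N"
    P = "P"


@dataclass(frozen=True)
class ClimateParams:
    """Climate constants of the simulated catchment.

    summer_precip_mm
        Mean monthly precipitation (mm) in July–August; enters the
        water-table regression.  The default of 70 mm/month is consistent
        with an annual total around 520 mm in the central-boreal zone.
    latitude_deg
        Northern latitude in degrees (regression covariate).
    temperature_sum_dd
        Effective temperature sum (degree days, +5 °C threshold); scales the
        surrogate growth model and the continuous-cover cutting threshold.
    """

    summer_precip_mm: float = 70.0
    latitude_deg: float = 65.0
    temperature_sum_dd: float = 1000.0

    def __post_init__(self) -> None:
        if self.summer_precip_mm <= 0:
            raise ConfigurationError("summer_precip_mm must be positive")
        if self.temperature_sum_dd <= 0:
            raise ConfigurationError("temperature_sum_dd must be positive")
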