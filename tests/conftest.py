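import numpy as np
import pytest

from catchex import (
    CatchmentConfig,
    ClimateParams,
    ManagementRules,
    StandCompartment,
    generate_catchment,
)
from catchex.types import Fertility, LandClass, Origin, Species


@pytest.fixture
def rules():
    return ManagementRules()


@pytest.fixture
def climate():
    return ClimateParams()


@pytest.fixture
def make_compartment():
    """Factory for hand-built compartments with sensible defaults."""

    def _make(
        diam=(10.0, 20.0, 30.0),
        stems=(400.0, 300.0, 100.0),
        land_class=LandClass.MINERAL,
        fertility=Fertility.MESIC,
        species=Species.SPRUCE,
        origin=Origin.NATURAL,
        **kw,
    ):
        defaults = dict(
            id=kw.pop("id", "t0"),
            area_ha=kw.pop("area_ha", 2.0),
            land_class=land_class,
            fertility=fertility,
            dominant_species=species,
            origin=origin,
            diam_cm=np.asarray(diam, float),
            stems_ha=np.asarray(stems, float),
            age_years=kw.pop("age_years", 60.0),
        )
        if LandClass(land_class) is LandClass.DRAINED_PEAT:
            defaults["ditch_depth_cm"] = kw.pop("ditch_depth_cm", 60.0)
        defaults.update(kw)
        return StandCompartment(**defaults)

    return _make


@pytest.fixture(scope="session")
def small_register():
    """A 300-compartment synthetic register shared by read-only tests."""
    return generate_catchment(CatchmentConfig(n_compartments=300, seed=42))
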