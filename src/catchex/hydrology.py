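"""Peatland hydrology: August water-table level and drainage-legacy exports.

Drained peatlands keep releasing N and P decades after drainage because a
deep water table lets the peat below the rooting zone mineralize aerobically.
The simulator captures this with two maps:

1. A published empirical regression for the late-summer (August) water-table
   level (WTL, cm below the soil surface; positive = deeper) in drained
   peatland stands::

       WTL = 47.92 + 159.83*(1 - 0.3**(V/90))
             - 30.684*(1 - 0.3**(V/90))*ln(S)
             + 8.095*ln(D) - 0.73*LAT - 0.185*S

   where V is growing-stock volume (m3/ha), S the mean monthly July–August
   precipitation (mm), D the average ditch depth (cm) and LAT the northern
   latitude (deg).  A larger standing volume means more evapotranspiration
   and hence a deeper water table.

2. A fertility-specific monotone response mapping WTL to annual legacy N and
   P export (kg/ha/yr).  The published curves come from a process-based
   peatland simulator and are available only graphically, so the default
   here is a piecewise-linear hinge, export = slope * max(0, WTL - WTL0),
   with per-fertility slopes calibrated so a mature synthetic register's
   catchment-mean legacy N export falls in the 0.3-0.6 kg/ha/yr band typical
   of first-period scenario results.  Users can substitute their own curve
   parameters via configuration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .types import Fertility, Nutrient

__all__ = ["WTLInputs", "LegacyResponse", "compute_wtl", "legacy_export"]


@dataclass(frozen=True)
class WTLInputs:
    """Inputs of the water-table-level regression.

    The regression was fitted on Finnish drained-peatland plots; latitudes
    outside (59, 71) degrees north are outside the calibration domain and
    trigger a warning, not an error.
    """

    volume_m3_ha: float
    summer_precip_mm: float
    ditch_depth_cm: float
    latitude_deg: float

    def __post_init__(self) -> None:
        if self.volume_m3_ha < 0:
            raise ConfigurationError("growing-stock volume must be >= 0")
        if self.summer_precip_mm <= 0:
            raise ConfigurationError("summer precipitation must be > 0 (log argument)")
        if self.ditch_depth_cm <= 0:
            raise ConfigurationError("ditch depth must be > 0 (log argument)")
        if not 59.0 < self.latitude_deg < 71.0:
            warnings.warn(
                "latitude outside the WTL model's calibration domain (59..71 N)",
                stacklevel=3,
            )


def compute_wtl(inputs: WTLInputs) -> float:
    """August water-table level (cm below surface) for one compartment."""
    return float(
        wtl_from_arrays(
            np.asarray(inputs.volume_m3_ha, float),
            inputs.summer_precip_mm,
            inputs.ditch_depth_cm,
            inputs.latitude_deg,
        )
    )


def wtl_from_arrays(volume_m3_ha, summer_precip_mm, ditch_depth_cm, latitude_deg):
    """Vectorized water-table regression (volume may be an array)."""
    v = np.asarray(volume_m3_ha, dtype=float)
    s = float(summer_precip_mm)
    d = float(ditch_depth_cm)
    lat = float(latitude_deg)
    if s <= 0 or d <= 0:
        raise ConfigurationError("precipitation and ditch depth must be positive")
    if np.any(v < 0):
        raise ConfigurationError("volume must be >= 0")
    canopy = 1.0 - 0.3 ** (v / 90.0)
    return (
        47.92
        + 159.83 * canopy
        - 30.684 * canopy * math.log(s)
        + 8.095 * math.log(d)
        - 0.73 * lat
        - 0.185 * s
    )


_DEFAULT_SLOPES = {
    # kg/ha/yr per cm of water-table depth beyond the hinge
    Fertility.HERB_RICH: {Nutrient.N: 0.040, Nutrient.P: 0.0046},
    Fertility.MESIC: {Nutrient.N: 0.032, Nutrient.P: 0.0036},
    Fertility.SUB_XERIC: {Nutrient.N: 0.024, Nutrient.P: 0.0026},
    Fertility.XERIC: {Nutrient.N: 0.017, Nutrient.P: 0.0018},
}


@dataclass
class LegacyResponse:
    """Hinge response: export = slope[fertility][nutrient] * max(0, WTL - wtl0).

    ``wtl0_cm`` is the water-table depth at which legacy export vanishes
    (default 30 cm); exports are zero at or above it (shallower water table)
    and increase linearly with depth below it.  More fertile classes have
    steeper slopes, so at equal WTL a fertile site exports at least as much
    as a poorer one.
    """

    wtl0_cm: float = 30.0
    slopes: dict = field(default_factory=lambda: {
        f: dict(v) for f, v in _DEFAULT_SLOPES.items()
    })

    def __post_init__(self) -> None:
        slopes = {}
        for f, sub in self.slopes.items():
            sub = {Nutrient(k): float(v) for k, v in sub.items()}
            if any(v < 0 for v in sub.values()):
                raise ConfigurationError("legacy-response slopes must be >= 0")
            slopes[Fertility(f)] = sub
        self.slopes = slopes

    def slope(self, fertility: Fertility, nutrient: Nutrient) -> float:
        fertility = Fertility(fertility)
        if fertility not in self.slopes:
            raise ConfigurationError(f"no legacy response for fertility {fertility!r}")
        return self.slopes[fertility][Nutrient(nutrient)]


def legacy_export(
    wtl_cm: float, fertility: Fertility, response: LegacyResponse | None = None
) -> tuple[float, float]:
    """Annual legacy (N, P) export in kg/ha/yr at a given water-table depth."""
    if response is None:
        response = LegacyResponse()
    if not np.all(np.isfinite(wtl_cm)):
        raise ConfigurationError("WTL must be finite")
    excess = max(0.0, float(wtl_cm) - response.wtl0_cm)
    return (
        response.slope(fertility, Nutrient.N) * excess,
        response.slope(fertility, Nutrient.P) * excess,
    )


def legacy_export_arrays(
    wtl_cm: np.ndarray, fertility: Fertility, response: LegacyResponse
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized hinge response over a WTL trajectory."""
    excess = np.maximum(0.0, np.asarray(wtl_cm, float) - response.wtl0_cm)
    return (
        response.slope(fertility, Nutrient.N) * excess,
        response.slope(fertility, Nutrient.P) * excess,
    )
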