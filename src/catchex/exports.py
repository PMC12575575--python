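"""Operation-induced nutrient exports.

Each forestry operation adds an annual N and P export increment per treated
hectare for a limited number of years after treatment ("export
coefficients", kg/ha/yr, indexed by years since treatment, year 1 = first
year following the operation):

* ditch-network maintenance (DNM) on drained peat: a 10-year declining
  schedule of particulate (suspended-solids-bound) N and P;
* fertilization: ammonium nitrate on mineral soils leaks N for two years,
  wood ash on drained peat leaks P for five years (no N: peat is not
  N-fertilized);
* clear-cutting on mineral soils: a 10-year schedule for N and P; partial
  harvests on mineral soils are export-free;
* any harvest on drained peat (clear-cut, thinning, selection cut): a
  constant annual export for 4 years (sub-xeric or poorer) or 6 years
  (mesic or better), at a level given by a logistic function of the
  harvested stem volume Vcut (m3/ha)::

      N = 10  / (1 + exp(-(-3.3375 + 0.0164 * Vcut)))
      P = 1.3 / (1 + exp(-(-5.1772 + 0.0209 * Vcut)))

The DNM coefficients already embed the back-correction for water-protection
efficiency and the suspended-solids N/P concentrations; they are used as
printed and nothing is re-applied.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, UsageError
from .register import ManagementEvent, StandCompartment
from .types import (
    FERTILITY_RANK,
    HARVEST_EVENTS,
    EventType,
    Fertility,
    LandClass,
    Nutrient,
)

__all__ = [
    "Operation",
    "ExportCoefficientTable",
    "HarvestExportParams",
    "ExportSchedule",
    "coefficient_lookup",
    "harvest_export_peat",
    "event_export_schedule",
]


class Operation(enum.StrEnum):
    """Coefficient-based operations of the export-coefficient table."""

    DNM = "dnm"
    FERT_MINERAL = "fert_mineral"
    FERT_PEAT = "fert_peat"
    CLEARCUT_MINERAL = "clearcut_mineral"


_DEFAULT_COEFFICIENTS = {
    (Operation.DNM, Nutrient.N): (4.00, 1.33, 1.07, 0.80, 0.67, 0.53, 0.40, 0.27, 0.13, 0.07),
    (Operation.DNM, Nutrient.P): (0.288, 0.096, 0.077, 0.058, 0.048, 0.038, 0.029, 0.019, 0.010, 0.005),
    (Operation.FERT_MINERAL, Nutrient.N): (12.0, 3.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    (Operation.FERT_MINERAL, Nutrient.P): (0.0,) * 10,
    (Operation.FERT_PEAT, Nutrient.N): (0.0,) * 10,
    (Operation.FERT_PEAT, Nutrient.P): (0.27, 0.27, 0.27, 0.27, 0.27, 0.0, 0.0, 0.0, 0.0, 0.0),
    (Operation.CLEARCUT_MINERAL, Nutrient.N): (1.43, 1.42, 1.61, 1.41, 1.21, 1.01, 0.81, 0.60, 0.40, 0.20),
    (Operation.CLEARCUT_MINERAL, Nutrient.P): (0.20, 0.21, 0.20, 0.18, 0.15, 0.13, 0.10, 0.08, 0.05, 0.03),
}

SCHEDULE_YEARS = 10


@dataclass
class ExportCoefficientTable:
    """Per-operation, per-nutrient 10-year export-coefficient schedules."""

    coefficients: dict = field(
        default_factory=lambda: {k: tuple(v) for k, v in _DEFAULT_COEFFICIENTS.items()}
    )

    def __post_init__(self) -> None:
        table = {}
        for key, vals in self.coefficients.items():
            op, nut = key
            vals = tuple(float(v) for v in vals)
            if len(vals) != SCHEDULE_YEARS:
                raise ConfigurationError(
                    f"coefficient schedule for {key} must have {SCHEDULE_YEARS} entries"
                )
            if any(v < 0 for v in vals):
                raise ConfigurationError(f"negative coefficient in schedule {key}")
            table[(Operation(op), Nutrient(nut))] = vals
        for op in Operation:
            for nut in Nutrient:
                if (op, nut) not in table:
                    raise ConfigurationError(f"missing schedule for ({op}, {nut})")
        self.coefficients = table

    def lookup(self, operation: Operation, nutrient: Nutrient, years_since: int) -> float:
        if years_since < 1 or not float(years_since).is_integer():
            raise ConfigurationError("years_since_treatment must be an integer >= 1")
        try:
            sched = self.coefficients[(Operation(operation), Nutrient(nutrient))]
        except ValueError as exc:
            raise ConfigurationError(str(exc)) from None
        years_since = int(years_since)
        if years_since > SCHEDULE_YEARS:
            return 0.0
        return sched[years_since - 1]

    def schedule(self, operation: Operation, nutrient: Nutrient) -> np.ndarray:
        return np.asarray(
            self.coefficients[(Operation(operation), Nutrient(nutrient))], float
        )


def coefficient_lookup(
    operation: Operation,
    nutrient: Nutrient,
    years_since_treatment: int,
    table: ExportCoefficientTable | None = None,
) -> float:
    """Export coefficient (kg/ha/yr) for an operation at a given lag.

    Year 1 is the first year following the treatment; beyond year 10 the
    schedule is exhausted and the coefficient is zero.
    """
    if table is None:
        table = ExportCoefficientTable()
    return table.lookup(operation, nutrient, years_since_treatment)


@dataclass(frozen=True)
class HarvestExportParams:
    """Logistic harvested-volume response for drained-peatland harvests.

    ``export = asymptote / (1 + exp(-(intercept + slope * Vcut)))`` with the
    published N and P parameterizations as defaults.  Export duration is 4
    years on low-productive sites (sub-xeric or poorer) and 6 years on
    fertile sites (mesic or better).
    """

    n_asymptote: float = 10.0
    n_intercept: float = -3.3375
    n_slope: float = 0.0164
    p_asymptote: float = 1.3
    p_intercept: float = -5.1772
    p_slope: float = 0.0209
    duration_poor_years: int = 4
    duration_fertile_years: int = 6

    def __post_init__(self) -> None:
        if self.n_asymptote <= 0 or self.p_asymptote <= 0:
            raise ConfigurationError("asymptotes must be positive")
        if self.n_slope <= 0 or self.p_slope <= 0:
            raise ConfigurationError("slopes must be positive")

    def duration_years(self, fertility: Fertility) -> int:
        if FERTILITY_RANK[Fertility(fertility)] <= FERTILITY_RANK[Fertility.MESIC]:
            return self.duration_fertile_years
        return self.duration_poor_years


def harvest_export_peat(
    v_cut_m3_ha: float,
    nutrient: Nutrient,
    params: HarvestExportParams | None = None,
) -> float:
    """Annual harvest-induced export (kg/ha/yr) from a drained-peat harvest."""
    if params is None:
        params = HarvestExportParams()
    if v_cut_m3_ha < 0:
        raise ConfigurationError("harvested volume must be >= 0")
    nutrient = Nutrient(nutrient)
    if nutrient is Nutrient.N:
        a, b0, b1 = params.n_asymptote, params.n_intercept, params.n_slope
    else:
        a, b0, b1 = params.p_asymptote, params.p_intercept, params.p_slope
    return a / (1.0 + math.exp(-(b0 + b1 * v_cut_m3_ha)))


@dataclass(frozen=True)
class ExportSchedule:
    """Annual per-hectare (N, P) export increments caused by one event.

    ``n_kg_ha`` / ``p_kg_ha`` are indexed by years-since-treatment minus one:
    element 0 applies to the first year *after* the event year.  DNM
    schedules carry ``particulate=True`` so that settling-based protection
    structures (ponds, peak-runoff-control dams) can target them.
    """

    n_kg_ha: tuple
    p_kg_ha: tuple
    particulate: bool = False
    source: str = "harvest"

    def __len__(self) -> int:
        return len(self.n_kg_ha)


_ZERO = ExportSchedule((), (), False, "none")

_NEUTRAL_EVENTS = frozenset(
    {
        EventType.SITE_PREPARATION,
        EventType.PLANTING,
        EventType.SEEDING,
        EventType.TENDING,
    }
)


def event_export_schedule(
    event: ManagementEvent,
    compartment: StandCompartment,
    table: ExportCoefficientTable | None = None,
    harvest_params: HarvestExportParams | None = None,
) -> ExportSchedule:
    """Map a management event on a compartment to its per-hectare export schedule.

    Raises :class:`UsageError` when the operation is undefined for the
    compartment's land class (e.g. DNM on mineral soil).
    """
    if table is None:
        table = ExportCoefficientTable()
    if harvest_params is None:
        harvest_params = HarvestExportParams()
    lc = compartment.land_class
    et = event.event_type

    if et in _NEUTRAL_EVENTS:
        return _ZERO

    if et is EventType.DNM:
        if lc is not LandClass.DRAINED_PEAT:
            raise UsageError("DNM is only defined on drained peatland")
        return ExportSchedule(
            tuple(table.schedule(Operation.DNM, Nutrient.N)),
            tuple(table.schedule(Operation.DNM, Nutrient.P)),
            particulate=True,
            source="dnm",
        )

    if et is EventType.FERTILIZATION_MINERAL_N:
        if lc is not LandClass.MINERAL:
            raise UsageError("N fertilization schedule applies to mineral soils only")
        return ExportSchedule(
            tuple(table.schedule(Operation.FERT_MINERAL, Nutrient.N)),
            tuple(table.schedule(Operation.FERT_MINERAL, Nutrient.P)),
            source="fertilization",
        )

    if et is EventType.FERTILIZATION_PEAT_ASH:
        if lc is not LandClass.DRAINED_PEAT:
            raise UsageError("ash fertilization schedule applies to drained peat only")
        return ExportSchedule(
            tuple(table.schedule(Operation.FERT_PEAT, Nutrient.N)),
            tuple(table.schedule(Operation.FERT_PEAT, Nutrient.P)),
            source="fertilization",
        )

    if et in HARVEST_EVENTS:
        if lc is LandClass.MINERAL:
            if et in (EventType.CLEAR_CUT, EventType.SEED_TREE_FELLING):
                return ExportSchedule(
                    tuple(table.schedule(Operation.CLEARCUT_MINERAL, Nutrient.N)),
                    tuple(table.schedule(Operation.CLEARCUT_MINERAL, Nutrient.P)),
                    source="harvest",
                )
            # partial harvests on mineral soils are export-free
            return _ZERO
        if lc is LandClass.DRAINED_PEAT:
            dur = harvest_params.duration_years(compartment.fertility)
            n = harvest_export_peat(event.removed_volume_m3_ha, Nutrient.N, harvest_params)
            p = harvest_export_peat(event.removed_volume_m3_ha, Nutrient.P, harvest_params)
            return ExportSchedule((n,) * dur, (p,) * dur, source="harvest")
        raise UsageError(f"harvest events are undefined on land class {lc}")

    raise UsageError(f"unhandled event type {et}")
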