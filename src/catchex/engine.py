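"""Scenario engine: 50-year management x protection runs over a register.

For every compartment and 10-year period the engine steps the stand through
the management rule set, converts emitted events into export schedules,
adds the annual drainage-legacy export of drained-peat compartments (via
the water-table regression evaluated on the evolving stand volume), and
finally applies the scenario's water-protection practice to the assembled
ledger.  Outputs mirror the standard reporting surfaces: per-period mean
annual harvest volumes by land class, accumulated per-hectare exports by
land class, and the harvest-volume vs. export relation.

The ledger keeps one entry per (compartment, year, source, nutrient) with
the generated and retained mass in kg, so delivered = generated - retained
holds exactly by construction at any aggregation level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import ManagementRules, step_period
from .errors import ConfigurationError
from .exports import (
    ExportCoefficientTable,
    HarvestExportParams,
    event_export_schedule,
)
from .hydrology import LegacyResponse, legacy_export_arrays, wtl_from_arrays
from .protection import LEDGER_COLUMNS, RetentionModels, apply_protection
from .register import StandRegister
from .types import (
    HARVEST_EVENTS,
    ClimateParams,
    LandClass,
    Management,
    Nutrient,
    Protection,
)

__all__ = [
    "ScenarioSpec",
    "ExportLedger",
    "ScenarioResult",
    "run_scenario",
    "accumulate",
    "harvest_export_relation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScenarioSpec:
    """One management x protection scenario.

    The extended-rotation system is defined for mineral soils only; a
    register containing forested drained peatland is rejected for ERP.
    Exactly one protection practice applies per scenario (combinations are
    out of scope).
    """

    management: Management = Management.RF
    protection: Protection = Protection.NONE
    horizon_years: int = 50
    period_length: int = 10
    climate: ClimateParams = field(default_factory=ClimateParams)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "management", Management(self.management))
        object.__setattr__(self, "protection", Protection(self.protection))
        if self.period_length < 2 or self.horizon_years <= 0:
            raise ConfigurationError("horizon and period length must be positive")
        if self.horizon_years % self.period_length != 0:
            raise ConfigurationError("horizon must be divisible by the period length")

    @property
    def n_periods(self) -> int:
        return self.horizon_years // self.period_length


class ExportLedger:
    """Annual N and P export entries per compartment and source.

    ``entries`` is a tidy frame with columns ``compartment_id, land_class,
    area_ha, year, source, nutrient, kg, particulate, retained_kg``; mass
    delivered to the water body is ``kg - retained_kg``.
    """

    def __init__(self, entries: pd.DataFrame, class_area_ha: dict, horizon_years: int):
        missing = [c for c in LEDGER_COLUMNS if c not in entries.columns]
        if missing:
            raise ConfigurationError(f"ledger frame lacks columns {missing}")
        if len(entries):
            if (entries["kg"] < 0).any():
                raise ConfigurationError("negative export mass in ledger")
            if (entries["retained_kg"] > entries["kg"] + 1e-9).any():
                raise ConfigurationError("retained mass exceeds generated mass")
        self.entries = entries.reset_index(drop=True)
        self.class_area_ha = {LandClass(k): float(v) for k, v in class_area_ha.items()}
        self.horizon_years = int(horizon_years)

    # -- aggregation ------------------------------------------------------
    def delivered(self) -> pd.Series:
        return self.entries["kg"] - self.entries["retained_kg"]

    def totals(self) -> dict:
        """Generated/retained/delivered totals (kg) per nutrient."""
        out = {}
        for nut in Nutrient:
            sub = self.entries[self.entries["nutrient"] == str(nut)]
            gen = float(sub["kg"].sum())
            ret = float(sub["retained_kg"].sum())
            out[str(nut)] = {"generated": gen, "retained": ret, "delivered": gen - ret}
        return out

    def accumulate(self, land_class: LandClass, nutrient: Nutrient) -> np.ndarray:
        """Cumulative delivered export (kg/ha of land-class area) per year."""
        lc = LandClass(land_class)
        area = self.class_area_ha.get(lc, 0.0)
        series = np.zeros(self.horizon_years)
        if area <= 0:
            return series
        sub = self.entries[
            (self.entries["land_class"] == str(lc))
            & (self.entries["nutrient"] == str(Nutrient(nutrient)))
        ]
        if len(sub):
            delivered = (sub["kg"] - sub["retained_kg"]).to_numpy()
            np.add.at(series, sub["year"].to_numpy(int), delivered / area)
        return np.cumsum(series)

    def period_mean_kg_ha_yr(
        self, land_class: LandClass, nutrient: Nutrient, period_length: int = 10
    ) -> np.ndarray:
        """Mean annual delivered export (kg/ha/yr) per reporting period."""
        annual = np.diff(np.concatenate(([0.0], self.accumulate(land_class, nutrient))))
        n_per = self.horizon_years // period_length
        return annual[: n_per * period_length].reshape(n_per, period_length).mean(axis=1)

    def write(self, path) -> None:
        self.entries.to_csv(path, index=False)


@dataclass
class ScenarioResult:
    """Ledger plus the per-period harvest-volume series of one scenario run."""

    spec: ScenarioSpec
    ledger: ExportLedger
    harvest_series: pd.DataFrame  # land_class, period, m3_ha_yr


def run_scenario(
    register: StandRegister,
    spec: ScenarioSpec,
    rules: ManagementRules | None = None,
    models: RetentionModels | None = None,
    legacy_response: LegacyResponse | None = None,
    coefficients: ExportCoefficientTable | None = None,
    harvest_params: HarvestExportParams | None = None,
) -> ScenarioResult:
    """Simulate one scenario over a register and assemble its export ledger.

    Deterministic: identical (register, spec) pairs give identical ledgers.
    The no-management system still grows the stands, because drainage-legacy
    exports depend on the evolving stand volume through the water-table
    regression.  Legacy exports accrue only on drained peatland; mineral
    compartments have no legacy term.
    """
    rules = rules or ManagementRules()
    models = models or RetentionModels()
    legacy_response = legacy_response or LegacyResponse()
    coefficients = coefficients or ExportCoefficientTable()
    harvest_params = harvest_params or HarvestExportParams()

    if spec.management is Management.ERP and any(
        c.land_class is LandClass.DRAINED_PEAT for c in register
    ):
        raise ConfigurationError(
            "extended rotation (ERP) is not defined for drained peatland forests; "
            "run it on the mineral-soil subset"
        )

    rng = np.random.default_rng(spec.seed)
    horizon = spec.horizon_years
    plen = spec.period_length
    n_periods = spec.n_periods

    cols: dict[str, list] = {c: [] for c in LEDGER_COLUMNS}
    harvest_m3: dict[tuple[LandClass, int], float] = {}
    event_counts = np.zeros(n_periods, int)

    for comp0 in register:
        lc = comp0.land_class
        if lc in (LandClass.UNDRAINED_PEAT, LandClass.NONFOREST):
            continue  # carried in the register; no forestry-induced exports

        comp = comp0.copy()
        pre_events = list(comp.event_history)
        emitted = []
        vols: list[float] = []
        for p in range(n_periods):
            comp, ev, v = step_period(comp, spec.management, rules, spec.climate, p, rng, plen)
            emitted.extend(ev)
            vols.extend(v)
            event_counts[p] += len(ev)

        for event in pre_events + emitted:
            sched = event_export_schedule(event, comp0, coefficients, harvest_params)
            if len(sched) == 0:
                continue
            area = event.treated_area_ha if event.treated_area_ha > 0 else comp0.area_ha
            for k in range(len(sched)):
                year = event.year + 1 + k
                if not 0 <= year < horizon:
                    continue
                for nut, per_ha in ((Nutrient.N, sched.n_kg_ha[k]), (Nutrient.P, sched.p_kg_ha[k])):
                    if per_ha <= 0:
                        continue
                    cols["compartment_id"].append(comp0.id)
                    cols["land_class"].append(str(lc))
                    cols["area_ha"].append(comp0.area_ha)
                    cols["year"].append(year)
                    cols["source"].append(sched.source)
                    cols["nutrient"].append(str(nut))
                    cols["kg"].append(per_ha * area)
                    cols["particulate"].append(sched.particulate)
                    cols["retained_kg"].append(0.0)
            if event.event_type in HARVEST_EVENTS and event.year >= 0:
                key = (lc, event.year // plen)
                harvest_m3[key] = harvest_m3.get(key, 0.0) + (
                    event.removed_volume_m3_ha * area
                )

        if lc is LandClass.DRAINED_PEAT:
            wtl = wtl_from_arrays(
                np.asarray(vols),
                spec.climate.summer_precip_mm,
                comp0.ditch_depth_cm,
                spec.climate.latitude_deg,
            )
            n_arr, p_arr = legacy_export_arrays(wtl, comp0.fertility, legacy_response)
            for nut, arr in ((Nutrient.N, n_arr), (Nutrient.P, p_arr)):
                nz = np.nonzero(arr > 0)[0]
                for y in nz:
                    cols["compartment_id"].append(comp0.id)
                    cols["land_class"].append(str(lc))
                    cols["area_ha"].append(comp0.area_ha)
                    cols["year"].append(int(y))
                    cols["source"].append("legacy")
                    cols["nutrient"].append(str(nut))
                    cols["kg"].append(float(arr[y]) * comp0.area_ha)
                    cols["particulate"].append(False)
                    cols["retained_kg"].append(0.0)

    entries = pd.DataFrame(cols, columns=LEDGER_COLUMNS)
    entries = apply_protection(entries, spec.protection, models)

    class_area = register.area_by_land_class()
    rows = []
    for lc in (LandClass.MINERAL, LandClass.DRAINED_PEAT):
        area = class_area.get(lc, 0.0)
        for p in range(n_periods):
            m3 = harvest_m3.get((lc, p), 0.0)
            rows.append(
                {
                    "land_class": str(lc),
                    "period": p,
                    "m3_ha_yr": (m3 / area / plen) if area > 0 else 0.0,
                }
            )
    harvest_series = pd.DataFrame(rows)

    for p in range(n_periods):
        logger.info(
            "period %d: %d events, harvest %s m3",
            p,
            event_counts[p],
            {str(lc): round(harvest_m3.get((lc, p), 0.0), 1) for lc in (LandClass.MINERAL, LandClass.DRAINED_PEAT)},
        )

    ledger = ExportLedger(entries, class_area, horizon)
    return ScenarioResult(spec=spec, ledger=ledger, harvest_series=harvest_series)


def accumulate(ledger: ExportLedger, land_class: LandClass, nutrient: Nutrient) -> np.ndarray:
    """Cumulative delivered export (kg/ha) time series for one land class."""
    return ledger.accumulate(land_class, nutrient)


def harvest_export_relation(
    ledger: ExportLedger,
    harvest_series: pd.DataFrame,
    scenario: str = "",
    period_length: int = 10,
) -> pd.DataFrame:
    """Per-period mean annual harvest vs. mean annual delivered exports.

    One row per (scenario, land class, period) with the mean annual harvest
    (m3/ha/yr) and mean annual delivered N and P exports (kg/ha/yr).
    """
    rows = []
    for lc in (LandClass.MINERAL, LandClass.DRAINED_PEAT):
        n_means = ledger.period_mean_kg_ha_yr(lc, Nutrient.N, period_length)
        p_means = ledger.period_mean_kg_ha_yr(lc, Nutrient.P, period_length)
        sub = harvest_series[harvest_series["land_class"] == str(lc)].set_index("period")
        for p in range(len(n_means)):
            rows.append(
                {
                    "scenario": scenario,
                    "land_class": str(lc),
                    "period": p,
                    "harvest_m3_ha_yr": float(sub["m3_ha_yr"].get(p, 0.0)),
                    "n_kg_ha_yr": float(n_means[p]),
                    "p_kg_ha_yr": float(p_means[p]),
                }
            )
    return pd.DataFrame(rows)
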