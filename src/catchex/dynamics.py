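"""Stand dynamics: surrogate growth and the management rule engine.

Simulation proceeds in 10-year periods; cuttings and other treatments are
evaluated and applied in the middle of each period (grow 5 years, treat,
grow 5 years).  Within a period the evaluation order is: final felling,
then thinning / selection cut, then fertilization, then ditch-network
maintenance; regeneration immediately follows a final felling and tending
of the new stand is scheduled for the following period.

Growth is a *surrogate* stand-level model standing in for individual-tree
increment/survival/ingrowth model chains that are not publicly tabulated:
cohort diameter increment declines with stand basal area (competition),
increases with site fertility and temperature sum, and saturates with tree
size::

    dd/dt = base(fertility) * (TS / TS_ref) * d/(d + d_half) * exp(-k * G)

with constant background ingrowth into a seedling cohort and a small
density-independent mortality.  Trees of planted origin grow their diameter
exactly 1.10x, and artificially seeded ones 1.05x, as fast as otherwise
identical naturally regenerated trees.  Nitrogen fertilization and DNM
temporarily boost the increment by a configurable fraction.  The model is
behind this module's interface so a calibrated growth engine can be
substituted without touching the rest of the pipeline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import structure
from .errors import ConfigurationError, StandStateError, UsageError
from .register import ManagementEvent, StandCompartment
from .structure import VolumeFunction
from .types import (
    ClimateParams,
    EventType,
    Fertility,
    LandClass,
    Management,
    Origin,
    Species,
)

__all__ = [
    "GrowthParams",
    "CCFParams",
    "ManagementRules",
    "grow_stand",
    "check_final_felling",
    "apply_thinning",
    "check_ccf_harvest",
    "apply_ccf_plan",
    "check_fertilization",
    "check_dnm",
    "step_period",
]


@dataclass
class GrowthParams:
    """Parameters of the surrogate growth model (all per-year rates)."""

    base_increment_cm_yr: dict = field(
        default_factory=lambda: {
            Fertility.HERB_RICH: 0.45,
            Fertility.MESIC: 0.40,
            Fertility.SUB_XERIC: 0.32,
            Fertility.XERIC: 0.25,
        }
    )
    d_half_cm: float = 5.0
    ba_decay_per_m2: float = 0.03
    temperature_sum_ref: float = 1000.0
    mortality_per_yr: float = 0.005
    ingrowth_stems_yr: float = 20.0
    ingrowth_ba_decay: float = 0.08
    ingrowth_diam_cm: float = 0.5
    planted_multiplier: float = 1.10
    seeded_multiplier: float = 1.05
    treatment_boost_fraction: float = 0.15
    treatment_boost_duration_yr: float = 10.0
    volume_fn: VolumeFunction = field(default_factory=VolumeFunction)

    def __post_init__(self) -> None:
        self.base_increment_cm_yr = {
            Fertility(k): float(v) for k, v in self.base_increment_cm_yr.items()
        }
        if any(v < 0 for v in self.base_increment_cm_yr.values()):
            raise ConfigurationError("base increments must be >= 0")
        if not 0.0 <= self.mortality_per_yr < 1.0:
            raise ConfigurationError("mortality must be in [0, 1)")
        if self.temperature_sum_ref <= 0 or self.d_half_cm <= 0:
            raise ConfigurationError("reference scales must be positive")

    def origin_multiplier(self, origin: Origin) -> float:
        origin = Origin(origin)
        if origin is Origin.PLANTED:
            return self.planted_multiplier
        if origin is Origin.SEEDED:
            return self.seeded_multiplier
        return 1.0

    def increment_cm_yr(
        self,
        d_cm,
        basal_area_m2_ha: float,
        fertility: Fertility,
        temperature_sum_dd: float,
        origin: Origin,
        boosted: bool = False,
    ):
        """Annual diameter increment of cohorts at the given stand density."""
        d = np.asarray(d_cm, float)
        inc = (
            self.base_increment_cm_yr[Fertility(fertility)]
            * (temperature_sum_dd / self.temperature_sum_ref)
            * d / (d + self.d_half_cm)
            * math.exp(-self.ba_decay_per_m2 * basal_area_m2_ha)
            * self.origin_multiplier(origin)
        )
        if boosted:
            inc = inc * (1.0 + self.treatment_boost_fraction)
        return inc


@dataclass
class CCFParams:
    """Continuous-cover cutting guideline surrogate.

    The cutting-threshold basal area is linear in mean diameter with a
    fertility-specific intercept, scaled by temperature sum and discount
    rate (a higher rate lowers the threshold, i.e. cuts earlier)::

        G_thr = (a_fert + b * mean_d) * (TS/TS_ref)^e_ts * (r_ref/r)^e_r

    When the stand exceeds the threshold it is cut down to
    ``post_cut_fraction * G_thr``, with class-wise removal intensities that
    increase toward larger diameters (thinning from above).
    """

    intercept_m2_ha: dict = field(
        default_factory=lambda: {
            Fertility.HERB_RICH: 11.0,
            Fertility.MESIC: 10.0,
            Fertility.SUB_XERIC: 9.0,
            Fertility.XERIC: 8.0,
        }
    )
    slope_m2_ha_per_cm: float = 0.5
    temperature_sum_ref: float = 1200.0
    temperature_sum_exp: float = 0.3
    discount_rate: float = 0.03
    discount_rate_ref: float = 0.03
    discount_rate_exp: float = 0.2
    post_cut_fraction: float = 0.6
    intensity_max: float = 0.9
    intensity_d_offset_cm: float = 2.0
    intensity_width_cm: float = 4.0

    def __post_init__(self) -> None:
        self.intercept_m2_ha = {
            Fertility(k): float(v) for k, v in self.intercept_m2_ha.items()
        }
        if self.discount_rate <= 0:
            raise ConfigurationError("discount rate must be positive")
        if not 0.0 < self.post_cut_fraction < 1.0:
            raise ConfigurationError("post_cut_fraction must be in (0, 1)")

    def threshold_basal_area(
        self, mean_d_cm: float, fertility: Fertility, temperature_sum_dd: float
    ) -> float:
        return (
            (self.intercept_m2_ha[Fertility(fertility)] + self.slope_m2_ha_per_cm * mean_d_cm)
            * (temperature_sum_dd / self.temperature_sum_ref) ** self.temperature_sum_exp
            * (self.discount_rate_ref / self.discount_rate) ** self.discount_rate_exp
        )


_DEFAULT_FELLING_D = {
    # minimum mean diameter (cm) for final felling; editable recommendations,
    # not published values
    Fertility.HERB_RICH: 28.0,
    Fertility.MESIC: 27.0,
    Fertility.SUB_XERIC: 25.0,
    Fertility.XERIC: 24.0,
}

_DEFAULT_THINNING_LIMIT = {
    Fertility.HERB_RICH: 26.0,
    Fertility.MESIC: 24.0,
    Fertility.SUB_XERIC: 22.0,
    Fertility.XERIC: 20.0,
}

_DEFAULT_POST_THINNING = {
    Fertility.HERB_RICH: 17.0,
    Fertility.MESIC: 16.0,
    Fertility.SUB_XERIC: 14.0,
    Fertility.XERIC: 13.0,
}

_DEFAULT_REGEN_PROBS = {
    # species probabilities for planting after clear-felling
    Fertility.HERB_RICH: {Species.PINE: 0.0, Species.SPRUCE: 0.9, Species.BIRCH: 0.1},
    Fertility.MESIC: {Species.PINE: 0.3, Species.SPRUCE: 0.6, Species.BIRCH: 0.1},
}


@dataclass
class ManagementRules:
    """All numeric knobs of the management rule engine.

    Defaults follow national silviculture recommendations in spirit; every
    value is configuration and can be overridden (``rules.yaml``).
    """

    felling_min_diameter_cm: dict = field(
        default_factory=lambda: dict(_DEFAULT_FELLING_D)
    )
    species_felling_overrides: dict = field(default_factory=dict)
    erp_diameter_multiplier: float = 1.10
    thinning_limit_m2_ha: dict = field(
        default_factory=lambda: dict(_DEFAULT_THINNING_LIMIT)
    )
    post_thinning_m2_ha: dict = field(
        default_factory=lambda: dict(_DEFAULT_POST_THINNING)
    )
    ccf: CCFParams = field(default_factory=CCFParams)
    # mineral N fertilization window (even-aged systems only)
    mineral_fert_diameter_cm: tuple = (23.0, 33.0)
    mineral_fert_basal_area: tuple = (15.0, 40.0)
    mineral_fert_interval_yr: float = 10.0  # strict "more than"
    mineral_fert_site_species: tuple = (
        (Fertility.XERIC, Species.PINE),
        (Fertility.MESIC, Species.SPRUCE),
    )
    # peatland wood-ash fertilization window (RF and CCF)
    peat_fert_diameter_cm: tuple = (5.0, 30.0)
    peat_fert_basal_area: tuple = (10.0, 40.0)
    peat_fert_interval_yr: float = 50.0  # strict "more than"
    # ditch-network maintenance window
    dnm_diameter_cm: tuple = (5.0, 30.0)
    dnm_basal_area: tuple = (10.0, 40.0)
    dnm_min_elapsed_yr: float = 30.0  # inclusive "at least"
    dnm_max_volume_m3_ha: float = 150.0
    regen_species_probs: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_REGEN_PROBS.items()}
    )
    regen_stems_planted: float = 2000.0
    regen_stems_seeded: float = 2500.0
    regen_stems_natural: float = 1800.0
    regen_initial_diam_cm: float = 0.5
    growth: GrowthParams = field(default_factory=GrowthParams)

    def __post_init__(self) -> None:
        self.felling_min_diameter_cm = {
            Fertility(k): float(v) for k, v in self.felling_min_diameter_cm.items()
        }
        self.thinning_limit_m2_ha = {
            Fertility(k): float(v) for k, v in self.thinning_limit_m2_ha.items()
        }
        self.post_thinning_m2_ha = {
            Fertility(k): float(v) for k, v in self.post_thinning_m2_ha.items()
        }
        for fert in Fertility:
            if self.post_thinning_m2_ha[fert] >= self.thinning_limit_m2_ha[fert]:
                raise ConfigurationError(
                    f"post-thinning basal area must be below the thinning limit ({fert})"
                )
        for name in ("mineral_fert_diameter_cm", "mineral_fert_basal_area",
                     "peat_fert_diameter_cm", "peat_fert_basal_area",
                     "dnm_diameter_cm", "dnm_basal_area"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigurationError(f"window {name} must have lower < upper bound")
        probs = {}
        for fert, sub in self.regen_species_probs.items():
            sub = {Species(k): float(v) for k, v in sub.items()}
            if abs(sum(sub.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"regeneration probabilities for {fert} must sum to 1")
            probs[Fertility(fert)] = sub
        self.regen_species_probs = probs

    def felling_diameter(self, species: Species, fertility: Fertility) -> float:
        key = (Species(species), Fertility(fertility))
        if key in self.species_felling_overrides:
            return float(self.species_felling_overrides[key])
        return self.felling_min_diameter_cm[Fertility(fertility)]


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------


def _grow_inplace(
    comp: StandCompartment,
    years: int,
    climate: ClimateParams,
    params: GrowthParams,
    record: list | None = None,
) -> None:
    """Advance a compartment's cohorts ``years`` one-year steps in place."""
    ts = climate.temperature_sum_dd
    boost_dur = params.treatment_boost_duration_yr
    for _ in range(years):
        if comp.diam_cm.size and np.any(comp.stems_ha < 0):
            raise StandStateError("negative stems before growth step")
        ba = structure.basal_area(comp.diam_cm, comp.stems_ha)
        boosted = (
            comp.years_since_dnm < boost_dur
            or comp.years_since_fertilization < boost_dur
        )
        if comp.diam_cm.size:
            inc = params.increment_cm_yr(
                comp.diam_cm, ba, comp.fertility, ts, comp.origin, boosted
            )
            comp.diam_cm = comp.diam_cm + inc
            if params.mortality_per_yr:
                comp.stems_ha = comp.stems_ha * (1.0 - params.mortality_per_yr)
        if params.ingrowth_stems_yr > 0:
            n_in = params.ingrowth_stems_yr * math.exp(-params.ingrowth_ba_decay * ba)
            d_in = params.ingrowth_diam_cm
            if comp.diam_cm.size and comp.diam_cm[0] - d_in < 1.0:
                # fold into the existing seedling cohort, conserving basal area
                n0, d0 = comp.stems_ha[0], comp.diam_cm[0]
                tot = n0 + n_in
                comp.diam_cm[0] = math.sqrt((n0 * d0**2 + n_in * d_in**2) / tot)
                comp.stems_ha[0] = tot
            else:
                comp.diam_cm = np.concatenate(([d_in], comp.diam_cm))
                comp.stems_ha = np.concatenate(([n_in], comp.stems_ha))
        comp.age_years += 1.0
        comp.years_since_dnm += 1.0
        comp.years_since_fertilization += 1.0
        if record is not None:
            record.append(structure.stand_volume(comp.diam_cm, comp.stems_ha, params.volume_fn))


def grow_stand(
    compartment: StandCompartment,
    years: int,
    climate: ClimateParams | None = None,
    growth_params: GrowthParams | None = None,
) -> StandCompartment:
    """Grow a forested compartment for ``years`` years; returns a new object."""
    if years <= 0:
        raise ConfigurationError("years must be > 0")
    if not compartment.forested:
        raise UsageError("cannot grow a nonforest compartment")
    comp = compartment.copy()
    _grow_inplace(comp, int(years), climate or ClimateParams(), growth_params or GrowthParams())
    return comp


# ---------------------------------------------------------------------------
# treatment checks and applications
# ---------------------------------------------------------------------------


def check_final_felling(
    compartment: StandCompartment, rules: ManagementRules, system: Management
) -> bool:
    """Is the stand mature for final felling under RF or ERP?

    True iff the mean diameter strictly exceeds the recommended minimum;
    the ERP threshold is the RF threshold times ``erp_diameter_multiplier``.
    """
    system = Management(system)
    if system not in (Management.RF, Management.ERP):
        raise UsageError("final felling is defined for even-aged systems (RF, ERP)")
    thr = rules.felling_diameter(compartment.dominant_species, compartment.fertility)
    if system is Management.ERP:
        thr *= rules.erp_diameter_multiplier
    return compartment.mean_diameter_cm > thr


def apply_thinning(
    compartment: StandCompartment, mode: str, rules: ManagementRules
) -> tuple[StandCompartment, float]:
    """Commercial thinning to the recommended post-thinning basal area.

    Half of the basal-area removal uses the same percentage in every cohort;
    the other half removes the smallest trees first (``mode="below"``) or the
    largest first (``mode="above"``).  Stems are continuous (fractions of a
    stem per hectare are allowed), so removal plans are order-independent
    within a cohort.  Returns the thinned compartment and the removed stem
    volume (m3/ha); a stand at or below the thinning limit is returned
    unchanged.
    """
    if mode not in ("below", "above"):
        raise UsageError("mode must be 'below' or 'above'")
    fert = compartment.fertility
    limit = rules.thinning_limit_m2_ha[fert]
    target = rules.post_thinning_m2_ha[fert]
    ba = compartment.basal_area_m2_ha
    if ba <= limit:
        return compartment.copy(), 0.0
    removal = ba - target
    if removal <= 0:  # defensive; limit > target is enforced in rules
        warnings.warn("thinning target above current basal area; no-op")
        return compartment.copy(), 0.0

    comp = compartment.copy()
    diam, stems = comp.diam_cm, comp.stems_ha.copy()
    ba_per_stem = np.pi * (diam / 200.0) ** 2
    # half uniformly across cohorts
    frac_uniform = (removal / 2.0) / ba
    removed = stems * frac_uniform
    stems = stems - removed
    # other half from one end of the diameter distribution
    need = removal / 2.0
    order = np.argsort(diam) if mode == "below" else np.argsort(diam)[::-1]
    for i in order:
        if need <= 1e-12:
            break
        avail_ba = stems[i] * ba_per_stem[i]
        take_ba = min(avail_ba, need)
        if ba_per_stem[i] > 0:
            take_stems = take_ba / ba_per_stem[i]
            stems[i] -= take_stems
            removed[i] += take_stems
            need -= take_ba
    removed_volume = float(np.sum(removed * rules.growth.volume_fn(diam)))
    comp.stems_ha = np.maximum(stems, 0.0)  # guard float round-off
    comp.diam_cm, comp.stems_ha = structure.merge_cohorts(comp.diam_cm, comp.stems_ha, 0.0)
    return comp, removed_volume


@dataclass(frozen=True)
class CCFPlan:
    """Removal plan of one continuous-cover selection harvest."""

    diam_cm: np.ndarray
    remove_fraction: np.ndarray  # per cohort, nondecreasing in diameter
    removed_basal_area: float
    removed_volume_m3_ha: float


def check_ccf_harvest(
    compartment: StandCompartment,
    rules: ManagementRules,
    climate: ClimateParams | None = None,
) -> tuple[bool, CCFPlan | None]:
    """Selection-harvest decision under continuous cover forestry.

    The stand is cut when its basal area exceeds the guideline threshold
    (a function of mean diameter, fertility, temperature sum and discount
    rate); removal intensity is monotone nondecreasing toward larger
    diameter cohorts and scaled so the cut reaches the post-cut target.
    """
    climate = climate or ClimateParams()
    ccf = rules.ccf
    ba = compartment.basal_area_m2_ha
    thr = ccf.threshold_basal_area(
        compartment.mean_diameter_cm, compartment.fertility, climate.temperature_sum_dd
    )
    if ba <= thr:
        return False, None
    target = ccf.post_cut_fraction * thr
    need = ba - target
    diam, stems = compartment.diam_cm, compartment.stems_ha
    ba_i = stems * np.pi * (diam / 200.0) ** 2
    d_half = compartment.mean_diameter_cm + ccf.intensity_d_offset_cm
    rel = ccf.intensity_max / (1.0 + np.exp(-(diam - d_half) / ccf.intensity_width_cm))
    # scale the relative intensities so the plan removes exactly `need`,
    # water-filling cohorts that hit the per-cohort cap
    cap = 0.98
    capped = np.zeros(diam.shape, bool)
    lam = 0.0
    for _ in range(diam.size + 1):
        denom = float(np.sum(rel[~capped] * ba_i[~capped]))
        if denom <= 0:
            break
        lam = (need - cap * float(np.sum(ba_i[capped]))) / denom
        newly = (~capped) & (lam * rel > cap)
        if not newly.any():
            break
        capped |= newly
    frac = np.minimum(lam * rel, cap)
    frac[capped] = cap
    removed_ba = float(np.sum(frac * ba_i))
    removed_vol = float(np.sum(frac * stems * rules.growth.volume_fn(diam)))
    return True, CCFPlan(diam.copy(), frac, removed_ba, removed_vol)


def apply_ccf_plan(compartment: StandCompartment, plan: CCFPlan) -> StandCompartment:
    comp = compartment.copy()
    if plan.diam_cm.shape != comp.diam_cm.shape or not np.allclose(
        plan.diam_cm, comp.diam_cm
    ):
        raise UsageError("removal plan does not match the compartment's cohorts")
    comp.stems_ha = np.maximum(comp.stems_ha * (1.0 - plan.remove_fraction), 0.0)
    comp.diam_cm, comp.stems_ha = structure.merge_cohorts(comp.diam_cm, comp.stems_ha, 0.0)
    return comp


def check_fertilization(
    compartment: StandCompartment, rules: ManagementRules, system: Management
) -> bool:
    """Fertilization eligibility of a compartment under a management system.

    Mineral soils: ammonium-nitrate N fertilization, even-aged systems only
    (RF/ERP), restricted to pine-dominated xeric and spruce-dominated mesic
    sites with mean diameter 23-33 cm, basal area 15-40 m2/ha and more than
    10 years since the previous fertilization.  Drained peat: wood-ash
    fertilization under RF and CCF with diameter 5-30 cm, basal area
    10-40 m2/ha and more than 50 years elapsed.
    """
    system = Management(system)
    d = compartment.mean_diameter_cm
    ba = compartment.basal_area_m2_ha
    if compartment.land_class is LandClass.MINERAL:
        if system not in (Management.RF, Management.ERP):
            return False
        if (compartment.fertility, compartment.dominant_species) not in {
            (Fertility(f), Species(s)) for f, s in rules.mineral_fert_site_species
        }:
            return False
        d_lo, d_hi = rules.mineral_fert_diameter_cm
        g_lo, g_hi = rules.mineral_fert_basal_area
        return (
            d_lo <= d <= d_hi
            and g_lo <= ba <= g_hi
            and compartment.years_since_fertilization > rules.mineral_fert_interval_yr
        )
    if compartment.land_class is LandClass.DRAINED_PEAT:
        if system not in (Management.RF, Management.CCF):
            return False
        d_lo, d_hi = rules.peat_fert_diameter_cm
        g_lo, g_hi = rules.peat_fert_basal_area
        return (
            d_lo <= d <= d_hi
            and g_lo <= ba <= g_hi
            and compartment.years_since_fertilization > rules.peat_fert_interval_yr
        )
    return False


def check_dnm(
    compartment: StandCompartment,
    rules: ManagementRules,
    after_final_felling: bool = False,
) -> bool:
    """Ditch-network-maintenance eligibility of a drained-peat compartment.

    Eligible immediately after a final felling, or when the stand sits in
    the diameter/basal-area window; in both cases at least
    ``dnm_min_elapsed_yr`` years must have passed since the previous DNM and
    the growing stock must not exceed ``dnm_max_volume_m3_ha`` (a mature
    stand's evapotranspiration keeps the water table down without ditch
    maintenance).
    """
    if compartment.land_class is not LandClass.DRAINED_PEAT:
        raise UsageError("DNM is only defined on drained peatland")
    if compartment.years_since_dnm < rules.dnm_min_elapsed_yr:
        return False
    if compartment.volume_m3_ha > rules.dnm_max_volume_m3_ha:
        return False
    if after_final_felling:
        return True
    d = compartment.mean_diameter_cm
    ba = compartment.basal_area_m2_ha
    d_lo, d_hi = rules.dnm_diameter_cm
    g_lo, g_hi = rules.dnm_basal_area
    return d_lo <= d <= d_hi and g_lo <= ba <= g_hi


# ---------------------------------------------------------------------------
# period stepping
# ---------------------------------------------------------------------------


def _regenerate(
    comp: StandCompartment,
    rules: ManagementRules,
    rng: np.random.Generator,
    year: int,
    natural: bool,
) -> list[ManagementEvent]:
    """Reset the stand to a newly regenerated state; returns regen events."""
    events: list[ManagementEvent] = []
    if natural:
        # seed-tree natural regeneration (xeric pine)
        comp.origin = Origin.NATURAL
        comp.dominant_species = Species.PINE
        stems = rules.regen_stems_natural
    else:
        events.append(ManagementEvent(EventType.SITE_PREPARATION, year, 0.0, comp.area_ha))
        if comp.fertility in (Fertility.SUB_XERIC, Fertility.XERIC):
            events.append(ManagementEvent(EventType.SEEDING, year, 0.0, comp.area_ha))
            comp.origin = Origin.SEEDED
            comp.dominant_species = Species.PINE
            stems = rules.regen_stems_seeded
        else:
            probs = rules.regen_species_probs[comp.fertility]
            keys = list(probs)
            p = np.array([probs[k] for k in keys], float)
            comp.dominant_species = keys[rng.choice(len(keys), p=p / p.sum())]
            comp.origin = Origin.PLANTED
            events.append(ManagementEvent(EventType.PLANTING, year, 0.0, comp.area_ha))
            stems = rules.regen_stems_planted
    comp.diam_cm = np.array([rules.regen_initial_diam_cm])
    comp.stems_ha = np.array([float(stems)])
    comp.age_years = 0.0
    comp.tending_due = True
    return events


def step_period(
    compartment: StandCompartment,
    system: Management,
    rules: ManagementRules,
    climate: ClimateParams,
    period_index: int,
    rng: np.random.Generator,
    period_length: int = 10,
) -> tuple[StandCompartment, list[ManagementEvent], list[float]]:
    """Advance one compartment through one simulation period.

    Grows ``period_length/2`` years, evaluates and applies treatments at the
    mid-period year (felling, then thinning/selection cut, then
    fertilization, then DNM), grows the remaining years, and returns the
    advanced compartment, the emitted events (all dated to the mid-period
    year) and the end-of-year stand volume for each year of the period
    (used for the annual water-table evaluation).
    """
    system = Management(system)
    comp = compartment.copy()
    vols: list[float] = []
    events: list[ManagementEvent] = []
    half = period_length // 2
    year_mid = period_index * period_length + half

    if not comp.forested or system is Management.NONE:
        if comp.forested and comp.diam_cm.size:
            _grow_inplace(comp, period_length, climate, rules.growth, vols)
        else:
            vols.extend([comp.volume_m3_ha] * period_length)
        comp.event_history.extend(events)
        return comp, events, vols

    _grow_inplace(comp, half, climate, rules.growth, vols)

    area = comp.area_ha
    felled = False

    if comp.tending_due:
        events.append(ManagementEvent(EventType.TENDING, year_mid, 0.0, area))
        comp.tending_due = False

    if system in (Management.RF, Management.ERP):
        if check_final_felling(comp, rules, system):
            removed = comp.volume_m3_ha
            natural = (
                comp.fertility is Fertility.XERIC
                and comp.dominant_species is Species.PINE
            )
            etype = EventType.SEED_TREE_FELLING if natural else EventType.CLEAR_CUT
            events.append(ManagementEvent(etype, year_mid, removed, area))
            comp.diam_cm = np.array([])
            comp.stems_ha = np.array([])
            events.extend(_regenerate(comp, rules, rng, year_mid, natural))
            felled = True
        else:
            mode = "below" if system is Management.RF else "above"
            thinned, removed_vol = apply_thinning(comp, mode, rules)
            if removed_vol > 0:
                etype = (
                    EventType.THINNING_BELOW if mode == "below" else EventType.THINNING_ABOVE
                )
                events.append(ManagementEvent(etype, year_mid, removed_vol, area))
                comp = thinned
    elif system is Management.CCF:
        cut, plan = check_ccf_harvest(comp, rules, climate)
        if cut:
            comp = apply_ccf_plan(comp, plan)
            events.append(
                ManagementEvent(
                    EventType.CCF_HARVEST, year_mid, plan.removed_volume_m3_ha, area
                )
            )

    if check_fertilization(comp, rules, system):
        if comp.land_class is LandClass.MINERAL:
            events.append(
                ManagementEvent(EventType.FERTILIZATION_MINERAL_N, year_mid, 0.0, area)
            )
        else:
            events.append(
                ManagementEvent(EventType.FERTILIZATION_PEAT_ASH, year_mid, 0.0, area)
            )
        comp.years_since_fertilization = 0.0

    # DNM belongs to the rotation-forestry cycle; continuous cover forestry
    # avoids the clear-cut -> water-table rise that motivates it
    if (
        comp.land_class is LandClass.DRAINED_PEAT
        and system in (Management.RF, Management.ERP)
        and check_dnm(comp, rules, after_final_felling=felled)
    ):
        events.append(ManagementEvent(EventType.DNM, year_mid, 0.0, area))
        comp.years_since_dnm = 0.0

    _grow_inplace(comp, period_length - half, climate, rules.growth, vols)
    comp.event_history.extend(events)
    return comp, events, vols
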