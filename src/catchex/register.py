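"""Stand register: data model, CSV round trip, synthetic catchment generator.

The register is the simulator's sole stand-level input: one record per
forest compartment with land class, site fertility, dominant species,
regeneration origin, a diameter-cohort table, drainage attributes and a
management-event history.  Because no real stand data are deposited for the
study region, :func:`generate_catchment` draws a seeded synthetic register
whose land-class composition emulates a large central-boreal catchment
(defaults: 3824 km2 total; mineral-soil forest 40%, forestry-drained
peatland 31.5%, undrained peatland 21.1%).

File layout: ``register.csv`` (one compartment per row) plus a companion
``events.csv`` keyed by compartment id.  Writing then reading a register
reproduces it field for field.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import structure
from .errors import ConfigurationError, SchemaError, StandStateError, UsageError
from .types import (
    HARVEST_EVENTS,
    EventType,
    Fertility,
    LandClass,
    Origin,
    Species,
)

__all__ = [
    "ManagementEvent",
    "StandCompartment",
    "StandRegister",
    "CatchmentConfig",
    "generate_catchment",
    "read_register",
    "write_register",
]

DEFAULT_DITCH_DEPTH_CM = 60.0  # typical depth >10 y after the last maintenance

#: sentinel for "no such treatment in living memory"
NEVER = 100.0


@dataclass
class ManagementEvent:
    """A dated silvicultural or drainage operation on one compartment.

    ``year`` is a simulation year; negative years are pre-simulation history
    (e.g. a clear-cut a few years before the horizon starts, whose residual
    exports spill into the first period).  ``removed_volume_m3_ha`` is zero
    for all non-harvest events.
    """

    event_type: EventType
    year: int
    removed_volume_m3_ha: float = 0.0
    treated_area_ha: float = 0.0

    def __post_init__(self) -> None:
        self.event_type = EventType(self.event_type)
        if not float(self.year).is_integer():
            raise ConfigurationError("event year must be an integer")
        self.year = int(self.year)
        if self.removed_volume_m3_ha < 0:
            raise ConfigurationError("removed volume must be >= 0")
        if self.event_type not in HARVEST_EVENTS and self.removed_volume_m3_ha != 0:
            raise ConfigurationError(
                f"{self.event_type} is not a harvest and must have zero removed volume"
            )
        if self.treated_area_ha < 0:
            raise ConfigurationError("treated area must be >= 0")


@dataclass
class StandCompartment:
    """One forest compartment's state.

    The stand structure lives in the cohort arrays ``diam_cm`` /
    ``stems_ha`` (see :mod:`catchex.structure`); mean diameter, basal area
    and volume are derived from them and always consistent by construction.
    ``ditch_depth_cm`` is present iff the compartment is drained peatland.
    """

    id: str
    area_ha: float
    land_class: LandClass
    fertility: Fertility
    dominant_species: Species
    origin: Origin
    diam_cm: np.ndarray
    stems_ha: np.ndarray
    age_years: float = 0.0
    ditch_depth_cm: float | None = None
    years_since_dnm: float = NEVER
    years_since_fertilization: float = NEVER
    event_history: list[ManagementEvent] = field(default_factory=list)
    tending_due: bool = False

    def __post_init__(self) -> None:
        self.land_class = LandClass(self.land_class)
        self.fertility = Fertility(self.fertility)
        self.dominant_species = Species(self.dominant_species)
        self.origin = Origin(self.origin)
        self.diam_cm = np.asarray(self.diam_cm, dtype=float)
        self.stems_ha = np.asarray(self.stems_ha, dtype=float)
        if self.area_ha <= 0:
            raise StandStateError(f"compartment {self.id}: area must be > 0")
        if np.any(self.stems_ha < 0):
            raise StandStateError(f"compartment {self.id}: negative stems")
        if (self.land_class is LandClass.DRAINED_PEAT) != (
            self.ditch_depth_cm is not None
        ):
            raise StandStateError(
                f"compartment {self.id}: ditch_depth_cm present iff drained_peat"
            )
        if self.ditch_depth_cm is not None and self.ditch_depth_cm <= 0:
            raise StandStateError(f"compartment {self.id}: ditch depth must be > 0")

    # -- derived stand metrics -------------------------------------------
    @property
    def basal_area_m2_ha(self) -> float:
        return structure.basal_area(self.diam_cm, self.stems_ha)

    @property
    def mean_diameter_cm(self) -> float:
        return structure.mean_diameter(self.diam_cm, self.stems_ha)

    @property
    def volume_m3_ha(self) -> float:
        return structure.stand_volume(self.diam_cm, self.stems_ha)

    @property
    def forested(self) -> bool:
        return self.land_class is not LandClass.NONFOREST

    def copy(self) -> "StandCompartment":
        return replace(
            self,
            diam_cm=self.diam_cm.copy(),
            stems_ha=self.stems_ha.copy(),
            event_history=list(self.event_history),
        )


class StandRegister:
    """An ordered collection of compartments with area bookkeeping helpers."""

    def __init__(self, compartments: list[StandCompartment]):
        self.compartments = list(compartments)
        ids = [c.id for c in self.compartments]
        if len(set(ids)) != len(ids):
            raise SchemaError("duplicate compartment ids in register")

    def __len__(self) -> int:
        return len(self.compartments)

    def __iter__(self):
        return iter(self.compartments)

    @property
    def total_area_ha(self) -> float:
        return sum(c.area_ha for c in self.compartments)

    def area_by_land_class(self) -> dict[LandClass, float]:
        out: dict[LandClass, float] = {lc: 0.0 for lc in LandClass}
        for c in self.compartments:
            out[c.land_class] += c.area_ha
        return out

    def subset(self, land_class: LandClass) -> "StandRegister":
        lc = LandClass(land_class)
        return StandRegister([c.copy() for c in self.compartments if c.land_class is lc])

    def copy(self) -> "StandRegister":
        return StandRegister([c.copy() for c in self.compartments])


# ---------------------------------------------------------------------------
# synthetic catchment generation
# ---------------------------------------------------------------------------

_DEFAULT_LAND_CLASS_SHARES = {
    LandClass.MINERAL: 0.40,
    LandClass.DRAINED_PEAT: 0.315,
    LandClass.UNDRAINED_PEAT: 0.211,
    LandClass.NONFOREST: 0.074,
}

# Site-fertility composition per land class.  The study region's fertility
# breakdown is not published; these are editable placeholders representing a
# typical central-boreal mix (flagged as such in the docs).
_DEFAULT_FERTILITY_SHARES = {
    LandClass.MINERAL: {
        Fertility.HERB_RICH: 0.05,
        Fertility.MESIC: 0.35,
        Fertility.SUB_XERIC: 0.45,
        Fertility.XERIC: 0.15,
    },
    LandClass.DRAINED_PEAT: {
        Fertility.HERB_RICH: 0.10,
        Fertility.MESIC: 0.30,
        Fertility.SUB_XERIC: 0.40,
        Fertility.XERIC: 0.20,
    },
    LandClass.UNDRAINED_PEAT: {
        Fertility.HERB_RICH: 0.05,
        Fertility.MESIC: 0.20,
        Fertility.SUB_XERIC: 0.40,
        Fertility.XERIC: 0.35,
    },
    LandClass.NONFOREST: {Fertility.SUB_XERIC: 1.0},
}

#: initial-state ranges per fertility: (mean diameter cm, basal area m2/ha)
_DEFAULT_STAND_STATE = {
    Fertility.HERB_RICH: ((10.0, 28.0), (12.0, 28.0)),
    Fertility.MESIC: ((9.0, 27.0), (10.0, 26.0)),
    Fertility.SUB_XERIC: ((8.0, 25.0), (8.0, 24.0)),
    Fertility.XERIC: ((7.0, 23.0), (6.0, 20.0)),
}


@dataclass
class CatchmentConfig:
    """Configuration of the synthetic catchment generator.

    Land-class shares must sum to 1; realized per-class *areas* are rescaled
    to match the shares exactly, so the configured composition is honoured to
    numerical precision regardless of compartment-count rounding.

    ``pre_clearcut_fraction`` of mineral compartments receive a clear-cut in
    a uniformly drawn pre-simulation year (-1 ... -9) and start as seedling
    stands, so residual exports of past fellings appear in the first period
    even under no-management scenarios.
    """

    total_area_km2: float = 3824.0
    land_class_shares: dict = field(
        default_factory=lambda: dict(_DEFAULT_LAND_CLASS_SHARES)
    )
    fertility_shares: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_FERTILITY_SHARES.items()}
    )
    stand_state_ranges: dict = field(
        default_factory=lambda: dict(_DEFAULT_STAND_STATE)
    )
    n_compartments: int = 2000
    median_compartment_area_ha: float = 3.0
    area_lognormal_sigma: float = 0.8
    pre_clearcut_fraction: float = 0.10
    pre_clearcut_years: tuple[int, int] = (1, 9)  # years before start, inclusive
    ditch_depth_cm: float = DEFAULT_DITCH_DEPTH_CM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_area_km2 <= 0:
            raise ConfigurationError("total area must be positive")
        if self.n_compartments < 1:
            raise ConfigurationError("need at least one compartment")
        if self.median_compartment_area_ha <= 0:
            raise ConfigurationError("median compartment area must be positive")
        shares = {LandClass(k): float(v) for k, v in self.land_class_shares.items()}
        if any(v < 0 for v in shares.values()):
            raise ConfigurationError("land-class shares must be nonnegative")
        if abs(sum(shares.values()) - 1.0) > 1e-9:
            raise ConfigurationError("land-class shares must sum to 1")
        self.land_class_shares = shares
        if not 0.0 <= self.pre_clearcut_fraction <= 1.0:
            raise ConfigurationError("pre_clearcut_fraction must be in [0, 1]")
        fshares = {}
        for lc, sub in self.fertility_shares.items():
            sub = {Fertility(k): float(v) for k, v in sub.items()}
            if abs(sum(sub.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"fertility shares for {lc} must sum to 1")
            fshares[LandClass(lc)] = sub
        self.fertility_shares = fshares


_SPECIES_PROBS = {
    # (land class tier, fertility) -> species probabilities
    LandClass.MINERAL: {
        Fertility.HERB_RICH: {Species.SPRUCE: 0.7, Species.BIRCH: 0.2, Species.PINE: 0.1},
        Fertility.MESIC: {Species.SPRUCE: 0.55, Species.PINE: 0.3, Species.BIRCH: 0.15},
        Fertility.SUB_XERIC: {Species.PINE: 0.85, Species.BIRCH: 0.1, Species.SPRUCE: 0.05},
        Fertility.XERIC: {Species.PINE: 0.95, Species.BIRCH: 0.05},
    },
    LandClass.DRAINED_PEAT: {
        Fertility.HERB_RICH: {Species.BIRCH: 0.4, Species.SPRUCE: 0.4, Species.PINE: 0.2},
        Fertility.MESIC: {Species.PINE: 0.5, Species.BIRCH: 0.3, Species.SPRUCE: 0.2},
        Fertility.SUB_XERIC: {Species.PINE: 0.8, Species.BIRCH: 0.2},
        Fertility.XERIC: {Species.PINE: 1.0},
    },
}


def _largest_remainder_counts(n: int, shares: dict) -> dict:
    """Integer class counts with the largest-remainder method."""
    raw = {k: n * v for k, v in shares.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def _draw_choice(rng: np.random.Generator, probs: dict):
    keys = list(probs)
    p = np.array([probs[k] for k in keys], float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def generate_catchment(config: CatchmentConfig) -> StandRegister:
    """Draw a seeded synthetic stand register matching the configured composition.

    Deterministic under a fixed seed: two calls with equal configs produce
    byte-identical registers.  Summed compartment areas match the configured
    total within 0.1% (in fact exactly, up to float rounding), and per-class
    area shares match the configured shares exactly by per-class rescaling.
    """
    rng = np.random.default_rng(config.seed)
    total_ha = config.total_area_km2 * 100.0
    counts = _largest_remainder_counts(config.n_compartments, config.land_class_shares)

    comps: list[StandCompartment] = []
    idx = 0
    mu = math.log(config.median_compartment_area_ha)
    for lc in LandClass:
        n_lc = counts.get(lc, 0)
        if n_lc == 0:
            continue
        class_area = config.land_class_shares[lc] * total_ha
        areas = rng.lognormal(mean=mu, sigma=config.area_lognormal_sigma, size=n_lc)
        areas *= class_area / areas.sum()  # exact per-class total
        fert_probs = config.fertility_shares.get(
            lc, {Fertility.SUB_XERIC: 1.0}
        )
        for a in areas:
            fert = _draw_choice(rng, fert_probs)
            comp = _draw_compartment(rng, f"c{idx:05d}", float(a), lc, fert, config)
            comps.append(comp)
            idx += 1

    # pre-simulation clear-cut history on a fraction of mineral compartments
    mineral_idx = [i for i, c in enumerate(comps) if c.land_class is LandClass.MINERAL]
    n_cut = int(round(config.pre_clearcut_fraction * len(mineral_idx)))
    if n_cut > 0:
        chosen = rng.choice(len(mineral_idx), size=n_cut, replace=False)
        lo, hi = config.pre_clearcut_years
        for j in sorted(chosen):
            comps[mineral_idx[j]] = _apply_pre_clearcut(rng, comps[mineral_idx[j]], lo, hi)
    return StandRegister(comps)


def _draw_compartment(
    rng: np.random.Generator,
    cid: str,
    area_ha: float,
    lc: LandClass,
    fert: Fertility,
    config: CatchmentConfig,
) -> StandCompartment:
    if lc is LandClass.NONFOREST:
        return StandCompartment(
            id=cid,
            area_ha=area_ha,
            land_class=lc,
            fertility=fert,
            dominant_species=Species.MIXED,
            origin=Origin.NATURAL,
            diam_cm=np.array([]),
            stems_ha=np.array([]),
        )
    (d_lo, d_hi), (g_lo, g_hi) = config.stand_state_ranges[fert]
    mean_d = rng.uniform(d_lo, d_hi)
    ba = rng.uniform(g_lo, g_hi)
    if lc is LandClass.UNDRAINED_PEAT:
        ba *= 0.4  # sparse pristine-mire tree cover
    diam, stems = structure.weibull_cohorts(mean_d, ba)
    species = _draw_choice(rng, _SPECIES_PROBS.get(lc, _SPECIES_PROBS[LandClass.MINERAL])[fert])
    if lc is LandClass.MINERAL:
        origin = _draw_choice(
            rng, {Origin.PLANTED: 0.4, Origin.SEEDED: 0.2, Origin.NATURAL: 0.4}
        )
    else:
        origin = Origin.NATURAL
    age = mean_d * rng.uniform(3.0, 4.5)
    return StandCompartment(
        id=cid,
        area_ha=area_ha,
        land_class=lc,
        fertility=fert,
        dominant_species=species,
        origin=origin,
        diam_cm=diam,
        stems_ha=stems,
        age_years=round(float(age), 1),
        ditch_depth_cm=config.ditch_depth_cm if lc is LandClass.DRAINED_PEAT else None,
        years_since_dnm=(
            float(rng.integers(15, 61)) if lc is LandClass.DRAINED_PEAT else NEVER
        ),
        years_since_fertilization=NEVER,
    )


def _apply_pre_clearcut(
    rng: np.random.Generator, comp: StandCompartment, lo: int, hi: int
) -> StandCompartment:
    """Replace a compartment by its just-regenerated state after a recent cut."""
    years_ago = int(rng.integers(lo, hi + 1))
    removed = float(rng.uniform(150.0, 300.0))
    year = -years_ago
    events = [
        ManagementEvent(EventType.CLEAR_CUT, year, removed, comp.area_ha),
        ManagementEvent(EventType.SITE_PREPARATION, year, 0.0, comp.area_ha),
        ManagementEvent(EventType.PLANTING, year, 0.0, comp.area_ha),
    ]
    comp = comp.copy()
    comp.diam_cm = np.array([0.5 + 0.2 * years_ago])
    comp.stems_ha = np.array([2000.0])
    comp.origin = Origin.PLANTED
    comp.age_years = float(years_ago)
    comp.event_history = events + comp.event_history
    comp.tending_due = years_ago <= 5
    return comp


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_REGISTER_COLUMNS = [
    "id",
    "area_ha",
    "land_class",
    "fertility",
    "dominant_species",
    "origin",
    "mean_diameter_cm",
    "basal_area_m2_ha",
    "volume_m3_ha",
    "age_years",
    "ditch_depth_cm",
    "years_since_dnm",
    "years_since_fertilization",
    "tending_due",
    "diameter_classes",
]

_EVENT_COLUMNS = [
    "compartment_id",
    "event_type",
    "year",
    "removed_volume_m3_ha",
    "treated_area_ha",
]


def _encode_cohorts(diam: np.ndarray, stems: np.ndarray) -> str:
    return "|".join(f"{float(d)!r}:{float(n)!r}" for d, n in zip(diam, stems))


def _decode_cohorts(s: str) -> tuple[np.ndarray, np.ndarray]:
    if not s:
        return np.array([]), np.array([])
    ds, ns = [], []
    for pair in s.split("|"):
        d, n = pair.split(":")
        ds.append(float(d))
        ns.append(float(n))
    return np.array(ds), np.array(ns)


def write_register(register: StandRegister, register_path, events_path) -> None:
    """Write ``register.csv`` and its companion ``events.csv`` (UTF-8).

    Floats are written with full ``repr`` precision so that
    ``read_register(write_register(r))`` reproduces ``r`` exactly.
    """
    register_path, events_path = Path(register_path), Path(events_path)
    with register_path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_REGISTER_COLUMNS)
        for c in register:
            w.writerow(
                [
                    c.id,
                    repr(c.area_ha),
                    str(c.land_class),
                    str(c.fertility),
                    str(c.dominant_species),
                    str(c.origin),
                    repr(c.mean_diameter_cm),
                    repr(c.basal_area_m2_ha),
                    repr(c.volume_m3_ha),
                    repr(c.age_years),
                    "" if c.ditch_depth_cm is None else repr(c.ditch_depth_cm),
                    repr(c.years_since_dnm),
                    repr(c.years_since_fertilization),
                    int(c.tending_due),
                    _encode_cohorts(c.diam_cm, c.stems_ha),
                ]
            )
    with events_path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_EVENT_COLUMNS)
        for c in register:
            for e in c.event_history:
                w.writerow(
                    [c.id, str(e.event_type), e.year, repr(e.removed_volume_m3_ha), repr(e.treated_area_ha)]
                )


def _parse_enum(enum_cls, token: str, row: int, col: str):
    try:
        return enum_cls(token)
    except ValueError:
        raise SchemaError(
            f"row {row}: unknown {col} {token!r} (expected one of "
            f"{[str(v) for v in enum_cls]})"
        ) from None


def read_register(register_path, events_path=None) -> StandRegister:
    """Read a register written by :func:`write_register`.

    ``events_path`` defaults to ``events.csv`` next to the register file.
    Schema violations raise :class:`SchemaError` with the offending
    (1-based, header-exclusive) row number.
    """
    register_path = Path(register_path)
    if events_path is None:
        events_path = register_path.with_name("events.csv")
    else:
        events_path = Path(events_path)

    events_by_id: dict[str, list[ManagementEvent]] = {}
    if events_path.exists():
        with events_path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames != _EVENT_COLUMNS:
                raise SchemaError(f"unexpected events header: {reader.fieldnames}")
            for i, row in enumerate(reader, start=1):
                etype = _parse_enum(EventType, row["event_type"], i, "event_type")
                try:
                    ev = ManagementEvent(
                        etype,
                        int(row["year"]),
                        float(row["removed_volume_m3_ha"]),
                        float(row["treated_area_ha"]),
                    )
                except (ValueError, ConfigurationError) as exc:
                    raise SchemaError(f"events row {i}: {exc}") from None
                events_by_id.setdefault(row["compartment_id"], []).append(ev)

    comps: list[StandCompartment] = []
    with register_path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _REGISTER_COLUMNS:
            raise SchemaError(f"unexpected register header: {reader.fieldnames}")
        for i, row in enumerate(reader, start=1):
            lc = _parse_enum(LandClass, row["land_class"], i, "land_class")
            fert = _parse_enum(Fertility, row["fertility"], i, "fertility")
            spec = _parse_enum(Species, row["dominant_species"], i, "dominant_species")
            orig = _parse_enum(Origin, row["origin"], i, "origin")
            ditch = row["ditch_depth_cm"]
            if lc is LandClass.DRAINED_PEAT and ditch == "":
                raise SchemaError(f"row {i}: drained_peat compartment missing ditch_depth_cm")
            diam, stems = _decode_cohorts(row["diameter_classes"])
            try:
                comp = StandCompartment(
                    id=row["id"],
                    area_ha=float(row["area_ha"]),
                    land_class=lc,
                    fertility=fert,
                    dominant_species=spec,
                    origin=orig,
                    diam_cm=diam,
                    stems_ha=stems,
                    age_years=float(row["age_years"]),
                    ditch_depth_cm=None if ditch == "" else float(ditch),
                    years_since_dnm=float(row["years_since_dnm"]),
                    years_since_fertilization=float(row["years_since_fertilization"]),
                    event_history=events_by_id.get(row["id"], []),
                    tending_due=bool(int(row["tending_due"])),
                )
            except (ValueError, StandStateError) as exc:
                raise SchemaError(f"row {i}: {exc}") from None
            # stored summaries must agree with the cohort table
            for col, val in (
                ("mean_diameter_cm", comp.mean_diameter_cm),
                ("basal_area_m2_ha", comp.basal_area_m2_ha),
                ("volume_m3_ha", comp.volume_m3_ha),
            ):
                stored = float(row[col])
                if not math.isclose(stored, val, rel_tol=0.1, abs_tol=0.5):
                    raise SchemaError(
                        f"row {i}: {col}={stored} inconsistent with cohort table ({val:.3f})"
                    )
            comps.append(comp)
    return StandRegister(comps)
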