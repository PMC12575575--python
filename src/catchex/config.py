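"""YAML configuration loaders.

Every numeric in the pipeline is overridable from plain YAML mappings whose
keys mirror the dataclass field names; omitted keys keep their defaults.
Per-fertility tables are written with fertility names as keys, e.g.::

    # rules.yaml
    erp_diameter_multiplier: 1.10
    felling_min_diameter_cm: {mesic: 27, xeric: 24}
    growth:
      mortality_per_yr: 0.004

    # scenario.yaml
    management: RF
    protection: wetlands
    seed: 7
    climate: {summer_precip_mm: 70, latitude_deg: 65}
"""

from __future__ import annotations

from dataclasses import fields, is_dataclass, replace
from pathlib import Path

import yaml

from .dynamics import CCFParams, GrowthParams, ManagementRules
from .engine import ScenarioSpec
from .errors import ConfigurationError
from .exports import ExportCoefficientTable, HarvestExportParams, Operation
from .hydrology import LegacyResponse
from .protection import PondDamParams, RetentionModels, RiparianParams, WetlandParams
from .register import CatchmentConfig
from .structure import VolumeFunction
from .types import ClimateParams, Nutrient

__all__ = [
    "load_yaml",
    "scenario_from_dict",
    "rules_from_dict",
    "catchment_config_from_dict",
    "retention_models_from_dict",
    "coefficient_table_from_dict",
    "legacy_response_from_dict",
    "load_scenario",
    "load_rules",
    "load_catchment_config",
]


def load_yaml(path) -> dict:
    with Path(path).open(encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    return data


def _apply_overrides(obj, overrides: dict):
    """Return a dataclass with ``overrides`` applied; nested mappings recurse."""
    known = {f.name: f for f in fields(obj)}
    updates = {}
    for key, val in overrides.items():
        if key not in known:
            raise ConfigurationError(
                f"unknown {type(obj).__name__} option {key!r}"
            )
        current = getattr(obj, key)
        if is_dataclass(current) and isinstance(val, dict):
            updates[key] = _apply_overrides(current, val)
        elif isinstance(current, dict) and isinstance(val, dict):
            merged = dict(current)
            merged.update(val)
            updates[key] = merged
        elif isinstance(val, list):
            updates[key] = tuple(val)
        else:
            updates[key] = val
    try:
        return replace(obj, **updates)
    except TypeError:
        # frozen dataclasses with validation: rebuild
        kwargs = {f.name: getattr(obj, f.name) for f in fields(obj)}
        kwargs.update(updates)
        return type(obj)(**kwargs)


def scenario_from_dict(data: dict) -> ScenarioSpec:
    return _apply_overrides(ScenarioSpec(), data)


def rules_from_dict(data: dict) -> ManagementRules:
    data = dict(data)
    growth = data.pop("growth", None)
    ccf = data.pop("ccf", None)
    rules = _apply_overrides(ManagementRules(), data)
    if growth:
        vol = growth.pop("volume_fn", None)
        gp = _apply_overrides(GrowthParams(), growth)
        if vol:
            gp.volume_fn = _apply_overrides(VolumeFunction(), vol)
        rules.growth = gp
    if ccf:
        rules.ccf = _apply_overrides(CCFParams(), ccf)
    return rules


def catchment_config_from_dict(data: dict) -> CatchmentConfig:
    return _apply_overrides(CatchmentConfig(), data)


def retention_models_from_dict(data: dict) -> RetentionModels:
    models = RetentionModels()
    mapping = {
        "pond": PondDamParams,
        "dam": PondDamParams,
        "wetland": WetlandParams,
        "riparian": RiparianParams,
    }
    for key, cls in mapping.items():
        if key in data:
            setattr(models, key, _apply_overrides(cls(), data[key]))
    if "riparian_coverage_pct" in data:
        models.riparian_coverage_pct = float(data["riparian_coverage_pct"])
    return models


def coefficient_table_from_dict(data: dict) -> ExportCoefficientTable:
    """Override coefficient schedules, keyed ``operation: {N: [...], P: [...]}``."""
    table = ExportCoefficientTable()
    coeffs = dict(table.coefficients)
    for op, sub in data.items():
        for nut, vals in sub.items():
            coeffs[(Operation(op), Nutrient(nut))] = tuple(float(v) for v in vals)
    return ExportCoefficientTable(coeffs)


def legacy_response_from_dict(data: dict) -> LegacyResponse:
    return _apply_overrides(LegacyResponse(), data)


def harvest_params_from_dict(data: dict) -> HarvestExportParams:
    return _apply_overrides(HarvestExportParams(), data)


def load_scenario(path) -> ScenarioSpec:
    return scenario_from_dict(load_yaml(path))


def load_rules(path) -> ManagementRules:
    return rules_from_dict(load_yaml(path))


def load_catchment_config(path) -> CatchmentConfig:
    return catchment_config_from_dict(load_yaml(path))
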