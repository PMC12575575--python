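"""Diameter-cohort arithmetic.

A stand is represented as a table of diameter cohorts: pairs of
(mid-diameter at breast height, cm; stems per hectare).  Cohort diameters
move continuously during growth, so no mass is smeared across a fixed grid.
Stand-level summaries are derived from the cohorts:

* basal area  G = sum n_i * pi * (d_i / 200)^2      [m2/ha]
* mean diameter = basal-area-weighted mean of d_i   [cm]
* volume      V = sum n_i * v(d_i)                  [m3/ha]

with a two-parameter single-tree volume function v(d) = coef * d^exponent
(m3; d in cm).  The defaults give v(20 cm) ~ 0.25 m3 and v(30 cm) ~ 0.63 m3,
plausible for boreal conifers, and are editable wherever a VolumeFunction is
accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, StandStateError

__all__ = [
    "VolumeFunction",
    "DEFAULT_VOLUME_FUNCTION",
    "basal_area",
    "mean_diameter",
    "stand_volume",
    "merge_cohorts",
    "weibull_cohorts",
]


@dataclass(frozen=True)
class VolumeFunction:
    """Single-tree stem volume v(d) = coef * d**exponent (m3, d in cm)."""

    coef: float = 2.54e-4
    exponent: float = 2.3

    def __post_init__(self) -> None:
        if self.coef <= 0 or self.exponent <= 0:
            raise ConfigurationError("volume-function parameters must be positive")

    def __call__(self, d_cm):
        return self.coef * np.asarray(d_cm, dtype=float) ** self.exponent


DEFAULT_VOLUME_FUNCTION = VolumeFunction()


def _check(diam_cm: np.ndarray, stems_ha: np.ndarray) -> None:
    if diam_cm.shape != stems_ha.shape:
        raise StandStateError("cohort arrays must have equal length")
    if np.any(stems_ha < 0):
        raise StandStateError("negative stem count in cohort table")
    if np.any(diam_cm < 0):
        raise StandStateError("negative diameter in cohort table")


def basal_area(diam_cm: np.ndarray, stems_ha: np.ndarray) -> float:
    """Stand basal area (m2/ha) of a cohort table."""
    diam_cm = np.asarray(diam_cm, float)
    stems_ha = np.asarray(stems_ha, float)
    _check(diam_cm, stems_ha)
    return float(np.sum(stems_ha * np.pi * (diam_cm / 200.0) ** 2))


def mean_diameter(diam_cm: np.ndarray, stems_ha: np.ndarray) -> float:
    """Basal-area-weighted mean diameter (cm); 0 for an empty stand."""
    diam_cm = np.asarray(diam_cm, float)
    stems_ha = np.asarray(stems_ha, float)
    _check(diam_cm, stems_ha)
    w = stems_ha * diam_cm**2
    tot = w.sum()
    if tot <= 0:
        return 0.0
    return float((w * diam_cm).sum() / tot)


def stand_volume(
    diam_cm: np.ndarray,
    stems_ha: np.ndarray,
    volume_fn: VolumeFunction = DEFAULT_VOLUME_FUNCTION,
) -> float:
    """Stand volume (m3/ha) of a cohort table."""
    diam_cm = np.asarray(diam_cm, float)
    stems_ha = np.asarray(stems_ha, float)
    _check(diam_cm, stems_ha)
    if diam_cm.size == 0:
        return 0.0
    return float(np.sum(stems_ha * volume_fn(diam_cm)))


def merge_cohorts(
    diam_cm: np.ndarray, stems_ha: np.ndarray, min_gap_cm: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Sort cohorts by diameter, merge near-coincident ones, drop empties.

    Adjacent cohorts closer than ``min_gap_cm`` are pooled at their
    basal-area-conserving quadratic mean diameter, which keeps the cohort
    count bounded as ingrowth adds seedling cohorts year after year.
    """
    diam_cm = np.asarray(diam_cm, float)
    stems_ha = np.asarray(stems_ha, float)
    _check(diam_cm, stems_ha)
    keep = stems_ha > 1e-9
    diam_cm, stems_ha = diam_cm[keep], stems_ha[keep]
    if diam_cm.size == 0:
        return diam_cm, stems_ha
    order = np.argsort(diam_cm)
    diam_cm, stems_ha = diam_cm[order], stems_ha[order]
    out_d: list[float] = [float(diam_cm[0])]
    out_n: list[float] = [float(stems_ha[0])]
    for d, n in zip(diam_cm[1:], stems_ha[1:]):
        if d - out_d[-1] < min_gap_cm:
            tot = out_n[-1] + n
            # pool at the quadratic mean so basal area is conserved
            out_d[-1] = float(np.sqrt((out_n[-1] * out_d[-1] ** 2 + n * d**2) / tot))
            out_n[-1] = float(tot)
        else:
            out_d.append(float(d))
            out_n.append(float(n))
    return np.array(out_d), np.array(out_n)


def weibull_cohorts(
    mean_d_cm: float,
    basal_area_m2_ha: float,
    shape: float = 2.5,
    class_width_cm: float = 2.0,
    rel_range: tuple[float, float] = (0.3, 1.9),
) -> tuple[np.ndarray, np.ndarray]:
    """Build a 2-cm-class diameter distribution with a given mean and basal area.

    Class midpoints span ``rel_range`` times the target mean diameter and are
    weighted by a truncated Weibull density with the given shape; stem counts
    are then scaled so the stand basal area matches exactly.  This is the
    initial-state generator's stand-structure primitive.
    """
    if mean_d_cm <= 0 or basal_area_m2_ha < 0:
        raise ConfigurationError("mean diameter must be positive, basal area >= 0")
    from scipy.special import gamma as _gamma

    scale = mean_d_cm / _gamma(1.0 + 1.0 / shape)
    lo = max(class_width_cm / 2.0, rel_range[0] * mean_d_cm)
    hi = rel_range[1] * mean_d_cm
    mids = np.arange(lo, hi + class_width_cm / 2.0, class_width_cm)
    z = (mids / scale) ** (shape - 1.0) * np.exp(-((mids / scale) ** shape))
    if z.sum() <= 0:
        raise ConfigurationError("degenerate diameter distribution")
    stems = z / z.sum()
    g1 = basal_area(mids, stems)
    if g1 > 0:
        stems = stems * (basal_area_m2_ha / g1)
    else:
        stems = np.zeros_like(stems)
    return merge_cohorts(mids, stems)
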