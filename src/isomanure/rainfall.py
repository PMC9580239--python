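"""Past-rainfall estimates from present-day rainfall.

Two adjustment rules are supported. For regions with a speleothem
oxygen-isotope record, the past/present δ18O difference of precipitation
converts to a rainfall offset at −200 mm per ‰ (a 1 ‰ *decrease* in
precipitation δ18O corresponds to roughly 200 mm *more* annual rain).
For regions covered by pollen-based seasonal anomaly maps, extreme
monthly summer and winter anomalies are each scaled by six months and
summed to bound the deviation from the modern value; the point estimate
is the midpoint of the resulting range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: calibration slope of precipitation δ18O against annual rainfall
MM_PER_PERMIL = 200.0


@dataclass(frozen=True)
class RainfallEstimate:
    """A past mean-annual-rainfall point estimate with a min/max range."""

    mean_mm: float
    min_mm: float
    max_mm: float

    def __post_init__(self):
        if not (self.min_mm <= self.mean_mm <= self.max_mm):
            raise ValueError(
                f"require min <= mean <= max, got "
                f"({self.min_mm}, {self.mean_mm}, {self.max_mm})"
            )
        if self.min_mm <= 0:
            raise ValueError("rainfall must be positive after clamping")


def speleothem_adjust(
    present_mm: float, delta_d18o: float, floor_mm: float = 1.0
) -> float:
    """Adjust present-day rainfall using a speleothem δ18O anomaly.

    Parameters
    ----------
    present_mm : float
        Present-day mean annual rainfall, mm/yr (> 0).
    delta_d18o : float
        Precipitation δ18O anomaly in ‰, sign convention past − present.
        A negative anomaly (wetter past) increases rainfall.
    floor_mm : float
        Lower clamp guarding against nonphysical negative rainfall.

    Returns
    -------
    float
        ``present_mm − 200 · delta_d18o``, clamped at ``floor_mm``.
    """
    if not (math.isfinite(present_mm) and math.isfinite(delta_d18o)):
        raise ValueError("inputs must be finite")
    if present_mm <= 0:
        raise ValueError(f"present_mm must be positive, got {present_mm}")
    return max(present_mm - MM_PER_PERMIL * delta_d18o, floor_mm)


def pollen_anomaly_range(
    present_mm: float,
    summer_extreme_min: float,
    summer_extreme_max: float,
    winter_extreme_min: float,
    winter_extreme_max: float,
    floor_mm: float = 1.0,
) -> RainfallEstimate:
    """Bound past rainfall from seasonal pollen-derived monthly anomalies.

    The extreme monthly deviations (mm/month, past − present) for summer
    and winter are each multiplied by six months and summed:

    * ``min_mm = present + 6·(summer_min + winter_min)``
    * ``max_mm = present + 6·(summer_max + winter_max)``

    and the point estimate is the midpoint of the two.
    """
    if summer_extreme_min > summer_extreme_max:
        raise ValueError("summer_extreme_min > summer_extreme_max")
    if winter_extreme_min > winter_extreme_max:
        raise ValueError("winter_extreme_min > winter_extreme_max")
    if present_mm <= 0:
        raise ValueError(f"present_mm must be positive, got {present_mm}")
    lo = max(present_mm + 6.0 * (summer_extreme_min + winter_extreme_min), floor_mm)
    hi = max(present_mm + 6.0 * (summer_extreme_max + winter_extreme_max), floor_mm)
    return RainfallEstimate(mean_mm=0.5 * (lo + hi), min_mm=lo, max_mm=hi)
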