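"""Photoperiod-driven plant development simulator (pgrowth).

A deterministic daily model linking a base level of the floral repressor
TFL1, latitude and a critical day-length threshold to stem height,
flowering time and flower production.  The mechanism is threshold-gated
accumulation of a florigen (FT-like) signal against a TFL1 set-point:

* while vegetative, the apical meristem initiates nodes at a constant rate
  and the FT signal grows by ``ft_gain * max(0, L(day) - threshold)``
  where L is the astronomical day length;
* the plant switches to flowering on the first day the accumulated signal
  strictly exceeds the TFL1 base level T;
* after the switch it produces flowers at a constant daily rate on days
  whose day length still exceeds the threshold, until the season ends.

Higher T therefore delays flowering and yields taller (longer-stemmed)
plants; high latitudes, whose summer day lengths overshoot the threshold
by much more, both accumulate signal faster and keep flowering longer.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "GrowthParams",
    "PlantArchitecture",
    "day_length",
    "simulate_growth",
    "architecture_sweep",
]


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the photoperiod growth model.

    Attributes
    ----------
    tfl1_base
        Dimensionless TFL1 set-point T >= 0 the florigen signal must exceed.
    threshold_hours
        Critical day length (hours) for floral induction; default 14.
    latitude
        Degrees north.
    sowing_day, season_end
        Day-of-year bounds of the growing season (defaults 105 and 280,
        mid-April to early October).
    node_rate
        Vegetative node initiation rate (nodes/day).
    internode_mm
        Internode length (mm/node); stem height = nodes * internode_mm.
    ft_gain
        Florigen accumulation per hour of day length above threshold per
        day (signal h^-1 day^-1).
    flower_rate
        Flowers initiated per flowering day.
    """

    tfl1_base: float = 0.0
    threshold_hours: float = 14.0
    latitude: float = 50.0
    sowing_day: int = 105
    season_end: int = 280
    node_rate: float = 0.5
    internode_mm: float = 10.0
    ft_gain: float = 1.0
    flower_rate: float = 1.0

    def __post_init__(self):
        if self.tfl1_base < 0:
            raise ValueError("tfl1_base must be >= 0")
        if not 0.0 < self.threshold_hours < 24.0:
            raise ValueError("threshold_hours must lie in (0, 24)")
        if not 1 <= self.sowing_day < self.season_end <= 365:
            raise ValueError("need 1 <= sowing_day < season_end <= 365")
        for name in ("node_rate", "internode_mm", "ft_gain", "flower_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class PlantArchitecture:
    """Simulated end-of-season outputs for one parameter combination."""

    stem_height_mm: float
    days_to_flowering: int | None
    flower_count: float
    flowering_duration_days: int
    flower_rate_realized: float
    flowered: bool


def day_length(latitude: float, day_of_year) -> float:
    """Astronomical day length (hours) from the cosine-declination formula.

    delta = -23.44 * cos(2*pi*(day + 10)/365) degrees;
    L = 24/pi * arccos(-tan(phi) tan(delta)), clamped to [0, 24] (polar day
    or night at extreme latitude/season combinations, with a warning).
    No atmospheric refraction correction is applied.
    """
    day = np.asarray(day_of_year, dtype=float)
    phi = np.deg2rad(latitude)
    delta = np.deg2rad(-23.44 * np.cos(2.0 * np.pi * (day + 10.0) / 365.0))
    cos_h0 = -np.tan(phi) * np.tan(delta)
    clipped = (cos_h0 < -1.0) | (cos_h0 > 1.0)
    if np.any(clipped):
        warnings.warn(
            "polar day/night encountered; day length clamped to 0 or 24 h",
            stacklevel=2,
        )
    h0 = np.arccos(np.clip(cos_h0, -1.0, 1.0))
    length = 24.0 * h0 / np.pi
    return float(length) if length.ndim == 0 else length


def simulate_growth(params: GrowthParams) -> PlantArchitecture:
    """Run the daily growth loop for one parameter set (deterministic)."""
    nodes = 0.0
    signal = 0.0
    flowers = 0.0
    flowering_days = 0
    transition_day = None
    for day in range(params.sowing_day, params.season_end + 1):
        length = day_length(params.latitude, day)
        excess = max(0.0, length - params.threshold_hours)
        if transition_day is None:
            nodes += params.node_rate
            signal += params.ft_gain * excess
            if signal > params.tfl1_base:  # strict threshold crossing
                transition_day = day
        else:
            if length > params.threshold_hours:
                flowers += params.flower_rate
                flowering_days += 1
    flowered = transition_day is not None
    if not flowered:
        flowers = 0.0
        flowering_days = 0
    return PlantArchitecture(
        stem_height_mm=nodes * params.internode_mm,
        days_to_flowering=(
            transition_day - params.sowing_day + 1 if transition_day else None
        ),
        flower_count=flowers,
        flowering_duration_days=flowering_days,
        flower_rate_realized=(
            flowers / flowering_days if flowering_days else 0.0
        ),
        flowered=flowered,
    )


def architecture_sweep(
    tfl1_levels,
    latitudes,
    params: GrowthParams | None = None,
) -> pd.DataFrame:
    """Simulate every (TFL1 level, latitude) combination.

    Returns one row per combination with all :class:`PlantArchitecture`
    outputs, ready for TSV export and external plotting.
    """
    if params is None:
        params = GrowthParams()
    tfl1_levels = list(tfl1_levels)
    latitudes = list(latitudes)
    if not tfl1_levels or not latitudes:
        raise ValueError("need at least one TFL1 level and one latitude")
    rows = []
    for level, lat in itertools.product(tfl1_levels, latitudes):
        arch = simulate_growth(replace(params, tfl1_base=level, latitude=lat))
        rows.append(
            {
                "tfl1_base": level,
                "latitude": lat,
                "stem_height_mm": arch.stem_height_mm,
                "days_to_flowering": arch.days_to_flowering,
                "flower_count": arch.flower_count,
                "flowering_duration_days": arch.flowering_duration_days,
                "flower_rate_realized": arch.flower_rate_realized,
                "flowered": arch.flowered,
            }
        )
    return pd.DataFrame(rows)
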