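"""Terrain-aware locomotion energetics.

Metabolic power while walking is modelled as a banded linear function of
speed, from treadmill respirometry of helmeted guineafowl at controlled
speeds and inclines:

    VO2 = a_g * v + b_g      [ml O2 kg-1 min-1],  v in m s-1

with one (a_g, b_g) pair per incline band g (level, 10 %, 20 % grade) and a
fixed stationary rate while not moving.  Oxygen volumes convert to energy at
20.1 J per ml O2.  The incline a bird experiences on a step is derived from
the terrain slope, the terrain aspect (direction of steepest ascent) and the
step's bearing; downhill movement is costed as level ground.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import correlate

from .trackio import DemGrid

BAND_LEVEL = 0
BAND_10 = 1
BAND_20 = 2
BAND_NAMES = {BAND_LEVEL: "level", BAND_10: "10%", BAND_20: "20%"}


@dataclass
class CostModelParams:
    """Banded linear VO2 coefficients plus stationary rate and conversion.

    Units: slopes in ml O2 kg-1 min-1 per (m s-1), intercepts and
    ``stationary_rate`` in ml O2 kg-1 min-1, ``energy_per_ml_o2`` in J ml-1.
    """

    slopes: tuple[float, float, float] = (24.0, 30.7, 47.7)
    intercepts: tuple[float, float, float] = (27.2, 27.6, 21.3)
    stationary_rate: float = 19.1
    energy_per_ml_o2: float = 20.1

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.slopes) or any(
            b <= 0 for b in self.intercepts
        ):
            raise ValueError("cost-model coefficients must be positive")
        if self.stationary_rate <= 0 or self.energy_per_ml_o2 <= 0:
            raise ValueError("rates must be positive")


def compute_slope_aspect(dem: DemGrid) -> DemGrid:
    """Derive slope and aspect layers with Horn's 8-neighbour method.

    Slope in degrees; aspect as the compass direction of steepest ascent
    (0 = north, clockwise), set to 0 and meaningless where slope is 0.
    Edges use reflected padding.  Modifies ``dem`` in place and returns it.
    """
    z = dem.elevation
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("grid must be at least 3x3")
    if np.all(np.isnan(z)):
        raise ValueError("all cells are nodata")
    # Horn kernels for dz/dx (x east = increasing column) and dz/dy
    # (y north = decreasing row index).
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
    ky = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], dtype=float)
    zf = np.where(np.isnan(z), np.nanmean(z), z)
    dzdx = correlate(zf, kx, mode="reflect") / (8.0 * dem.cell_size)
    dzdy = correlate(zf, ky, mode="reflect") / (8.0 * dem.cell_size)
    grad = np.hypot(dzdx, dzdy)
    dem.slope = np.degrees(np.arctan(grad))
    aspect = np.degrees(np.arctan2(dzdx, dzdy)) % 360.0
    aspect[grad == 0.0] = 0.0
    dem.aspect = aspect
    return dem


def experienced_slope(theta, aspect, bearing):
    """Incline along the direction of travel, in degrees.

    ``theta`` is the terrain slope, ``aspect`` the direction of steepest
    ascent and ``bearing`` the travel bearing (all degrees).  Positive values
    mean uphill movement:

        theta' = atan(tan(theta) * cos(aspect - bearing))
    """
    theta = np.asarray(theta, dtype=float)
    dpsi = np.radians(np.asarray(aspect, dtype=float) - np.asarray(bearing, dtype=float))
    return np.degrees(np.arctan(np.tan(np.radians(theta)) * np.cos(dpsi)))


def percent_grade(theta_prime):
    """Percent grade of an experienced slope (degrees): 100 * tan(theta')."""
    return 100.0 * np.tan(np.radians(np.asarray(theta_prime, dtype=float)))


def grade_band(theta_prime):
    """Map experienced slope (degrees) to a cost band.

    Downhill (negative grade) is treated as level ground; 0-5 % grade is
    level, 5-15 % uses the 10 % relationship, >=15 % the 20 % relationship.
    """
    pg = percent_grade(theta_prime)
    band = np.full(np.shape(pg), BAND_LEVEL, dtype=int)
    band = np.where(pg >= 5.0, BAND_10, band)
    band = np.where(pg >= 15.0, BAND_20, band)
    if np.ndim(pg) == 0:
        return int(band)
    return band


def per_second_cost(state, v, band, params: CostModelParams | None = None):
    """Metabolic cost of one second of data, in J kg-1 s-1.

    Stationary seconds (state 1) cost the resting rate; moving seconds
    (states 2-4) follow the banded linear VO2-speed relationship evaluated
    at the smoothed speed ``v``.
    """
    params = params or CostModelParams()
    state = np.asarray(state)
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("speed must be non-negative")
    band = np.asarray(band, dtype=int)
    a = np.asarray(params.slopes)[band]
    b = np.asarray(params.intercepts)[band]
    vo2_per_min = np.where(state == 1, params.stationary_rate, a * v + b)
    cost = vo2_per_min / 60.0 * params.energy_per_ml_o2
    if cost.ndim == 0:
        return float(cost)
    return cost


def step_bearings(x, y):
    """Compass bearing (degrees, 0 = north, clockwise) of each step.

    For n positions returns n-1 bearings; zero-length steps get bearing 0.
    """
    dx = np.diff(np.asarray(x, dtype=float))
    dy = np.diff(np.asarray(y, dtype=float))
    return np.degrees(np.arctan2(dx, dy)) % 360.0


def track_costs(
    block: pd.DataFrame,
    dem: DemGrid,
    params: CostModelParams | None = None,
) -> pd.DataFrame:
    """Per-second costs for one continuous 1 Hz block.

    ``block`` needs columns ``x``, ``y``, ``state`` and smoothed speed ``v``.
    The incline band of each second comes from the DEM cell containing the
    fix and the bearing of the step leaving it; the last fix reuses the final
    step's bearing.  Returns ``block`` with added ``band`` and ``cost``
    columns.
    """
    params = params or CostModelParams()
    if dem.slope is None or dem.aspect is None:
        compute_slope_aspect(dem)
    x = block["x"].to_numpy()
    y = block["y"].to_numpy()
    if len(block) < 2:
        out = block.copy()
        out["band"] = BAND_LEVEL
        out["cost"] = per_second_cost(
            block["state"].to_numpy(), block["v"].to_numpy(), 0, params
        )
        return out
    bearings = step_bearings(x, y)
    bearings = np.append(bearings, bearings[-1])
    row, col = dem.cell_index(x, y)
    theta = dem.slope[row, col]
    aspect = dem.aspect[row, col]
    theta = np.where(np.isnan(theta), 0.0, theta)
    band = grade_band(experienced_slope(theta, aspect, bearings))
    out = block.copy()
    out["band"] = band
    out["cost"] = per_second_cost(
        block["state"].to_numpy(), block["v"].to_numpy(), band, params
    )
    return out
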