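"""Cost of transport over 50 m displacement segments and daily energy use.

High-resolution blocks (with per-second costs attached) are partitioned into
consecutive segments of 50 m *net* displacement (straight-line distance from
the segment's first fix) or 50 m *cumulative* displacement (running sum of
step lengths).  The fix that crosses the threshold closes the current
segment and opens the next; its per-second cost belongs to the closing
segment only.  The trailing incomplete segment is discarded.  Cost of
transport (J kg-1 m-1) divides the segment's summed energy by the *achieved*
distance, which may overshoot 50 m.

Daily energy standardises the mean per-second cost across a day's
high-resolution seconds to a 13 h (46 800 s) tracking day; days with fewer
than 2 h of high-resolution data are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEGMENT_METRES = 50.0
DAY_SECONDS = 46_800
MIN_HIRES_SECONDS = 7200  # 2 h


@dataclass
class DisplacementSegment:
    kind: str  # "net" | "cumulative"
    start_t: int
    end_t: int
    distance: float  # achieved distance, metres (>= threshold)
    energy: float  # J kg-1
    individual: str = ""
    date: str = ""
    context: str | None = None

    @property
    def cot(self) -> float:
        return self.energy / self.distance


def _net_boundaries(x: np.ndarray, y: np.ndarray, threshold: float) -> list[int]:
    """Indices of fixes that close successive net-displacement segments."""
    bounds = []
    start = 0
    n = len(x)
    chunk = 4096
    while True:
        lo = start + 1
        hit = -1
        while lo < n:
            hi = min(n, lo + chunk)
            d = np.hypot(x[lo:hi] - x[start], y[lo:hi] - y[start])
            over = np.nonzero(d >= threshold)[0]
            if len(over):
                hit = lo + int(over[0])
                break
            lo = hi
        if hit < 0:
            break
        bounds.append(hit)
        start = hit
    return bounds


def _cumulative_boundaries(steps: np.ndarray, threshold: float) -> list[int]:
    """Indices of fixes closing cumulative-displacement segments.

    ``steps[i]`` is the length of the step from fix i to fix i+1; a segment
    closes at the fix whose incoming step pushes the running sum to the
    threshold.
    """
    cum = np.cumsum(steps)
    bounds = []
    base = 0.0
    while True:
        j = int(np.searchsorted(cum, base + threshold - 1e-12, side="left"))
        if j >= len(cum):
            break
        bounds.append(j + 1)  # fix index = step index + 1
        base = cum[j]
    return bounds


def segment_block(
    block: pd.DataFrame,
    kind: str,
    threshold: float = SEGMENT_METRES,
    individual: str = "",
    date: str = "",
    context: str | None = None,
) -> list[DisplacementSegment]:
    """Partition one costed block into displacement segments.

    ``block`` needs columns ``t``, ``x``, ``y`` and ``cost``.  Segment
    energy sums per-second costs from the opening fix (inclusive) to the
    crossing fix (inclusive); the crossing fix's cost is not double-counted
    in the segment it opens.
    """
    if kind not in ("net", "cumulative"):
        raise ValueError("kind must be 'net' or 'cumulative'")
    x = block["x"].to_numpy(dtype=float)
    y = block["y"].to_numpy(dtype=float)
    cost = block["cost"].to_numpy(dtype=float)
    t = block["t"].to_numpy()
    if len(x) < 2:
        return []
    if kind == "net":
        bounds = _net_boundaries(x, y, threshold)
    else:
        bounds = _cumulative_boundaries(
            np.hypot(np.diff(x), np.diff(y)), threshold
        )
    if not bounds:
        logger.info("block never reached %.0f m %s displacement", threshold, kind)
        return []
    segments = []
    cum_steps = np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(x), np.diff(y)))])
    cum_cost = np.concatenate([[0.0], np.cumsum(cost)])
    start = 0
    for i, end in enumerate(bounds):
        if kind == "net":
            dist = float(np.hypot(x[end] - x[start], y[end] - y[start]))
        else:
            dist = float(cum_steps[end] - cum_steps[start])
        # seconds start..end inclusive; a crossing fix belongs to the segment
        # it closes, so segments after the first start at start+1
        first_sec = start if i == 0 else start + 1
        energy = float(cum_cost[end + 1] - cum_cost[first_sec])
        segments.append(
            DisplacementSegment(
                kind=kind,
                start_t=int(t[start]),
                end_t=int(t[end]),
                distance=dist,
                energy=energy,
                individual=individual,
                date=date,
                context=context,
            )
        )
        start = end
    return segments


def segment_net(block: pd.DataFrame, **kwargs) -> list[DisplacementSegment]:
    """50 m net-displacement segments of one costed block."""
    return segment_block(block, "net", **kwargs)


def segment_cumulative(block: pd.DataFrame, **kwargs) -> list[DisplacementSegment]:
    """50 m cumulative-displacement segments of one costed block."""
    return segment_block(block, "cumulative", **kwargs)


def segment_table(segments) -> pd.DataFrame:
    rows = [
        {
            "individual": s.individual,
            "date": s.date,
            "context": s.context,
            "kind": s.kind,
            "start_t": s.start_t,
            "end_t": s.end_t,
            "distance": s.distance,
            "energy": s.energy,
            "cot": s.cot,
        }
        for s in segments
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "individual", "date", "context", "kind",
            "start_t", "end_t", "distance", "energy", "cot",
        ],
    )


@dataclass
class DailyEnergy:
    individual: str
    date: str
    context: str | None
    mean_cost: float  # J kg-1 s-1 over available hires seconds
    expenditure: float  # J kg-1 d-1, standardised to 46 800 s
    hires_hours: float


def daily_energy(
    track,
    day_seconds: int = DAY_SECONDS,
    min_hires_seconds: int = MIN_HIRES_SECONDS,
) -> DailyEnergy | None:
    """Standardised daily energetic expenditure of one costed day-track.

    Mean per-second cost over the day's high-resolution seconds multiplied
    by 46 800 s; days under 2 h of high-resolution data are excluded
    (returns None, logged).
    """
    hires = track.hires
    if "cost" not in hires.columns:
        raise ValueError("track has no per-second costs; run energetics first")
    costed = hires[hires["cost"].notna()]
    if len(costed) < min_hires_seconds:
        logger.info(
            "day %s/%s excluded from daily energy: %.2f h of hires data",
            track.individual,
            track.date,
            len(costed) / 3600.0,
        )
        return None
    mean_cost = float(costed["cost"].mean())
    return DailyEnergy(
        individual=track.individual,
        date=track.date,
        context=track.context,
        mean_cost=mean_cost,
        expenditure=mean_cost * day_seconds,
        hires_hours=len(costed) / 3600.0,
    )


def daily_energy_table(entries) -> pd.DataFrame:
    rows = [e.__dict__ for e in entries if e is not None]
    return pd.DataFrame(
        rows,
        columns=[
            "individual", "date", "context",
            "mean_cost", "expenditure", "hires_hours",
        ],
    )
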