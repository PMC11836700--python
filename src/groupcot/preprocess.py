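"""Split tracking data into resolutions and build analysis structures.

Each individual-day is decomposed into:

* *high-resolution blocks* — maximal runs of fixes with inter-fix gaps of at
  most 1 s (continuous 1 Hz data; a 10-fix GPS burst also forms a short
  block, which the downstream coverage and length rules exclude from
  high-resolution analyses);
* the *5 min series* — for every 5 min slot of the day, the fix recorded at
  the slot's 10th second, taken from burst data or by subsampling 1 Hz data.

Per-second speeds are smoothed with a centred rolling 5 s mean of per-second
displacements to suppress GPS jitter.  Windowed analyses tile the day from
its start and keep only windows that meet a high-resolution coverage
threshold (strict inequality).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WINDOW_LENGTHS = (30, 60, 120, 300, 600, 900, 1800, 3600)
FIVE_MIN = 300
SLOT_FIX_SECOND = 9  # the 10th second of each 5 min slot, zero-based


@dataclass
class DayTrack:
    """One individual-day, split into resolutions.

    ``hires`` holds all fixes belonging to high-resolution blocks with
    columns ``t`` (second of day), ``x``, ``y``, ``block`` and, once
    computed, ``v`` (smoothed speed), ``state``, ``band`` and ``cost``.
    ``five_min`` holds one row per filled 5 min slot.
    """

    individual: str
    date: str
    context: str | None
    day_start: pd.Timestamp
    hires: pd.DataFrame
    five_min: pd.DataFrame

    @property
    def n_hires_seconds(self) -> int:
        return len(self.hires)

    def blocks(self):
        """Iterate over high-resolution blocks as DataFrames."""
        if self.hires.empty:
            return
        for _, grp in self.hires.groupby("block", sort=True):
            yield grp


@dataclass
class AnalysisWindow:
    """A coverage-qualified tiling window of one day."""

    start: int  # second of day
    length: int
    coverage: float
    index: np.ndarray  # positional indices into DayTrack.hires


def split_resolutions(
    fixes: pd.DataFrame,
    day_start_clock: str = "06:00",
    context: str | None = None,
    min_block_fixes: int = 11,
) -> DayTrack:
    """Decompose one individual-day of time-sorted fixes into resolutions.

    A maximal gap<=1 s run qualifies as a high-resolution block only when it
    is longer than a GPS burst (``min_block_fixes``, default 11 fixes), so
    burst-only days contribute no high-resolution blocks; every fix still
    feeds the 5 min series.
    """
    if fixes.empty:
        return DayTrack(
            individual="",
            date="",
            context=context,
            day_start=pd.NaT,
            hires=pd.DataFrame(columns=["t", "x", "y", "block"]),
            five_min=pd.DataFrame(columns=["slot", "t", "x", "y"]),
        )
    individual = str(fixes["individual"].iloc[0])
    date = fixes["time"].iloc[0].strftime("%Y-%m-%d")
    day_start = pd.Timestamp(f"{date} {day_start_clock}")
    t = (
        (fixes["time"] - day_start).dt.total_seconds().round().astype(int).to_numpy()
    )
    x = fixes["x"].to_numpy(dtype=float)
    y = fixes["y"].to_numpy(dtype=float)

    # maximal runs with inter-fix gap <= 1 s, kept if longer than a burst
    gaps = np.diff(t)
    block = np.concatenate([[0], np.cumsum(gaps > 1)])
    sizes = np.bincount(block)
    keep = sizes[block] >= min_block_fixes
    hires = pd.DataFrame(
        {"t": t[keep], "x": x[keep], "y": y[keep], "block": block[keep]}
    ).reset_index(drop=True)

    # 5 min series: the fix at each slot's 10th second
    slot_mask = (t % FIVE_MIN) == SLOT_FIX_SECOND
    five_min = pd.DataFrame(
        {
            "slot": t[slot_mask] // FIVE_MIN,
            "t": t[slot_mask],
            "x": x[slot_mask],
            "y": y[slot_mask],
        }
    )
    return DayTrack(
        individual=individual,
        date=date,
        context=context,
        day_start=day_start,
        hires=hires,
        five_min=five_min,
    )


def smooth_speeds(track: DayTrack) -> DayTrack:
    """Attach the smoothed per-second speed ``v`` to every hires fix.

    The speed at second ``t`` is the mean per-second displacement over
    seconds ``[t-2, t+2]`` within the fix's block, truncated at block edges.
    The block's final fix (which starts no step) inherits the mean of the
    displacements remaining in its window.  Blocks of a single fix get v=0.
    """
    if track.hires.empty:
        track.hires["v"] = pd.Series(dtype=float)
        return track
    v_parts = []
    for blk in track.blocks():
        n = len(blk)
        if n < 2:
            v_parts.append(pd.Series([0.0], index=blk.index))
            continue
        dx = np.diff(blk["x"].to_numpy())
        dy = np.diff(blk["y"].to_numpy())
        steps = pd.Series(np.hypot(dx, dy))
        v = steps.rolling(5, center=True, min_periods=1).mean().to_numpy()
        v_last = steps.iloc[max(0, n - 3):].mean()
        v_parts.append(pd.Series(np.append(v, v_last), index=blk.index))
    track.hires["v"] = pd.concat(v_parts)
    return track


def make_windows(
    track: DayTrack, length: int, coverage_min: float
) -> list[AnalysisWindow]:
    """Tile the day from its start; keep windows whose high-resolution
    coverage strictly exceeds ``coverage_min``."""
    if length not in WINDOW_LENGTHS:
        raise ValueError(f"window length must be one of {WINDOW_LENGTHS}")
    if track.hires.empty:
        return []
    t = track.hires["t"].to_numpy()
    win_id = t // length
    windows = []
    order = np.arange(len(t))
    for wid in np.unique(win_id):
        sel = order[win_id == wid]
        coverage = len(sel) / length
        if coverage > coverage_min:
            windows.append(
                AnalysisWindow(
                    start=int(wid) * length,
                    length=length,
                    coverage=coverage,
                    index=sel,
                )
            )
    return windows


def split_cohort(
    fixes: pd.DataFrame,
    day_start_clock: str = "06:00",
    contexts: dict | None = None,
) -> list[DayTrack]:
    """Split a multi-individual fix table into per-individual-day tracks.

    ``contexts`` optionally maps individual id -> context label; if absent
    and the individual id embeds the context (synthetic cohorts), the prefix
    before the final ``-`` is used.
    """
    tracks = []
    fixes = fixes.copy()
    fixes["date"] = fixes["time"].dt.strftime("%Y-%m-%d")
    for (individual, _date), grp in fixes.groupby(
        ["individual", "date"], sort=True
    ):
        if contexts is not None:
            context = contexts.get(individual)
        else:
            context = individual.rsplit("-", 1)[0]
        tracks.append(
            split_resolutions(grp, day_start_clock=day_start_clock, context=context)
        )
    return tracks
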