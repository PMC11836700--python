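"""Movement-behaviour measures: track length, speed while moving,
straightness — at daily and windowed scales.

Daily track length sums consecutive 5 min displacements (available for every
bird on every day).  The straightness index divides net displacement by
cumulative displacement over an interval; daily straightness uses the day's
first and last fixes over the 5 min track length, windowed straightness uses
per-second displacements within tiling windows of >95 % high-resolution
coverage.  Speed while moving averages the smoothed per-second speed over
seconds decoded to the moving states (2-4) within windows of >50 %
high-resolution coverage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import DayTrack, make_windows
from .states import moving_mask

SPEED_COVERAGE = 0.5
STRAIGHTNESS_COVERAGE = 0.95


def daily_track_length(track: DayTrack) -> float | None:
    """Sum of consecutive 5 min displacements, metres; None if < 2 fixes."""
    fm = track.five_min
    if len(fm) < 2:
        return None
    return float(
        np.hypot(np.diff(fm["x"].to_numpy()), np.diff(fm["y"].to_numpy())).sum()
    )


def straightness_index(x, y) -> float | None:
    """Net over cumulative displacement of an ordered point sequence.

    None when the cumulative displacement is zero (undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2:
        return None
    cumulative = float(np.hypot(np.diff(x), np.diff(y)).sum())
    if cumulative == 0.0:
        return None
    net = float(np.hypot(x[-1] - x[0], y[-1] - y[0]))
    return net / cumulative


def daily_straightness(track: DayTrack) -> float | None:
    """Daily net displacement (first to last fix) over the 5 min track length."""
    fm = track.five_min
    if len(fm) < 2:
        return None
    length = daily_track_length(track)
    if not length:
        return None
    net = float(
        np.hypot(
            fm["x"].iloc[-1] - fm["x"].iloc[0], fm["y"].iloc[-1] - fm["y"].iloc[0]
        )
    )
    return net / length


def window_speed(
    track: DayTrack, length: int = 300, coverage_min: float = SPEED_COVERAGE
) -> pd.DataFrame:
    """Mean speed-while-moving per qualifying window.

    One row per window containing at least one moving (state 2-4) second;
    columns ``window_start``, ``length``, ``value`` (m s-1), ``hour_bin``.
    """
    if "v" not in track.hires.columns or "state" not in track.hires.columns:
        raise ValueError("track needs smoothed speeds and decoded states")
    rows = []
    for win in make_windows(track, length, coverage_min):
        sub = track.hires.iloc[win.index]
        moving = moving_mask(sub["state"].to_numpy())
        if not moving.any():
            continue
        rows.append(
            {
                "individual": track.individual,
                "date": track.date,
                "context": track.context,
                "window_start": win.start,
                "length": length,
                "value": float(sub["v"].to_numpy()[moving].mean()),
                "hour_bin": win.start // 3600,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "individual", "date", "context",
            "window_start", "length", "value", "hour_bin",
        ],
    )


def window_straightness(
    track: DayTrack, length: int = 300, coverage_min: float = STRAIGHTNESS_COVERAGE
) -> pd.DataFrame:
    """Straightness index per qualifying window (per-second displacements)."""
    rows = []
    for win in make_windows(track, length, coverage_min):
        sub = track.hires.iloc[win.index]
        value = straightness_index(sub["x"].to_numpy(), sub["y"].to_numpy())
        if value is None:
            continue
        rows.append(
            {
                "individual": track.individual,
                "date": track.date,
                "context": track.context,
                "window_start": win.start,
                "length": length,
                "value": value,
                "hour_bin": win.start // 3600,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "individual", "date", "context",
            "window_start", "length", "value", "hour_bin",
        ],
    )


def daily_metrics(tracks) -> pd.DataFrame:
    """One row per individual-day: track length and daily straightness."""
    rows = []
    for track in tracks:
        length = daily_track_length(track)
        if length is None:
            continue
        rows.append(
            {
                "individual": track.individual,
                "date": track.date,
                "context": track.context,
                "track_length": length,
                "straightness": daily_straightness(track),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["individual", "date", "context", "track_length", "straightness"],
    )


def sensitivity_grid(
    tracks, lengths=(30, 60, 120, 300, 600, 900, 1800, 3600)
) -> dict[int, dict[str, pd.DataFrame]]:
    """Windowed speed and straightness recomputed at several window lengths."""
    out: dict[int, dict[str, pd.DataFrame]] = {}
    for length in lengths:
        speed_frames = [window_speed(t, length) for t in tracks]
        straight_frames = [window_straightness(t, length) for t in tracks]
        out[length] = {
            "speed": pd.concat(speed_frames, ignore_index=True)
            if speed_frames
            else pd.DataFrame(),
            "straightness": pd.concat(straight_frames, ignore_index=True)
            if straight_frames
            else pd.DataFrame(),
        }
    return out
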