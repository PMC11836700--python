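"""Classify days as large-displacement versus normal ranging.

A day counts as a large displacement when the roost-to-roost distance (net
displacement between the day's first and last fix) exceeds 1500 m, or when
it exceeds 1200 m and the ratio of roost-to-roost distance to the total
daily track length (summed 5 min displacements) exceeds 0.3 — the second
rule catches days with one large turn.  For each group-living individual a
matched set of normal days is drawn at random, as many as that individual
contributed large days; lone dispersers contribute only large days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import DayTrack

logger = logging.getLogger(__name__)

ROOST_THRESHOLD = 1500.0
ROOST_THRESHOLD_TURN = 1200.0
STRAIGHTNESS_THRESHOLD = 0.3


@dataclass
class DayClassification:
    individual: str
    date: str
    context: str | None
    roost_to_roost: float
    daily_track_length: float
    straightness_ratio: float
    label: str  # "large" | "normal"


def classify_day(
    track: DayTrack,
    roost_threshold: float = ROOST_THRESHOLD,
    roost_threshold_turn: float = ROOST_THRESHOLD_TURN,
    straightness_threshold: float = STRAIGHTNESS_THRESHOLD,
) -> DayClassification | None:
    """Classify one day; returns None (logged) when unclassifiable."""
    fm = track.five_min
    if len(fm) < 2:
        logger.info(
            "day %s/%s unclassifiable: fewer than two 5 min fixes",
            track.individual,
            track.date,
        )
        return None
    x = fm["x"].to_numpy()
    y = fm["y"].to_numpy()
    roost = float(np.hypot(x[-1] - x[0], y[-1] - y[0]))
    length = float(np.hypot(np.diff(x), np.diff(y)).sum())
    ratio = roost / length if length > 0 else 0.0
    large = roost > roost_threshold or (
        roost > roost_threshold_turn and ratio > straightness_threshold
    )
    return DayClassification(
        individual=track.individual,
        date=track.date,
        context=track.context,
        roost_to_roost=roost,
        daily_track_length=length,
        straightness_ratio=ratio,
        label="large" if large else "normal",
    )


def classification_table(classifications) -> pd.DataFrame:
    rows = [c.__dict__ for c in classifications if c is not None]
    return pd.DataFrame(
        rows,
        columns=[
            "individual",
            "date",
            "context",
            "roost_to_roost",
            "daily_track_length",
            "straightness_ratio",
            "label",
        ],
    )


def sample_matched_days(table: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Draw, per individual, as many random normal days as it has large days.

    Input is a classification table (one row per individual-day).  Returns
    the selected normal-day rows; sampling is uniform without replacement and
    reproducible from the seed.  Individuals short of normal days contribute
    all of them, with a logged shortfall.
    """
    rng = np.random.default_rng(seed)
    picks = []
    for individual, grp in table.groupby("individual", sort=True):
        n_large = int((grp["label"] == "large").sum())
        if n_large == 0:
            continue
        normal = grp[grp["label"] == "normal"]
        if len(normal) < n_large:
            logger.warning(
                "individual %s: only %d normal days for %d large days",
                individual,
                len(normal),
                n_large,
            )
            picks.append(normal)
        else:
            idx = rng.choice(len(normal), size=n_large, replace=False)
            picks.append(normal.iloc[np.sort(idx)])
    if not picks:
        return table.iloc[0:0]
    return pd.concat(picks)
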