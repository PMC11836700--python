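"""End-to-end orchestration: simulate -> preprocess -> classify -> decode ->
cost -> segment -> metrics -> contrasts.

Every stage persists its table to the run's output directory so any stage
can be rerun or inspected in isolation, and a structured log accounts for
each record retained or excluded.  The whole run is deterministic given the
configured seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cot as cot_mod
from . import daytype, energetics, metrics, preprocess, simulate, states, stats, trackio

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Thresholds default to the published analysis constants; the simulation
    block defines the synthetic cohort when no fix table is supplied.
    """

    out_dir: str = "runs/demo"
    seed: int = 0
    fixes_path: str | None = None  # read instead of simulating when set
    dem_path: str | None = None
    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    roost_threshold: float = daytype.ROOST_THRESHOLD
    roost_threshold_turn: float = daytype.ROOST_THRESHOLD_TURN
    straightness_threshold: float = daytype.STRAIGHTNESS_THRESHOLD
    segment_metres: float = cot_mod.SEGMENT_METRES
    speed_coverage: float = metrics.SPEED_COVERAGE
    straightness_coverage: float = metrics.STRAIGHTNESS_COVERAGE
    min_hires_seconds: int = cot_mod.MIN_HIRES_SECONDS
    window_length: int = 300
    cost_params: energetics.CostModelParams = field(
        default_factory=energetics.CostModelParams
    )
    hmm_restarts: int = 10

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class RunResult:
    """Tables and fitted objects produced by one pipeline run."""

    tracks: list
    classifications: pd.DataFrame
    bins: pd.DataFrame
    hmm: states.HmmResults
    segments: pd.DataFrame
    daily_energy: pd.DataFrame
    daily_metrics: pd.DataFrame
    window_speed: pd.DataFrame
    window_straightness: pd.DataFrame
    contrasts: stats.ContrastResults
    counts: dict


def attach_states(tracks, decoded: pd.DataFrame) -> None:
    """Expand decoded 10 s bin states back to every hires second."""
    keyed = {
        key: grp
        for key, grp in decoded.groupby(["individual", "date", "block"], sort=False)
    }
    for track in tracks:
        if track.hires.empty:
            track.hires["state"] = pd.Series(dtype=int)
            continue
        state_col = np.zeros(len(track.hires), dtype=int)
        offset = 0
        for blk in track.blocks():
            key = (track.individual, track.date, int(blk["block"].iloc[0]))
            n = len(blk)
            if key in keyed:
                bin_states = keyed[key].sort_values("bin")["state"].to_numpy()
                state_col[offset : offset + n] = states.expand_states_to_seconds(
                    bin_states, blk
                )
            offset += n
        track.hires["state"] = state_col


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline and persist stage outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    # --- stage: input data -------------------------------------------------
    if config.fixes_path is None:
        dem = simulate.simulate_terrain(config.sim.seed, 200, 200, 30.0, 60.0)
        fixes, truths, manifest = simulate.simulate_cohort(config.sim, dem)
        simulate.write_manifest(manifest, out / "manifest.txt")
        trackio.write_dem(dem, out / "dem.asc")
        trackio.write_fixes(fixes, out / "fixes.csv")
    else:
        fixes = trackio.read_fixes(config.fixes_path)
        dem = (
            trackio.read_dem(config.dem_path)
            if config.dem_path
            else simulate.simulate_terrain(config.seed, 200, 200, 30.0, 60.0)
        )
    counts["fixes"] = len(fixes)

    # --- stage: preprocess -------------------------------------------------
    tracks = preprocess.split_cohort(fixes, day_start_clock=config.sim.day_start)
    for track in tracks:
        preprocess.smooth_speeds(track)
    counts["days"] = len(tracks)

    # --- stage: day classification -----------------------------------------
    classifications = daytype.classification_table(
        daytype.classify_day(
            t,
            roost_threshold=config.roost_threshold,
            roost_threshold_turn=config.roost_threshold_turn,
            straightness_threshold=config.straightness_threshold,
        )
        for t in tracks
    )
    classifications.to_csv(out / "classifications.csv", index=False)
    # retain: large-displacement days of the large-movement contexts; all
    # normal-context days form the matched normal pool (the synthetic design
    # already matches day counts per individual)
    keyed = classifications.set_index(["individual", "date"])["label"]

    def _keep(track) -> bool:
        if track.context == "group-normal":
            return True
        try:
            return keyed.loc[(track.individual, track.date)] == "large"
        except KeyError:
            return False

    analysis_tracks = [t for t in tracks if _keep(t)]
    counts["days_retained"] = len(analysis_tracks)
    counts["days_excluded_classification"] = len(tracks) - len(analysis_tracks)

    # --- stage: behavioural states -----------------------------------------
    bins = states.bin_cohort(analysis_tracks)
    counts["bins_10s"] = len(bins)
    model = states.ContextHMM(bins)
    hmm = model.fit(seed=config.seed, n_restarts=config.hmm_restarts)
    decoded = model.decode(hmm)
    decoded.to_csv(out / "decoded_bins.csv", index=False)
    with open(out / "hmm_params.txt", "w") as fh:
        for key, value in hmm.to_flat().items():
            fh.write(f"{key}={value!r}\n")
    attach_states(analysis_tracks, decoded)

    # --- stage: energetics -------------------------------------------------
    energetics.compute_slope_aspect(dem)
    costed_tracks = []
    for track in analysis_tracks:
        if track.hires.empty or "state" not in track.hires.columns:
            continue
        parts = []
        for blk in track.blocks():
            if (blk["state"] == 0).all():  # block too short to decode
                blk = blk.assign(band=0, cost=np.nan)
            else:
                blk = energetics.track_costs(blk, dem, config.cost_params)
            parts.append(blk)
        track.hires = pd.concat(parts) if parts else track.hires
        costed_tracks.append(track)
    counts["costed_days"] = len(costed_tracks)

    # --- stage: cost of transport ------------------------------------------
    segments = []
    for track in costed_tracks:
        for blk in track.blocks():
            if blk["cost"].isna().all():
                continue
            for kind in ("net", "cumulative"):
                segments.extend(
                    cot_mod.segment_block(
                        blk,
                        kind,
                        threshold=config.segment_metres,
                        individual=track.individual,
                        date=track.date,
                        context=track.context,
                    )
                )
    seg_table = cot_mod.segment_table(segments)
    if len(seg_table):
        seg_table["hour_bin"] = seg_table["start_t"] // 3600
    seg_table.to_csv(out / "segments.csv", index=False)
    counts["segments_net"] = int((seg_table["kind"] == "net").sum())
    counts["segments_cumulative"] = int((seg_table["kind"] == "cumulative").sum())

    denergy = cot_mod.daily_energy_table(
        cot_mod.daily_energy(t, min_hires_seconds=config.min_hires_seconds)
        for t in costed_tracks
    )
    denergy.to_csv(out / "daily_energy.csv", index=False)
    counts["daily_energy_days"] = len(denergy)

    # --- stage: movement metrics -------------------------------------------
    dmetrics = metrics.daily_metrics(analysis_tracks)
    dmetrics.to_csv(out / "daily_metrics.csv", index=False)
    speed_frames = [
        f
        for f in (
            metrics.window_speed(t, config.window_length, config.speed_coverage)
            for t in costed_tracks
        )
        if len(f)
    ]
    straight_frames = [
        f
        for f in (
            metrics.window_straightness(
                t, config.window_length, config.straightness_coverage
            )
            for t in costed_tracks
        )
        if len(f)
    ]
    wspeed = pd.concat(speed_frames, ignore_index=True)
    wstraight = pd.concat(straight_frames, ignore_index=True)
    wspeed.to_csv(out / "window_speed.csv", index=False)
    wstraight.to_csv(out / "window_straightness.csv", index=False)
    counts["speed_windows"] = len(wspeed)
    counts["straightness_windows"] = len(wstraight)

    # --- stage: contrasts --------------------------------------------------
    results: list[stats.ContrastResult] = []
    results += list(
        stats.fit_context_lmm(
            dmetrics, response="track_length", log_transform=True,
            random=("individual",),
        )
    )
    results += list(
        stats.fit_straightness_beta(
            dmetrics, response="straightness", random=("individual",)
        )
    )
    results += list(
        stats.fit_context_lmm(
            wspeed, response="value", log_transform=True,
            random=("individual", "hour_bin"),
        )
    )
    beta_fine = stats.fit_straightness_beta(
        wstraight, response="value", random=("individual", "hour_bin")
    )
    for r in beta_fine:
        r.response = "straightness (5 min windows)"
    results += list(beta_fine)
    for kind in ("net", "cumulative"):
        sub = seg_table[seg_table["kind"] == kind]
        cres = stats.fit_context_lmm(
            sub, response="cot", log_transform=False,
            random=("individual", "hour_bin"),
        )
        for r in cres:
            r.response = f"cot ({kind})"
        results += list(cres)
    eres = stats.fit_context_lmm(
        denergy, response="expenditure", log_transform=False,
        random=("individual",),
    )
    for r in eres:
        r.response = "daily energy"
    results += list(eres)

    contrasts = stats.ContrastResults(results)
    stats.report(
        contrasts, csv_path=out / "contrasts.csv", json_path=out / "contrasts.json"
    )
    (out / "summary.txt").write_text(
        hmm.summary() + "\n\n" + contrasts.summary() + "\n"
    )
    with open(out / "run_log.json", "w") as fh:
        json.dump(counts, fh, indent=1)

    return RunResult(
        tracks=costed_tracks,
        classifications=classifications,
        bins=bins,
        hmm=hmm,
        segments=seg_table,
        daily_energy=denergy,
        daily_metrics=dmetrics,
        window_speed=wspeed,
        window_straightness=wstraight,
        contrasts=contrasts,
        counts=counts,
    )
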