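"""Synthetic terrain, day and cohort generation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from groupcot import energetics, simulate
from groupcot.simulate import SimConfig, simulate_day, simulate_terrain


def _cfg(**kwargs):
    return dataclasses.replace(SimConfig(seed=0), **kwargs)


def _single_state_cfg(state, turn_sd=0.0, **kwargs):
    """Config whose latent chain never leaves `state` (0-based)."""
    P = np.full((4, 4), 1e-13)
    P[:, state] = 1.0 - 3e-13
    mats = {c: P.copy() for c in simulate.CONTEXTS}
    sds = [0.0, 0.0, 0.0, 0.0]
    sds[state] = turn_sd
    return _cfg(
        transition_matrices=mats,
        state_turn_sds=tuple(sds),
        gps_noise_sd=0.0,
        context_bias_gains={c: 0.0 for c in simulate.CONTEXTS},
        **kwargs,
    )


class TestTerrain:
    def test_deterministic(self):
        a = simulate_terrain(5, 40, 50, 30.0, 25.0)
        b = simulate_terrain(5, 40, 50, 30.0, 25.0)
        np.testing.assert_array_equal(a.elevation, b.elevation)
        c = simulate_terrain(6, 40, 50, 30.0, 25.0)
        assert not np.array_equal(a.elevation, c.elevation)

    def test_zero_relief_flat(self):
        dem = simulate_terrain(1, 30, 30, 30.0, 0.0)
        assert np.all(dem.elevation == 0.0)
        energetics.compute_slope_aspect(dem)
        assert np.all(dem.slope == 0.0)

    def test_relief_and_slope_bound(self):
        dem = simulate_terrain(2, 100, 100, 30.0, 30.0)
        assert np.ptp(dem.elevation) == pytest.approx(30.0, rel=1e-9)
        energetics.compute_slope_aspect(dem)
        assert np.all(dem.slope < 45.0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            simulate_terrain(0, 2, 10, 30.0, 10.0)
        with pytest.raises(ValueError):
            simulate_terrain(0, 10, 10, -1.0, 10.0)
        with pytest.raises(ValueError):
            simulate_terrain(0, 10, 10, 30.0, -5.0)


class TestConfigValidation:
    def test_bad_transition_matrix_rejected(self):
        mats = {c: np.eye(4) for c in simulate.CONTEXTS}
        mats["group-large"] = np.eye(4) * 1.01
        with pytest.raises(ValueError):
            _cfg(transition_matrices=mats)

    def test_reference_multiplier_must_be_one(self):
        with pytest.raises(ValueError):
            _cfg(
                context_speed_multipliers={
                    "group-normal": 0.9,
                    "group-large": 1.1,
                    "lone-disperser": 1.2,
                }
            )

    def test_speed_means_strictly_increasing(self):
        with pytest.raises(ValueError):
            _cfg(state_speed_means=(0.0, 0.5, 0.5, 1.0))


class TestSimulateDay:
    def test_unknown_context_rejected(self):
        dem = simulate_terrain(0, 10, 10, 30.0, 0.0)
        with pytest.raises(ValueError):
            simulate_day(SimConfig(seed=0), "flock", dem, seed=0)

    def test_stationary_chain_zero_displacement(self):
        cfg = _single_state_cfg(0)
        dem = simulate_terrain(0, 10, 10, 30.0, 0.0)
        fixes, truth = simulate_day(cfg, "group-large", dem, seed=3)
        assert np.ptp(truth.x) == 0.0 and np.ptp(truth.y) == 0.0
        assert np.ptp(fixes["x"]) == 0.0  # gps noise disabled

    def test_straight_line_limit(self):
        cfg = _single_state_cfg(3, turn_sd=0.0)
        dem = simulate_terrain(0, 10, 10, 30.0, 0.0)
        _, truth = simulate_day(cfg, "group-large", dem, seed=4)
        net = np.hypot(truth.x[-1] - truth.x[0], truth.y[-1] - truth.y[0])
        cumulative = np.hypot(np.diff(truth.x), np.diff(truth.y)).sum()
        assert net == pytest.approx(cumulative, rel=1e-9)

    def test_day_spans_configured_window(self):
        cfg = SimConfig(seed=0)
        dem = simulate_terrain(0, 10, 10, 30.0, 0.0)
        fixes, truth = simulate_day(cfg, "group-normal", dem, seed=5)
        assert len(truth.states) == 46800
        start = fixes["time"].min()
        end = fixes["time"].max()
        assert start.strftime("%H:%M:%S") == "06:00:00"
        assert end < pd.Timestamp("2020-01-01 19:00:00")

    def test_burst_regime_structure(self):
        cfg = SimConfig(seed=0)
        dem = simulate_terrain(0, 10, 10, 30.0, 0.0)
        fixes, _ = simulate_day(cfg, "group-normal", dem, seed=6, regime="burst")
        assert len(fixes) == 156 * cfg.burst_length
        sec = (
            (fixes["time"] - pd.Timestamp("2020-01-01 06:00:00"))
            .dt.total_seconds()
            .astype(int)
        )
        per_burst = sec.groupby(sec // cfg.burst_interval).size()
        assert (per_burst == cfg.burst_length).all()

    def test_transition_frequencies_follow_matrix(self):
        # the 1 Hz chain subsampled at the 10 s bin scale follows the
        # configured matrix; check empirical frequencies on a long day
        cfg = SimConfig(seed=0)
        dem = simulate_terrain(0, 10, 10, 30.0, 0.0)
        chains = []
        for i in range(4):
            _, truth = simulate_day(cfg, "group-large", dem, seed=100 + i)
            chains.append(truth.states[::10])
        chain = np.concatenate(chains)
        P = cfg.transition_matrices["group-large"]
        counts = np.zeros((4, 4))
        np.add.at(counts, (chain[:-1] - 1, chain[1:] - 1), 1.0)
        freq = counts / counts.sum(axis=1, keepdims=True)
        assert np.abs(freq - P).max() < 0.03


class TestCohort:
    def test_ground_truth_speed_scales_with_multiplier(self):
        # with noise off and composition held fixed, mean moving speed
        # scales by the imposed multiplier within 1%
        base = _single_state_cfg(3)
        fast = dataclasses.replace(
            base,
            context_speed_multipliers={
                "group-normal": 0.912,
                "group-large": 1.0,
                "lone-disperser": 1.27,
            },
        )
        dem = simulate_terrain(0, 10, 10, 30.0, 0.0)
        speeds = {}
        for ctx in ("group-large", "lone-disperser"):
            steps = []
            for i in range(3):
                _, truth = simulate_day(fast, ctx, dem, seed=50 + i)
                d = np.hypot(np.diff(truth.x), np.diff(truth.y))
                steps.append(d[truth.states[:-1] >= 2])
            speeds[ctx] = np.concatenate(steps).mean()
        ratio = speeds["lone-disperser"] / speeds["group-large"]
        assert ratio == pytest.approx(1.27, rel=0.01)

    def test_cohort_reproducible(self, tmp_path):
        cfg = SimConfig(seed=9, n_individuals_per_context=1, n_days_per_individual=1)
        dem = simulate_terrain(9, 20, 20, 30.0, 10.0)
        fixes_a, truths_a, man_a = simulate.simulate_cohort(cfg, dem)
        fixes_b, truths_b, man_b = simulate.simulate_cohort(cfg, dem)
        pd.testing.assert_frame_equal(fixes_a, fixes_b)
        assert man_a == man_b
        np.testing.assert_array_equal(truths_a[0].states, truths_b[0].states)
        path = tmp_path / "manifest.txt"
        simulate.write_manifest(man_a, path)
        back = simulate.read_manifest(path)
        assert back["p44_lone_disperser"] == pytest.approx(0.752)

    def test_day_length_bound(self):
        cfg = SimConfig(
            seed=3, n_individuals_per_context=1, n_days_per_individual=1,
            hires_fraction=1.0,
        )
        dem = simulate_terrain(3, 20, 20, 30.0, 10.0)
        fixes, truths, _ = simulate.simulate_cohort(cfg, dem)
        per_day = fixes.groupby([fixes["individual"], fixes["time"].dt.date]).size()
        assert (per_day <= 46800).all()

    def test_matrix_root_reconstructs_bin_scale(self):
        cfg = SimConfig(seed=0)
        for ctx in simulate.CONTEXTS:
            root = cfg.second_scale_matrix(ctx)
            assert np.all(root >= 0.0)
            np.testing.assert_allclose(root.sum(axis=1), 1.0, atol=1e-12)
            np.testing.assert_allclose(
                np.linalg.matrix_power(root, 10),
                cfg.transition_matrices[ctx],
                atol=1e-8,
            )
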