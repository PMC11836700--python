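"""10 s binning, HMM fitting, decoding and state expansion."""

import numpy as np
import pandas as pd
import pytest

from groupcot import states
from groupcot.states import ContextHMM, bin_10s, expand_states_to_seconds

# canonical well-separated test model (log-scale emissions)
MEANS = np.array([[0.3, 2.3], [1.1, 1.5], [1.9, 0.6], [2.5, -0.4]])
VARS = np.full((4, 2), 0.09)
TRANS = {
    "group-large": np.array(
        [
            [0.850, 0.080, 0.040, 0.030],
            [0.060, 0.750, 0.130, 0.060],
            [0.040, 0.100, 0.700, 0.160],
            [0.050, 0.040, 0.258, 0.652],
        ]
    ),
    "lone-disperser": np.array(
        [
            [0.780, 0.080, 0.060, 0.080],
            [0.050, 0.700, 0.150, 0.100],
            [0.030, 0.080, 0.670, 0.220],
            [0.030, 0.035, 0.183, 0.752],
        ]
    ),
}


def _block(x, y):
    return pd.DataFrame({"x": np.asarray(x, float), "y": np.asarray(y, float)})


class TestBin10s:
    def test_floor_division(self):
        n = 95
        bins = bin_10s(_block(np.arange(n), np.zeros(n)))
        assert len(bins) == 9

    def test_straight_track(self):
        n = 41
        bins = bin_10s(_block(np.arange(n, dtype=float), np.zeros(n)))
        np.testing.assert_allclose(bins["distance"], 10.0)
        np.testing.assert_allclose(bins["turn_sum"], 0.0)

    def test_square_wave_turns(self):
        # alternate east/north steps: a 90 degree turn at every fix
        n = 41
        moves = np.tile([[1.0, 0.0], [0.0, 1.0]], (n // 2 + 1, 1))[: n - 1]
        xy = np.vstack([[0.0, 0.0], np.cumsum(moves, axis=0)])
        bins = bin_10s(_block(xy[:, 0], xy[:, 1]))
        np.testing.assert_allclose(bins["distance"], 10.0)
        np.testing.assert_allclose(bins["turn_sum"], 9 * np.pi / 2, rtol=1e-12)

    def test_zero_length_steps_contribute_no_turn(self):
        x = np.array([0.0, 1.0, 1.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        bins = bin_10s(_block(x, np.zeros(len(x))))
        assert bins["turn_sum"].iloc[0] == 0.0

    def test_too_short_block_empty(self):
        assert bin_10s(_block(np.arange(10), np.zeros(10))).empty


class TestExpand:
    def test_single_bin(self):
        block = _block(np.arange(11), np.zeros(11))
        out = expand_states_to_seconds([3], block)
        assert (out == 3).all() and len(out) == 11

    def test_remainder_inherits_last_bin(self):
        block = _block(np.arange(95), np.zeros(95))
        bin_states = [1, 2, 3, 4, 1, 2, 3, 4, 2]
        out = expand_states_to_seconds(bin_states, block)
        assert (out[90:] == 2).all()
        assert (out[:10] == 1).all()
        assert (out[40:50] == 1).all()

    def test_moving_mask(self):
        assert list(states.moving_mask([1, 2, 3, 4])) == [False, True, True, True]


def _sim(n_bins=300, n_seqs=4, seed=0, trans=None):
    return states.simulate_bins(
        MEANS, VARS, trans or TRANS, n_bins, n_seqs, seed=seed
    )


class TestFit:
    def test_recovers_well_separated_model(self):
        # widely separated emissions (~8 sd between neighbouring states)
        tight = np.full((4, 2), 0.01)
        bins, truth = states.simulate_bins(MEANS, tight, TRANS, 400, 10, seed=1)
        model = ContextHMM(bins)
        res = model.fit(seed=0, n_restarts=4, short_iter=10)
        assert res.converged
        np.testing.assert_allclose(res.means, MEANS, atol=0.05)
        decoded = model.decode(res)
        accuracy = (decoded["state"].to_numpy() == truth).mean()
        assert accuracy > 0.99

    def test_likelihood_nondecreasing(self):
        bins, _ = _sim(n_bins=100, n_seqs=3, seed=2)
        model = ContextHMM(bins)
        start = model._quantile_start()
        means, variances, trans, init = start
        lls = []
        for _ in range(8):
            gamma, A, ll = model._e_step(means, variances, trans, init)
            lls.append(ll)
            means, variances, init, _ = model._m_step(gamma)
            trans = model._normalise_trans(A)
        assert all(b >= a - 1e-8 for a, b in zip(lls, lls[1:]))

    def test_degenerate_single_state_flagged(self):
        rng = np.random.default_rng(0)
        bins = pd.DataFrame(
            {
                "bin": np.arange(300),
                "distance": np.exp(rng.standard_normal(300) * 0.1 + 1.0),
                "turn_sum": np.exp(rng.standard_normal(300) * 0.1),
                "individual": "a",
                "date": "2020-01-01",
                "block": 0,
                "context": "group-large",
            }
        )
        res = ContextHMM(bins).fit(seed=0, n_restarts=2, short_iter=5, max_iter=30)
        assert isinstance(res.empty_states, list)  # no crash; flag present

    def test_relabelling_orders_states_by_distance(self):
        bins, _ = _sim(n_bins=200, n_seqs=6, seed=3)
        res = ContextHMM(bins).fit(seed=7, n_restarts=3, short_iter=10)
        assert np.all(np.diff(res.means[:, 0]) > 0)

    def test_seed_determinism(self):
        bins, _ = _sim(n_bins=150, n_seqs=4, seed=4)
        a = ContextHMM(bins).fit(seed=5, n_restarts=3, short_iter=8)
        b = ContextHMM(bins).fit(seed=5, n_restarts=3, short_iter=8)
        np.testing.assert_array_equal(a.means, b.means)

    def test_single_context_matches_hmmlearn(self):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        trans = {"group-large": TRANS["group-large"]}
        bins, _ = _sim(n_bins=500, n_seqs=6, seed=6, trans=trans)
        res = ContextHMM(bins).fit(seed=0, n_restarts=4, short_iter=10)

        obs = np.column_stack(
            [
                np.log(bins["distance"] + states.DIST_OFFSET),
                np.log(bins["turn_sum"] + states.TURN_OFFSET),
            ]
        )
        lengths = bins.groupby(["individual", "date", "block"]).size().to_numpy()
        ref = hmmlearn.GaussianHMM(
            n_components=4, covariance_type="diag", n_iter=200, tol=1e-4,
            random_state=0,
        )
        ref.fit(obs, lengths)
        order = np.argsort(ref.means_[:, 0])
        np.testing.assert_allclose(ref.means_[order], res.means, atol=0.05)
        np.testing.assert_allclose(
            ref.transmat_[order][:, order],
            res.transitions["group-large"],
            atol=0.05,
        )


class TestDecode:
    def test_posteriors_sum_to_one(self):
        bins, _ = _sim(n_bins=100, n_seqs=3, seed=8)
        model = ContextHMM(bins)
        res = model.fit(seed=0, n_restarts=2, short_iter=8)
        decoded = model.decode(res)
        post = decoded[[f"post_{k}" for k in range(1, 5)]].to_numpy()
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_uniform_emissions_give_stationary_posterior(self):
        from groupcot.simulate import stationary_distribution

        rng = np.random.default_rng(9)
        n = 2000
        bins = pd.DataFrame(
            {
                "bin": np.arange(n),
                "distance": np.exp(rng.standard_normal(n)),
                "turn_sum": np.exp(rng.standard_normal(n)),
                "individual": "a",
                "date": "2020-01-01",
                "block": 0,
                "context": "group-large",
            }
        )
        model = ContextHMM(bins)
        P = TRANS["group-large"]
        pi = stationary_distribution(P)
        res = states.HmmResults(
            means=np.zeros((4, 2)),  # identical emissions for all states
            variances=np.ones((4, 2)),
            transitions={"group-large": P},
            initial=pi,
            log_likelihood=0.0,
            n_obs=n,
            converged=True,
            n_iter=0,
        )
        decoded = model.decode(res)
        post = decoded[[f"post_{k}" for k in range(1, 5)]].to_numpy()
        np.testing.assert_allclose(post.mean(axis=0), pi, atol=1e-6)

    def test_unseen_context_rejected(self):
        bins, _ = _sim(n_bins=50, n_seqs=2, seed=10)
        model = ContextHMM(bins)
        res = model.fit(seed=0, n_restarts=2, short_iter=5)
        other = bins.copy()
        other["context"] = "unknown-context"
        with pytest.raises(ValueError):
            states.decode_states(res, other)
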