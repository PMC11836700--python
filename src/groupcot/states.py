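"""Behavioural-state decoding with a four-state hidden Markov model.

High-resolution (1 Hz) data are summarised into 10 s bins — total distance
moved and summed absolute turning angles — and a single HMM is fitted across
the whole high-resolution dataset.  The four states map onto stationary
(state 1), slow tortuous foraging (2), medium-speed walking (3) and fast
directed travel (4); a dedicated stationary state is required because
metabolic cost is modelled differently for non-moving seconds.  The movement
context (normal group ranging / large group displacement / lone dispersal)
enters as a categorical covariate on the state transition matrix — one
4x4 matrix per context, with large group displacements as the reference
category — while emission distributions are shared across contexts.

Emissions are diagonal Gaussians on ``log(distance + 0.1 m)`` and
``log(turn_sum + 0.01 rad)``, a conventional choice for left-truncated,
long-tailed step-length distributions.  Fitting is by EM (Baum-Welch with
context-specific transition counts); states are relabelled by ascending mean
distance so results do not depend on initialisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_STATES = 4
BIN_SECONDS = 10
DIST_OFFSET = 0.1
TURN_OFFSET = 0.01
_VAR_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


def bin_10s(block: pd.DataFrame) -> pd.DataFrame:
    """Summarise one high-resolution block into consecutive 10 s bins.

    Bin *k* covers fixes ``10k .. 10k+10``: its distance is the summed step
    lengths and its ``turn_sum`` the summed absolute turning angles at the
    bin's nine interior fixes (the angle between each fix's incoming and
    outgoing step; zero-length steps contribute 0).  A trailing remainder
    shorter than 10 s is dropped.
    """
    x = block["x"].to_numpy(dtype=float)
    y = block["y"].to_numpy(dtype=float)
    n_bins = (len(x) - 1) // BIN_SECONDS
    if n_bins <= 0:
        return pd.DataFrame(columns=["bin", "distance", "turn_sum"])
    dx = np.diff(x)
    dy = np.diff(y)
    steps = np.hypot(dx, dy)
    headings = np.arctan2(dx, dy)
    turns = np.abs(_wrap_angle(np.diff(headings)))
    # undefined angles at zero-length steps contribute nothing
    turns[(steps[:-1] == 0) | (steps[1:] == 0)] = 0.0

    used = n_bins * BIN_SECONDS
    distance = steps[:used].reshape(n_bins, BIN_SECONDS).sum(axis=1)
    # the turning angle at fix j is turns[j - 1]; bin k's interior fixes are
    # 10k+1 .. 10k+9, i.e. turns[10k] .. turns[10k+8]
    turn_sum = np.zeros(n_bins)
    base = np.arange(n_bins) * BIN_SECONDS
    for off in range(BIN_SECONDS - 1):
        idx = base + off
        valid = idx < len(turns)
        turn_sum[valid] += turns[idx[valid]]
    return pd.DataFrame(
        {"bin": np.arange(n_bins), "distance": distance, "turn_sum": turn_sum}
    )


def _wrap_angle(a):
    return (np.asarray(a) + np.pi) % (2.0 * np.pi) - np.pi


def bin_cohort(tracks) -> pd.DataFrame:
    """10 s bins for every block of every day-track, tagged with context."""
    frames = []
    for track in tracks:
        for blk in track.blocks():
            bins = bin_10s(blk)
            if bins.empty:
                continue
            bins["individual"] = track.individual
            bins["date"] = track.date
            bins["block"] = int(blk["block"].iloc[0])
            bins["context"] = track.context
            frames.append(bins)
    if not frames:
        return pd.DataFrame(
            columns=[
                "bin", "distance", "turn_sum",
                "individual", "date", "block", "context",
            ]
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


@dataclass
class HmmResults:
    """Fitted parameters and diagnostics of the context HMM."""

    means: np.ndarray  # (K, 2) emission means on the log scale
    variances: np.ndarray  # (K, 2)
    transitions: dict  # context -> (K, K) row-stochastic matrix
    initial: np.ndarray  # (K,)
    log_likelihood: float
    n_obs: int
    converged: bool
    n_iter: int
    empty_states: list = field(default_factory=list)

    @property
    def mean_distance(self) -> np.ndarray:
        """Per-state mean 10 s distance (metres, back-transformed)."""
        return np.exp(self.means[:, 0] + self.variances[:, 0] / 2.0) - DIST_OFFSET

    def summary(self) -> str:
        lines = [
            "Context HMM (4 states, shared emissions, per-context transitions)",
            f"  observations: {self.n_obs}   log-likelihood: {self.log_likelihood:.1f}",
            f"  converged: {self.converged} after {self.n_iter} iterations",
            "  state   mean 10s distance (m)   mean turn sum (rad)",
        ]
        mean_turn = np.exp(self.means[:, 1] + self.variances[:, 1] / 2.0) - TURN_OFFSET
        for k in range(len(self.means)):
            lines.append(
                f"    {k + 1}    {self.mean_distance[k]:14.2f}    {mean_turn[k]:14.2f}"
            )
        for ctx, P in self.transitions.items():
            lines.append(f"  transition matrix [{ctx}]:")
            for row in P:
                lines.append("    " + "  ".join(f"{p:.3f}" for p in row))
        if self.empty_states:
            lines.append(f"  WARNING: empty states {self.empty_states}")
        return "\n".join(lines)

    def to_flat(self) -> dict:
        out = {"log_likelihood": self.log_likelihood, "n_obs": self.n_obs}
        for k in range(len(self.means)):
            out[f"mean_logdist_{k + 1}"] = self.means[k, 0]
            out[f"mean_logturn_{k + 1}"] = self.means[k, 1]
            out[f"var_logdist_{k + 1}"] = self.variances[k, 0]
            out[f"var_logturn_{k + 1}"] = self.variances[k, 1]
        for ctx, P in self.transitions.items():
            key = ctx.replace("-", "_")
            for i in range(P.shape[0]):
                for j in range(P.shape[1]):
                    out[f"p_{key}_{i + 1}{j + 1}"] = P[i, j]
        return out


class ContextHMM:
    """Four-state HMM with a categorical covariate on the transitions.

    Parameters
    ----------
    bins : DataFrame
        10 s summaries with columns ``distance``, ``turn_sum``, ``context``
        and sequence keys ``individual``, ``date``, ``block``.
    """

    def __init__(self, bins: pd.DataFrame, n_states: int = N_STATES):
        if n_states != N_STATES:
            raise ValueError("the behavioural model is fixed at four states")
        self.bins = bins.reset_index(drop=True)
        self.contexts = sorted(self.bins["context"].unique())
        self._prepare()

    def _prepare(self) -> None:
        obs = np.column_stack(
            [
                np.log(self.bins["distance"].to_numpy(dtype=float) + DIST_OFFSET),
                np.log(self.bins["turn_sum"].to_numpy(dtype=float) + TURN_OFFSET),
            ]
        )
        groups = self.bins.groupby(["individual", "date", "block"], sort=True).indices
        seqs = [(np.sort(groups[key]), key) for key in sorted(groups)]
        self._obs = obs
        n_seq = len(seqs)
        t_max = max(len(idx) for idx, _ in seqs)
        self._pad_obs = np.zeros((n_seq, t_max, 2))
        self._mask = np.zeros((n_seq, t_max), dtype=bool)
        self._ctx_idx = np.zeros(n_seq, dtype=int)
        self._flat_idx = np.full((n_seq, t_max), 0, dtype=int)
        for s, (idx, _key) in enumerate(seqs):
            self._pad_obs[s, : len(idx)] = obs[idx]
            self._mask[s, : len(idx)] = True
            self._ctx_idx[s] = self.contexts.index(self.bins["context"].iloc[idx[0]])
            self._flat_idx[s, : len(idx)] = idx

    # -- EM internals ------------------------------------------------------

    def _emission_probs(self, means, variances):
        """Scaled densities b (S, T, K) and the per-cell max log density
        that was divided out (S, T); masked cells are neutral."""
        diff = self._pad_obs[:, :, None, :] - means[None, None, :, :]
        logp = -0.5 * (
            np.sum(diff**2 / variances[None, None], axis=-1)
            + np.sum(np.log(2.0 * np.pi * variances), axis=-1)[None, None, :]
        )
        logp_max = logp.max(axis=-1)
        b = np.exp(logp - logp_max[:, :, None])
        b[~self._mask] = 1.0
        logp_max = np.where(self._mask, logp_max, 0.0)
        return b, logp_max

    def _forward_backward(self, b, trans, init):
        S, T, K = b.shape
        P_seq = trans[self._ctx_idx]  # (S, K, K)
        alpha = np.zeros((S, T, K))
        c = np.ones((S, T))
        a = init[None, :] * b[:, 0, :]
        c[:, 0] = a.sum(axis=1)
        alpha[:, 0] = a / c[:, 0, None]
        for t in range(1, T):
            a = np.einsum("sk,skj->sj", alpha[:, t - 1], P_seq) * b[:, t, :]
            live = self._mask[:, t]
            tot = a.sum(axis=1)
            a = np.where(live[:, None], a, alpha[:, t - 1])
            c[:, t] = np.where(live, tot, 1.0)
            alpha[:, t] = a / c[:, t, None]
        beta = np.zeros((S, T, K))
        beta[:, T - 1] = 1.0
        for t in range(T - 2, -1, -1):
            nxt = self._mask[:, t + 1]
            bb = np.einsum(
                "skj,sj->sk", P_seq, beta[:, t + 1] * b[:, t + 1, :]
            ) / c[:, t + 1, None]
            beta[:, t] = np.where(nxt[:, None], bb, beta[:, t + 1])
        gamma = alpha * beta
        gamma /= gamma.sum(axis=-1, keepdims=True)
        return alpha, beta, gamma, c

    def _e_step(self, means, variances, trans, init):
        b, logp_max = self._emission_probs(means, variances)
        alpha, beta, gamma, c = self._forward_backward(b, trans, init)
        ll = float(np.log(c[self._mask]).sum() + logp_max[self._mask].sum())
        S, T, K = b.shape
        P_seq = trans[self._ctx_idx]
        A = np.zeros((len(self.contexts), K, K))
        for t in range(T - 1):
            live = self._mask[:, t + 1]
            if not live.any():
                continue
            xi = (
                alpha[live, t, :, None]
                * P_seq[live]
                * (beta[live, t + 1] * b[live, t + 1, :])[:, None, :]
                / c[live, t + 1, None, None]
            )
            ctx_live = self._ctx_idx[live]
            for ci in range(len(self.contexts)):
                sel = ctx_live == ci
                if sel.any():
                    A[ci] += xi[sel].sum(axis=0)
        return gamma, A, ll

    def _m_step(self, gamma):
        w = gamma[self._mask]  # (N, K)
        obs = self._pad_obs[self._mask]  # (N, 2)
        tot = w.sum(axis=0)
        empty = tot < 1e-8
        tot_safe = np.where(empty, 1.0, tot)
        means = (w.T @ obs) / tot_safe[:, None]
        var = w.T @ (obs**2) / tot_safe[:, None] - means**2
        variances = np.maximum(var, _VAR_FLOOR)
        init = gamma[:, 0, :].mean(axis=0)
        init /= init.sum()
        return means, variances, init, list(np.where(empty)[0])

    @staticmethod
    def _normalise_trans(A):
        A = A + 1e-12
        return A / A.sum(axis=-1, keepdims=True)

    def _run_em(self, means, variances, trans, init, max_iter, tol):
        prev_ll = -np.inf
        ll = -np.inf
        empty: list[int] = []
        for it in range(max_iter):
            gamma, A, ll = self._e_step(means, variances, trans, init)
            if it > 0 and ll - prev_ll < tol * self._obs.shape[0]:
                return means, variances, trans, init, ll, True, it + 1, empty
            prev_ll = ll
            means, variances, init, empty = self._m_step(gamma)
            trans = self._normalise_trans(A)
        return means, variances, trans, init, ll, False, max_iter, empty

    def _uniform_trans(self):
        return np.tile(
            (np.eye(N_STATES) * 4.0 + 1.0) / 8.0, (len(self.contexts), 1, 1)
        )

    def _random_start(self, rng):
        obs = self._obs
        idx = rng.choice(len(obs), size=N_STATES, replace=False)
        means = obs[idx] + rng.standard_normal((N_STATES, 2)) * 0.1
        variances = np.tile(obs.var(axis=0), (N_STATES, 1)) + _VAR_FLOOR
        return means, variances, self._uniform_trans(), np.full(N_STATES, 0.25)

    def _quantile_start(self):
        obs = self._obs
        qs = np.quantile(obs[:, 0], [0.125, 0.375, 0.625, 0.875])
        means = np.column_stack([qs, np.full(N_STATES, obs[:, 1].mean())])
        variances = np.tile(obs.var(axis=0) / N_STATES, (N_STATES, 1)) + _VAR_FLOOR
        return means, variances, self._uniform_trans(), np.full(N_STATES, 0.25)

    def fit(
        self,
        seed: int = 0,
        n_restarts: int = 10,
        max_iter: int = 200,
        short_iter: int = 25,
        tol: float = 1e-6,
    ) -> HmmResults:
        """Fit by EM with multiple restarts.

        One deterministic quantile-based start plus ``n_restarts - 1`` random
        starts each run for ``short_iter`` iterations; the best continues to
        convergence (log-likelihood gain below ``tol`` per observation).
        Non-convergence returns the best iterate with a warning flag.
        """
        rng = np.random.default_rng(seed)
        candidates = [self._quantile_start()] + [
            self._random_start(rng) for _ in range(max(0, n_restarts - 1))
        ]
        best = None
        for start in candidates:
            out = self._run_em(*start, max_iter=short_iter, tol=tol)
            if best is None or out[4] > best[4]:
                best = out
        means, variances, trans, init, ll, conv, n_it, empty = self._run_em(
            best[0], best[1], best[2], best[3], max_iter=max_iter, tol=tol
        )
        if empty:
            logger.warning("HMM fit left states empty: %s", empty)
        if not conv:
            logger.warning("EM did not converge within %d iterations", max_iter)
        order = np.argsort(means[:, 0])
        means = means[order]
        variances = variances[order]
        init = init[order]
        trans = trans[:, order][:, :, order]
        return HmmResults(
            means=means,
            variances=variances,
            transitions={ctx: trans[i] for i, ctx in enumerate(self.contexts)},
            initial=init,
            log_likelihood=ll,
            n_obs=self._obs.shape[0],
            converged=conv,
            n_iter=n_it,
            empty_states=[int(e) for e in empty],
        )

    # -- decoding ----------------------------------------------------------

    def decode(self, results: HmmResults) -> pd.DataFrame:
        """Posterior-decode the model's bins under fitted parameters.

        Returns the bin table with added ``state`` (most probable marginal
        state, 1..4) and ``post_1`` .. ``post_4`` columns.
        """
        for ctx in self.contexts:
            if ctx not in results.transitions:
                raise ValueError(f"context not in fitted model: {ctx}")
        trans = np.stack([results.transitions[c] for c in self.contexts])
        b, _ = self._emission_probs(results.means, results.variances)
        _, _, gamma, _ = self._forward_backward(b, trans, results.initial)
        post = np.zeros((self._obs.shape[0], N_STATES))
        post[self._flat_idx[self._mask]] = gamma[self._mask]
        out = self.bins.copy()
        out["state"] = post.argmax(axis=1) + 1
        for k in range(N_STATES):
            out[f"post_{k + 1}"] = post[:, k]
        return out


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def fit_hmm(bins: pd.DataFrame, seed: int = 0, **kwargs) -> HmmResults:
    """Fit the four-state context HMM to a cohort bin table."""
    return ContextHMM(bins).fit(seed=seed, **kwargs)


def decode_states(results: HmmResults, bins: pd.DataFrame) -> pd.DataFrame:
    """Posterior-decode a bin table under a fitted model."""
    return ContextHMM(bins).decode(results)


def expand_states_to_seconds(bin_states, block: pd.DataFrame) -> np.ndarray:
    """Assign every second (fix) of a block its 10 s bin's state.

    Fix ``j`` belongs to bin ``j // 10``; fixes in the trailing remainder
    inherit the last bin's state.  Birds count as moving in states 2-4.
    """
    bin_states = np.asarray(bin_states, dtype=int)
    n_bins = len(bin_states)
    if n_bins == 0:
        return np.zeros(len(block), dtype=int)
    j = np.arange(len(block))
    return bin_states[np.minimum(j // BIN_SECONDS, n_bins - 1)]


def moving_mask(states) -> np.ndarray:
    """Seconds decoded to states 2-4 count as moving."""
    states = np.asarray(states, dtype=int)
    return states >= 2


def simulate_bins(
    means: np.ndarray,
    variances: np.ndarray,
    transitions: dict,
    n_bins_per_seq: int,
    n_seqs_per_context: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample a bin table directly from HMM parameters (recovery harness).

    Returns the bin table (``distance``/``turn_sum`` back-transformed from
    log-scale Gaussian draws) and the flat array of true states (1..4).
    """
    from .simulate import stationary_distribution

    rng = np.random.default_rng(seed)
    rows = []
    all_states = []
    for ctx, P in transitions.items():
        pi = stationary_distribution(P)
        cum = np.cumsum(P, axis=1)
        for s_i in range(n_seqs_per_context):
            states = np.empty(n_bins_per_seq, dtype=int)
            st = int(np.searchsorted(np.cumsum(pi), rng.random()))
            u = rng.random(n_bins_per_seq)
            for t in range(n_bins_per_seq):
                st = int(np.searchsorted(cum[st], u[t], side="right"))
                states[t] = st
            z = rng.standard_normal((n_bins_per_seq, 2))
            obs = means[states] + z * np.sqrt(variances[states])
            rows.append(
                pd.DataFrame(
                    {
                        "bin": np.arange(n_bins_per_seq),
                        "distance": np.exp(obs[:, 0]) - DIST_OFFSET,
                        "turn_sum": np.exp(obs[:, 1]) - TURN_OFFSET,
                        "individual": f"{ctx}-{s_i:03d}",
                        "date": "2020-01-01",
                        "block": 0,
                        "context": ctx,
                    }
                )
            )
            all_states.append(states + 1)
    return pd.concat(rows, ignore_index=True), np.concatenate(all_states)
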