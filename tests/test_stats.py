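"""Mixed-model contrasts: LMM wrapper and the Laplace beta GLMM."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from groupcot import stats


def _lmm_table(
    n_ind=12, n_obs=20, effects=(0.0, 0.2), ind_sd=0.1, noise_sd=0.3, seed=0,
    with_hour=False,
):
    rng = np.random.default_rng(seed)
    rows = []
    contexts = ["group-large", "group-normal", "lone-disperser"]
    deltas = {"group-large": 0.0, "group-normal": effects[0], "lone-disperser": effects[1]}
    for ctx in contexts:
        for i in range(n_ind):
            b = rng.standard_normal() * ind_sd
            for j in range(n_obs):
                mu = 1.0 + deltas[ctx] + b + rng.standard_normal() * noise_sd
                rows.append(
                    {
                        "individual": f"{ctx}-{i}",
                        "context": ctx,
                        "hour_bin": int(rng.integers(6, 19)),
                        "value": np.exp(mu),
                    }
                )
    return pd.DataFrame(rows)


class TestLmm:
    def test_recovers_imposed_log_effects(self):
        table = _lmm_table(effects=(-0.1, 0.24), seed=1)
        res = stats.fit_context_lmm(table, response="value", log_transform=True)
        by = {r.contrast: r for r in res}
        norm = by["group-normal vs group-large"]
        disp = by["lone-disperser vs group-large"]
        assert norm.ci_low < -0.1 < norm.ci_high
        assert disp.ci_low < 0.24 < disp.ci_high
        assert disp.percent == pytest.approx((np.exp(disp.coef) - 1) * 100)

    def test_zero_variance_matches_ols(self):
        import statsmodels.formula.api as smf

        table = _lmm_table(ind_sd=0.0, n_ind=6, n_obs=10, seed=2)
        table["y"] = np.log(table["value"])
        res = stats.fit_context_lmm(table, response="value", log_transform=True)
        ols = smf.ols(
            "y ~ C(context, Treatment('group-large'))", data=table
        ).fit()
        by = {r.contrast: r for r in res}
        for name, coef in ols.params.items():
            level = stats._contrast_name(name)
            if level is None:
                continue
            got = by[f"{level} vs group-large"]
            assert got.coef == pytest.approx(coef, abs=1e-3)

    def test_crossed_random_intercepts(self):
        table = _lmm_table(seed=3, with_hour=True)
        res = stats.fit_context_lmm(
            table, response="value", random=("individual", "hour_bin")
        )
        r = next(iter(res))
        assert set(r.re_variances) == {"individual", "hour_bin"}

    def test_needs_two_contexts(self):
        table = _lmm_table()
        with pytest.raises(ValueError):
            stats.fit_context_lmm(table[table["context"] == "group-large"])


class TestSqueeze:
    def test_formula(self):
        y = np.concatenate([[1.0], np.full(99, 0.5)])
        out = stats.squeeze_boundaries(y)
        assert out[0] == pytest.approx(0.995)
        assert (out[1:] == 0.5).all()

    def test_zero_boundary(self):
        y = np.concatenate([[0.0], np.full(9, 0.5)])
        assert stats.squeeze_boundaries(y)[0] == pytest.approx(0.05)

    def test_all_boundary_rejected(self):
        with pytest.raises(ValueError):
            stats.squeeze_boundaries(np.ones(5))


def _beta_table(n_ind=10, n_obs=25, effects=(-0.6, 0.0), ind_sd=0.2, phi=30.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    deltas = {"group-large": 0.0, "group-normal": effects[0], "lone-disperser": effects[1]}
    for ctx, delta in deltas.items():
        for i in range(n_ind):
            b = rng.standard_normal() * ind_sd
            mu = expit(0.5 + delta + b)
            y = rng.beta(mu * phi, (1 - mu) * phi, size=n_obs)
            for j, yy in enumerate(y):
                rows.append(
                    {
                        "individual": f"{ctx}-{i}",
                        "context": ctx,
                        "hour_bin": int(rng.integers(6, 19)),
                        "value": yy,
                    }
                )
    return pd.DataFrame(rows)


class TestBetaMixed:
    def test_recovers_imposed_logit_effects(self):
        table = _beta_table(seed=4)
        res = stats.fit_straightness_beta(table, response="value")
        by = {r.contrast: r for r in res}
        norm = by["group-normal vs group-large"]
        assert norm.ci_low < -0.6 < norm.ci_high
        assert norm.coef < 0 and norm.pvalue < 0.01
        null = by["lone-disperser vs group-large"]
        assert null.ci_low < 0.0 < null.ci_high

    def test_zero_variance_matches_betamodel(self):
        from statsmodels.othermod.betareg import BetaModel

        table = _beta_table(ind_sd=0.0, n_ind=6, n_obs=30, seed=5)
        res = stats.fit_straightness_beta(table, response="value")
        y = table["value"].to_numpy()
        levels = ["group-large", "group-normal", "lone-disperser"]
        X = np.column_stack(
            [np.ones(len(y))]
            + [(table["context"] == lev).to_numpy(float) for lev in levels[1:]]
        )
        ref = BetaModel(y, X).fit(disp=0)
        by = {r.contrast: r for r in res}
        for i, lev in enumerate(levels[1:], start=1):
            got = by[f"{lev} vs group-large"]
            assert got.coef == pytest.approx(ref.params[i], abs=0.02)

    def test_directional_straightness_effect(self):
        table = _beta_table(effects=(-0.8, 0.0), seed=6)
        res = stats.fit_straightness_beta(table, response="value")
        by = {r.contrast: r for r in res}
        assert by["group-normal vs group-large"].percent < 0


class TestReport:
    def _results(self):
        return stats.ContrastResults(
            [
                stats.ContrastResult(
                    response="log value",
                    contrast="lone-disperser vs group-large",
                    coef=0.24,
                    ci_low=0.2,
                    ci_high=0.28,
                    pvalue=1e-5,
                    percent=(np.exp(0.24) - 1) * 100,
                    scale="log",
                    re_variances={"individual": 0.01},
                )
            ]
        )

    def test_json_roundtrip(self, tmp_path):
        res = self._results()
        path = tmp_path / "contrasts.json"
        stats.report(res, json_path=path)
        back = json.loads(path.read_text())
        assert back[0]["coef"] == pytest.approx(0.24)
        # percent difference recomputable from the exported coefficient
        assert back[0]["percent"] == pytest.approx(
            (np.exp(back[0]["coef"]) - 1) * 100
        )

    def test_empty_results_header_only(self, tmp_path):
        res = stats.ContrastResults([])
        path = tmp_path / "contrasts.csv"
        stats.report(res, csv_path=path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 and "coef" in lines[0]

    def test_summary_contains_values(self):
        text = self._results().summary()
        assert "lone-disperser" in text and "0.240" in text
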