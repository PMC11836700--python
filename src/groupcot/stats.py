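"""Regression contrasts of movement metrics across contexts.

Responses (daily track length, windowed speed-while-moving, segment cost of
transport, daily energy) are modelled with linear mixed models fitted by
maximum likelihood, with the movement context treatment-coded against the
reference category (large group displacements) and random intercepts for
individual identity — plus hour of day where the sampling design repeats
within days.  Straightness indices, being proportions, are modelled with
mixed beta regression (logit link); boundary values are squeezed by the
standard (y (n-1) + 0.5) / n transform before fitting.

Percent differences for log-transformed responses are the standard
back-transform 100 (exp(beta) - 1); for responses modelled on their raw
scale the coefficient is expressed relative to the model intercept, and the
raw group-mean ratio is reported alongside.

statsmodels' MixedLM provides the LMM machinery (crossed random intercepts
via the variance-components formulation); the beta mixed model is fitted
here by Laplace approximation, since no Python library offers one.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

REFERENCE = "group-large"


@dataclass
class ContrastResult:
    """One fixed-effect contrast from a fitted mixed model."""

    response: str
    contrast: str  # context level compared against the reference
    coef: float
    ci_low: float
    ci_high: float
    pvalue: float
    percent: float  # percent difference implied by the coefficient
    scale: str  # "log" | "raw" | "logit"
    re_variances: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["re_variances"] = dict(self.re_variances)
        d["flags"] = list(self.flags)
        return d


class ContrastResults:
    """Collection of contrasts with a printable summary."""

    def __init__(self, results: list[ContrastResult]):
        self.results = list(results)

    def __iter__(self):
        return iter(self.results)

    def __len__(self):
        return len(self.results)

    def to_frame(self) -> pd.DataFrame:
        rows = [r.to_dict() for r in self.results]
        return pd.DataFrame(
            rows,
            columns=[
                "response", "contrast", "coef", "ci_low", "ci_high",
                "pvalue", "percent", "scale", "re_variances", "flags",
            ],
        )

    def summary(self) -> str:
        lines = [
            f"{'response':<28}{'contrast':<18}{'coef':>9}{'95% CI':>22}"
            f"{'p':>9}{'pct':>8}",
        ]
        for r in self.results:
            ci = f"[{r.ci_low: .3f}, {r.ci_high: .3f}]"
            lines.append(
                f"{r.response:<28}{r.contrast:<18}{r.coef:>9.3f}{ci:>22}"
                f"{r.pvalue:>9.3g}{r.percent:>8.1f}"
            )
        return "\n".join(lines)

    def write_csv(self, path) -> None:
        frame = self.to_frame().copy()
        frame["re_variances"] = frame["re_variances"].map(json.dumps)
        frame["flags"] = frame["flags"].map(json.dumps)
        frame.to_csv(path, index=False)

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([r.to_dict() for r in self.results], fh, indent=1)


def _contrast_name(param: str) -> str | None:
    if "C(context" in param and "[T." in param:
        return param.split("[T.")[1].rstrip("]")
    return None


def fit_context_lmm(
    table: pd.DataFrame,
    response: str = "value",
    log_transform: bool = True,
    random: tuple = ("individual",),
    reference: str = REFERENCE,
) -> ContrastResults:
    """Linear mixed model of a metric against context, by ML.

    ``random`` is ``("individual",)`` or ``("individual", "hour_bin")``
    (the latter fitted as crossed variance components).  Returns one
    contrast per non-reference context.  A singular random-intercept fit is
    refitted without the offending intercept and flagged.
    """
    data = table.dropna(subset=[response]).copy()
    if data["context"].nunique() < 2:
        raise ValueError("need at least two context levels")
    data["y"] = np.log(data[response]) if log_transform else data[response]
    fixed = f"y ~ C(context, Treatment('{reference}'))"
    flags: list[str] = []
    terms = list(random)

    def _fit(terms):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if not terms:
                res = smf.ols(fixed, data=data).fit()
                return res, {}
            if len(terms) == 1:
                res = smf.mixedlm(fixed, data=data, groups=data[terms[0]]).fit(
                    reml=False
                )
                re_var = {terms[0]: float(np.asarray(res.cov_re)[0, 0])}
            else:
                vc = {t: f"0 + C({t})" for t in terms}
                res = smf.mixedlm(
                    fixed,
                    data=data,
                    groups=np.ones(len(data)),
                    vc_formula=vc,
                ).fit(reml=False)
                re_var = {
                    t: float(res.vcomp[i]) for i, t in enumerate(sorted(vc))
                }
            return res, re_var

    res, re_var = _fit(terms)
    while terms:
        singular = [t for t, v in re_var.items() if v < 1e-8]
        if not singular:
            break
        for t in singular:
            terms.remove(t)
            flags.append(f"dropped singular random intercept: {t}")
        res, re_var = _fit(terms)

    params = res.params
    conf = res.conf_int()
    intercept = float(params["Intercept"])
    out = []
    for name in params.index:
        level = _contrast_name(name)
        if level is None:
            continue
        coef = float(params[name])
        if log_transform:
            percent = (np.exp(coef) - 1.0) * 100.0
            scale = "log"
        else:
            percent = coef / intercept * 100.0 if intercept != 0 else np.nan
            scale = "raw"
        out.append(
            ContrastResult(
                response=response if not log_transform else f"log {response}",
                contrast=f"{level} vs {reference}",
                coef=coef,
                ci_low=float(conf.loc[name, 0]),
                ci_high=float(conf.loc[name, 1]),
                pvalue=float(res.pvalues[name]),
                percent=percent,
                scale=scale,
                re_variances=re_var,
                flags=list(flags),
            )
        )
    return ContrastResults(out)


# ---------------------------------------------------------------------------
# beta mixed model (Laplace approximation)
# ---------------------------------------------------------------------------


def squeeze_boundaries(y: np.ndarray) -> np.ndarray:
    """Pull exact 0/1 responses off the boundary: y -> (y (n-1) + 0.5) / n."""
    y = np.asarray(y, dtype=float).copy()
    n = len(y)
    boundary = (y <= 0.0) | (y >= 1.0)
    if boundary.all():
        raise ValueError(
            "all responses on the boundary; inspect the data before fitting"
        )
    y[boundary] = (y[boundary] * (n - 1) + 0.5) / n
    return y


class _BetaMixed:
    """Beta GLMM with logit link and independent random intercepts,
    marginal likelihood by Laplace approximation."""

    def __init__(self, y, X, factors):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.codes = []
        self.sizes = []
        for f in factors:
            codes, uniques = pd.factorize(f, sort=True)
            self.codes.append(codes)
            self.sizes.append(len(uniques))
        self.q = int(np.sum(self.sizes))
        self.offsets = np.concatenate([[0], np.cumsum(self.sizes)])[:-1]
        self.ystar = np.log(self.y / (1.0 - self.y))
        self._b = np.zeros(self.q)

    def _zb(self, b):
        eta = np.zeros(len(self.y))
        for codes, off in zip(self.codes, self.offsets):
            eta += b[off + codes]
        return eta

    def _accumulate(self, w):
        """Z' diag(w) Z as a dense (q, q) matrix."""
        H = np.zeros((self.q, self.q))
        for i, (ci, oi) in enumerate(zip(self.codes, self.offsets)):
            for j, (cj, oj) in enumerate(zip(self.codes, self.offsets)):
                if i == j:
                    np.add.at(H, (oi + ci, oi + ci), w)
                elif i < j:
                    np.add.at(H, (oi + ci, oj + cj), w)
                    np.add.at(H, (oj + cj, oi + ci), w)
        return H

    def _zt(self, g):
        out = np.zeros(self.q)
        for codes, off in zip(self.codes, self.offsets):
            np.add.at(out, off + codes, g)
        return out

    def _loglik_terms(self, eta, phi):
        mu = special.expit(eta)
        mu = np.clip(mu, 1e-10, 1.0 - 1e-10)
        a = mu * phi
        b = (1.0 - mu) * phi
        ll = (
            special.gammaln(phi)
            - special.gammaln(a)
            - special.gammaln(b)
            + (a - 1.0) * np.log(self.y)
            + (b - 1.0) * np.log(1.0 - self.y)
        ).sum()
        mustar = special.digamma(a) - special.digamma(b)
        dmu = mu * (1.0 - mu)
        grad_eta = phi * (self.ystar - mustar) * dmu
        fisher_eta = phi**2 * (special.polygamma(1, a) + special.polygamma(1, b)) * dmu**2
        return ll, grad_eta, fisher_eta

    def laplace_nll(self, params):
        p = self.X.shape[1]
        beta = params[:p]
        phi = np.exp(params[p])
        sigmas = np.exp(params[p + 1:])
        xb = self.X @ beta
        d_inv = np.concatenate(
            [
                np.full(size, 1.0 / max(s**2, 1e-12))
                for size, s in zip(self.sizes, sigmas)
            ]
        )
        b = self._b.copy()
        for _ in range(50):
            eta = xb + self._zb(b)
            _, grad_eta, fisher_eta = self._loglik_terms(eta, phi)
            grad = self._zt(grad_eta) - d_inv * b
            H = self._accumulate(fisher_eta)
            H[np.diag_indices_from(H)] += d_inv
            step = np.linalg.solve(H, grad)
            b_new = b + step
            # dampen overshoots
            if np.max(np.abs(step)) > 5.0:
                b_new = b + step * 5.0 / np.max(np.abs(step))
            if np.max(np.abs(b_new - b)) < 1e-9:
                b = b_new
                break
            b = b_new
        self._b = b
        eta = xb + self._zb(b)
        ll, _, fisher_eta = self._loglik_terms(eta, phi)
        H = self._accumulate(fisher_eta)
        H[np.diag_indices_from(H)] += d_inv
        sign, logdet_h = np.linalg.slogdet(H)
        if sign <= 0:
            return 1e10
        logdet_d = -np.log(d_inv).sum()
        nll = -(
            ll
            - 0.5 * np.sum(d_inv * b**2)
            - 0.5 * logdet_d
            - 0.5 * logdet_h
        )
        return float(nll)

    def fit(self):
        p = self.X.shape[1]
        # initialise from a logit-scale least squares and moment matching
        beta0, *_ = np.linalg.lstsq(self.X, self.ystar, rcond=None)
        resid = self.ystar - self.X @ beta0
        mu0 = special.expit(self.X @ beta0)
        var_logit = max(np.var(resid), 1e-3)
        phi0 = max(np.mean(1.0 / (var_logit * mu0 * (1.0 - mu0))) - 1.0, 2.0)
        x0 = np.concatenate([beta0, [np.log(phi0)], np.full(len(self.sizes), np.log(0.1))])
        bounds = (
            [(None, None)] * p
            + [(np.log(1e-3), np.log(1e6))]
            + [(np.log(1e-4), np.log(10.0))] * len(self.sizes)
        )
        res = optimize.minimize(
            self.laplace_nll,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 300, "ftol": 1e-11},
        )
        cov = self._param_cov(res.x)
        return res, cov

    def _param_cov(self, params):
        """Covariance of the fixed effects from a finite-difference Hessian."""
        p = self.X.shape[1]
        n = p + 1 + len(self.sizes)
        h = 1e-4 * np.maximum(np.abs(params), 1.0)
        H = np.zeros((n, n))
        f0 = self.laplace_nll(params)
        fp = np.zeros(n)
        fm = np.zeros(n)
        for i in range(n):
            e = np.zeros(n)
            e[i] = h[i]
            fp[i] = self.laplace_nll(params + e)
            fm[i] = self.laplace_nll(params - e)
            H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h[i] ** 2
        for i in range(n):
            for j in range(i + 1, n):
                e_i = np.zeros(n)
                e_j = np.zeros(n)
                e_i[i] = h[i]
                e_j[j] = h[j]
                fpp = self.laplace_nll(params + e_i + e_j)
                H[i, j] = H[j, i] = (
                    fpp - fp[i] - fp[j] + f0
                ) / (h[i] * h[j])
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
        return cov[:p, :p]


def fit_straightness_beta(
    table: pd.DataFrame,
    response: str = "value",
    random: tuple = ("individual",),
    reference: str = REFERENCE,
) -> ContrastResults:
    """Mixed beta regression of a straightness index against context.

    Logit link; random intercepts per factor in ``random``; Laplace
    marginal likelihood.  Returns one contrast per non-reference context
    with Wald confidence intervals.
    """
    data = table.dropna(subset=[response]).copy()
    if data["context"].nunique() < 2:
        raise ValueError("need at least two context levels")
    y = squeeze_boundaries(data[response].to_numpy())
    levels = [reference] + sorted(set(data["context"]) - {reference})
    X = np.column_stack(
        [np.ones(len(data))]
        + [(data["context"] == lev).to_numpy(float) for lev in levels[1:]]
    )
    factors = [data[f].to_numpy() for f in random]
    model = _BetaMixed(y, X, factors)
    res, cov = model.fit()
    p = X.shape[1]
    beta = res.x[:p]
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    sigmas = np.exp(res.x[p + 1:])
    re_var = {f: float(s**2) for f, s in zip(random, sigmas)}
    flags = []
    if not res.success:
        flags.append("optimizer did not report convergence")
    out = []
    from scipy.stats import norm

    for i, lev in enumerate(levels[1:], start=1):
        z = beta[i] / se[i] if se[i] > 0 else np.nan
        out.append(
            ContrastResult(
                response=f"straightness ({response})",
                contrast=f"{lev} vs {reference}",
                coef=float(beta[i]),
                ci_low=float(beta[i] - 1.959963984540054 * se[i]),
                ci_high=float(beta[i] + 1.959963984540054 * se[i]),
                pvalue=float(2.0 * norm.sf(abs(z))) if np.isfinite(z) else np.nan,
                percent=(np.exp(beta[i]) - 1.0) * 100.0,
                scale="logit",
                re_variances=re_var,
                flags=flags,
            )
        )
    return ContrastResults(out)


def raw_mean_ratio(
    table: pd.DataFrame, response: str = "value", reference: str = REFERENCE
) -> dict:
    """Raw group-mean ratios versus the reference context, as percents."""
    means = table.groupby("context")[response].mean()
    ref = means[reference]
    return {
        f"{ctx} vs {reference}": float((m / ref - 1.0) * 100.0)
        for ctx, m in means.items()
        if ctx != reference
    }


def report(results: ContrastResults, csv_path=None, json_path=None) -> str:
    """Human-readable summary; optionally persists CSV/JSON exports."""
    text = results.summary()
    if csv_path is not None:
        results.write_csv(csv_path)
    if json_path is not None:
        results.write_json(json_path)
    return text
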