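"""Bayesian multilevel growth models for cognitive trajectories.

Fits intercept-only, linear and quadratic change models by Gibbs sampling
(all conditionals are conjugate), with random effects for intercept and
linear change only - random quadratic components are not identified with at
most four occasions per person, so quadratic change enters as a fixed
effect.  Ages are centered at 65 years throughout.

Fitting a model returns the posterior summary of the population parameters
together with per-person posterior means of (u0, u1) - the "random-effect
scores" that the two-stage survival analysis consumes as fixed predictors.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import _lmm
from .mcmc import MCMCSettings, PosteriorSummary, summarize_draws
from .params import GrowthParams

__all__ = [
    "ModelSpec",
    "GrowthPriors",
    "PanelData",
    "prepare_data",
    "fit_mlm",
    "pseudo_r2",
    "predict_trajectory",
    "compare_fits",
    "chisq_test",
    "mlm_log_posterior",
]

FORMS = ("intercept_only", "linear", "quadratic")
AGE_CENTER = 65.0
AGE_SUPPORT = (50.0, 87.0)


@dataclass(frozen=True)
class ModelSpec:
    """Which growth model to fit, on which slice of the data."""

    form: str = "quadratic"
    adjusted: bool = False
    subset: str = "all"  # all | decedents
    stratum: str | None = None  # women | men | None = pooled
    domain: str | None = None  # Gc | Gf | None = whatever the panel holds

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"form must be one of {FORMS}")
        if self.subset not in ("all", "decedents"):
            raise ValueError("subset must be 'all' or 'decedents'")
        if self.adjusted and self.form == "intercept_only":
            raise ValueError("covariate adjustment requires a change model")

    @property
    def re_slope(self) -> bool:
        return self.form != "intercept_only"

    def replace(self, **kw) -> "ModelSpec":
        return replace(self, **kw)


@dataclass(frozen=True)
class GrowthPriors:
    """Weakly informative defaults: broad normals on fixed effects,
    inverse-gamma on variances, inverse-Wishart on the 2x2 random-effect
    covariance (chosen for conjugacy; see the methods note)."""

    beta_sd: float = 100.0
    resid_a: float = 0.01
    resid_b: float = 0.01
    iw_df: float = 4.0
    iw_scale: tuple = ((1.0, 0.0), (0.0, 0.01))
    u0_a: float = 2.0
    u0_b: float = 0.5


@dataclass
class PanelData:
    """Design matrices and indexing for one model fit, sorted by person."""

    y: np.ndarray
    x: np.ndarray
    age: np.ndarray
    pid_idx: np.ndarray
    person_ids: np.ndarray
    starts: np.ndarray  # person block boundaries in the sorted arrays
    fixed_names: list
    re_slope: bool
    fingerprint: str
    age_range: tuple

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_persons(self) -> int:
        return self.person_ids.size


def _fixed_names(form: str, adjusted: bool) -> list:
    names = ["B0"]
    if form in ("linear", "quadratic"):
        names.append("B1")
    if form == "quadratic":
        names.append("B2")
    if adjusted:
        names += ["B3", "B4", "B5", "B6"]
    return names


def build_fixed_design(df: pd.DataFrame, form: str, adjusted: bool) -> np.ndarray:
    age = df["age_c"].to_numpy(dtype=float)
    cols = [np.ones(age.size)]
    if form in ("linear", "quadratic"):
        cols.append(age)
    if form == "quadratic":
        cols.append(age * age)
    if adjusted:
        sa = df["start_age_c"].to_numpy(dtype=float)
        cols += [
            sa,
            sa * age,
            df["smoker"].to_numpy(dtype=float),
            df["srh"].to_numpy(dtype=float) - 3.0,
        ]
    return np.column_stack(cols)


def prepare_data(panel: pd.DataFrame, cohort: pd.DataFrame, spec: ModelSpec) -> PanelData:
    cohort_sel = cohort
    if spec.stratum is not None:
        cohort_sel = cohort_sel[cohort_sel["sex"] == spec.stratum]
    if spec.subset == "decedents":
        cohort_sel = cohort_sel[cohort_sel["event"] == 1]
    sel = panel[panel["person_id"].isin(set(cohort_sel["person_id"]))]
    if spec.domain is not None:
        sel = sel[sel["domain"] == spec.domain]
    if sel.empty:
        raise ValueError(f"no observations left after applying {spec}")
    covars = ["person_id", "start_age_c", "smoker", "srh"]
    df = sel.merge(cohort_sel[covars], on="person_id", validate="many_to_one")
    df = df.sort_values(["person_id", "age_c"], kind="stable").reset_index(drop=True)

    person_ids, pid_idx = np.unique(df["person_id"].to_numpy(), return_inverse=True)
    order = np.argsort(pid_idx, kind="stable")
    df = df.iloc[order].reset_index(drop=True)
    pid_idx = pid_idx[order]
    starts = np.searchsorted(pid_idx, np.arange(person_ids.size + 1))

    y = df["score"].to_numpy(dtype=float)
    age = df["age_c"].to_numpy(dtype=float)
    x = build_fixed_design(df, spec.form, spec.adjusted)
    fp = hashlib.sha1(y.tobytes() + pid_idx.tobytes()).hexdigest()[:16]
    return PanelData(
        y=y,
        x=x,
        age=age,
        pid_idx=pid_idx,
        person_ids=person_ids,
        starts=starts,
        fixed_names=_fixed_names(spec.form, spec.adjusted),
        re_slope=spec.re_slope,
        fingerprint=fp,
        age_range=(float(age.min() + AGE_CENTER), float(age.max() + AGE_CENTER)),
    )


def _init_state(data: PanelData, priors: GrowthPriors, rng: np.random.Generator):
    beta, *_ = np.linalg.lstsq(data.x, data.y, rcond=None)
    beta = beta + 0.05 * rng.standard_normal(beta.size) * (1.0 + np.abs(beta))
    resid = data.y - data.x @ beta
    sigma2 = max(float(resid.var()), 1e-6) * float(rng.uniform(0.5, 1.5))
    person_mean = np.bincount(data.pid_idx, weights=resid) / np.maximum(
        np.bincount(data.pid_idx), 1
    )
    v0 = max(float(person_mean.var()), 1e-3)
    if data.re_slope:
        re_cov = np.diag([v0, 0.01]) * float(rng.uniform(0.5, 1.5))
    else:
        re_cov = v0 * float(rng.uniform(0.5, 1.5))
    u = np.zeros((data.n_persons, 2)) if data.re_slope else np.zeros(data.n_persons)
    return beta, sigma2, re_cov, u


def _gibbs_chain(data: PanelData, priors: GrowthPriors, n_iter: int, burn_in: int,
                 rng: np.random.Generator):
    ni, sa, saa = _lmm.person_design_stats(data.pid_idx, data.age, data.n_persons)
    xtx = data.x.T @ data.x
    beta, sigma2, re_cov, u = _init_state(data, priors, rng)
    p = beta.size

    kept = n_iter
    out_beta = np.empty((kept, p))
    out_var = np.empty((kept, 4))  # var_u0, var_u1, corr, var_resid
    u_sum = np.zeros((data.n_persons, 2))
    u_sq = np.zeros((data.n_persons, 2))

    for it in range(n_iter + burn_in):
        resid = data.y - data.x @ beta
        if data.re_slope:
            m, chol = _lmm.re_conditional(resid, data.pid_idx, data.age, ni, sa, saa,
                                          sigma2, re_cov)
            u = _lmm.draw_bivariate(m, chol, rng)
            zu = u[data.pid_idx, 0] + u[data.pid_idx, 1] * data.age
        else:
            m, var = _lmm.re_conditional_intercept(resid, data.pid_idx, ni, sigma2,
                                                   re_cov)
            u = m + np.sqrt(var) * rng.standard_normal(data.n_persons)
            zu = u[data.pid_idx]

        beta = _lmm.draw_fixed_effects(
            xtx, lambda r: data.x.T @ r, data.y - zu, sigma2, priors.beta_sd, rng
        )
        resid = data.y - data.x @ beta - zu
        sigma2 = _lmm.draw_sigma2(resid, priors.resid_a, priors.resid_b, rng)
        if data.re_slope:
            re_cov = _lmm.draw_re_cov(u, priors.iw_df, priors.iw_scale, rng)
            if p >= 2:
                _lmm.recenter(beta, u, re_cov, priors.beta_sd, rng)
        else:
            re_cov = _lmm.draw_var_u0(u, priors.u0_a, priors.u0_b, rng)
            _lmm.recenter_intercept(beta, u, re_cov, priors.beta_sd, rng)

        k = it - burn_in
        if k >= 0:
            out_beta[k] = beta
            if data.re_slope:
                corr = re_cov[0, 1] / np.sqrt(re_cov[0, 0] * re_cov[1, 1])
                out_var[k] = (re_cov[0, 0], re_cov[1, 1], corr, sigma2)
                u_sum += u
                u_sq += u * u
            else:
                out_var[k] = (re_cov, np.nan, np.nan, sigma2)
                u_sum[:, 0] += u
                u_sq[:, 0] += u * u

    return out_beta, out_var, u_sum, u_sq


def fit_mlm(panel, cohort, spec: ModelSpec = ModelSpec(),
            mcmc: MCMCSettings = MCMCSettings(),
            priors: GrowthPriors = GrowthPriors(), keep_draws: bool = True):
    """Fit the growth model by MCMC; returns (PosteriorSummary, scores).

    ``scores`` holds each person's posterior-mean random intercept and
    linear change with posterior SDs - the stage-1 output of the two-stage
    procedure.
    """
    data = prepare_data(panel, cohort, spec)
    names = data.fixed_names
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    betas, vars_, u_sum, u_sq = [], [], 0.0, 0.0
    for seq in seeds:
        rng = np.random.default_rng(seq)
        b, v, us, uq = _gibbs_chain(data, priors, mcmc.iterations, mcmc.burn_in, rng)
        betas.append(b)
        vars_.append(v)
        u_sum = u_sum + us
        u_sq = u_sq + uq
    betas = np.stack(betas)  # (chains, draws, p)
    vars_ = np.stack(vars_)

    draws = {name: betas[:, :, j] for j, name in enumerate(names)}
    draws["var_u0"] = vars_[:, :, 0]
    if data.re_slope:
        draws["var_u1"] = vars_[:, :, 1]
        draws["corr_u0u1"] = vars_[:, :, 2]
    draws["var_resid"] = vars_[:, :, 3]

    n_draws_total = mcmc.chains * mcmc.iterations
    u_mean = u_sum / n_draws_total
    u_var = np.maximum(u_sq / n_draws_total - u_mean**2, 0.0)
    scores = pd.DataFrame(
        {
            "person_id": data.person_ids,
            "u0_hat": u_mean[:, 0],
            "u0_sd": np.sqrt(u_var[:, 0]),
            "u1_hat": u_mean[:, 1] if data.re_slope else np.zeros(data.n_persons),
            "u1_sd": np.sqrt(u_var[:, 1]) if data.re_slope else np.zeros(data.n_persons),
        }
    )

    meta = {
        "model": "mlm",
        "spec": spec.__dict__ | {},
        "settings": mcmc.__dict__ | {},
        "n_obs": data.n_obs,
        "n_persons": data.n_persons,
        "fingerprint": data.fingerprint,
        "age_range": data.age_range,
        "fixed_names": names,
    }
    summary = summarize_draws(draws, meta, keep_draws=keep_draws)

    # deviance at posterior means, under the marginal (u integrated out)
    # likelihood, and BIC with k counting all free parameters
    beta_hat = np.array([summary.mean(n) for n in names])
    sigma2_hat = summary.mean("var_resid")
    if data.re_slope:
        v0, v1 = summary.mean("var_u0"), summary.mean("var_u1")
        c = summary.mean("corr_u0u1") * np.sqrt(v0 * v1)
        re_hat = np.array([[v0, c], [c, v1]])
        k = len(names) + 4
    else:
        re_hat = np.array([[summary.mean("var_u0")]])
        k = len(names) + 2
    ll = _lmm.marginal_loglik(beta_hat, re_hat, sigma2_hat, data.y, data.x, data.age,
                              data.starts, data.re_slope)
    summary.meta["deviance"] = -2.0 * ll
    summary.meta["k"] = k
    summary.meta["bic"] = -2.0 * ll + k * np.log(data.n_obs)
    return summary, scores


def pseudo_r2(fit: PosteriorSummary, null_fit: PosteriorSummary) -> float:
    """Proportional reduction in residual variance relative to the
    unconditional-means (intercept-only) model, rounded to 2 decimals."""
    if fit.meta.get("fingerprint") != null_fit.meta.get("fingerprint"):
        raise ValueError("fits were not estimated on the same data")
    return round(1.0 - fit.mean("var_resid") / null_fit.mean("var_resid"), 2)


def predict_trajectory(fit: PosteriorSummary, ages, profile: dict | None = None) -> pd.DataFrame:
    """Posterior mean fixed-effect trajectory with a pointwise 95% band.

    ``ages`` are chronological ages in years; ``profile`` optionally sets
    start_age_c, smoker and srh for adjusted models (defaults: covariate
    reference - entry at 65, non-smoker, SRH 3).
    """
    ages = np.asarray(ages, dtype=float)
    lo, hi = fit.meta.get("age_range", AGE_SUPPORT)
    if ages.min() < lo - 1e-9 or ages.max() > hi + 1e-9:
        warnings.warn("requested ages fall outside the fitted age support",
                      stacklevel=2)
    profile = {"start_age_c": 0.0, "smoker": 0.0, "srh": 3.0} | (profile or {})
    names = fit.meta["fixed_names"]
    draws = fit.require_draws()
    beta = np.stack([np.ravel(draws[n]) for n in names], axis=1)  # (ndraw, p)

    age_c = ages - AGE_CENTER
    df = pd.DataFrame(
        {
            "age_c": age_c,
            "start_age_c": profile["start_age_c"],
            "smoker": profile["smoker"],
            "srh": profile["srh"],
        }
    )
    form = "quadratic" if "B2" in names else ("linear" if "B1" in names else "intercept_only")
    x = build_fixed_design(df, form, adjusted="B3" in names)
    curves = beta @ x.T  # (ndraw, n_ages)
    return pd.DataFrame(
        {
            "age": ages,
            "mean": curves.mean(axis=0),
            "ci_low": np.quantile(curves, 0.025, axis=0),
            "ci_high": np.quantile(curves, 0.975, axis=0),
        }
    )


def compare_fits(fits) -> pd.DataFrame:
    """Deviance/BIC table for fits of nested forms on identical data."""
    fps = {f.meta.get("fingerprint") for f in fits}
    if len(fps) != 1:
        raise ValueError("fits were not estimated on the same data")
    rows = [
        {
            "form": f.meta["spec"]["form"],
            "adjusted": f.meta["spec"]["adjusted"],
            "k": f.meta["k"],
            "deviance": f.meta["deviance"],
            "bic": f.meta["bic"],
        }
        for f in fits
    ]
    return pd.DataFrame(rows).sort_values("k").reset_index(drop=True)


def _is_nested(spec_small: dict, spec_big: dict) -> bool:
    order = {f: i for i, f in enumerate(FORMS)}
    if order[spec_small["form"]] > order[spec_big["form"]]:
        return False
    if spec_small["adjusted"] and not spec_big["adjusted"]:
        return False
    return spec_small != spec_big


def chisq_test(fit_small: PosteriorSummary, fit_big: PosteriorSummary) -> dict:
    """Chi-square screen on the change in deviance between nested models."""
    if fit_small.meta.get("fingerprint") != fit_big.meta.get("fingerprint"):
        raise ValueError("fits were not estimated on the same data")
    if not _is_nested(fit_small.meta["spec"], fit_big.meta["spec"]):
        raise ValueError("chi-square comparison requires nested models")
    stat = fit_small.meta["deviance"] - fit_big.meta["deviance"]
    df = fit_big.meta["k"] - fit_small.meta["k"]
    return {"statistic": stat, "df": df, "pvalue": float(stats.chi2.sf(stat, df))}


def mlm_log_posterior(growth: GrowthParams, u: np.ndarray, data: PanelData,
                      priors: GrowthPriors = GrowthPriors(),
                      adjusted: bool | None = None) -> float:
    """Log-posterior of the growth model conditional on the person effects.

    Gaussian observation terms + bivariate-normal density of (u0, u1) +
    the log-priors of all growth parameters.
    """
    if adjusted is None:
        adjusted = len(data.fixed_names) > 3
    beta = growth.fixed_effects(adjusted)[: len(data.fixed_names)]
    mean = data.x @ beta + u[data.pid_idx, 0] + u[data.pid_idx, 1] * data.age
    ll = float(np.sum(stats.norm.logpdf(data.y, mean, np.sqrt(growth.var_resid))))
    re_term = float(
        np.sum(stats.multivariate_normal.logpdf(u, np.zeros(2), growth.re_cov))
    )
    lp = float(np.sum(stats.norm.logpdf(beta, 0.0, priors.beta_sd)))
    lp += float(stats.invgamma.logpdf(growth.var_resid, priors.resid_a,
                                      scale=priors.resid_b))
    lp += float(stats.invwishart.logpdf(growth.re_cov, priors.iw_df,
                                        np.asarray(priors.iw_scale)))
    return ll + re_term + lp
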