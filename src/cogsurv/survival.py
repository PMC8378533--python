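"""Bayesian proportional-hazards model with a piecewise-constant baseline.

Time runs from study entry; entry age is a covariate rather than the time
scale.  The baseline hazard is a step function with cut points at the
deciles of the observed event times, which keeps the cumulative hazard
piecewise linear and the whole likelihood in closed form:

    log L = sum_i [ d_i * (log h0(t_i) + eta_i) - H0(t_i) * exp(eta_i) ],

with eta the linear predictor.  Used standalone this is the second stage of
the two-stage procedure, where the cognitive predictors are posterior-mean
random-effect scores from the growth model.

Sampling alternates conjugate gamma updates of the baseline levels with
adaptive random-walk Metropolis updates of the regression coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hazards import PiecewiseConstantHazard
from .mcmc import ComponentwiseMH, MCMCSettings, PosteriorSummary, summarize_draws

__all__ = [
    "PHPriors",
    "SurvivalData",
    "make_survival_input",
    "default_cuts",
    "log_likelihood_ph",
    "ph_log_posterior",
    "fit_ph",
]


@dataclass(frozen=True)
class PHPriors:
    beta_sd: float = 10.0
    lam_a: float = 0.01
    lam_b: float = 0.01


@dataclass
class SurvivalData:
    """Per-person follow-up time, event indicator and predictor matrix."""

    person_ids: np.ndarray
    times: np.ndarray
    events: np.ndarray
    x: np.ndarray  # (n, p); p may be 0
    names: list  # coefficient names, aligned with columns of x

    def __post_init__(self) -> None:
        if np.any(self.times <= 0):
            raise ValueError("survival times must be positive")
        if self.x.shape != (self.times.size, len(self.names)):
            raise ValueError("predictor matrix does not match coefficient names")

    @property
    def n(self) -> int:
        return self.times.size


def make_survival_input(cohort: pd.DataFrame, scores: pd.DataFrame | None = None,
                        adjusted: bool = False) -> SurvivalData:
    """Assemble the survival design from a cohort table and, optionally,
    stage-1 random-effect scores (columns u0_hat, u1_hat)."""
    df = cohort
    if scores is not None:
        df = df.merge(scores[["person_id", "u0_hat", "u1_hat"]], on="person_id",
                      validate="one_to_one")
        if len(df) < len(cohort):
            missing = set(cohort["person_id"]) - set(df["person_id"])
            raise ValueError(f"scores missing for {len(missing)} persons")
    cols, names = [], []
    if scores is not None:
        cols += [df["u0_hat"].to_numpy(float), df["u1_hat"].to_numpy(float)]
        names += ["alpha1", "alpha2"]
    if adjusted:
        cols += [
            df["start_age_c"].to_numpy(float),
            df["smoker"].to_numpy(float),
            df["srh"].to_numpy(float) - 3.0,
        ]
        names += ["gamma_start_age", "gamma_smoker", "gamma_srh"]
    x = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return SurvivalData(
        person_ids=df["person_id"].to_numpy(),
        times=df["time"].to_numpy(float),
        events=df["event"].to_numpy(int),
        x=x,
        names=names,
    )


def default_cuts(times, events, n_intervals: int = 10) -> tuple:
    """Interior cut points at the deciles of the observed event times."""
    ev = np.asarray(times, float)[np.asarray(events).astype(bool)]
    if ev.size == 0:
        raise ValueError("no events observed; cannot anchor the baseline hazard")
    qs = np.linspace(0, 1, n_intervals + 1)[1:-1]
    cuts = np.unique(np.quantile(ev, qs))
    return tuple(c for c in cuts if c > 0)


def _break_ties(times, events, seed: int = 0) -> np.ndarray:
    """Perturb tied event times by a seeded jitter far below the time
    resolution (simulated continuous times make ties measure-zero; observed
    ties are broken reproducibly)."""
    times = np.asarray(times, float).copy()
    ev = np.asarray(events).astype(bool)
    vals, counts = np.unique(times[ev], return_counts=True)
    if np.any(counts > 1):
        rng = np.random.default_rng(seed)
        times[ev] = times[ev] + rng.uniform(0, 1e-8, ev.sum())
    return times


def log_likelihood_ph(baseline: PiecewiseConstantHazard, beta, data: SurvivalData) -> float:
    """Full parametric PH log-likelihood; times beyond the last cut point
    keep the final hazard level (the step function extends to infinity)."""
    beta = np.asarray(beta, float)
    eta = data.x @ beta if beta.size else np.zeros(data.n)
    h0 = baseline.hazard(data.times)
    cum = baseline.cum_hazard(data.times)
    return float(np.sum(data.events * (np.log(h0) + eta) - cum * np.exp(eta)))


def ph_log_posterior(baseline: PiecewiseConstantHazard, beta, data: SurvivalData,
                     priors: PHPriors = PHPriors()) -> float:
    """Log-likelihood plus log-priors (normal on coefficients, gamma on the
    baseline hazard levels)."""
    beta = np.asarray(beta, float)
    lp = log_likelihood_ph(baseline, beta, data)
    if beta.size:
        lp += float(np.sum(stats.norm.logpdf(beta, 0.0, priors.beta_sd)))
    lam = np.asarray(baseline.levels)
    lp += float(np.sum(stats.gamma.logpdf(lam, priors.lam_a, scale=1.0 / priors.lam_b)))
    return lp


def _check_collinearity(x: np.ndarray, names) -> None:
    if x.shape[1] < 2:
        return
    sd = x.std(axis=0)
    if np.any(sd == 0):
        warnings.warn("constant predictor column in survival design", stacklevel=3)
        return
    corr = np.corrcoef(x, rowvar=False)
    iu = np.triu_indices_from(corr, k=1)
    if np.any(np.abs(corr[iu]) > 0.999):
        j = int(np.argmax(np.abs(corr[iu])))
        warnings.warn(
            f"collinear survival predictors (|r| > 0.999) among {list(names)}",
            stacklevel=3,
        )


def fit_ph(data: SurvivalData, mcmc: MCMCSettings = MCMCSettings(),
           priors: PHPriors = PHPriors(), cuts=None,
           keep_draws: bool = True) -> PosteriorSummary:
    """Sample the PH posterior; requires at least one event."""
    if int(np.sum(data.events)) == 0:
        raise ValueError("all observations are censored; no events to anchor the baseline")
    _check_collinearity(data.x, data.names)
    times = _break_ties(data.times, data.events, seed=mcmc.seed)
    if cuts is None:
        cuts = default_cuts(times, data.events)
    cuts = tuple(cuts)
    k = len(cuts) + 1
    probe = PiecewiseConstantHazard(cuts, tuple(np.ones(k)))
    expo = probe.exposure_matrix(times)  # (n, K)
    interval = probe.interval_index(times)
    d_k = np.bincount(interval[data.events.astype(bool)], minlength=k).astype(float)
    p = data.x.shape[1]

    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    beta_draws, lam_draws = [], []
    for seq in seeds:
        rng = np.random.default_rng(seq)
        b, lam = _ph_chain(data, times, expo, interval, d_k, priors, mcmc, rng)
        beta_draws.append(b)
        lam_draws.append(lam)
    beta_draws = np.stack(beta_draws)  # (chains, draws, p)
    lam_draws = np.stack(lam_draws)  # (chains, draws, K)

    draws = {name: beta_draws[:, :, j] for j, name in enumerate(data.names)}
    for j in range(k):
        draws[f"log_lambda_{j}"] = np.log(lam_draws[:, :, j])
    meta = {
        "model": "ph",
        "settings": mcmc.__dict__ | {},
        "cuts": list(cuts),
        "n": data.n,
        "events": int(np.sum(data.events)),
        "coef_names": list(data.names),
    }
    return summarize_draws(draws, meta, keep_draws=keep_draws)


def _ph_chain(data, times, expo, interval, d_k, priors, mcmc, rng):
    n, p = data.x.shape
    k = d_k.size
    crude = np.maximum(d_k, 0.5) / np.maximum(expo.sum(axis=0), 1e-12)
    lam = crude * rng.uniform(0.7, 1.4, size=k)
    beta = np.zeros(p) if p else np.zeros(0)
    events = data.events.astype(float)

    def beta_logpost(b, _j, h0_at):
        eta = data.x @ b
        return float(
            np.sum(events * eta) - np.sum(h0_at * np.exp(eta))
            + np.sum(stats.norm.logpdf(b, 0.0, priors.beta_sd))
        )

    sampler = ComponentwiseMH(p) if p else None
    out_beta = np.empty((mcmc.iterations, p))
    out_lam = np.empty((mcmc.iterations, k))
    for it in range(mcmc.iterations + mcmc.burn_in):
        eta = data.x @ beta if p else np.zeros(n)
        w = np.exp(eta)
        rate = priors.lam_b + expo.T @ w
        lam = rng.gamma(priors.lam_a + d_k) / rate
        lam = np.maximum(lam, 1e-300)
        if p:
            h0_at = expo @ lam
            lp = beta_logpost(beta, None, h0_at)
            beta, lp = sampler.step(
                beta, lambda b, j: beta_logpost(b, j, h0_at), lp, rng,
                adapt=it < mcmc.burn_in,
            )
        j = it - mcmc.burn_in
        if j >= 0:
            out_beta[j] = beta
            out_lam[j] = lam
    return out_beta, out_lam
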