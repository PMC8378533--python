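"""Shared-random-effects joint longitudinal-survival model.

The growth model and the proportional-hazards model are linked through the
person-level effects (u0, u1): the hazard for person i is

    h_i(t) = h0(t) * exp(gamma' w_i + alpha1 * u0_i + alpha2 * u1_i).

Because the association runs through the (time-constant) random effects and
the baseline is piecewise-constant, each person's cumulative hazard is
H0(t) * exp(eta_i) in closed form - no time quadrature anywhere.

Estimation is Metropolis-within-Gibbs: the growth fixed effects, variances
and random-effect covariance keep their conjugate updates from the
standalone model; the baseline hazard levels keep their conjugate gamma
updates; (gamma, alpha) move by adaptive random-walk Metropolis; and each
person's (u0, u1) is proposed from its longitudinal full conditional and
accepted against the survival factor - an independence proposal whose
acceptance ratio involves only that person's hazard terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import _lmm
from .hazards import PiecewiseConstantHazard
from .longitudinal import GrowthPriors, ModelSpec, PanelData, prepare_data
from .mcmc import ComponentwiseMH, MCMCSettings, PosteriorSummary, summarize_draws
from .params import GrowthParams, HazardParams
from .survival import PHPriors, SurvivalData, _break_ties, default_cuts, ph_log_posterior

__all__ = [
    "JointFitResult",
    "joint_log_posterior",
    "fit_joint",
    "extract_shared_association",
    "init_from_standalone",
]


@dataclass
class JointFitResult:
    """Posterior summary over all joint parameters, per-person latent
    posterior means, and the log-posterior trace."""

    summary: PosteriorSummary
    latent: pd.DataFrame
    lp_trace: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))


def _aligned_cohort(cohort: pd.DataFrame, data: PanelData) -> pd.DataFrame:
    sub = cohort.set_index("person_id").loc[data.person_ids].reset_index()
    return sub


def _survival_design(cohort_aligned: pd.DataFrame, u: np.ndarray,
                     adjusted: bool) -> SurvivalData:
    cols = [u[:, 0], u[:, 1]]
    names = ["alpha1", "alpha2"]
    if adjusted:
        cols += [
            cohort_aligned["start_age_c"].to_numpy(float),
            cohort_aligned["smoker"].to_numpy(float),
            cohort_aligned["srh"].to_numpy(float) - 3.0,
        ]
        names += ["gamma_start_age", "gamma_smoker", "gamma_srh"]
    return SurvivalData(
        person_ids=cohort_aligned["person_id"].to_numpy(),
        times=cohort_aligned["time"].to_numpy(float),
        events=cohort_aligned["event"].to_numpy(int),
        x=np.column_stack(cols),
        names=names,
    )


def joint_log_posterior(growth: GrowthParams, hazard_coefs: dict,
                        baseline: PiecewiseConstantHazard, u: np.ndarray,
                        panel: pd.DataFrame, cohort: pd.DataFrame,
                        spec: ModelSpec = ModelSpec(),
                        growth_priors: GrowthPriors = GrowthPriors(),
                        hazard_priors: PHPriors = PHPriors()) -> float:
    """Log-posterior of the joint model at a parameter/latent configuration.

    ``u`` has one (u0, u1) row per person, aligned with the sorted person
    ids of the filtered panel.  ``hazard_coefs`` maps coefficient names
    (alpha1, alpha2, gamma_*) to values.  The result is, by construction,
    the standalone growth-model log-posterior plus the standalone PH
    log-posterior evaluated with the shared-effect offset - with
    alpha1 = alpha2 = 0 the two decouple exactly.

    Raises if any person contributes a non-finite term, naming the ids.
    """
    from .longitudinal import mlm_log_posterior

    data = prepare_data(panel, cohort, spec)
    u = np.asarray(u, dtype=float)
    if u.shape != (data.n_persons, 2):
        raise ValueError(f"u must have shape ({data.n_persons}, 2), got {u.shape}")
    cohort_aligned = _aligned_cohort(cohort, data)
    sdata = _survival_design(cohort_aligned, u, spec.adjusted)
    beta = np.array([hazard_coefs.get(name, 0.0) for name in sdata.names])

    long_lp = mlm_log_posterior(growth, u, data, growth_priors)
    surv_lp = ph_log_posterior(baseline, beta, sdata, hazard_priors)
    total = long_lp + surv_lp
    if not np.isfinite(total):
        eta = sdata.x @ beta
        per = (
            sdata.events * (np.log(baseline.hazard(sdata.times)) + eta)
            - baseline.cum_hazard(sdata.times) * np.exp(eta)
        )
        bad = sdata.person_ids[~np.isfinite(per)]
        raise FloatingPointError(
            f"non-finite joint posterior; offending person ids: {list(bad[:10])}"
        )
    return float(total)


def init_from_standalone(mlm_summary: PosteriorSummary, scores: pd.DataFrame,
                         ph_summary: PosteriorSummary | None = None) -> dict:
    """Build joint-sampler starting values from standalone fits."""
    names = mlm_summary.meta["fixed_names"]
    beta = np.array([mlm_summary.mean(n) for n in names])
    v0 = mlm_summary.mean("var_u0")
    v1 = mlm_summary.mean("var_u1")
    c = mlm_summary.mean("corr_u0u1") * np.sqrt(v0 * v1)
    init = {
        "beta": beta,
        "sigma2": mlm_summary.mean("var_resid"),
        "re_cov": np.array([[v0, c], [c, v1]]),
        "scores": scores,
        "phi": {},
    }
    if ph_summary is not None:
        for name in ph_summary.table.index:
            if name.startswith(("alpha", "gamma")):
                init["phi"][name] = ph_summary.mean(name)
    return init


def fit_joint(panel: pd.DataFrame, cohort: pd.DataFrame,
              spec: ModelSpec = ModelSpec(), mcmc: MCMCSettings = MCMCSettings(),
              init: dict | None = None, cuts=None,
              growth_priors: GrowthPriors = GrowthPriors(),
              hazard_priors: PHPriors = PHPriors(),
              keep_draws: bool = True) -> JointFitResult:
    """Fit the joint model by Metropolis-within-Gibbs MCMC.

    ``init`` optionally carries starting values (see
    :func:`init_from_standalone`); otherwise data-driven defaults are used.
    The longitudinal form must include a linear change component so that
    both shared effects exist.
    """
    if not spec.re_slope:
        raise ValueError("the joint model requires a random linear-change term")
    data = prepare_data(panel, cohort, spec)
    cohort_aligned = _aligned_cohort(cohort, data)
    times = _break_ties(cohort_aligned["time"].to_numpy(float),
                        cohort_aligned["event"].to_numpy(int), seed=mcmc.seed)
    events = cohort_aligned["event"].to_numpy(float)
    if events.sum() == 0:
        raise ValueError("all observations are censored; no events to anchor the baseline")
    if cuts is None:
        cuts = default_cuts(times, events)
    cuts = tuple(cuts)
    k = len(cuts) + 1
    probe = PiecewiseConstantHazard(cuts, tuple(np.ones(k)))
    expo = probe.exposure_matrix(times)
    interval = probe.interval_index(times)
    d_k = np.bincount(interval[events.astype(bool)], minlength=k).astype(float)

    if spec.adjusted:
        w = np.column_stack([
            cohort_aligned["start_age_c"].to_numpy(float),
            cohort_aligned["smoker"].to_numpy(float),
            cohort_aligned["srh"].to_numpy(float) - 3.0,
        ])
        gamma_names = ["gamma_start_age", "gamma_smoker", "gamma_srh"]
    else:
        w = np.empty((data.n_persons, 0))
        gamma_names = []
    phi_names = ["alpha1", "alpha2"] + gamma_names

    start = _joint_init(data, init, phi_names)

    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    chains = []
    for seq in seeds:
        rng = np.random.default_rng(seq)
        chains.append(
            _joint_chain(data, events, times, expo, interval, d_k, w, phi_names,
                         start, growth_priors, hazard_priors, mcmc, rng)
        )

    p = len(data.fixed_names)
    draws = {}
    for j, name in enumerate(data.fixed_names):
        draws[name] = np.stack([c["beta"][:, j] for c in chains])
    for j, name in enumerate(("var_u0", "var_u1", "corr_u0u1", "var_resid")):
        draws[name] = np.stack([c["vars"][:, j] for c in chains])
    for j, name in enumerate(phi_names):
        draws[name] = np.stack([c["phi"][:, j] for c in chains])
    for j in range(k):
        draws[f"log_lambda_{j}"] = np.stack([np.log(c["lam"][:, j]) for c in chains])
    lp_trace = np.stack([c["lp"] for c in chains])

    n_total = mcmc.chains * mcmc.iterations
    u_mean = sum(c["u_sum"] for c in chains) / n_total
    u_var = np.maximum(sum(c["u_sq"] for c in chains) / n_total - u_mean**2, 0.0)
    latent = pd.DataFrame(
        {
            "person_id": data.person_ids,
            "u0_hat": u_mean[:, 0],
            "u0_sd": np.sqrt(u_var[:, 0]),
            "u1_hat": u_mean[:, 1],
            "u1_sd": np.sqrt(u_var[:, 1]),
        }
    )
    meta = {
        "model": "joint",
        "spec": spec.__dict__ | {},
        "settings": mcmc.__dict__ | {},
        "n_obs": data.n_obs,
        "n_persons": data.n_persons,
        "fingerprint": data.fingerprint,
        "age_range": data.age_range,
        "fixed_names": data.fixed_names,
        "cuts": list(cuts),
        "events": int(events.sum()),
        "coef_names": phi_names,
    }
    summary = summarize_draws(draws, meta, keep_draws=keep_draws)
    return JointFitResult(summary=summary, latent=latent, lp_trace=lp_trace)


def _joint_init(data: PanelData, init: dict | None, phi_names: list) -> dict:
    p = len(data.fixed_names)
    if init is None:
        beta, *_ = np.linalg.lstsq(data.x, data.y, rcond=None)
        resid = data.y - data.x @ beta
        return {
            "beta": beta,
            "sigma2": max(float(resid.var()), 1e-6),
            "re_cov": np.diag([max(float(resid.var()), 1e-3), 0.01]),
            "u": np.zeros((data.n_persons, 2)),
            "phi": np.zeros(len(phi_names)),
        }
    beta = np.asarray(init["beta"], dtype=float)
    if beta.size != p:
        raise ValueError(
            f"initialization mismatch for fixed effects: got {beta.size} values, "
            f"model has {data.fixed_names}"
        )
    re_cov = np.asarray(init["re_cov"], dtype=float)
    if re_cov.shape != (2, 2):
        raise ValueError("initialization mismatch for re_cov: expected a 2x2 matrix")
    u = np.zeros((data.n_persons, 2))
    scores = init.get("scores")
    if scores is not None:
        merged = pd.DataFrame({"person_id": data.person_ids}).merge(
            scores, on="person_id", how="left"
        )
        u[:, 0] = merged["u0_hat"].fillna(0.0).to_numpy()
        u[:, 1] = merged["u1_hat"].fillna(0.0).to_numpy()
    phi = np.zeros(len(phi_names))
    for name, val in (init.get("phi") or {}).items():
        if name not in phi_names:
            raise ValueError(f"initialization mismatch: unknown coefficient {name}")
        phi[phi_names.index(name)] = val
    return {"beta": beta, "sigma2": float(init["sigma2"]), "re_cov": re_cov,
            "u": u, "phi": phi}


def _joint_chain(data, events, times, expo, interval, d_k, w, phi_names, start,
                 gp: GrowthPriors, hp: PHPriors, mcmc: MCMCSettings,
                 rng: np.random.Generator):
    n = data.n_persons
    ni, sa, saa = _lmm.person_design_stats(data.pid_idx, data.age, n)
    xtx = data.x.T @ data.x
    p = len(data.fixed_names)
    k = d_k.size
    q = w.shape[1]

    beta = start["beta"] + 0.05 * rng.standard_normal(p) * (1.0 + np.abs(start["beta"]))
    sigma2 = start["sigma2"] * float(rng.uniform(0.8, 1.25))
    re_cov = np.array(start["re_cov"], dtype=float)
    u = np.array(start["u"], dtype=float)
    phi = np.array(start["phi"], dtype=float) + 0.01 * rng.standard_normal(2 + q)

    log_lam_events = None  # filled after each lam update
    sampler = ComponentwiseMH(2 + q, scales=np.r_[[0.05, 0.2], np.full(q, 0.05)])

    out = {
        "beta": np.empty((mcmc.iterations, p)),
        "vars": np.empty((mcmc.iterations, 4)),
        "phi": np.empty((mcmc.iterations, 2 + q)),
        "lam": np.empty((mcmc.iterations, k)),
        "lp": np.empty(mcmc.iterations),
        "u_sum": np.zeros((n, 2)),
        "u_sq": np.zeros((n, 2)),
    }

    lam = np.maximum(d_k, 0.5) / np.maximum(expo.sum(axis=0), 1e-12)
    h0 = expo @ lam
    gw = w @ phi[2:] if q else np.zeros(n)

    for it in range(mcmc.iterations + mcmc.burn_in):
        # --- latent effects: longitudinal conditional as independence
        # proposal, accepted against each person's survival factor
        resid = data.y - data.x @ beta
        m, chol = _lmm.re_conditional(resid, data.pid_idx, data.age, ni, sa, saa,
                                      sigma2, re_cov)
        u_prop = _lmm.draw_bivariate(m, chol, rng)
        a_cur = phi[0] * u[:, 0] + phi[1] * u[:, 1]
        a_prop = phi[0] * u_prop[:, 0] + phi[1] * u_prop[:, 1]
        base = h0 * np.exp(gw)
        log_ratio = events * (a_prop - a_cur) - base * (np.exp(a_prop) - np.exp(a_cur))
        accept = np.log(rng.random(n)) < log_ratio
        u[accept] = u_prop[accept]

        # --- growth model conditional updates (conjugate)
        zu = u[data.pid_idx, 0] + u[data.pid_idx, 1] * data.age
        beta = _lmm.draw_fixed_effects(xtx, lambda r: data.x.T @ r, data.y - zu,
                                       sigma2, gp.beta_sd, rng)
        resid = data.y - data.x @ beta - zu
        sigma2 = _lmm.draw_sigma2(resid, gp.resid_a, gp.resid_b, rng)
        re_cov = _lmm.draw_re_cov(u, gp.iw_df, gp.iw_scale, rng)

        # translation move (B0, B1) += delta, u -= delta: proposed from its
        # survival-free conditional, accepted against the survival factor
        # (the proposal construction cancels all other terms exactly)
        if p >= 2:
            mean, cholT = _lmm.translation_conditional(beta[:2], u, re_cov,
                                                       gp.beta_sd)
            delta = mean + cholT @ rng.standard_normal(2)
            a_delta = phi[0] * delta[0] + phi[1] * delta[1]
            s = h0 * np.exp(gw + phi[0] * u[:, 0] + phi[1] * u[:, 1])
            log_ratio = -events.sum() * a_delta - (np.exp(-a_delta) - 1.0) * s.sum()
            if np.log(rng.random()) < log_ratio:
                beta[:2] += delta
                u -= delta

        # --- baseline hazard levels (conjugate gamma)
        eta = gw + phi[0] * u[:, 0] + phi[1] * u[:, 1]
        exp_eta = np.exp(eta)
        lam = rng.gamma(hp.lam_a + d_k) / (hp.lam_b + expo.T @ exp_eta)
        lam = np.maximum(lam, 1e-300)
        h0 = expo @ lam
        log_lam_events = np.log(lam)[interval]

        # --- shared and covariate coefficients (adaptive MH)
        x_surv = np.column_stack([u, w]) if q else u

        def phi_logpost(ph, _j):
            e = x_surv @ ph
            return float(
                np.sum(events * e) - np.sum(h0 * np.exp(e))
                - 0.5 * np.sum((ph / hp.beta_sd) ** 2)
            )

        lp_phi = phi_logpost(phi, None)
        phi, lp_phi = sampler.step(phi, phi_logpost, lp_phi, rng,
                                   adapt=it < mcmc.burn_in)
        gw = w @ phi[2:] if q else np.zeros(n)

        j = it - mcmc.burn_in
        if j >= 0:
            out["beta"][j] = beta
            corr = re_cov[0, 1] / np.sqrt(re_cov[0, 0] * re_cov[1, 1])
            out["vars"][j] = (re_cov[0, 0], re_cov[1, 1], corr, sigma2)
            out["phi"][j] = phi
            out["lam"][j] = lam
            out["u_sum"] += u
            out["u_sq"] += u * u
            out["lp"][j] = _fast_joint_lp(
                data, beta, sigma2, re_cov, u, phi, lam, events, times, h0,
                log_lam_events, x_surv, d_k, gp, hp
            )
    return out


def _fast_joint_lp(data, beta, sigma2, re_cov, u, phi, lam, events, times, h0,
                   log_lam_events, x_surv, d_k, gp: GrowthPriors, hp: PHPriors):
    """Joint log-posterior in plain numpy (for the trace)."""
    n_obs = data.n_obs
    n = u.shape[0]
    resid = data.y - data.x @ beta - u[data.pid_idx, 0] - u[data.pid_idx, 1] * data.age
    ll = -0.5 * (n_obs * np.log(2 * np.pi * sigma2) + float(resid @ resid) / sigma2)
    q = np.linalg.inv(re_cov)
    _, logdet = np.linalg.slogdet(re_cov)
    quad = float(np.einsum("ij,jk,ik->", u, q, u))
    ll += -0.5 * (n * (2.0 * np.log(2 * np.pi) + logdet) + quad)
    eta = x_surv @ phi
    ll += float(np.sum(events * (log_lam_events + eta)) - np.sum(h0 * np.exp(eta)))
    # priors
    ll += -0.5 * float(beta @ beta) / gp.beta_sd**2 - beta.size * np.log(
        gp.beta_sd * np.sqrt(2 * np.pi)
    )
    ll += (
        gp.resid_a * np.log(gp.resid_b)
        - gammaln(gp.resid_a)
        - (gp.resid_a + 1) * np.log(sigma2)
        - gp.resid_b / sigma2
    )
    ll += _invwishart_logpdf(re_cov, gp.iw_df, np.asarray(gp.iw_scale))
    ll += float(
        np.sum((hp.lam_a - 1) * np.log(lam) - hp.lam_b * lam)
        + lam.size * (hp.lam_a * np.log(hp.lam_b) - gammaln(hp.lam_a))
    )
    ll += -0.5 * float(phi @ phi) / hp.beta_sd**2 - phi.size * np.log(
        hp.beta_sd * np.sqrt(2 * np.pi)
    )
    return ll


def _invwishart_logpdf(x, df, scale):
    d = x.shape[0]
    _, logdet_s = np.linalg.slogdet(scale)
    _, logdet_x = np.linalg.slogdet(x)
    tr = float(np.trace(np.linalg.solve(x, scale)))
    mvgamma = d * (d - 1) / 4 * np.log(np.pi) + sum(
        gammaln(df / 2 + (1 - j) / 2) for j in range(1, d + 1)
    )
    return (
        df / 2 * logdet_s
        - df * d / 2 * np.log(2)
        - mvgamma
        - (df + d + 1) / 2 * logdet_x
        - 0.5 * tr
    )


def extract_shared_association(fit: JointFitResult) -> pd.DataFrame:
    """Posterior mean and 95% CI for alpha1 and alpha2, flagged significant
    when the interval excludes zero."""
    rows = []
    for name in ("alpha1", "alpha2"):
        lo, hi = fit.summary.ci(name)
        rows.append(
            {
                "param": name,
                "mean": fit.summary.mean(name),
                "ci_low": lo,
                "ci_high": hi,
                "significant": bool(lo > 0 or hi < 0),
            }
        )
    return pd.DataFrame(rows).set_index("param")
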