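"""Independent brute-force references used only by the tests.

These deliberately avoid the package's likelihood code paths: densities are
taken from scipy one term at a time and cumulative hazards are obtained by
numerical integration of the hazard function.
"""

import numpy as np
from scipy import integrate, stats


def step_hazard_fn(cuts, levels):
    cuts = np.asarray(cuts, dtype=float)
    levels = np.asarray(levels, dtype=float)

    def h(t):
        return levels[np.searchsorted(cuts, t, side="right")]

    return h


def numeric_cum_hazard(cuts, levels, t):
    h = step_hazard_fn(cuts, levels)
    val, _ = integrate.quad(h, 0.0, t, points=[c for c in cuts if c < t], limit=200)
    return val


def brute_force_joint_lp(growth, coefs, baseline, u, panel, cohort, adjusted,
                         growth_priors, hazard_priors):
    """Direct density-product evaluation of the joint log-posterior."""
    person_ids = np.sort(panel["person_id"].unique())
    uu = {pid: u[i] for i, pid in enumerate(person_ids)}
    cov_by_pid = cohort.set_index("person_id")

    total = 0.0
    # longitudinal observation terms
    for row in panel.itertuples():
        c = cov_by_pid.loc[row.person_id]
        a = row.age_c
        mean = growth.b0 + growth.b1 * a + growth.b2 * a * a
        if adjusted:
            mean += (
                growth.b3 * c["start_age_c"]
                + growth.b4 * c["start_age_c"] * a
                + growth.b5 * c["smoker"]
                + growth.b6 * (c["srh"] - 3.0)
            )
        mean += uu[row.person_id][0] + uu[row.person_id][1] * a
        total += stats.norm.logpdf(row.score, mean, np.sqrt(growth.var_resid))

    # random-effect density and survival terms, per person
    for pid in person_ids:
        c = cov_by_pid.loc[pid]
        total += stats.multivariate_normal.logpdf(uu[pid], np.zeros(2), growth.re_cov)
        eta = coefs["alpha1"] * uu[pid][0] + coefs["alpha2"] * uu[pid][1]
        if adjusted:
            eta += (
                coefs["gamma_start_age"] * c["start_age_c"]
                + coefs["gamma_smoker"] * c["smoker"]
                + coefs["gamma_srh"] * (c["srh"] - 3.0)
            )
        t = float(c["time"])
        h = step_hazard_fn(baseline.cuts, baseline.levels)
        cum = numeric_cum_hazard(baseline.cuts, baseline.levels, t)
        if c["event"] == 1:
            total += np.log(h(t)) + eta
        total -= cum * np.exp(eta)

    # priors
    beta = growth.fixed_effects(adjusted)[: 7 if adjusted else 3]
    total += np.sum(stats.norm.logpdf(beta, 0.0, growth_priors.beta_sd))
    total += stats.invgamma.logpdf(growth.var_resid, growth_priors.resid_a,
                                   scale=growth_priors.resid_b)
    total += stats.invwishart.logpdf(growth.re_cov, growth_priors.iw_df,
                                     np.asarray(growth_priors.iw_scale))
    lam = np.asarray(baseline.levels)
    total += np.sum(stats.gamma.logpdf(lam, hazard_priors.lam_a,
                                       scale=1.0 / hazard_priors.lam_b))
    names = ["alpha1", "alpha2"] + (
        ["gamma_start_age", "gamma_smoker", "gamma_srh"] if adjusted else []
    )
    coef_vec = np.array([coefs[n] for n in names])
    total += np.sum(stats.norm.logpdf(coef_vec, 0.0, hazard_priors.beta_sd))
    return float(total)
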