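"""Conjugate building blocks for the Gaussian growth model.

Everything here is conditional on the person-level effects u, which makes
all updates closed-form: the fixed effects and residual variance are
normal/inverse-gamma, the random-effect covariance is inverse-Wishart, and
the per-person conditional for (u0, u1) is bivariate normal with 2x2
precision, solved explicitly so the update vectorizes over persons.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def person_design_stats(pid_idx, age, n_persons):
    """Per-person sufficient statistics of the random-effect design:
    counts, sum of ages and sum of squared ages."""
    ni = np.bincount(pid_idx, minlength=n_persons).astype(float)
    sa = np.bincount(pid_idx, weights=age, minlength=n_persons)
    saa = np.bincount(pid_idx, weights=age * age, minlength=n_persons)
    return ni, sa, saa


def re_conditional(resid, pid_idx, age, ni, sa, saa, sigma2, re_cov):
    """Conditional N(m_i, C_i) of (u0_i, u1_i) given everything else.

    Returns means (n, 2) and the Cholesky entries (l00, l10, l11) of C_i so
    callers can either draw from the conditional (Gibbs) or use it as an
    independence proposal (joint sampler).
    """
    q = np.linalg.inv(re_cov)
    sr = np.bincount(pid_idx, weights=resid, minlength=ni.size)
    sar = np.bincount(pid_idx, weights=age * resid, minlength=ni.size)
    p00 = ni / sigma2 + q[0, 0]
    p01 = sa / sigma2 + q[0, 1]
    p11 = saa / sigma2 + q[1, 1]
    det = p00 * p11 - p01 * p01
    c00, c01, c11 = p11 / det, -p01 / det, p00 / det
    b0, b1 = sr / sigma2, sar / sigma2
    m = np.column_stack([c00 * b0 + c01 * b1, c01 * b0 + c11 * b1])
    l00 = np.sqrt(c00)
    l10 = c01 / l00
    l11 = np.sqrt(np.maximum(c11 - l10 * l10, 1e-300))
    return m, (l00, l10, l11)


def draw_bivariate(m, chol, rng):
    l00, l10, l11 = chol
    z0 = rng.standard_normal(m.shape[0])
    z1 = rng.standard_normal(m.shape[0])
    return np.column_stack([m[:, 0] + l00 * z0, m[:, 1] + l10 * z0 + l11 * z1])


def re_conditional_intercept(resid, pid_idx, ni, sigma2, var_u0):
    sr = np.bincount(pid_idx, weights=resid, minlength=ni.size)
    var = 1.0 / (ni / sigma2 + 1.0 / var_u0)
    return var * sr / sigma2, var


def draw_fixed_effects(xtx, xty_fn, resid_target, sigma2, beta_sd, rng):
    """Conjugate normal draw of B given u; ``resid_target`` is y - Zu."""
    p = xtx.shape[0]
    prec = xtx / sigma2 + np.eye(p) / beta_sd**2
    rhs = xty_fn(resid_target) / sigma2
    chol = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, rhs)
    z = rng.standard_normal(p)
    return mean + np.linalg.solve(chol.T, z)


def draw_sigma2(resid, a0, b0, rng):
    shape = a0 + 0.5 * resid.size
    rate = b0 + 0.5 * float(resid @ resid)
    return rate / rng.gamma(shape)


def draw_re_cov(u, iw_df, iw_scale, rng):
    scale = np.asarray(iw_scale) + u.T @ u
    df = iw_df + u.shape[0]
    return stats.invwishart.rvs(df, scale, random_state=rng)


def draw_var_u0(u0, a0, b0, rng):
    shape = a0 + 0.5 * u0.size
    rate = b0 + 0.5 * float(u0 @ u0)
    return rate / rng.gamma(shape)


def translation_conditional(beta01, u, re_cov, beta_sd):
    """Conditional of the shift delta in the move (B0, B1) += delta,
    u_i -= delta, which leaves the observation mean unchanged.

    Sampling this jointly with the standard updates breaks the strong
    posterior coupling between the fixed effects and the random-effect
    mean.  Returns (mean, cholesky factor of the 2x2 covariance).
    """
    n = u.shape[0]
    q = np.linalg.inv(re_cov)
    prec = n * q + np.eye(2) / beta_sd**2
    rhs = q @ u.sum(axis=0) - beta01 / beta_sd**2
    cov = np.linalg.inv(prec)
    return cov @ rhs, np.linalg.cholesky(cov)


def recenter(beta, u, re_cov, beta_sd, rng):
    """Gibbs translation move for the slope-and-intercept model (in place)."""
    mean, chol = translation_conditional(beta[:2], u, re_cov, beta_sd)
    delta = mean + chol @ rng.standard_normal(2)
    beta[:2] += delta
    u -= delta
    return delta


def recenter_intercept(beta, u0, var_u0, beta_sd, rng):
    """Translation move for the intercept-only model (in place)."""
    n = u0.size
    prec = n / var_u0 + 1.0 / beta_sd**2
    mean = (u0.sum() / var_u0 - beta[0] / beta_sd**2) / prec
    delta = mean + rng.standard_normal() / np.sqrt(prec)
    beta[0] += delta
    u0 -= delta
    return delta


def marginal_loglik(beta, re_cov, sigma2, y, x, age, starts, re_slope=True):
    """Log-likelihood with u integrated out: y_i ~ N(X_i B, Z_i G Z_i' + s2 I).

    ``starts`` delimits each person's contiguous block of rows (data must be
    sorted by person).
    """
    resid = y - x @ beta
    total = 0.0
    for i in range(starts.size - 1):
        sl = slice(starts[i], starts[i + 1])
        r = resid[sl]
        a = age[sl]
        z = np.column_stack([np.ones(a.size), a]) if re_slope else np.ones((a.size, 1))
        g = re_cov if re_slope else np.atleast_2d(re_cov)[:1, :1]
        v = z @ g @ z.T + sigma2 * np.eye(a.size)
        chol = np.linalg.cholesky(v)
        w = np.linalg.solve(chol, r)
        total += -0.5 * (
            a.size * np.log(2.0 * np.pi)
            + 2.0 * np.log(np.diag(chol)).sum()
            + float(w @ w)
        )
    return total
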