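"""Derived quantities and comparison reports.

Covers the scaled hazard ratios (risk change per 1 SD of a predictor),
credible-interval width contrasts between frameworks, standardized decline
per decade, occasion-level panel summaries, and MCMC diagnostics.  All
reporting is pure: every table regenerates byte-identically from stored fit
artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mcmc import ESS_LIMIT, RHAT_LIMIT, PosteriorSummary

__all__ = [
    "scaled_hazard_ratio",
    "ci_width_contrast",
    "DeltaZConvention",
    "delta_z_per_decade",
    "summarize_panel",
    "mcmc_diagnostics",
]


def scaled_hazard_ratio(coef: float, sd: float) -> float:
    """Hazard ratio for a 1-SD increase of a predictor: exp(coef * sd)."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    return float(np.exp(coef * sd))


def ci_width_contrast(fit_a: PosteriorSummary, fit_b: PosteriorSummary,
                      params) -> dict:
    """Per-parameter ratio of 95% CI widths, width_a / width_b."""
    out = {}
    for name in params:
        for fit, label in ((fit_a, "first"), (fit_b, "second")):
            if name not in fit.table.index:
                raise ValueError(f"parameter {name!r} missing from {label} fit")
        out[name] = fit_a.ci_width(name) / fit_b.ci_width(name)
    return out


@dataclass(frozen=True)
class DeltaZConvention:
    """How standardized change per decade is computed: the model-implied raw
    change over ``window`` (chronological ages, default 70 to 80) at the
    covariate reference, divided by ``sd_ref``.  With ``sd_ref=None`` the
    baseline between-person score SD, sqrt(var_u0 + var_resid), is used
    draw by draw."""

    window: tuple = (70.0, 80.0)
    sd_ref: float | None = None
    start_age_c: float = 0.0


def delta_z_per_decade(fit: PosteriorSummary,
                       convention: DeltaZConvention = DeltaZConvention()) -> dict:
    """Standardized change in the fixed-effect trajectory per decade.

    Returns the posterior mean and 95% CI together with the convention
    used, so that alternative windows can be reported side by side.
    """
    a1, a2 = convention.window
    lo, hi = fit.meta.get("age_range", (50.0, 87.0))
    if a1 < lo - 1e-9 or a2 > hi + 1e-9:
        warnings.warn("delta-z window extends beyond the fitted age support",
                      stacklevel=2)
    draws = fit.require_draws()
    c1, c2 = a1 - 65.0, a2 - 65.0
    names = fit.meta["fixed_names"]
    change = np.zeros_like(np.ravel(draws[names[0]]), dtype=float)
    if "B1" in names:
        change = change + np.ravel(draws["B1"]) * (c2 - c1)
    if "B2" in names:
        change = change + np.ravel(draws["B2"]) * (c2**2 - c1**2)
    if "B4" in names:
        change = change + np.ravel(draws["B4"]) * convention.start_age_c * (c2 - c1)
    if convention.sd_ref is not None:
        sd = convention.sd_ref
    else:
        sd = np.sqrt(np.ravel(draws["var_u0"]) + np.ravel(draws["var_resid"]))
    z = change / sd
    return {
        "mean": float(np.mean(z)),
        "ci_low": float(np.quantile(z, 0.025)),
        "ci_high": float(np.quantile(z, 0.975)),
        "window": (a1, a2),
        "sd_ref": "baseline_total_sd" if convention.sd_ref is None else convention.sd_ref,
    }


def summarize_panel(panel: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Occasion-level summary per domain and stratum: sample size,
    cumulative deaths, median age and mean score.

    Cumulative deaths at occasion k count cohort members who died before
    the stratum's median time-on-study of that occasion; occasions with no
    observations are omitted.
    """
    merged = panel.merge(cohort[["person_id", "sex", "start_age_c", "time", "event"]],
                         on="person_id", validate="many_to_one")
    merged["years_in"] = merged["age_c"] - merged["start_age_c"]
    rows = []
    for (domain, sex), grp in merged.groupby(["domain", "sex"]):
        base = cohort[(cohort["sex"] == sex)]
        if "domain" in cohort.columns:
            base = base[base["domain"] == domain]
        for occ, g in grp.groupby("occasion"):
            t_occ = float(g["years_in"].median())
            dead = int(((base["event"] == 1) & (base["time"] <= t_occ)).sum())
            rows.append(
                {
                    "domain": domain,
                    "stratum": sex,
                    "occasion": int(occ),
                    "n": int(len(g)),
                    "cum_deaths": dead,
                    "median_age": float(g["age_c"].median() + 65.0),
                    "mean_score": float(g["score"].mean()),
                }
            )
    return (
        pd.DataFrame(rows)
        .sort_values(["domain", "stratum", "occasion"])
        .reset_index(drop=True)
    )


def mcmc_diagnostics(fit: PosteriorSummary, out_dir=None, params=None) -> pd.DataFrame:
    """Scalar convergence table, optionally with trace / autocorrelation /
    density plots written to ``out_dir`` (one PNG per parameter).

    Raises if the fit was run without retaining draws.
    """
    draws = fit.require_draws()
    names = list(params) if params is not None else list(draws)
    table = fit.table.loc[[n for n in names if n in fit.table.index]].copy()
    table["rhat_ok"] = table["rhat"] < RHAT_LIMIT
    table["ess_ok"] = table["ess"] > ESS_LIMIT
    table["converged"] = table["rhat_ok"] & table["ess_ok"]
    if out_dir is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in table.index:
            arr = np.asarray(draws[name])
            fig, axes = plt.subplots(1, 3, figsize=(10, 2.6))
            for chain in arr:
                axes[0].plot(chain, lw=0.5)
                axes[2].hist(chain, bins=40, histtype="step", density=True)
            axes[0].set_title(f"trace: {name}")
            acf = autocorrelation(arr[0], max_lag=min(50, arr.shape[1] - 1))
            axes[1].bar(np.arange(acf.size), acf, width=0.8)
            axes[1].set_title("autocorrelation")
            axes[2].set_title("density")
            fig.tight_layout()
            fig.savefig(out / f"{name}.png", dpi=100)
            plt.close(fig)
    return table


def autocorrelation(x: np.ndarray, max_lag: int = 50) -> np.ndarray:
    """Sample autocorrelation function at lags 0..max_lag."""
    x = np.asarray(x, dtype=float) - np.mean(x)
    denom = float(x @ x)
    if denom == 0:
        return np.zeros(max_lag + 1)
    return np.array([float(x[: x.size - k] @ x[k:]) / denom for k in range(max_lag + 1)])
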