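"""Synthetic cohort generator emulating an aging-cohort repeated-measures design.

The generator reproduces the design of a large longitudinal study of
cognitive aging: ~70.5% women, entry ages with median 65 (IQR 60-70,
truncated to 50-87), ~24.7% smokers, self-rated health on a 1-5 scale, up to
four assessment occasions at roughly 4-year gaps, and administrative
censoring of mortality follow-up 29 years after entry (by which point ~75%
of participants have died).

Cognitive factor scores follow the quadratic growth model of
:mod:`cogsurv.params` and death times are drawn by inverse-transform
sampling from the shared-random-effects proportional hazard, so
death-related dropout is missing-not-at-random whenever alpha1 or alpha2 is
non-zero.  Crystallized (Gc) and fluid (Gf) ability cohorts are generated
independently, mirroring the per-domain analyses downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .hazards import PiecewiseConstantHazard, sample_survival_time
from .params import ConfigError, GrowthParams, HazardParams

__all__ = [
    "SimConfig",
    "simulate_cohort",
    "truncate_panel",
    "default_config",
    "recovery_config",
    "covariate_linked_config",
    "default_growth_truth",
    "default_hazard_truth",
]

_BASELINE_CUTS = (5.0, 10.0, 15.0, 20.0, 25.0)
#: hazard level ratio between adjacent 5-year bands; mortality roughly doubles
#: every 7-8 years of age, i.e. a factor ~1.55 per 5 years
_GOMPERTZ_STEP = 1.55


def _gompertz_baseline(base_rate: float) -> PiecewiseConstantHazard:
    levels = tuple(base_rate * _GOMPERTZ_STEP**k for k in range(len(_BASELINE_CUTS) + 1))
    return PiecewiseConstantHazard(_BASELINE_CUTS, levels)


def default_growth_truth() -> dict:
    """Growth-model truth per (sex, domain), set to the joint-model estimates
    from the motivating cohort (unadjusted quadratic-change models)."""
    return {
        ("women", "Gc"): GrowthParams(-0.18, 0.06, -0.01, var_u0=74.27, var_u1=0.32,
                                      corr_u0u1=0.07, var_resid=1.12),
        ("men", "Gc"): GrowthParams(1.82, 0.08, -0.01, var_u0=69.50, var_u1=0.47,
                                    corr_u0u1=0.08, var_resid=1.11),
        ("women", "Gf"): GrowthParams(0.08, 0.04, -0.02, var_u0=71.75, var_u1=0.09,
                                      corr_u0u1=-0.07, var_resid=0.95),
        ("men", "Gf"): GrowthParams(2.66, 0.05, -0.02, var_u0=74.09, var_u1=0.12,
                                    corr_u0u1=-0.06, var_resid=1.04),
    }


# Baseline rates calibrated (once, numerically) so that with the default
# truth above ~71% of women and ~84% of men die before the 29-year census,
# i.e. ~74.8% overall at 70.5% women.
_DEFAULT_BASE_RATE = {
    ("women", "Gc"): 0.01141,
    ("men", "Gc"): 0.01874,
    ("women", "Gf"): 0.01149,
    ("men", "Gf"): 0.01810,
}


def default_hazard_truth() -> dict:
    """Hazard truth per (sex, domain): shared-effect coefficients from the
    unadjusted joint fits, no covariate effects, Gompertz-like baseline."""
    alphas = {
        ("women", "Gc"): (-0.009, -0.234),
        ("men", "Gc"): (0.000, -0.755),
        ("women", "Gf"): (-0.005, -1.294),
        ("men", "Gf"): (-0.010, -1.266),
    }
    return {
        key: HazardParams(
            baseline=_gompertz_baseline(_DEFAULT_BASE_RATE[key]),
            gamma=None,
            alpha1=a1,
            alpha2=a2,
        )
        for key, (a1, a2) in alphas.items()
    }


@dataclass(frozen=True)
class SimConfig:
    """Full specification of a synthetic cohort; identical configs (including
    the seed) produce byte-identical outputs."""

    n_individuals: int = 5954
    prop_women: float = 0.705
    entry_age_median: float = 65.0
    entry_age_iqr: tuple = (60.0, 70.0)
    entry_age_range: tuple = (50.0, 87.0)
    prop_smokers: float = 0.247
    #: probabilities of self-rated health 1 (poor) .. 5 (excellent);
    #: median 4, IQR 3-5 as in the emulated cohort
    srh_dist: tuple = (0.05, 0.10, 0.25, 0.30, 0.30)
    #: uniform bounds of the gap between assessments, years
    visit_gap_years: tuple = (3.0, 5.0)
    max_occasions: int = 4
    #: probability of returning for occasion k+1 given occasion k was
    #: completed (non-informative study dropout); calibrated so the mean
    #: number of completed occasions is ~2.2 under the default mortality
    continuation_probs: tuple = (0.682, 0.625, 0.552)
    census_horizon: float = 29.0
    domains: tuple = ("Gc", "Gf")
    growth_truth: dict = field(default_factory=default_growth_truth)
    hazard_truth: dict = field(default_factory=default_hazard_truth)
    #: optional dependence of self-rated health on the latent intercept
    #: (standardized units); 0 = independent
    srh_dependence: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prop_women", "prop_smokers"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.n_individuals < 1:
            raise ConfigError("n_individuals must be >= 1")
        srh = np.asarray(self.srh_dist, dtype=float)
        if srh.size != 5 or np.any(srh < 0) or abs(srh.sum() - 1.0) > 1e-9:
            raise ConfigError("srh_dist must be 5 non-negative probabilities summing to 1")
        if self.max_occasions < 1:
            raise ConfigError("max_occasions must be >= 1")
        if len(self.continuation_probs) < self.max_occasions - 1:
            raise ConfigError("continuation_probs must cover max_occasions - 1 gaps")
        if self.census_horizon <= 0:
            raise ConfigError("census_horizon must be positive")
        lo, hi = self.entry_age_range
        if not lo < hi:
            raise ConfigError("entry_age_range must be an increasing pair")
        q1, q3 = self.entry_age_iqr
        if not q1 < q3:
            raise ConfigError("entry_age_iqr must be an increasing pair")
        if not lo <= self.entry_age_median <= hi:
            raise ConfigError("entry_age_median must lie within entry_age_range")
        lo_g, hi_g = self.visit_gap_years
        if not 0 < lo_g <= hi_g:
            raise ConfigError("visit_gap_years must be a positive non-decreasing pair")
        for key in [(s, d) for d in self.domains for s in ("women", "men")]:
            if key not in self.growth_truth:
                raise ConfigError(f"growth_truth missing entry for {key}")
            if key not in self.hazard_truth:
                raise ConfigError(f"hazard_truth missing entry for {key}")

    def replace(self, **kw) -> "SimConfig":
        return replace(self, **kw)


def _psd_cholesky(cov: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(cov)
        return vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))


def _entry_age_sampler(config: SimConfig):
    q1, q3 = config.entry_age_iqr
    scale = (q3 - q1) / (stats.norm.ppf(0.75) - stats.norm.ppf(0.25))
    lo, hi = config.entry_age_range
    a = (lo - config.entry_age_median) / scale
    b = (hi - config.entry_age_median) / scale
    return stats.truncnorm(a, b, loc=config.entry_age_median, scale=scale)


def simulate_cohort(config: SimConfig):
    """Generate one synthetic cohort per configured domain.

    Returns ``(cohort, panel, latents)``:

    - cohort: one row per person - sex, centered entry age, smoker, SRH,
      event indicator and time from entry to death or administrative
      censoring at the census horizon;
    - panel: one row per completed assessment before death/census - occasion
      number, centered age at assessment, domain and factor score;
    - latents: the true (u0, u1) pairs, kept for recovery tests.

    Person ids are prefixed with the domain because domains are simulated as
    independent cohorts.
    """
    rng = np.random.default_rng(config.seed)
    cohorts, panels, latents = [], [], []
    for domain in config.domains:
        c, p, l = _simulate_domain(config, domain, rng)
        cohorts.append(c)
        panels.append(p)
        latents.append(l)
    cohort = pd.concat(cohorts, ignore_index=True)
    panel = pd.concat(panels, ignore_index=True)
    latent = pd.concat(latents, ignore_index=True)
    return cohort, truncate_panel(panel, cohort), latent


def _simulate_domain(config: SimConfig, domain: str, rng: np.random.Generator):
    n = config.n_individuals
    person_id = np.array([f"{domain}-{i:05d}" for i in range(n)])
    sex = np.where(rng.random(n) < config.prop_women, "women", "men")
    entry_age = _entry_age_sampler(config).rvs(size=n, random_state=rng)
    smoker = (rng.random(n) < config.prop_smokers).astype(int)

    # latent trajectory deviations, per sex stratum (degenerate covariances
    # with zero variance are allowed for noise-free checks)
    u = np.empty((n, 2))
    for s in ("women", "men"):
        mask = sex == s
        cov = config.growth_truth[(s, domain)].re_cov
        chol = _psd_cholesky(cov)
        u[mask] = rng.standard_normal((int(mask.sum()), 2)) @ chol.T

    # self-rated health: thresholded latent normal, optionally tilted by u0
    thresholds = stats.norm.ppf(np.cumsum(config.srh_dist)[:-1])
    z = rng.standard_normal(n)
    if config.srh_dependence:
        sd_u0 = np.array([np.sqrt(config.growth_truth[(s, domain)].var_u0) for s in sex])
        z = (z + config.srh_dependence * u[:, 0] / sd_u0) / np.sqrt(
            1.0 + config.srh_dependence**2
        )
    srh = 1 + np.searchsorted(thresholds, z)

    cohort = pd.DataFrame(
        {
            "person_id": person_id,
            "domain": domain,
            "sex": sex,
            "start_age_c": entry_age - 65.0,
            "smoker": smoker,
            "srh": srh,
        }
    )

    # death time by inverse-transform sampling of the shared-effect hazard
    death = np.empty(n)
    for s in ("women", "men"):
        mask = sex == s
        hp = config.hazard_truth[(s, domain)]
        lin = hp.linear_predictor(cohort[mask], u0=u[mask, 0], u1=u[mask, 1])
        death[mask] = sample_survival_time(1.0 - rng.random(int(mask.sum())), lin,
                                           hp.baseline)
    event = death <= config.census_horizon
    cohort["event"] = event.astype(int)
    cohort["time"] = np.where(event, death, config.census_horizon)

    # assessment schedule: first visit at entry, then ~4-year gaps, with
    # monotone non-informative dropout between occasions
    m = config.max_occasions
    gaps = rng.uniform(*config.visit_gap_years, size=(n, max(m - 1, 1)))
    visit_t = np.concatenate([np.zeros((n, 1)), np.cumsum(gaps, axis=1)], axis=1)[:, :m]
    cont = np.ones((n, m), dtype=bool)
    for k in range(1, m):
        cont[:, k] = cont[:, k - 1] & (rng.random(n) < config.continuation_probs[k - 1])

    rows = []
    for s in ("women", "men"):
        mask = sex == s
        gp = config.growth_truth[(s, domain)]
        age_c = entry_age[mask, None] + visit_t[mask] - 65.0
        mean = (
            gp.b0
            + gp.b1 * age_c
            + gp.b2 * age_c**2
            + gp.b3 * (entry_age[mask, None] - 65.0)
            + gp.b4 * (entry_age[mask, None] - 65.0) * age_c
            + gp.b5 * smoker[mask, None]
            + gp.b6 * (srh[mask, None] - 3.0)
        )
        noise = rng.standard_normal(age_c.shape) * np.sqrt(gp.var_resid)
        score = mean + u[mask, 0][:, None] + u[mask, 1][:, None] * age_c + noise
        keep = cont[mask]
        pid = person_id[mask]
        occ = np.broadcast_to(np.arange(1, m + 1), keep.shape)
        rows.append(
            pd.DataFrame(
                {
                    "person_id": np.repeat(pid, keep.sum(axis=1)),
                    "occasion": occ[keep],
                    "age_c": age_c[keep],
                    "domain": domain,
                    "score": score[keep],
                }
            )
        )
    panel = pd.concat(rows, ignore_index=True)
    panel = panel.sort_values(["person_id", "occasion"], kind="stable").reset_index(drop=True)

    latent = pd.DataFrame(
        {"person_id": person_id, "domain": domain, "sex": sex, "u0": u[:, 0], "u1": u[:, 1]}
    )
    return cohort, panel, latent


def truncate_panel(panel: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Drop assessments scheduled after death or censoring.

    Implements the death-related (MNAR) dropout mechanism: a person
    contributes observations only while alive and under follow-up, so the
    retained ages satisfy age <= entry age + follow-up time.
    """
    orphans = sorted(set(panel["person_id"]) - set(cohort["person_id"]))
    if orphans:
        raise ValueError(f"panel contains ids absent from cohort: {orphans[:10]}")
    merged = panel.merge(cohort[["person_id", "start_age_c", "time"]], on="person_id",
                         how="left", validate="many_to_one")
    keep = (merged["age_c"] - merged["start_age_c"]) <= merged["time"] + 1e-9
    return panel.loc[keep.to_numpy()].reset_index(drop=True)


def default_config(seed: int = 0, **kw) -> SimConfig:
    """The emulated study design at full scale."""
    return SimConfig(seed=seed, **kw)


# Recovery-harness baseline rate, calibrated so ~60% die before census
_RECOVERY_BASE_RATE = 0.00840


def recovery_config(seed: int = 0, n: int = 1000) -> SimConfig:
    """Single-stratum, single-domain cohort at realistic published-scale truth for
    parameter-recovery simulations (~60% deaths, alpha2 = -1)."""
    growth = GrowthParams(0.1, 0.04, -0.02, var_u0=72.0, var_u1=0.09,
                          corr_u0u1=-0.07, var_resid=0.95)
    hazard = HazardParams(baseline=_gompertz_baseline(_RECOVERY_BASE_RATE),
                          gamma=None, alpha1=-0.005, alpha2=-1.0)
    truth_keys = [("women", "Gf"), ("men", "Gf")]
    return SimConfig(
        n_individuals=n,
        prop_women=1.0,
        domains=("Gf",),
        growth_truth={k: growth for k in truth_keys},
        hazard_truth={k: hazard for k in truth_keys},
        seed=seed,
    )


# Covariate-linked baseline rate (criterion: smoking/SRH affect both the
# scores and the hazard), calibrated to ~70% deaths
_COVLINKED_BASE_RATE = 0.01225


def covariate_linked_config(seed: int = 0, n: int = 2000) -> SimConfig:
    """Cohort in which smoking and self-rated health affect both cognition
    and mortality, on top of a latent-intercept (MNAR) mortality link."""
    growth = GrowthParams(0.1, 0.04, -0.02, b5=-2.0, b6=1.5, var_u0=72.0,
                          var_u1=0.09, corr_u0u1=-0.07, var_resid=0.95)
    hazard = HazardParams(
        baseline=_gompertz_baseline(_COVLINKED_BASE_RATE),
        gamma={"start_age_c": 0.05, "smoker": 0.6, "srh_c": -0.3},
        alpha1=-0.02,
        alpha2=-0.5,
    )
    truth_keys = [("women", "Gf"), ("men", "Gf")]
    return SimConfig(
        n_individuals=n,
        prop_women=1.0,
        domains=("Gf",),
        growth_truth={k: growth for k in truth_keys},
        hazard_truth={k: hazard for k in truth_keys},
        seed=seed,
    )
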