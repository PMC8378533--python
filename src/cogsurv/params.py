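"""Parameter containers for the growth and hazard sub-models.

The quadratic growth model for a cognitive factor score Y at (centered) age a is

    Y = B0 + B1*a + B2*a^2 + B3*sa + B4*sa*a + B5*smoker + B6*srh_c
        + u0 + u1*a + e,

with ``sa`` the centered entry age, ``srh_c`` self-rated health centered at 3,
(u0, u1) a zero-mean bivariate-normal pair of person-level deviations in level
and linear change, and e Gaussian residual noise.  The proportional-hazards
model for mortality is

    h(t) = h0(t) * exp(gamma' w + alpha1*u0 + alpha2*u1),

where w collects baseline covariates and (alpha1, alpha2) tie the hazard to
the person's latent trajectory - the shared-random-effects association.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .hazards import PiecewiseConstantHazard

__all__ = ["ConfigError", "GrowthParams", "HazardParams", "GAMMA_COVARIATES"]

#: canonical order of baseline covariates in the hazard linear predictor
GAMMA_COVARIATES = ("start_age_c", "smoker", "srh_c")


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


@dataclass(frozen=True)
class GrowthParams:
    """Fixed effects, random-effect covariance and residual variance."""

    b0: float = 0.0
    b1: float = 0.0
    b2: float = 0.0
    b3: float = 0.0  # entry-age effect
    b4: float = 0.0  # entry-age x linear-change interaction
    b5: float = 0.0  # smoker effect
    b6: float = 0.0  # self-rated-health effect
    var_u0: float = 1.0
    var_u1: float = 0.01
    corr_u0u1: float = 0.0
    var_resid: float = 1.0

    def __post_init__(self) -> None:
        for name in ("var_u0", "var_u1", "var_resid"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not -1.0 <= self.corr_u0u1 <= 1.0:
            raise ConfigError("corr_u0u1 must lie in [-1, 1]")

    @property
    def re_cov(self) -> np.ndarray:
        c = self.corr_u0u1 * np.sqrt(self.var_u0 * self.var_u1)
        return np.array([[self.var_u0, c], [c, self.var_u1]])

    def fixed_effects(self, adjusted: bool = True) -> np.ndarray:
        if adjusted:
            return np.array([self.b0, self.b1, self.b2, self.b3, self.b4, self.b5, self.b6])
        return np.array([self.b0, self.b1, self.b2])

    def replace(self, **kw) -> "GrowthParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class HazardParams:
    """Baseline hazard, covariate coefficients and shared-effect coefficients."""

    baseline: PiecewiseConstantHazard = field(
        default_factory=lambda: PiecewiseConstantHazard((), (0.05,))
    )
    gamma: dict | None = None  # keys from GAMMA_COVARIATES; None = no covariates
    alpha1: float = 0.0
    alpha2: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma is not None:
            unknown = set(self.gamma) - set(GAMMA_COVARIATES)
            if unknown:
                raise ConfigError(f"gamma has unknown covariates: {sorted(unknown)}")

    def linear_predictor(self, cohort, u0=0.0, u1=0.0) -> np.ndarray:
        """gamma' w + alpha1*u0 + alpha2*u1 for each row of a cohort table."""
        lin = np.zeros(len(cohort))
        if self.gamma:
            for name, coef in self.gamma.items():
                col = cohort["srh"] - 3.0 if name == "srh_c" else cohort[name]
                lin = lin + coef * np.asarray(col, dtype=float)
        return lin + self.alpha1 * np.asarray(u0) + self.alpha2 * np.asarray(u1)

    def replace(self, **kw) -> "HazardParams":
        return replace(self, **kw)
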