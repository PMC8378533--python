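"""Baseline hazard specifications with closed-form cumulative hazards.

All baselines expose ``hazard``, ``cum_hazard`` and ``inverse_cum_hazard``,
which is what inverse-transform sampling of survival times and the
proportional-hazards likelihood need.  The piecewise-constant family is the
workhorse: its cumulative hazard is piecewise linear, so both the likelihood
and the sampling inversion are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConstantHazard",
    "WeibullHazard",
    "PiecewiseConstantHazard",
    "sample_survival_time",
]


@dataclass(frozen=True)
class ConstantHazard:
    """Exponential baseline: h0(t) = rate."""

    rate: float

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    def hazard(self, t):
        return np.full_like(np.asarray(t, dtype=float), self.rate)

    def cum_hazard(self, t):
        return self.rate * np.asarray(t, dtype=float)

    def inverse_cum_hazard(self, h):
        return np.asarray(h, dtype=float) / self.rate


@dataclass(frozen=True)
class WeibullHazard:
    """Weibull baseline with H0(t) = (t / scale) ** shape."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("shape and scale must be positive")

    def hazard(self, t):
        t = np.asarray(t, dtype=float)
        return (self.shape / self.scale) * (t / self.scale) ** (self.shape - 1.0)

    def cum_hazard(self, t):
        return (np.asarray(t, dtype=float) / self.scale) ** self.shape

    def inverse_cum_hazard(self, h):
        return self.scale * np.asarray(h, dtype=float) ** (1.0 / self.shape)


@dataclass(frozen=True)
class PiecewiseConstantHazard:
    """Step-function hazard on intervals [0, c_1), [c_1, c_2), ..., [c_{K-1}, inf).

    ``cuts`` holds the K-1 interior cut points (strictly increasing, > 0) and
    ``levels`` the K hazard rates.  Times beyond the last cut keep the final
    level, so the hazard is defined on all of (0, inf).
    """

    cuts: tuple = field(default=())
    levels: tuple = field(default=(1.0,))

    def __post_init__(self) -> None:
        cuts = np.asarray(self.cuts, dtype=float)
        levels = np.asarray(self.levels, dtype=float)
        if levels.ndim != 1 or levels.size != cuts.size + 1:
            raise ValueError("need exactly len(cuts) + 1 hazard levels")
        if np.any(levels <= 0):
            raise ValueError("hazard levels must be positive")
        if cuts.size and (cuts[0] <= 0 or np.any(np.diff(cuts) <= 0)):
            raise ValueError("cut points must be strictly increasing and > 0")
        object.__setattr__(self, "cuts", tuple(float(c) for c in cuts))
        object.__setattr__(self, "levels", tuple(float(v) for v in levels))

    @property
    def _edges(self):
        return np.concatenate([[0.0], np.asarray(self.cuts)])

    @property
    def _cum_at_edges(self):
        # H0 at each interval start; piecewise linear in between
        edges = self._edges
        widths = np.diff(edges)
        lv = np.asarray(self.levels)
        return np.concatenate([[0.0], np.cumsum(widths * lv[:-1])])

    def interval_index(self, t):
        return np.searchsorted(np.asarray(self.cuts), np.asarray(t, dtype=float), side="right")

    def hazard(self, t):
        return np.asarray(self.levels)[self.interval_index(t)]

    def cum_hazard(self, t):
        t = np.asarray(t, dtype=float)
        idx = self.interval_index(t)
        edges = self._edges
        return self._cum_at_edges[idx] + np.asarray(self.levels)[idx] * (t - edges[idx])

    def inverse_cum_hazard(self, h):
        h = np.asarray(h, dtype=float)
        cum = self._cum_at_edges
        idx = np.clip(np.searchsorted(cum, h, side="right") - 1, 0, len(self.levels) - 1)
        return self._edges[idx] + (h - cum[idx]) / np.asarray(self.levels)[idx]

    def exposure_matrix(self, times):
        """Time at risk per interval for each subject, shape (n, K).

        Row i dotted with the hazard levels gives H0(t_i) exactly.
        """
        times = np.asarray(times, dtype=float)
        edges = self._edges
        upper = np.concatenate([np.asarray(self.cuts), [np.inf]])
        lo = np.minimum(times[:, None], edges[None, :])
        hi = np.minimum(times[:, None], upper[None, :])
        return np.clip(hi - lo, 0.0, None)


def sample_survival_time(u, linpred, baseline):
    """Invert S(t) = u under hazard h0(t) * exp(linpred).

    ``u`` is a uniform(0, 1] draw (the survival probability at the returned
    time); u = 1 gives t = 0 and u = 0 is rejected because it corresponds to
    an infinite survival time.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0) or np.any(u > 1):
        raise ValueError("u must lie in (0, 1]")
    target = -np.log(u) * np.exp(-np.asarray(linpred, dtype=float))
    return baseline.inverse_cum_hazard(target)
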