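"""Sampler settings, posterior summaries and convergence diagnostics.

Summaries keep the raw draws (shape ``(chains, draws)`` per parameter) so
that reports and diagnostics can always be recomputed from them.  The
convergence rule is the usual split-chain one: rank-normalized R-hat below
1.05 and bulk effective sample size above 200.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import arviz as az
import numpy as np
import pandas as pd

__all__ = ["MCMCSettings", "PosteriorSummary", "summarize_draws"]

RHAT_LIMIT = 1.05
ESS_LIMIT = 200.0


@dataclass(frozen=True)
class MCMCSettings:
    """Chains x iterations layout of a run; ``iterations`` counts kept draws
    per chain after discarding ``burn_in`` warm-up iterations."""

    chains: int = 2
    iterations: int = 2000
    burn_in: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 1 or self.iterations < 1 or self.burn_in < 0:
            raise ValueError("chains/iterations must be >= 1 and burn_in >= 0")

    def replace(self, **kw) -> "MCMCSettings":
        return replace(self, **kw)

    @classmethod
    def full_scale(cls, seed: int = 0) -> "MCMCSettings":
        """The full-scale protocol: 20,000 iterations with 3,000 burn-in."""
        return cls(chains=2, iterations=17000, burn_in=3000, seed=seed)


@dataclass
class PosteriorSummary:
    """Per-parameter posterior means, 95% credible intervals and diagnostics.

    ``table`` is indexed by parameter name with columns mean, sd, ci_low,
    ci_high, ess, rhat.  ``draws`` maps parameter names to (chains, draws)
    arrays; ``meta`` records the sampler settings and model description.
    """

    table: pd.DataFrame
    draws: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def mean(self, name: str) -> float:
        return float(self.table.loc[name, "mean"])

    def ci(self, name: str) -> tuple:
        row = self.table.loc[name]
        return float(row["ci_low"]), float(row["ci_high"])

    def ci_width(self, name: str) -> float:
        lo, hi = self.ci(name)
        return hi - lo

    @property
    def converged(self) -> bool:
        ok = (self.table["rhat"] < RHAT_LIMIT) & (self.table["ess"] > ESS_LIMIT)
        return bool(ok.all())

    def require_draws(self) -> dict:
        if not self.draws:
            raise ValueError(
                "raw draws were not retained; re-run the fit with keep_draws=True"
            )
        return self.draws

    def to_json(self, path) -> None:
        payload = {
            "table": self.table.reset_index().to_dict(orient="records"),
            "meta": _jsonable(self.meta),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def summarize_draws(draws: dict, meta: dict | None = None,
                    keep_draws: bool = True) -> PosteriorSummary:
    """Build a :class:`PosteriorSummary` from (chains, draws) arrays."""
    rows = []
    for name, arr in draws.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"draws for {name} must have shape (chains, draws)")
        flat = arr.reshape(-1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess = float(az.ess(arr)) if arr.shape[1] >= 4 else float("nan")
            rhat = (
                float(az.rhat(arr))
                if arr.shape[0] >= 2 and arr.shape[1] >= 4
                else float("nan")
            )
        rows.append(
            {
                "param": name,
                "mean": float(flat.mean()),
                "sd": float(flat.std(ddof=1)) if flat.size > 1 else 0.0,
                "ci_low": float(np.quantile(flat, 0.025)),
                "ci_high": float(np.quantile(flat, 0.975)),
                "ess": ess,
                "rhat": rhat,
            }
        )
    table = pd.DataFrame(rows).set_index("param")
    return PosteriorSummary(table=table, draws=dict(draws) if keep_draws else {},
                            meta=dict(meta or {}))


class ComponentwiseMH:
    """Adaptive component-wise random-walk Metropolis for a log-density.

    Proposal scales are tuned toward ~44% acceptance during warm-up
    (Robbins-Monro on the log scale) and frozen afterwards.
    """

    def __init__(self, dim: int, scales=None, target: float = 0.44):
        self.log_scales = np.log(np.full(dim, 0.1) if scales is None else
                                 np.asarray(scales, dtype=float))
        self.target = target
        self.n_adapt = 0

    def step(self, x, logpost_fn, current_lp, rng, adapt: bool):
        """One sweep over all coordinates; returns (x, lp)."""
        x = np.array(x, dtype=float)
        if adapt:
            self.n_adapt += 1
        for j in range(x.size):
            prop = x.copy()
            prop[j] += np.exp(self.log_scales[j]) * rng.standard_normal()
            lp_prop = logpost_fn(prop, j)
            accept = np.log(rng.random()) < lp_prop - current_lp
            if accept:
                x, current_lp = prop, lp_prop
            if adapt:
                rate = 1.0 if accept else 0.0
                self.log_scales[j] += (rate - self.target) / np.sqrt(self.n_adapt)
        return x, current_lp
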