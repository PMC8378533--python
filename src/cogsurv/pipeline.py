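"""Orchestration: the two-stage procedure and the full analysis grid.

The two-stage procedure fits the standalone growth model, extracts each
person's posterior-mean random intercept and linear change, and feeds those
point estimates into the proportional-hazards model as fixed predictors.
Stage-1 uncertainty is deliberately not propagated - that is exactly the
shortcut whose consequences the joint model avoids.

The analysis grid crosses framework (two-stage/joint) x sex (women/men) x
cognitive domain (Gc/Gf) x covariate adjustment (no/yes): 16 survival
analyses in total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .joint import JointFitResult, fit_joint
from .longitudinal import ModelSpec, fit_mlm
from .mcmc import MCMCSettings, PosteriorSummary
from .reporting import scaled_hazard_ratio
from .survival import fit_ph, make_survival_input

__all__ = [
    "AnalysisCell",
    "grid_cells",
    "TwoStageResult",
    "run_two_stage",
    "run_grid",
    "grid_summary",
]

FRAMEWORKS = ("two_stage", "joint")
STRATA = ("women", "men")
DOMAINS = ("Gc", "Gf")


@dataclass(frozen=True)
class AnalysisCell:
    framework: str
    stratum: str
    domain: str
    adjusted: bool

    def __post_init__(self) -> None:
        if self.framework not in FRAMEWORKS:
            raise ValueError(f"framework must be one of {FRAMEWORKS}")
        if self.stratum not in STRATA:
            raise ValueError(f"stratum must be one of {STRATA}")
        if self.domain not in DOMAINS:
            raise ValueError(f"domain must be one of {DOMAINS}")

    @property
    def label(self) -> str:
        adj = "cov" if self.adjusted else "uncond"
        return f"{self.framework}_{self.stratum}_{self.domain}_{adj}"


def grid_cells() -> list:
    """All 16 framework x sex x domain x adjustment combinations."""
    return [
        AnalysisCell(f, s, d, a)
        for d in DOMAINS
        for s in STRATA
        for f in FRAMEWORKS
        for a in (False, True)
    ]


@dataclass
class TwoStageResult:
    mlm: PosteriorSummary
    scores: pd.DataFrame
    ph: PosteriorSummary
    meta: dict


def _cohort_slice(cohort: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    sel = cohort
    if spec.stratum is not None:
        sel = sel[sel["sex"] == spec.stratum]
    if spec.domain is not None and "domain" in sel.columns:
        sel = sel[sel["domain"] == spec.domain]
    return sel


def run_two_stage(panel, cohort, spec: ModelSpec = ModelSpec(),
                  mcmc: MCMCSettings = MCMCSettings(),
                  stage1_adjusted: bool | None = None,
                  keep_draws: bool = True) -> TwoStageResult:
    """Stage 1: growth-model fit on all participants of the slice; stage 2:
    PH fit with the stage-1 posterior-mean scores as fixed predictors.

    By default the stage-1 model mirrors the cell's adjustment flag;
    ``stage1_adjusted`` overrides that.
    """
    s1_adjusted = spec.adjusted if stage1_adjusted is None else stage1_adjusted
    spec1 = spec.replace(adjusted=s1_adjusted, subset="all")
    mlm_summary, scores = fit_mlm(panel, cohort, spec1, mcmc, keep_draws=keep_draws)

    csel = _cohort_slice(cohort, spec)
    csel = csel[csel["person_id"].isin(set(scores["person_id"]))]
    sdata = make_survival_input(csel, scores=scores, adjusted=spec.adjusted)
    ph_summary = fit_ph(sdata, mcmc.replace(seed=mcmc.seed + 1),
                        keep_draws=keep_draws)
    meta = {
        "stage1_spec": spec1.__dict__ | {},
        "stage2_adjusted": spec.adjusted,
        "scores_from": mlm_summary.meta["fingerprint"],
        "score_sd": {
            "u0_hat": float(scores["u0_hat"].std(ddof=1)),
            "u1_hat": float(scores["u1_hat"].std(ddof=1)),
        },
    }
    return TwoStageResult(mlm=mlm_summary, scores=scores, ph=ph_summary, meta=meta)


def _cell_seed(base: int, idx: int) -> int:
    return int((base * 131 + idx * 7919) % (2**31 - 1))


def run_grid(panel, cohort, mcmc: MCMCSettings = MCMCSettings(), cells=None,
             out_dir=None, keep_draws: bool = False) -> dict:
    """Run every requested grid cell, isolating failures per cell.

    Returns ``{cell: TwoStageResult | JointFitResult | {"error": ...}}``.
    With ``out_dir`` set, each finished cell is written as JSON and cells
    with an existing output file are skipped (resumable).
    """
    cells = list(cells) if cells is not None else grid_cells()
    out = {}
    for idx, cell in enumerate(cells):
        path = Path(out_dir) / f"{cell.label}.json" if out_dir else None
        if path is not None and path.exists():
            out[cell] = {"cached": str(path)}
            continue
        spec = ModelSpec(form="quadratic", adjusted=cell.adjusted,
                         stratum=cell.stratum, domain=cell.domain)
        cell_mcmc = mcmc.replace(seed=_cell_seed(mcmc.seed, idx))
        try:
            if cell.framework == "two_stage":
                res = run_two_stage(panel, cohort, spec, cell_mcmc,
                                    keep_draws=keep_draws)
            else:
                res = fit_joint(panel, cohort, spec, cell_mcmc,
                                keep_draws=keep_draws)
        except Exception as exc:  # noqa: BLE001 - cell isolation is the point
            out[cell] = {"error": f"{type(exc).__name__}: {exc}"}
            continue
        out[cell] = res
        if path is not None:
            path.parent.mkdir(parents=True, exist_ok=True)
            _write_cell(path, cell, res)
    return out


def _write_cell(path: Path, cell: AnalysisCell, res) -> None:
    if isinstance(res, TwoStageResult):
        payload = {
            "cell": cell.__dict__ | {},
            "mlm": res.mlm.table.reset_index().to_dict(orient="records"),
            "ph": res.ph.table.reset_index().to_dict(orient="records"),
        }
    else:
        payload = {
            "cell": cell.__dict__ | {},
            "summary": res.summary.table.reset_index().to_dict(orient="records"),
        }
    path.write_text(json.dumps(payload, indent=2))


def grid_summary(results: dict) -> pd.DataFrame:
    """One row per finished cell: shared-effect coefficients with 95% CIs
    and hazard ratios per 1 SD of each cognitive predictor.

    Scaling follows the framework-specific convention: the joint rows use
    the model's posterior-mean random-effect SDs, the two-stage rows the
    empirical SD of the stage-1 posterior-mean scores.
    """
    rows = []
    for cell, res in results.items():
        if isinstance(res, dict):
            continue
        if isinstance(res, TwoStageResult):
            summary = res.ph
            sd0 = res.meta["score_sd"]["u0_hat"]
            sd1 = res.meta["score_sd"]["u1_hat"]
        elif isinstance(res, JointFitResult):
            summary = res.summary
            sd0 = float(np.sqrt(res.summary.mean("var_u0")))
            sd1 = float(np.sqrt(res.summary.mean("var_u1")))
        else:
            continue
        row = {
            "domain": cell.domain,
            "stratum": cell.stratum,
            "framework": cell.framework,
            "adjusted": cell.adjusted,
        }
        for name, sd in (("alpha1", sd0), ("alpha2", sd1)):
            row[f"{name}"] = summary.mean(name)
            lo, hi = summary.ci(name)
            row[f"{name}_ci_low"] = lo
            row[f"{name}_ci_high"] = hi
            row[f"hr_{name}_1sd"] = scaled_hazard_ratio(summary.mean(name), sd)
        for name in ("gamma_start_age", "gamma_smoker", "gamma_srh"):
            if name in summary.table.index:
                row[name] = summary.mean(name)
        rows.append(row)
    return (
        pd.DataFrame(rows)
        .sort_values(["domain", "stratum", "framework", "adjusted"])
        .reset_index(drop=True)
    )
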