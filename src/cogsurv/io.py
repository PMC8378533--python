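"""CSV/YAML round-tripping for cohorts, panels and simulation configs."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .hazards import PiecewiseConstantHazard
from .params import GrowthParams, HazardParams
from .synthetic import SimConfig

COHORT_COLUMNS = ["person_id", "domain", "sex", "start_age_c", "smoker", "srh",
                  "event", "time"]
PANEL_COLUMNS = ["person_id", "occasion", "age_c", "domain", "score"]
LATENT_COLUMNS = ["person_id", "domain", "sex", "u0", "u1"]


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort[COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort file missing columns: {sorted(missing)}")
    return df


def write_panel(panel: pd.DataFrame, path) -> None:
    panel[PANEL_COLUMNS].to_csv(path, index=False)


def read_panel(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"panel file missing columns: {sorted(missing)}")
    return df


def write_latents(latents: pd.DataFrame, path) -> None:
    latents[LATENT_COLUMNS].to_csv(path, index=False)


def _growth_to_dict(g: GrowthParams) -> dict:
    return {k: float(v) for k, v in g.__dict__.items()}


def _hazard_to_dict(h: HazardParams) -> dict:
    return {
        "baseline": {"cuts": list(h.baseline.cuts), "levels": list(h.baseline.levels)},
        "gamma": dict(h.gamma) if h.gamma else None,
        "alpha1": float(h.alpha1),
        "alpha2": float(h.alpha2),
    }


def config_to_yaml(config: SimConfig, path) -> None:
    d = {
        k: v
        for k, v in config.__dict__.items()
        if k not in ("growth_truth", "hazard_truth")
    }
    d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
    d["growth_truth"] = {
        f"{s}/{dom}": _growth_to_dict(g) for (s, dom), g in config.growth_truth.items()
    }
    d["hazard_truth"] = {
        f"{s}/{dom}": _hazard_to_dict(h) for (s, dom), h in config.hazard_truth.items()
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def config_from_yaml(path) -> SimConfig:
    d = yaml.safe_load(Path(path).read_text())
    growth = {
        tuple(key.split("/")): GrowthParams(**params)
        for key, params in d.pop("growth_truth").items()
    }
    hazard = {}
    for key, params in d.pop("hazard_truth").items():
        base = params.pop("baseline")
        hazard[tuple(key.split("/"))] = HazardParams(
            baseline=PiecewiseConstantHazard(tuple(base["cuts"]), tuple(base["levels"])),
            **params,
        )
    for key in ("entry_age_iqr", "entry_age_range", "srh_dist", "visit_gap_years",
                "continuation_probs", "domains"):
        if key in d:
            d[key] = tuple(d[key])
    return SimConfig(growth_truth=growth, hazard_truth=hazard, **d)
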