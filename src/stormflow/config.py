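"""YAML run configuration: one documented schema, collected validation.

All pipeline defaults live here (``DEFAULTS``), never scattered in code;
:func:`validate_config` returns either a fully populated :class:`RunConfig`
or the complete list of violations (it does not stop at the first error).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .events import EventParams
from .prep import CleaningParams
from .stats import MODEL_FORMULAS, SiteDesign, StudyDesign

#: Full default configuration; user files override keys selectively.
DEFAULTS: dict = {
    "seed": 0,
    "output_dir": "stormflow_out",
    "sites": [],
    "cleaning": {
        "enabled": True,
        "quantile_window_h": 12.5,
        "q_low": 0.25,
        "q_high": 0.75,
        "long_quantile": 0.70,
        "long_window_days": 30.0,
        "smooth_window_h": 7.5,
    },
    "baseflow": {"alpha": 0.925, "passes": 3, "reflect": 30, "min_segment": 60},
    "events": {
        "min_dry_gap_h": 6.0,
        "min_event_rain_mm": 1.0,
        "quickflow_fraction": 1.0,
        "quickflow_floor": 0.001,
        "max_lead_h": 24.0,
    },
    "exclusions_csv": None,
    "stats": {
        "models": ["additive", "seasonal", "baci", "baci_seasonal"],
        "q5_subset": True,
        "q5_percent": 5.0,
        "q5_combined_record": True,
    },
}

SITE_KEYS = {"site", "role", "impact_date", "control_partner",
             "rain_csv", "flow_csv", "stage_csv", "rating"}


@dataclass
class RunConfig:
    """Validated, fully defaulted pipeline configuration."""

    raw: dict
    path: Path | None
    cleaning: CleaningParams
    clean_enabled: bool
    baseflow: dict
    events: EventParams
    design: StudyDesign
    site_files: dict           # site -> {"rain": ..., "flow"/"stage": ..., "rating": ...}
    models: list[str]
    q5_subset: bool
    q5_percent: float
    q5_combined_record: bool
    seed: int
    output_dir: Path
    exclusions_csv: Path | None


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def validate_config(path_or_dict) -> tuple["RunConfig | None", list[str]]:
    """Validate a YAML file (or dict) into a RunConfig.

    Returns ``(config, errors)``; ``config`` is None whenever ``errors`` is
    non-empty.  Validation is collected, not fail-fast, so one pass reports
    every violation.
    """
    errors: list[str] = []
    path: Path | None = None
    if isinstance(path_or_dict, dict):
        user = path_or_dict
    else:
        path = Path(path_or_dict)
        try:
            user = yaml.safe_load(path.read_text()) or {}
        except Exception as err:
            return None, [f"unparseable config file: {err}"]
        if not isinstance(user, dict):
            return None, ["config root must be a mapping"]
    doc = _merge(DEFAULTS, user)

    unknown = set(user) - set(DEFAULTS)
    errors += [f"unknown top-level key {k!r}" for k in sorted(unknown)]

    try:
        cleaning = CleaningParams(
            quantile_window_h=doc["cleaning"]["quantile_window_h"],
            q_low=doc["cleaning"]["q_low"], q_high=doc["cleaning"]["q_high"],
            long_quantile=doc["cleaning"]["long_quantile"],
            long_window_days=doc["cleaning"]["long_window_days"],
            smooth_window_h=doc["cleaning"]["smooth_window_h"])
    except Exception as err:
        cleaning = CleaningParams()
        errors.append(f"cleaning: {err}")
    try:
        events = EventParams(**{k: doc["events"][k] for k in (
            "min_dry_gap_h", "min_event_rain_mm", "quickflow_fraction",
            "quickflow_floor", "max_lead_h")})
    except Exception as err:
        events = EventParams()
        errors.append(f"events: {err}")
    bf = doc["baseflow"]
    if not 0 < bf.get("alpha", 0.925) < 1:
        errors.append("baseflow.alpha: must lie in (0, 1)")

    for m in doc["stats"]["models"]:
        if m not in MODEL_FORMULAS:
            errors.append(f"stats.models: unknown model {m!r} "
                          f"(choose from {sorted(MODEL_FORMULAS)})")

    sites: list[SiteDesign] = []
    site_files: dict = {}
    seen_outputs: set[str] = set()
    if not doc["sites"]:
        errors.append("sites: at least one site is required")
    for i, s in enumerate(doc["sites"]):
        label = s.get("site", f"#{i}")
        unknown = set(s) - SITE_KEYS
        errors += [f"sites[{label}]: unknown key {k!r}" for k in sorted(unknown)]
        if "site" not in s:
            errors.append(f"sites[{i}]: missing 'site' id")
            continue
        try:
            sites.append(SiteDesign(
                site=s["site"], role=s.get("role", "impact"),
                impact_date=pd.Timestamp(s["impact_date"]) if s.get("impact_date") else None,
                control_partner=s.get("control_partner")))
        except Exception as err:
            errors.append(f"sites[{label}]: {err}")
        files = {}
        if "rain_csv" not in s:
            errors.append(f"sites[{label}]: missing rain_csv")
        else:
            files["rain"] = s["rain_csv"]
        if "flow_csv" in s:
            files["flow"] = s["flow_csv"]
        elif "stage_csv" in s:
            files["stage"] = s["stage_csv"]
            files["rating"] = s.get("rating") or {}
            if s.get("rating") is None:
                errors.append(f"sites[{label}]: stage input needs a 'rating' block")
        else:
            errors.append(f"sites[{label}]: needs flow_csv or stage_csv")
        for key, f in files.items():
            if key != "rating" and not Path(str(f)).exists():
                errors.append(f"sites[{label}]: {key} file not found: {f}")
        out_name = f"{s.get('site')}"
        if out_name in seen_outputs:
            errors.append(f"sites[{label}]: duplicate site id / output collision")
        seen_outputs.add(out_name)
        site_files[s.get("site")] = files

    design: StudyDesign | None = None
    if sites and not errors:
        try:
            design = StudyDesign(sites=tuple(sites))
        except Exception as err:
            errors.append(f"design: {err}")

    if doc["exclusions_csv"] and not Path(doc["exclusions_csv"]).exists():
        errors.append(f"exclusions_csv file not found: {doc['exclusions_csv']}")

    if errors:
        return None, errors
    return RunConfig(
        raw=doc, path=path,
        cleaning=cleaning, clean_enabled=bool(doc["cleaning"]["enabled"]),
        baseflow={k: bf[k] for k in ("alpha", "passes", "reflect", "min_segment")},
        events=events, design=design, site_files=site_files,
        models=list(doc["stats"]["models"]),
        q5_subset=bool(doc["stats"]["q5_subset"]),
        q5_percent=float(doc["stats"]["q5_percent"]),
        q5_combined_record=bool(doc["stats"]["q5_combined_record"]),
        seed=int(doc["seed"]), output_dir=Path(doc["output_dir"]),
        exclusions_csv=Path(doc["exclusions_csv"]) if doc["exclusions_csv"] else None,
    ), []
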