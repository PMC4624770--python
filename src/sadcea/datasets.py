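"""Loaders for the packaged default inputs.

Three text files ship with the package:

* ``data/parameters.yaml``       — global model inputs (mirrors the in-code
                                   :class:`~sadcea.parameters.ModelParameters`
                                   defaults field-for-field);
* ``data/interventions.yaml``    — the 28 treatment arms with cost profiles
                                   and published recovery-probability
                                   summaries;
* ``data/reference_results.csv`` — published probabilistic mean results,
                                   used only to validate the incremental
                                   analysis.
"""

from __future__ import annotations

import functools
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import costing
from .parameters import (
    InterventionDefinition,
    InvalidParameterError,
    ModelParameters,
    spec_from_mapping,
)

_DIST_FIELDS = {
    "utility_recovered_dist",
    "utility_sad_dist",
    "cost_recovered_dist",
    "cost_sad_dist",
    "relapse_drug_y1_dist",
    "relapse_rr_dist",
    "recovery_y2_5_12yr_dist",
    "relapse_y2_5_12yr_dist",
    "gp_visits_initial_dist",
    "gp_visits_maintenance_dist",
}


def _data_path(name: str):
    return resources.files("sadcea").joinpath("data", name)


def load_default_parameters(path: str | Path | None = None) -> ModelParameters:
    """Build :class:`ModelParameters` from the packaged (or a user) YAML file."""
    source = Path(path) if path is not None else _data_path("parameters.yaml")
    raw: Mapping[str, Any] = yaml.safe_load(source.read_text()) or {}
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key in _DIST_FIELDS:
            kwargs[key] = spec_from_mapping(value)
        else:
            kwargs[key] = value
    return ModelParameters(**kwargs)


def _cost_profile(entry: Mapping[str, Any]):
    cost = dict(entry["cost"])
    kind = cost.pop("kind")
    if kind == "none":
        return None
    if kind == "drug":
        return costing.DrugCostProfile(
            drug_id=entry["id"],
            acquisition_cost_12wk=cost["acquisition_12wk"],
            acquisition_cost_26wk=cost["acquisition_26wk"],
            is_placebo=bool(cost.get("is_placebo", False)),
        )
    if kind == "individual":
        sessions_dist = cost.get("sessions_dist")
        return costing.PsychCostProfile(
            intervention_id=entry["id"],
            kind="individual",
            sessions_full_course=cost["sessions_full_course"],
            session_minutes=cost["session_minutes"],
            first_session_extra_minutes=cost.get("first_session_extra_minutes", 0.0),
            sessions_dist=spec_from_mapping(sessions_dist) if sessions_dist else None,
        )
    if kind == "group":
        return costing.PsychCostProfile(
            intervention_id=entry["id"],
            kind="group",
            course_session_hours=cost["course_session_hours"],
            therapists=cost["therapists"],
            participants=cost["participants"],
        )
    if kind == "self-help":
        return costing.PsychCostProfile(
            intervention_id=entry["id"],
            kind="self-help",
            contact_minutes_mean=cost["contact_minutes_mean"],
            consumable_cost=costing.consumable_cost_from_components(cost["consumables"]),
        )
    raise InvalidParameterError(f"unknown cost kind {kind!r} for {entry['id']!r}")


@functools.lru_cache(maxsize=1)
def _raw_interventions() -> tuple[dict, ...]:
    raw = yaml.safe_load(_data_path("interventions.yaml").read_text())
    return tuple(raw)


def load_interventions() -> tuple[InterventionDefinition, ...]:
    """The 28 packaged treatment arms, in the packaged column order."""
    return tuple(
        InterventionDefinition(
            id=entry["id"],
            label=entry["label"],
            treatment_class=entry["treatment_class"],
            relapse_class=entry["relapse_class"],
            cost_profile=_cost_profile(entry),
        )
        for entry in _raw_interventions()
    )


def interventions_by_id() -> dict[str, InterventionDefinition]:
    return {it.id: it for it in load_interventions()}


def load_recovery_summaries() -> pd.DataFrame:
    """Published recovery marginals: mean, median, 95% CrI per arm."""
    rows = {
        entry["id"]: entry["recovery_summary"] for entry in _raw_interventions()
    }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "id"
    return frame[["mean", "median", "cri_low", "cri_high"]]


def load_reference_results() -> pd.DataFrame:
    """Published probabilistic mean results (validation input only)."""
    with resources.as_file(_data_path("reference_results.csv")) as path:
        frame = pd.read_csv(path, comment="#")
    return frame.set_index("id")
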