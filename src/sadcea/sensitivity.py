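"""Deterministic and probabilistic scenario analyses.

Scenarios are named bundles of overrides applied on top of the base inputs:
cheaper therapist bands for self-help and group delivery, an alternative
utility pair, shorter/longer horizons, and fixed relapse risk ratios.
Applying a scenario never mutates the base parameter set or the packaged
intervention definitions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import cea, costing, psa
from .effects import ConfigurationError, RecoveryPosterior
from .parameters import InterventionDefinition, ModelParameters, point

#: Parameter-level override keys applied directly to ModelParameters.
_PARAM_KEYS = {
    "treatment_weeks",
    "horizon_years_post_treatment",
    "discount_rate",
    "wtp_threshold",
    "utility_recovered",
    "utility_sad",
    "annual_cost_recovered",
    "annual_cost_sad",
    "relapse_rr_point",
    "relapse_waitlist_y1",
    "gp_visit_unit_cost",
}
#: Cost-profile override keys, applied to all profiles of the matching kind.
_COST_KEYS = {
    "therapist_unit_cost_individual",
    "therapist_unit_cost_group",
    "therapist_unit_cost_selfhelp",
}
RECOGNISED_OVERRIDES = _PARAM_KEYS | _COST_KEYS

#: NHS banded therapist unit costs, GBP per hour.
THERAPIST_UNIT_COSTS = {"band7": 110.0, "band6": 93.0, "band5": 87.0}


@dataclass(frozen=True)
class Scenario:
    """A named set of overrides plus the evaluation mode."""

    name: str
    overrides: Mapping[str, float] = field(default_factory=dict)
    mode: str = "probabilistic"  # or "deterministic"

    def __post_init__(self) -> None:
        if self.mode not in {"probabilistic", "deterministic"}:
            raise ConfigurationError(f"unknown scenario mode {self.mode!r}")
        unknown = set(self.overrides) - RECOGNISED_OVERRIDES
        if unknown:
            raise ConfigurationError(f"unknown override keys {sorted(unknown)}")


def apply_scenario(
    params: ModelParameters,
    interventions: Sequence[InterventionDefinition],
    scenario: Scenario,
) -> tuple[ModelParameters, tuple[InterventionDefinition, ...]]:
    """Return (parameters, interventions) with the scenario applied.

    Point overrides of sampled quantities (utilities, the relapse risk
    ratio) also replace the corresponding PSA distribution with a point mass,
    so probabilistic scenario runs honour the override.
    """
    changes: dict[str, object] = {}
    for key in _PARAM_KEYS & set(scenario.overrides):
        value = scenario.overrides[key]
        changes[key] = value
        if key == "utility_recovered":
            changes["utility_recovered_dist"] = point(value)
        elif key == "utility_sad":
            changes["utility_sad_dist"] = point(value)
        elif key == "relapse_rr_point":
            changes["relapse_rr_dist"] = point(value)
    new_params = dataclasses.replace(params, **changes) if changes else params

    kind_key = {
        "individual": "therapist_unit_cost_individual",
        "group": "therapist_unit_cost_group",
        "self-help": "therapist_unit_cost_selfhelp",
    }
    new_interventions = []
    for it in interventions:
        profile = it.cost_profile
        if isinstance(profile, costing.PsychCostProfile):
            key = kind_key[profile.kind]
            if key in scenario.overrides:
                profile = costing.with_therapist_unit_cost(profile, scenario.overrides[key])
                it = dataclasses.replace(it, cost_profile=profile)
        if isinstance(profile, costing.DrugCostProfile) and "gp_visit_unit_cost" in scenario.overrides:
            profile = dataclasses.replace(
                profile, gp_visit_unit_cost=scenario.overrides["gp_visit_unit_cost"]
            )
            it = dataclasses.replace(it, cost_profile=profile)
        new_interventions.append(it)
    return new_params, tuple(new_interventions)


def built_in_scenarios(mode: str = "probabilistic") -> list[Scenario]:
    """The packaged sensitivity scenarios.

    * base — no overrides;
    * therapist-bands — self-help supported by a Band 5 therapist (87/h) and
      group delivery by one Band 7 plus one Band 6 therapist (blended
      101.50/h per therapist-hour);
    * alternative-utilities — 0.79 ill / 0.91 well;
    * horizon-1y / horizon-3y / horizon-10y — post-treatment horizon;
    * relapse-rr-X — fixed relapse risk ratio in place of the log-normal.
    """
    group_blend = 0.5 * (THERAPIST_UNIT_COSTS["band7"] + THERAPIST_UNIT_COSTS["band6"])
    scenarios = [
        Scenario("base", {}, mode),
        Scenario(
            "therapist-bands",
            {
                "therapist_unit_cost_selfhelp": THERAPIST_UNIT_COSTS["band5"],
                "therapist_unit_cost_group": group_blend,
            },
            mode,
        ),
        Scenario(
            "alternative-utilities",
            {"utility_recovered": 0.91, "utility_sad": 0.79},
            mode,
        ),
    ]
    for years in (1, 3, 10):
        scenarios.append(
            Scenario(f"horizon-{years}y", {"horizon_years_post_treatment": years}, mode)
        )
    for rr in (1.0, 1.15, 1.5, 2.0):
        scenarios.append(Scenario(f"relapse-rr-{rr:g}", {"relapse_rr_point": rr}, mode))
    return scenarios


def run_scenario(
    scenario: Scenario,
    interventions: Sequence[InterventionDefinition],
    params: ModelParameters,
    posterior: RecoveryPosterior | None = None,
    recovery_means: Mapping[str, float] | None = None,
    n_iter: int = 10_000,
    seed: int | None = None,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Evaluate all arms under one scenario and return the summary table."""
    s_params, s_interventions = apply_scenario(params, interventions, scenario)
    wtp = threshold if threshold is not None else s_params.wtp_threshold
    if scenario.mode == "deterministic":
        if recovery_means is None:
            raise ConfigurationError("deterministic scenarios need recovery means")
        sweep = psa.run_deterministic(s_interventions, recovery_means, s_params)
        return cea.summarize_means(
            list(sweep.index), sweep["cost"], sweep["qaly"], sweep["fraction_well"], wtp
        )
    if posterior is None:
        raise ConfigurationError("probabilistic scenarios need a recovery posterior")
    result = psa.run_psa(s_interventions, posterior, s_params, n_iter=n_iter, seed=seed)
    return cea.summarize(result, wtp)


def run_scenario_suite(
    scenarios: Sequence[Scenario],
    interventions: Sequence[InterventionDefinition],
    params: ModelParameters,
    posterior: RecoveryPosterior | None = None,
    recovery_means: Mapping[str, float] | None = None,
    n_iter: int = 10_000,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-scenario ranking tables, keyed by scenario name."""
    return {
        scenario.name: run_scenario(
            scenario,
            interventions,
            params,
            posterior=posterior,
            recovery_means=recovery_means,
            n_iter=n_iter,
            seed=seed,
        )
        for scenario in scenarios
    }
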