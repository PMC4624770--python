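"""Probabilistic sensitivity analysis.

Each iteration draws one joint realisation of every uncertain input — one
row of the recovery posterior plus the relapse, utility, state-cost and
resource-use distributions — and evaluates all treatment arms under that same
draw (common random numbers, which minimises the variance of incremental
comparisons).  GP visit counts are shared across all drug arms within an
iteration; session counts and self-help contact minutes are drawn once per
arm per iteration.  Parameter uncertainty is cohort-level: one draw applies
to the whole cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cohort, costing
from .effects import ConfigurationError, RecoveryPosterior
from .parameters import (
    InterventionDefinition,
    ModelParameters,
    multi_year_to_annual_prob,
    psych_relapse_year1,
)


@dataclass(frozen=True)
class ParameterDraw:
    """One realisation of every stochastic model input."""

    recovery: Mapping[str, float]
    relapse_drug_y1: float
    relapse_rr: float
    relapse_psych_y1: float
    relapse_waitlist_y1: float
    recovery_annual_y2_5: float
    relapse_annual_y2_5: float
    utility_recovered: float
    utility_sad: float
    annual_cost_recovered: float
    annual_cost_sad: float
    gp_visits_initial: int
    gp_visits_maintenance: int
    sessions: Mapping[str, int]
    contact_minutes: Mapping[str, float]


@dataclass(frozen=True)
class PSAResult:
    """Per-iteration cost/QALY/fraction-well surfaces for all arms."""

    interventions: tuple[str, ...]
    costs: np.ndarray
    qalys: np.ndarray
    fraction_well: np.ndarray
    seed: int | None
    n_iter: int

    def __post_init__(self) -> None:
        shape = (self.n_iter, len(self.interventions))
        for name in ("costs", "qalys", "fraction_well"):
            if getattr(self, name).shape != shape:
                raise ConfigurationError(f"{name} matrix shape {getattr(self, name).shape} != {shape}")

    def mean_costs(self) -> pd.Series:
        return pd.Series(self.costs.mean(axis=0), index=list(self.interventions), name="mean_cost")

    def mean_qalys(self) -> pd.Series:
        return pd.Series(self.qalys.mean(axis=0), index=list(self.interventions), name="mean_qaly")

    def mean_fraction_well(self) -> pd.Series:
        return pd.Series(
            self.fraction_well.mean(axis=0), index=list(self.interventions), name="mean_fraction_well"
        )


def point_parameter_draw(
    params: ModelParameters,
    recovery: Mapping[str, float],
    interventions: Sequence[InterventionDefinition],
) -> ParameterDraw:
    """The deterministic draw: every input at its published point estimate.

    Resource use sits at the mode (4 initial + 3 maintenance GP visits, full
    course of sessions, mean contact time).
    """
    sessions = {}
    minutes = {}
    for it in interventions:
        profile = it.cost_profile
        if isinstance(profile, costing.PsychCostProfile):
            if profile.kind == "individual":
                sessions[it.id] = profile.sessions_full_course
            elif profile.kind == "self-help":
                minutes[it.id] = profile.contact_minutes_mean
    return ParameterDraw(
        recovery=dict(recovery),
        relapse_drug_y1=params.relapse_drug_y1_point,
        relapse_rr=params.relapse_rr_point,
        relapse_psych_y1=params.relapse_psych_y1_point,
        relapse_waitlist_y1=params.relapse_waitlist_y1_value,
        recovery_annual_y2_5=params.recovery_annual_y2_5,
        relapse_annual_y2_5=params.relapse_annual_y2_5,
        utility_recovered=params.utility_recovered,
        utility_sad=params.utility_sad,
        annual_cost_recovered=params.annual_cost_recovered,
        annual_cost_sad=params.annual_cost_sad,
        gp_visits_initial=4,
        gp_visits_maintenance=3,
        sessions=sessions,
        contact_minutes=minutes,
    )


def sample_parameter_draw(
    params: ModelParameters,
    posterior_row: Mapping[str, float],
    interventions: Sequence[InterventionDefinition],
    rng: np.random.Generator,
) -> ParameterDraw:
    """One coherent joint draw of all uncertain inputs.

    Iteration-global quantities are drawn first in a fixed order, then
    per-arm resource use in sorted id order, so that arms whose draws are not
    needed (because they are excluded from a run) do not perturb the rest.
    The psychological relapse probability is derived from the drug relapse
    and risk-ratio draws of the same iteration.
    """
    relapse_drug = float(params.relapse_drug_y1_dist.sample(rng))
    rr = float(params.relapse_rr_dist.sample(rng))
    recovery_12yr = float(params.recovery_y2_5_12yr_dist.sample(rng))
    relapse_12yr = float(params.relapse_y2_5_12yr_dist.sample(rng))
    u_rec = float(params.utility_recovered_dist.sample(rng))
    u_sad = float(params.utility_sad_dist.sample(rng))
    c_rec = float(params.cost_recovered_dist.sample(rng))
    c_sad = float(params.cost_sad_dist.sample(rng))
    visits_initial = int(params.gp_visits_initial_dist.sample(rng))
    visits_maintenance = int(params.gp_visits_maintenance_dist.sample(rng))

    relapse_annual = multi_year_to_annual_prob(relapse_12yr, 12)
    waitlist = (
        params.relapse_waitlist_y1
        if params.relapse_waitlist_y1 is not None
        else relapse_annual
    )

    sessions: dict[str, int] = {}
    minutes: dict[str, float] = {}
    for it in sorted(interventions, key=lambda x: x.id):
        profile = it.cost_profile
        if not isinstance(profile, costing.PsychCostProfile):
            continue
        if profile.kind == "individual" and profile.sessions_dist is not None:
            sessions[it.id] = int(profile.sessions_dist.sample(rng))
        elif profile.kind == "self-help":
            minutes[it.id] = max(0.0, float(profile.contact_minutes_dist.sample(rng)))

    return ParameterDraw(
        recovery=dict(posterior_row),
        relapse_drug_y1=relapse_drug,
        relapse_rr=rr,
        relapse_psych_y1=psych_relapse_year1(min(1.0, relapse_drug), rr),
        relapse_waitlist_y1=waitlist,
        recovery_annual_y2_5=multi_year_to_annual_prob(recovery_12yr, 12),
        relapse_annual_y2_5=relapse_annual,
        utility_recovered=u_rec,
        utility_sad=u_sad,
        annual_cost_recovered=c_rec,
        annual_cost_sad=c_sad,
        gp_visits_initial=visits_initial,
        gp_visits_maintenance=visits_maintenance,
        sessions=sessions,
        contact_minutes=minutes,
    )


def _relapse_y1(intervention: InterventionDefinition, draw: ParameterDraw) -> float:
    return {
        "drug": min(1.0, draw.relapse_drug_y1),
        "psychological": draw.relapse_psych_y1,
        "waitlist": draw.relapse_waitlist_y1,
    }[intervention.relapse_class]


def evaluate_intervention(
    intervention: InterventionDefinition,
    draw: ParameterDraw,
    discount_rate: float,
    timeline: cohort.Timeline,
) -> cohort.CohortResult:
    """Run the cohort engine for one arm under one parameter draw."""
    cost_nonrec, cost_rec = costing.intervention_cost_pair(
        intervention,
        draw.gp_visits_initial,
        draw.gp_visits_maintenance,
        draw.sessions.get(intervention.id),
        draw.contact_minutes.get(intervention.id),
    )
    return cohort.evaluate_cohort(
        p_recover=draw.recovery[intervention.id],
        relapse_y1=_relapse_y1(intervention, draw),
        cost_nonrecovered=cost_nonrec,
        cost_recovered=cost_rec,
        p_recover_annual=draw.recovery_annual_y2_5,
        p_relapse_annual=draw.relapse_annual_y2_5,
        u_recovered=draw.utility_recovered,
        u_sad=draw.utility_sad,
        annual_cost_recovered=draw.annual_cost_recovered,
        annual_cost_sad=draw.annual_cost_sad,
        discount_rate=discount_rate,
        timeline=timeline,
    )


def timeline_for(params: ModelParameters) -> cohort.Timeline:
    """Model clock implied by the parameters (cycles = horizon years - 1)."""
    return cohort.Timeline(
        treatment_weeks=params.treatment_weeks,
        markov_cycles=params.horizon_years_post_treatment - 1,
    )


def run_psa(
    interventions: Sequence[InterventionDefinition],
    posterior: RecoveryPosterior,
    params: ModelParameters,
    n_iter: int = 10_000,
    seed: int | None = None,
    timeline: cohort.Timeline | None = None,
) -> PSAResult:
    """Monte-Carlo propagation of all input distributions through the model.

    Iteration ``i`` pairs posterior row ``i`` with one draw of the remaining
    parameters and evaluates every arm under it.  Fully reproducible under
    ``seed`` (a substream of the master seed sequence is used for parameter
    draws, so results do not depend on how the posterior was produced).
    """
    if n_iter < 1:
        raise ConfigurationError("n_iter must be at least 1")
    if posterior.n_draws < n_iter:
        raise ConfigurationError(
            f"posterior has {posterior.n_draws} draws, fewer than n_iter={n_iter}"
        )
    missing = [it.id for it in interventions if it.id not in posterior.interventions]
    if missing:
        raise ConfigurationError(f"posterior lacks draws for {missing}")
    if timeline is None:
        timeline = timeline_for(params)

    _, param_stream = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(param_stream)
    ids = tuple(it.id for it in interventions)
    costs = np.empty((n_iter, len(ids)))
    qalys = np.empty((n_iter, len(ids)))
    frac_well = np.empty((n_iter, len(ids)))
    for i in range(n_iter):
        draw = sample_parameter_draw(params, posterior.row(i), interventions, rng)
        for j, it in enumerate(interventions):
            result = evaluate_intervention(it, draw, params.discount_rate, timeline)
            costs[i, j] = result.discounted_cost
            qalys[i, j] = result.discounted_qaly
            frac_well[i, j] = result.fraction_well_at_horizon
    return PSAResult(ids, costs, qalys, frac_well, seed, n_iter)


def run_deterministic(
    interventions: Sequence[InterventionDefinition],
    recovery_means: Mapping[str, float],
    params: ModelParameters,
    timeline: cohort.Timeline | None = None,
) -> pd.DataFrame:
    """Single sweep at published point estimates and modal resource use."""
    if timeline is None:
        timeline = timeline_for(params)
    draw = point_parameter_draw(params, recovery_means, interventions)
    rows = {}
    for it in interventions:
        result = evaluate_intervention(it, draw, params.discount_rate, timeline)
        rows[it.id] = {
            "cost": result.discounted_cost,
            "qaly": result.discounted_qaly,
            "fraction_well": result.fraction_well_at_horizon,
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "id"
    return frame


# ---------------------------------------------------------------------------
# Matrix I/O
# ---------------------------------------------------------------------------

def write_psa_matrices(result: PSAResult, directory: str | Path) -> dict[str, Path]:
    """Export cost/QALY/fraction-well matrices as CSV, one row per iteration."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, matrix in (
        ("costs", result.costs),
        ("qalys", result.qalys),
        ("fraction_well", result.fraction_well),
    ):
        path = directory / f"psa_{name}.csv"
        pd.DataFrame(matrix, columns=list(result.interventions)).to_csv(
            path, index=False, float_format="%.17g"
        )
        paths[name] = path
    return paths


def read_psa_matrices(directory: str | Path, seed: int | None = None) -> PSAResult:
    """Rebuild a :class:`PSAResult` from matrices written by
    :func:`write_psa_matrices`."""
    directory = Path(directory)
    frames = {
        name: pd.read_csv(directory / f"psa_{name}.csv")
        for name in ("costs", "qalys", "fraction_well")
    }
    ids = tuple(frames["costs"].columns)
    return PSAResult(
        ids,
        frames["costs"].to_numpy(float),
        frames["qalys"].to_numpy(float),
        frames["fraction_well"].to_numpy(float),
        seed,
        len(frames["costs"]),
    )
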