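"""Intervention costs and annual state costs (2015 GBP).

Pharmacological arms cost GP visits plus drug acquisition for a 12-week
initial course and, for recoverers only, a 26-week maintenance course.
The probabilistic analysis varies the GP visit counts, with contingencies
linking them to acquisition costs: one initial visit halves the 12-week
acquisition cost, one or two initial visits rule out maintenance, and zero
maintenance visits drop the 26-week acquisition cost.

Psychological arms cost therapist time at a banded hourly unit cost plus a
GP referral visit.  Individual therapies scale with sessions attended; group
therapies cost the full course regardless of attendance (sessions run and
empty seats are not refilled); self-help costs therapist contact minutes
plus consumables (book, or internet hosting/hardware).

All amounts are carried at full precision; rounding to whole pounds happens
only in report writers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

from .parameters import (
    DistributionSpec,
    InterventionDefinition,
    InvalidParameterError,
    ModelParameters,
)

#: Band 7 therapist, GBP per hour (salary, on-costs, overheads, qualification).
DEFAULT_THERAPIST_UNIT_COST = 110.0
#: GP visit unit cost, GBP (qualification and direct care staff costs).
DEFAULT_GP_VISIT_COST = 46.75


class InvalidStateError(ValueError):
    """Unknown Markov health state."""


@dataclass(frozen=True)
class DrugCostProfile:
    """Acquisition and GP-visit costing inputs for one drug arm."""

    drug_id: str
    acquisition_cost_12wk: float
    acquisition_cost_26wk: float
    gp_visit_unit_cost: float = DEFAULT_GP_VISIT_COST
    is_placebo: bool = False

    def __post_init__(self) -> None:
        if min(self.acquisition_cost_12wk, self.acquisition_cost_26wk) < 0:
            raise InvalidParameterError("acquisition costs must be nonnegative")
        if self.gp_visit_unit_cost <= 0:
            raise InvalidParameterError("GP unit cost must be positive")
        if self.is_placebo and (self.acquisition_cost_12wk or self.acquisition_cost_26wk):
            raise InvalidParameterError("placebo has zero acquisition costs")


@dataclass(frozen=True)
class PsychCostProfile:
    """Therapist-time costing inputs for one psychological arm.

    ``kind`` is ``individual``, ``group`` or ``self-help``.  For groups,
    ``course_session_hours`` is the summed duration of all sessions of a full
    course (a 7.5 h retreat counts like any session) and per-person therapist
    hours are ``course_session_hours * therapists / participants``.
    """

    intervention_id: str
    kind: str
    therapist_unit_cost: float = DEFAULT_THERAPIST_UNIT_COST
    gp_visit_unit_cost: float = DEFAULT_GP_VISIT_COST
    referral_gp_visit: bool = True
    # individual therapies
    sessions_full_course: int = 0
    session_minutes: float = 0.0
    first_session_extra_minutes: float = 0.0
    sessions_dist: DistributionSpec | None = None
    # group therapies
    course_session_hours: float = 0.0
    therapists: int = 1
    participants: int = 1
    # self-help
    contact_minutes_mean: float = 0.0
    consumable_cost: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in {"individual", "group", "self-help"}:
            raise InvalidParameterError(f"unknown psychological cost kind {self.kind!r}")
        if self.therapist_unit_cost <= 0 or self.gp_visit_unit_cost <= 0:
            raise InvalidParameterError("unit costs must be positive")
        if self.participants < 1 or self.therapists < 1:
            raise InvalidParameterError("therapists and participants must be >= 1")
        if self.consumable_cost < 0 or self.contact_minutes_mean < 0:
            raise InvalidParameterError("self-help inputs must be nonnegative")

    @property
    def contact_minutes_dist(self) -> DistributionSpec:
        """Normal around mean contact time with SD 0.3 x mean (self-help)."""
        mean = self.contact_minutes_mean
        return DistributionSpec("normal-mean-var", {"mean": mean, "var": (0.3 * mean) ** 2})


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def therapist_hours_per_person(
    sessions: float,
    hours_per_session: float,
    therapists: int = 1,
    participants: int = 1,
    extra_hours: float = 0.0,
) -> float:
    """Therapist hours consumed per service user.

    ``(sessions * hours_per_session + extra_hours) * therapists /
    participants``; ``extra_hours`` covers one-off items such as an all-day
    retreat.
    """
    if participants <= 0 or therapists <= 0:
        raise InvalidParameterError("therapists and participants must be positive")
    if sessions < 0 or hours_per_session < 0 or extra_hours < 0:
        raise InvalidParameterError("session inputs must be nonnegative")
    return (sessions * hours_per_session + extra_hours) * therapists / participants


def drug_intervention_cost(
    profile: DrugCostProfile,
    initial_visits: int,
    maintenance_visits: int,
    recovered: bool,
) -> float:
    """Cost of one drug arm given GP visit counts and recovery status.

    Initial phase: visits plus the 12-week acquisition cost (halved when only
    one visit took place).  The maintenance phase (visits plus the 26-week
    acquisition cost, dropped when no maintenance visit occurred) is incurred
    only by recoverers who had at least three initial visits.
    """
    if initial_visits < 0 or maintenance_visits < 0:
        raise InvalidParameterError("visit counts must be nonnegative")
    gp = profile.gp_visit_unit_cost
    acquisition_fraction = 0.5 if initial_visits == 1 else 1.0
    cost = initial_visits * gp + profile.acquisition_cost_12wk * acquisition_fraction
    if recovered and initial_visits >= 3:
        cost += maintenance_visits * gp
        if maintenance_visits > 0:
            cost += profile.acquisition_cost_26wk
    return cost


def psych_intervention_cost(
    profile: PsychCostProfile,
    sessions_attended: int | None = None,
    contact_minutes: float | None = None,
) -> float:
    """Cost of one psychological arm.

    Individual therapies bill attended sessions (default: the full course);
    group therapies bill the full course regardless of attendance; self-help
    bills therapist contact minutes (truncated at zero) plus consumables.
    A GP referral visit is added when the profile includes one.
    """
    referral = profile.gp_visit_unit_cost if profile.referral_gp_visit else 0.0
    unit = profile.therapist_unit_cost
    if profile.kind == "group":
        hours = therapist_hours_per_person(
            1, profile.course_session_hours, profile.therapists, profile.participants
        )
        return hours * unit + referral
    if profile.kind == "individual":
        attended = profile.sessions_full_course if sessions_attended is None else sessions_attended
        if not 0 <= attended <= profile.sessions_full_course:
            raise InvalidParameterError(
                f"{profile.intervention_id}: attendance {attended} outside "
                f"[0, {profile.sessions_full_course}]"
            )
        minutes = attended * profile.session_minutes
        if attended >= 1:
            minutes += profile.first_session_extra_minutes
        return minutes / 60.0 * unit + referral
    # self-help
    minutes = profile.contact_minutes_mean if contact_minutes is None else contact_minutes
    minutes = max(0.0, minutes)
    return minutes / 60.0 * unit + profile.consumable_cost + referral


def intervention_cost_pair(
    intervention: InterventionDefinition,
    gp_visits_initial: int = 4,
    gp_visits_maintenance: int = 3,
    sessions_attended: int | None = None,
    contact_minutes: float | None = None,
) -> tuple[float, float]:
    """(cost if not recovered, cost if recovered) for one arm.

    The split matters only for drug arms, where maintenance treatment is
    given to recoverers; psychological costs are all incurred during the
    initial course.
    """
    profile = intervention.cost_profile
    if profile is None:
        return 0.0, 0.0
    if isinstance(profile, DrugCostProfile):
        return (
            drug_intervention_cost(profile, gp_visits_initial, gp_visits_maintenance, False),
            drug_intervention_cost(profile, gp_visits_initial, gp_visits_maintenance, True),
        )
    cost = psych_intervention_cost(profile, sessions_attended, contact_minutes)
    return cost, cost


def full_adherence_cost(intervention: InterventionDefinition) -> float:
    """Cost at modal resource use with recovery (the published table totals)."""
    return intervention_cost_pair(intervention)[1]


def annual_state_cost(state: str, params: ModelParameters) -> float:
    """Annual health and personal social service cost of a model state."""
    if state in {"recovered", "well", "no-sad"}:
        return params.annual_cost_recovered
    if state in {"sad", "social-anxiety-disorder"}:
        return params.annual_cost_sad
    raise InvalidStateError(f"unknown health state {state!r}")


def consumable_cost_from_components(components: Mapping[str, float]) -> float:
    """Per-person consumable cost from its structured-text components.

    Books are priced directly; internet programmes spread an annual hosting
    fee over the expected annual users and add hardware/overheads.
    """
    total = float(components.get("book", 0.0))
    if "hosting_annual" in components:
        total += components["hosting_annual"] / components["users_per_year"]
        total += float(components.get("hardware_overheads", 0.0))
    return total


def with_therapist_unit_cost(profile: PsychCostProfile, unit_cost: float) -> PsychCostProfile:
    """Copy of a profile billed at a different therapist unit cost."""
    return replace(profile, therapist_unit_cost=unit_cost)
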