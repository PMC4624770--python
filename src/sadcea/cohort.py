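"""The cohort engine: a one-year decision tree followed by a two-state
Markov model.

Each arm's cohort spends 12 weeks in initial treatment, at the end of which a
fraction ``p_recover`` leaves the 'social anxiety disorder' state.  Over the
first post-treatment year recoverers may relapse once (a decision-tree
branch, not a transition cycle).  Post-treatment years 2 onward run as annual
Markov cycles between 'no social anxiety disorder' and 'social anxiety
disorder' with common recovery/relapse probabilities, half-cycle correction
and annual discounting.  The total horizon is therefore the treatment
fraction of a year plus ``markov_cycles + 1`` post-treatment years (5 by
default).

Timing conventions (the published account leaves them open; these are this
package's choices, see docs/methods.md):

* utilities change linearly on transition: recoverers ramp from the ill to
  the well utility across the treatment weeks; year-1 relapsers are credited
  the average of the two state utilities over the first post-treatment year
  (uniformly distributed relapse time), and likewise for state costs;
* state costs start at the end of treatment week 12 (intervention costs
  cover the treatment window) and run for a full year in the decision tree;
* the decision-tree period (treatment plus first post-treatment year) is
  undiscounted; Markov cycle k (post-treatment year k+1) is discounted by
  (1 + r) ** -k;
* half-cycle correction credits each cycle at the average of its start and
  end occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import InvalidParameterError

WEEKS_PER_YEAR = 52


@dataclass(frozen=True)
class StateOccupancy:
    """Cohort split between the two health states (sums to one)."""

    well: float
    sad: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.well <= 1.0 and 0.0 <= self.sad <= 1.0):
            raise InvalidParameterError("occupancies must lie in [0, 1]")
        if abs(self.well + self.sad - 1.0) > 1e-12:
            raise InvalidParameterError("occupancies must sum to 1")


@dataclass(frozen=True)
class Timeline:
    """Clock of the model: treatment weeks, then year 1, then Markov cycles."""

    treatment_weeks: int = 12
    markov_cycles: int = 4
    half_cycle_correction: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.treatment_weeks < WEEKS_PER_YEAR:
            raise InvalidParameterError("treatment_weeks must lie in [1, 52)")
        if self.markov_cycles < 0:
            raise InvalidParameterError("markov_cycles must be nonnegative")

    @property
    def post_treatment_years_y1(self) -> float:
        """Duration of the decision-tree post-treatment window (one year)."""
        return 1.0

    @property
    def horizon_years_post_treatment(self) -> int:
        return self.markov_cycles + 1

    @property
    def total_years(self) -> float:
        """Treatment fraction plus post-treatment years."""
        return self.treatment_weeks / WEEKS_PER_YEAR + self.horizon_years_post_treatment


@dataclass(frozen=True)
class CohortResult:
    """Discounted totals for one arm under one parameter draw."""

    discounted_cost: float
    discounted_qaly: float
    fraction_well_at_horizon: float

    def __post_init__(self) -> None:
        if self.discounted_cost < 0 or self.discounted_qaly < 0:
            raise InvalidParameterError("totals must be nonnegative")
        if not 0.0 <= self.fraction_well_at_horizon <= 1.0:
            raise InvalidParameterError("fraction well must be a probability")


def qaly_segment(
    u_start: float,
    u_end: float,
    duration: float,
    discount_rate: float = 0.0,
    time_offset: float = 0.0,
) -> float:
    """QALYs over a segment with linearly changing utility.

    Trapezoid integral of the utility path over ``duration`` years, times the
    discount factor ``(1 + r) ** -time_offset`` applying to the segment.
    """
    if duration < 0:
        raise InvalidParameterError("duration must be nonnegative")
    if not (0.0 <= u_start <= 1.0 and 0.0 <= u_end <= 1.0):
        raise InvalidParameterError("utilities must lie in [0, 1]")
    return 0.5 * (u_start + u_end) * duration / (1.0 + discount_rate) ** time_offset


def run_decision_tree_year(
    p_recover: float,
    relapse_y1: float,
    cost_nonrecovered: float,
    cost_recovered: float,
    u_recovered: float,
    u_sad: float,
    annual_cost_recovered: float,
    annual_cost_sad: float,
    timeline: Timeline = Timeline(),
) -> tuple[StateOccupancy, float, float]:
    """Decision tree: treatment, recovery split, single relapse opportunity.

    Covers the treatment weeks plus the first full post-treatment year.
    Returns occupancy at the end of that year, accumulated cost and
    accumulated QALYs (all undiscounted — the decision tree starts the clock).
    """
    if not (0.0 <= p_recover <= 1.0 and 0.0 <= relapse_y1 <= 1.0):
        raise InvalidParameterError("probabilities must lie in [0, 1]")
    t_frac = timeline.treatment_weeks / WEEKS_PER_YEAR
    p_frac = timeline.post_treatment_years_y1

    well_end = p_recover * (1.0 - relapse_y1)
    relapsed = p_recover * relapse_y1
    never = 1.0 - p_recover

    qaly = p_recover * qaly_segment(u_sad, u_recovered, t_frac)
    qaly += never * qaly_segment(u_sad, u_sad, t_frac)
    u_relapser = 0.5 * (u_recovered + u_sad)
    qaly += (well_end * u_recovered + relapsed * u_relapser + never * u_sad) * p_frac

    cost = p_recover * cost_recovered + never * cost_nonrecovered
    c_relapser = 0.5 * (annual_cost_recovered + annual_cost_sad)
    cost += (
        well_end * annual_cost_recovered + relapsed * c_relapser + never * annual_cost_sad
    ) * p_frac

    return StateOccupancy(well_end, 1.0 - well_end), cost, qaly


def run_markov_years(
    start: StateOccupancy,
    p_recover_annual: float,
    p_relapse_annual: float,
    cycles: int,
    u_recovered: float,
    u_sad: float,
    annual_cost_recovered: float,
    annual_cost_sad: float,
    discount_rate: float = 0.0,
    half_cycle_correction: bool = True,
    first_cycle_offset: float = 1.0,
) -> tuple[StateOccupancy, float, float]:
    """Annual Markov cycles between the two states.

    Cycle k (k = 1..cycles) is discounted by
    ``(1 + r) ** -(first_cycle_offset + k - 1)``; with the default offset of
    one, cycle 1 — calendar year 2 — carries one year of discounting.  With
    half-cycle correction, outcomes are credited at the average of start and
    end occupancy of each cycle.
    """
    if not (0.0 <= p_recover_annual <= 1.0 and 0.0 <= p_relapse_annual <= 1.0):
        raise InvalidParameterError("probabilities must lie in [0, 1]")
    if cycles < 0:
        raise InvalidParameterError("cycles must be nonnegative")
    well = start.well
    qaly = 0.0
    cost = 0.0
    for k in range(1, cycles + 1):
        well_end = well * (1.0 - p_relapse_annual) + (1.0 - well) * p_recover_annual
        credited = 0.5 * (well + well_end) if half_cycle_correction else well_end
        factor = (1.0 + discount_rate) ** -(first_cycle_offset + k - 1)
        qaly += (credited * u_recovered + (1.0 - credited) * u_sad) * factor
        cost += (credited * annual_cost_recovered + (1.0 - credited) * annual_cost_sad) * factor
        well = well_end
    return StateOccupancy(well, 1.0 - well), cost, qaly


def evaluate_cohort(
    p_recover: float,
    relapse_y1: float,
    cost_nonrecovered: float,
    cost_recovered: float,
    p_recover_annual: float,
    p_relapse_annual: float,
    u_recovered: float,
    u_sad: float,
    annual_cost_recovered: float,
    annual_cost_sad: float,
    discount_rate: float = 0.035,
    timeline: Timeline = Timeline(),
) -> CohortResult:
    """Full pipeline for one arm under one parameter draw.

    Deterministic given its inputs: decision tree for year 1, then
    ``timeline.markov_cycles`` annual cycles.  The fraction well at horizon
    is read after the final cycle's transition, before any half-cycle
    averaging.
    """
    occupancy, cost_y1, qaly_y1 = run_decision_tree_year(
        p_recover,
        relapse_y1,
        cost_nonrecovered,
        cost_recovered,
        u_recovered,
        u_sad,
        annual_cost_recovered,
        annual_cost_sad,
        timeline,
    )
    occupancy, cost_mk, qaly_mk = run_markov_years(
        occupancy,
        p_recover_annual,
        p_relapse_annual,
        timeline.markov_cycles,
        u_recovered,
        u_sad,
        annual_cost_recovered,
        annual_cost_sad,
        discount_rate,
        timeline.half_cycle_correction,
    )
    return CohortResult(cost_y1 + cost_mk, qaly_y1 + qaly_mk, occupancy.well)
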