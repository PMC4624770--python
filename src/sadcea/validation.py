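"""Self-test: recompute the packaged derived inputs and compare them with
their published values.

These checks verify the parameter derivations (beta means, midpoints,
constant-hazard conversions) and the intervention cost components against the
published figures.  Two drug totals are compared within a two-pence band: the
published table embeds a GP component of 327.27 GBP while its own footnote
prices 7 visits at 46.75 GBP = 327.25 GBP, and this package uses the stated
unit cost exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.special import expit

from . import costing, datasets
from .parameters import ModelParameters


@dataclass(frozen=True)
class Check:
    name: str
    computed: float
    expected: float
    tolerance: float

    @property
    def passed(self) -> bool:
        return abs(self.computed - self.expected) <= self.tolerance


def derivation_checks(params: ModelParameters | None = None) -> list[Check]:
    """Derived parameters and cost components versus their published values."""
    if params is None:
        params = ModelParameters.defaults()
    by_id = datasets.interventions_by_id()
    checks = [
        Check("annual recovery, years 2-5", params.recovery_annual_y2_5, 0.0377, 5e-5),
        Check("annual relapse, years 2-5", params.relapse_annual_y2_5, 0.0409, 5e-5),
        Check("drug relapse, year 1", params.relapse_drug_y1_point, 0.4169, 5e-5),
        Check("psychological relapse, year 1", params.relapse_psych_y1_point, 0.139, 5e-4),
        Check("utility of recovery (beta mean)", params.utility_recovered_dist.mean(), 0.866, 5e-4),
        Check(
            "wait-list median recovery",
            float(expit(params.baseline_log_odds_mean)),
            0.07,
            5e-3,
        ),
        Check(
            "7 GP visits",
            7 * params.gp_visit_unit_cost,
            327.25,
            1e-9,
        ),
        Check(
            "citalopram full-adherence total",
            costing.full_adherence_cost(by_id["citalopram"]),
            339.43,
            0.05,
        ),
        Check(
            "pregabalin full-adherence total",
            costing.full_adherence_cost(by_id["pregabalin"]),
            939.07,
            0.05,
        ),
        Check(
            "group CBT therapist hours per person",
            costing.therapist_hours_per_person(12, 2.5, 2, 6),
            10.0,
            1e-12,
        ),
        Check(
            "mindfulness therapist hours per person",
            costing.therapist_hours_per_person(8, 2.5, 2, 12, extra_hours=7.5),
            4.58,
            0.005,
        ),
        Check(
            "individual cognitive therapy hours per person",
            costing.therapist_hours_per_person(14, 1.5),
            21.0,
            1e-12,
        ),
    ]
    return checks


def run_validation(params: ModelParameters | None = None) -> tuple[bool, list[Check]]:
    checks = derivation_checks(params)
    return all(c.passed for c in checks), checks
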