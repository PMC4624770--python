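"""Model inputs for the social-anxiety-disorder cost-utility model.

Every uncertain quantity in the model is described by a
:class:`DistributionSpec` — a declarative (family, parameters) pair that the
probabilistic sensitivity analysis samples from.  The point estimates and the
derivation rules that turn raw counts into probabilities (beta means, the
midpoint-of-two-betas construction for drug relapse, constant-hazard
conversion of multi-year probabilities) live here as well, so that the
deterministic and probabilistic analyses share a single source of inputs.

Defaults are mirrored field-for-field in ``data/parameters.yaml``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np


class InvalidParameterError(ValueError):
    """A parameter value violates its domain constraints."""


class UnsupportedDistributionError(ValueError):
    """A DistributionSpec names an unknown distribution family."""


# ---------------------------------------------------------------------------
# Distribution specifications
# ---------------------------------------------------------------------------

_FAMILY_PARAMS: dict[str, set[str]] = {
    "beta-counts": {"alpha", "beta"},
    "gamma-mean-se": {"mean", "se"},
    "log-normal-ci": {"mean", "ci_low", "ci_high"},
    "normal-mean-var": {"mean", "var"},
    "categorical": {"values", "probs"},
    "midpoint-of-two-betas": {"alpha1", "beta1", "alpha2", "beta2"},
    "point": {"value"},
}

#: z-width of a central 95% interval, used to recover a normal standard
#: deviation from reported interval endpoints.
Z95_WIDTH = 3.92


@dataclass(frozen=True)
class DistributionSpec:
    """One uncertain model input: a distribution family plus its parameters.

    Supported families
    ------------------
    ``beta-counts``            Beta(alpha, beta) from event counts.
    ``gamma-mean-se``          Gamma matched by method of moments to a mean
                               and standard error (both in natural units).
    ``log-normal-ci``          Log-normal from a reported mean and 95% CI;
                               the log-scale mean is the midpoint of the log
                               CI and the log-scale SD is the log CI width
                               divided by 3.92.
    ``normal-mean-var``        Normal(mean, var).
    ``categorical``            Discrete values with given probabilities.
    ``midpoint-of-two-betas``  Arithmetic mean of two independent beta draws.
    ``point``                  Degenerate: always returns ``value``.
    """

    family: str
    params: Mapping[str, Any]

    def __post_init__(self) -> None:
        if self.family not in _FAMILY_PARAMS:
            raise UnsupportedDistributionError(
                f"unknown distribution family {self.family!r}"
            )
        missing = _FAMILY_PARAMS[self.family] - set(self.params)
        if missing:
            raise InvalidParameterError(
                f"{self.family}: missing parameters {sorted(missing)}"
            )
        self._validate()

    def _validate(self) -> None:
        p = self.params
        f = self.family
        if f == "beta-counts":
            if p["alpha"] <= 0 or p["beta"] <= 0:
                raise InvalidParameterError("beta-counts requires alpha > 0 and beta > 0")
        elif f == "gamma-mean-se":
            if p["mean"] <= 0 or p["se"] <= 0:
                raise InvalidParameterError("gamma-mean-se requires mean > 0 and se > 0")
        elif f == "log-normal-ci":
            if not (0 < p["ci_low"] < p["ci_high"]):
                raise InvalidParameterError("log-normal-ci requires 0 < ci_low < ci_high")
            if p["mean"] <= 0:
                raise InvalidParameterError("log-normal-ci requires mean > 0")
        elif f == "normal-mean-var":
            if p["var"] < 0:
                raise InvalidParameterError("normal-mean-var requires var >= 0")
        elif f == "categorical":
            values, probs = p["values"], p["probs"]
            if len(values) != len(probs) or len(values) == 0:
                raise InvalidParameterError("categorical values/probs length mismatch")
            probs = np.asarray(probs, dtype=float)
            if (probs < 0).any():
                raise InvalidParameterError("categorical probabilities must be nonnegative")
            if abs(probs.sum() - 1.0) > 1e-9:
                raise InvalidParameterError("categorical probabilities must sum to 1")
        elif f == "midpoint-of-two-betas":
            if min(p["alpha1"], p["beta1"], p["alpha2"], p["beta2"]) <= 0:
                raise InvalidParameterError("midpoint-of-two-betas requires positive counts")

    # -- closed forms -------------------------------------------------------

    def mean(self) -> float:
        """Analytic mean of the sampling distribution."""
        p = self.params
        f = self.family
        if f == "beta-counts":
            return beta_mean_from_counts(p["alpha"], p["beta"])
        if f == "gamma-mean-se":
            return float(p["mean"])
        if f == "log-normal-ci":
            mu, sigma = lognormal_params_from_ci(p["ci_low"], p["ci_high"])
            return math.exp(mu + 0.5 * sigma**2)
        if f == "normal-mean-var":
            return float(p["mean"])
        if f == "categorical":
            return float(np.dot(p["values"], p["probs"]))
        if f == "midpoint-of-two-betas":
            return drug_relapse_year1((p["alpha1"], p["beta1"]), (p["alpha2"], p["beta2"]))
        return float(p["value"])

    # -- sampling -----------------------------------------------------------

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw from the distribution; reproducible under a seeded ``rng``."""
        p = self.params
        f = self.family
        if f == "beta-counts":
            return rng.beta(p["alpha"], p["beta"], size)
        if f == "gamma-mean-se":
            shape, scale = gamma_from_mean_se(p["mean"], p["se"])
            return rng.gamma(shape, scale, size)
        if f == "log-normal-ci":
            mu, sigma = lognormal_params_from_ci(p["ci_low"], p["ci_high"])
            return rng.lognormal(mu, sigma, size)
        if f == "normal-mean-var":
            return rng.normal(p["mean"], math.sqrt(p["var"]), size)
        if f == "categorical":
            return rng.choice(np.asarray(p["values"]), size=size, p=np.asarray(p["probs"], dtype=float))
        if f == "midpoint-of-two-betas":
            first = rng.beta(p["alpha1"], p["beta1"], size)
            second = rng.beta(p["alpha2"], p["beta2"], size)
            return 0.5 * (first + second)
        # point
        return float(p["value"]) if size is None else np.full(size, float(p["value"]))


def point(value: float) -> DistributionSpec:
    """Degenerate distribution fixed at ``value``."""
    return DistributionSpec("point", {"value": value})


def categorical_from_groups(groups: Sequence[Mapping[str, Any]]) -> DistributionSpec:
    """Build a categorical spec from probability groups.

    Each group is ``{"prob": p, "values": [...]}`` or
    ``{"prob": p, "range": [lo, hi]}`` (inclusive); the group's probability
    mass is split equally among its values.  This mirrors how resource-use
    distributions are reported ("10%: 3, 5 or 6").
    """
    values: list[float] = []
    probs: list[float] = []
    for group in groups:
        if "range" in group:
            lo, hi = group["range"]
            members = list(range(int(lo), int(hi) + 1))
        else:
            members = list(group["values"])
        if not members:
            raise InvalidParameterError("categorical group has no values")
        for v in members:
            values.append(v)
            probs.append(float(group["prob"]) / len(members))
    return DistributionSpec("categorical", {"values": values, "probs": probs})


def spec_from_mapping(mapping: Mapping[str, Any]) -> DistributionSpec:
    """Construct a spec from its structured-text form (``family`` + params)."""
    data = dict(mapping)
    family = data.pop("family", None)
    if family is None:
        raise InvalidParameterError("distribution mapping lacks a 'family' key")
    if family == "categorical-groups":
        return categorical_from_groups(data["groups"])
    return DistributionSpec(family, data)


def sample(spec: DistributionSpec, rng: np.random.Generator, size: int | None = None):
    """Functional alias for :meth:`DistributionSpec.sample`."""
    return spec.sample(rng, size)


# ---------------------------------------------------------------------------
# Derivation rules
# ---------------------------------------------------------------------------

def beta_mean_from_counts(alpha: float, beta: float) -> float:
    """Mean alpha / (alpha + beta) of a Beta distribution given its counts."""
    if alpha <= 0 or beta <= 0:
        raise InvalidParameterError("beta counts must be positive")
    return alpha / (alpha + beta)


def gamma_from_mean_se(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments (shape, scale) for a gamma with the given mean and SE."""
    if mean <= 0 or se <= 0:
        raise InvalidParameterError("gamma mean and se must be positive")
    shape = (mean / se) ** 2
    scale = se**2 / mean
    return shape, scale


def lognormal_params_from_ci(ci_low: float, ci_high: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of a log-normal from its central 95% interval.

    The interval is taken as symmetric on the log scale, the standard
    convention when a ratio is reported with a 95% CI.
    """
    if not (0 < ci_low < ci_high):
        raise InvalidParameterError("requires 0 < ci_low < ci_high")
    mu = 0.5 * (math.log(ci_low) + math.log(ci_high))
    sigma = (math.log(ci_high) - math.log(ci_low)) / Z95_WIDTH
    return mu, sigma


def multi_year_to_annual_prob(p_multi: float, years: int) -> float:
    """Convert a multi-year probability to an annual one (constant hazard).

    ``1 - (1 - p_multi) ** (1 / years)``; the inverse of
    :func:`annual_to_multi_year_prob`.
    """
    if not 0 <= p_multi < 1:
        raise InvalidParameterError("p_multi must be in [0, 1)")
    if years < 1:
        raise InvalidParameterError("years must be >= 1")
    return 1.0 - (1.0 - p_multi) ** (1.0 / years)


def annual_to_multi_year_prob(p_annual: float, years: int) -> float:
    """Compound an annual probability over ``years`` (constant hazard)."""
    if not 0 <= p_annual < 1:
        raise InvalidParameterError("p_annual must be in [0, 1)")
    if years < 1:
        raise InvalidParameterError("years must be >= 1")
    return 1.0 - (1.0 - p_annual) ** years


def drug_relapse_year1(first: tuple[float, float], second: tuple[float, float]) -> float:
    """Year-1 drug relapse probability: midpoint of two pooled beta means.

    The two count pairs are the pooled relapse risk during maintenance
    treatment and the pooled risk after responders were switched to placebo;
    the true post-recovery risk is taken as their midpoint.
    """
    return 0.5 * (beta_mean_from_counts(*first) + beta_mean_from_counts(*second))


def psych_relapse_year1(p_drug: float, rr: float) -> float:
    """Year-1 relapse after psychological therapy: drug relapse / risk ratio.

    Clipped to [0, 1] (a risk ratio below 1 could otherwise push the quotient
    above one).
    """
    if rr <= 0:
        raise InvalidParameterError("risk ratio must be positive")
    if not 0 <= p_drug <= 1:
        raise InvalidParameterError("p_drug must be a probability")
    return min(1.0, p_drug / rr)


# ---------------------------------------------------------------------------
# Default distribution constants
# ---------------------------------------------------------------------------

def _default_gp_initial() -> DistributionSpec:
    return categorical_from_groups([
        {"prob": 0.65, "values": [4]},
        {"prob": 0.10, "values": [3, 5, 6]},
        {"prob": 0.25, "values": [1, 2]},
    ])


def _default_gp_maintenance() -> DistributionSpec:
    return categorical_from_groups([
        {"prob": 0.55, "values": [3]},
        {"prob": 0.45, "values": [0, 1, 2, 4]},
    ])


# ---------------------------------------------------------------------------
# Model parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParameters:
    """All global inputs of the cohort model with their PSA distributions.

    Point-estimate fields hold the published values used by deterministic
    runs; ``*_dist`` fields hold the distributions sampled by the PSA.  Where
    a published point estimate differs slightly from its distribution's mean
    (the 0.659 utility vs the Beta(40, 20) mean of 0.667), the point estimate
    is used deterministically and the stated distribution probabilistically.
    """

    treatment_weeks: int = 12
    horizon_years_post_treatment: int = 5
    discount_rate: float = 0.035
    wtp_threshold: float = 20_000.0

    utility_recovered: float = 0.866
    utility_sad: float = 0.659
    utility_recovered_dist: DistributionSpec = field(
        default_factory=lambda: DistributionSpec("beta-counts", {"alpha": 4572, "beta": 707})
    )
    utility_sad_dist: DistributionSpec = field(
        default_factory=lambda: DistributionSpec("beta-counts", {"alpha": 40, "beta": 20})
    )

    annual_cost_recovered: float = 645.0
    annual_cost_sad: float = 1037.0
    cost_recovered_dist: DistributionSpec = field(
        default_factory=lambda: DistributionSpec("gamma-mean-se", {"mean": 645.0, "se": 93.0})
    )
    cost_sad_dist: DistributionSpec = field(
        default_factory=lambda: DistributionSpec("gamma-mean-se", {"mean": 1037.0, "se": 209.0})
    )

    relapse_drug_y1_dist: DistributionSpec = field(
        default_factory=lambda: DistributionSpec(
            "midpoint-of-two-betas",
            {"alpha1": 107, "beta1": 293, "alpha2": 222, "beta2": 170},
        )
    )
    relapse_rr_point: float = 3.0
    relapse_rr_dist: DistributionSpec = field(
        default_factory=lambda: DistributionSpec(
            "log-normal-ci", {"mean": 3.0, "ci_low": 0.73, "ci_high": 12.39}
        )
    )
    recovery_y2_5_12yr_dist: DistributionSpec = field(
        default_factory=lambda: DistributionSpec("beta-counts", {"alpha": 65, "beta": 111})
    )
    relapse_y2_5_12yr_dist: DistributionSpec = field(
        default_factory=lambda: DistributionSpec("beta-counts", {"alpha": 26, "beta": 40})
    )
    #: Year-1 relapse on wait list; ``None`` defaults to the annualised
    #: years-2-5 relapse probability (same naturalistic source).
    relapse_waitlist_y1: float | None = None

    gp_visit_unit_cost: float = 46.75
    gp_visits_initial_dist: DistributionSpec = field(default_factory=_default_gp_initial)
    gp_visits_maintenance_dist: DistributionSpec = field(default_factory=_default_gp_maintenance)

    baseline_log_odds_mean: float = -2.629
    baseline_log_odds_variance: float = 1.235

    def __post_init__(self) -> None:
        if not (0 <= self.utility_sad <= 1 and 0 <= self.utility_recovered <= 1):
            raise InvalidParameterError("utilities must lie in [0, 1]")
        if self.utility_recovered <= self.utility_sad:
            raise InvalidParameterError("utility_recovered must exceed utility_sad")
        if not 0 <= self.discount_rate < 1:
            raise InvalidParameterError("discount_rate must lie in [0, 1)")
        if self.horizon_years_post_treatment < 1:
            raise InvalidParameterError("horizon must be at least 1 year")
        if min(self.annual_cost_recovered, self.annual_cost_sad) < 0:
            raise InvalidParameterError("annual state costs must be nonnegative")
        if not 1 <= self.treatment_weeks < 52:
            raise InvalidParameterError("treatment_weeks must lie in [1, 52)")
        if self.relapse_waitlist_y1 is not None and not 0 <= self.relapse_waitlist_y1 <= 1:
            raise InvalidParameterError("relapse_waitlist_y1 must be a probability")
        if self.baseline_log_odds_variance <= 0:
            raise InvalidParameterError("baseline log-odds variance must be positive")

    # -- derived point estimates -------------------------------------------

    @property
    def relapse_drug_y1_point(self) -> float:
        """Year-1 drug relapse at the midpoint of the two pooled beta means."""
        p = self.relapse_drug_y1_dist.params
        return drug_relapse_year1((p["alpha1"], p["beta1"]), (p["alpha2"], p["beta2"]))

    @property
    def relapse_psych_y1_point(self) -> float:
        """Year-1 psychological relapse: drug relapse divided by the risk ratio."""
        return psych_relapse_year1(self.relapse_drug_y1_point, self.relapse_rr_point)

    @property
    def recovery_annual_y2_5(self) -> float:
        """Annual recovery probability in years 2-5 (constant hazard over 12 years)."""
        return multi_year_to_annual_prob(self.recovery_y2_5_12yr_dist.mean(), 12)

    @property
    def relapse_annual_y2_5(self) -> float:
        """Annual relapse probability in years 2-5 (constant hazard over 12 years)."""
        return multi_year_to_annual_prob(self.relapse_y2_5_12yr_dist.mean(), 12)

    @property
    def relapse_waitlist_y1_value(self) -> float:
        if self.relapse_waitlist_y1 is not None:
            return self.relapse_waitlist_y1
        return self.relapse_annual_y2_5

    @classmethod
    def defaults(cls) -> "ModelParameters":
        """Defaults as loaded from the packaged parameter file."""
        from . import datasets

        return datasets.load_default_parameters()


# ---------------------------------------------------------------------------
# Intervention identity
# ---------------------------------------------------------------------------

TREATMENT_CLASSES = {
    "pharmacological",
    "individual-psychological",
    "group-psychological",
    "self-help",
    "pill-placebo",
    "wait-list",
}
RELAPSE_CLASSES = {"drug", "psychological", "waitlist"}


@dataclass(frozen=True)
class InterventionDefinition:
    """Identity and cost profile of one treatment arm.

    ``relapse_class`` selects which year-1 relapse probability applies:
    the drug estimate (all pharmacological arms and pill placebo), the
    psychological estimate (drug estimate divided by the risk ratio), or the
    wait-list estimate.
    """

    id: str
    label: str
    treatment_class: str
    relapse_class: str
    cost_profile: Any = None  # DrugCostProfile | PsychCostProfile | None

    def __post_init__(self) -> None:
        if self.treatment_class not in TREATMENT_CLASSES:
            raise InvalidParameterError(f"unknown treatment class {self.treatment_class!r}")
        if self.relapse_class not in RELAPSE_CLASSES:
            raise InvalidParameterError(f"unknown relapse class {self.relapse_class!r}")
        if self.treatment_class == "pill-placebo" and self.relapse_class != "drug":
            raise InvalidParameterError("pill placebo must use the drug relapse estimate")
        if self.treatment_class == "wait-list" and self.cost_profile is not None:
            raise InvalidParameterError("wait list carries no intervention cost")
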