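"""Synthetic recovery-probability posterior for the 28 treatment arms.

The model's evidence input is a joint posterior of end-of-treatment recovery
probabilities produced by a network meta-analysis.  Only marginal summaries
of that posterior are published (mean, median, 95% credible interval per
arm), so this module reconstructs a stand-in generative model

    logit(p_k) = b + d_k,   b ~ Normal(-2.629, 1.235),
                            d_k ~ Normal(lor_mean_k, lor_sd_k^2)

where ``b`` is the shared wait-list baseline log-odds of recovery and ``d_k``
the log-odds ratio of arm ``k`` versus wait list.  Sharing the baseline draw
across arms within each iteration induces the positive cross-arm correlation
the downstream incremental analysis relies on.  ``(lor_mean_k, lor_sd_k)``
are calibrated so the implied marginals match the published medians and
credible intervals (the logit is monotone, so the median maps exactly; the
mean is then a free check).

A user-supplied draw matrix (delimited text, header of arm ids, one row per
draw) can replace the synthetic posterior via :func:`read_posterior`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .parameters import Z95_WIDTH, InvalidParameterError

#: Conversion factor between a standardised mean difference and a log-odds
#: ratio under the logistic-distribution assumption.
SMD_TO_LOR = -math.pi / math.sqrt(3.0)


class InvalidSummaryError(ValueError):
    """Published summary values violate their required ordering."""


class ConfigurationError(ValueError):
    """The posterior does not cover the requested interventions/draws."""


@dataclass(frozen=True)
class BaselineLogOdds:
    """Normal distribution of the wait-list log-odds of recovery."""

    mean: float = -2.629
    variance: float = 1.235

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise InvalidParameterError("baseline variance must be positive")

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)


@dataclass(frozen=True)
class TreatmentEffectSpec:
    """Log-odds ratio of recovery versus wait list for one arm."""

    intervention_id: str
    lor_mean: float
    lor_sd: float

    def __post_init__(self) -> None:
        if self.lor_sd < 0:
            raise InvalidParameterError("lor_sd must be nonnegative")


@dataclass(frozen=True)
class RecoveryPosterior:
    """Draws x interventions matrix of recovery probabilities."""

    draws: np.ndarray
    interventions: tuple[str, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        draws = np.asarray(self.draws, dtype=float)
        if draws.ndim != 2 or draws.shape[1] != len(self.interventions):
            raise ConfigurationError("draw matrix shape does not match intervention ids")
        if not ((draws > 0.0) & (draws < 1.0)).all():
            raise ConfigurationError("recovery probabilities must lie strictly in (0, 1)")
        object.__setattr__(self, "draws", draws)
        object.__setattr__(self, "interventions", tuple(self.interventions))

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def column(self, intervention_id: str) -> np.ndarray:
        try:
            j = self.interventions.index(intervention_id)
        except ValueError:
            raise ConfigurationError(f"posterior lacks intervention {intervention_id!r}") from None
        return self.draws[:, j]

    def row(self, i: int) -> dict[str, float]:
        return dict(zip(self.interventions, self.draws[i]))


# ---------------------------------------------------------------------------
# SMD bridge
# ---------------------------------------------------------------------------

def smd_to_recovery_lor(smd: float) -> float:
    """Convert a standardised mean difference to a recovery log-odds ratio.

    ``LOR = -(pi / sqrt(3)) * SMD``: a negative SMD (symptom reduction versus
    the comparator) maps to a positive log-odds ratio of recovery.
    """
    if not math.isfinite(smd):
        raise InvalidParameterError("smd must be finite")
    return SMD_TO_LOR * smd


def recovery_lor_to_smd(lor: float) -> float:
    """Inverse of :func:`smd_to_recovery_lor`."""
    if not math.isfinite(lor):
        raise InvalidParameterError("lor must be finite")
    return lor / SMD_TO_LOR


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibrate_effect_spec(
    intervention_id: str,
    median_p: float,
    cri_low: float,
    cri_high: float,
    baseline: BaselineLogOdds,
) -> TreatmentEffectSpec:
    """Calibrate (lor_mean, lor_sd) to a published median and 95% CrI.

    On the logit scale the marginal is Normal(baseline.mean + lor_mean,
    baseline.variance + lor_sd**2), so the median pins ``lor_mean`` and the
    CrI width pins the total variance.  When the published interval is
    narrower than the baseline alone implies, the effect variance is floored
    at zero.
    """
    if not (0.0 < cri_low < median_p < cri_high < 1.0):
        raise InvalidSummaryError(
            f"{intervention_id}: need 0 < cri_low < median < cri_high < 1"
        )
    lor_mean = float(logit(median_p) - baseline.mean)
    total_var = ((logit(cri_high) - logit(cri_low)) / Z95_WIDTH) ** 2
    lor_sd = math.sqrt(max(0.0, total_var - baseline.variance))
    return TreatmentEffectSpec(intervention_id, lor_mean, lor_sd)


def default_effect_specs(
    baseline: BaselineLogOdds | None = None,
) -> tuple[BaselineLogOdds, list[TreatmentEffectSpec]]:
    """Effect specs calibrated to the packaged recovery summaries.

    The wait-list arm is pinned to the exact null effect (0, 0) rather than
    calibrated from its rounded median, so that the wait-list column is the
    baseline distribution itself.
    """
    from . import datasets

    if baseline is None:
        params = datasets.load_default_parameters()
        baseline = BaselineLogOdds(
            params.baseline_log_odds_mean, params.baseline_log_odds_variance
        )
    summaries = datasets.load_recovery_summaries()
    specs = []
    for row in summaries.itertuples():
        if row.Index == "wait_list":
            specs.append(TreatmentEffectSpec("wait_list", 0.0, 0.0))
        else:
            specs.append(
                calibrate_effect_spec(
                    row.Index, row.median, row.cri_low, row.cri_high, baseline
                )
            )
    return baseline, specs


# ---------------------------------------------------------------------------
# Sampling and summaries
# ---------------------------------------------------------------------------

def sample_recovery_posterior(
    specs: Sequence[TreatmentEffectSpec],
    baseline: BaselineLogOdds,
    n_draws: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> RecoveryPosterior:
    """Draw a joint recovery posterior from the calibrated generative model.

    Per draw a single baseline value ``b`` is shared across all arms and the
    per-arm effects ``d_k`` are independent normals; probabilities are
    ``inverse-logit(b + d_k)``.
    """
    if n_draws < 1:
        raise ConfigurationError("n_draws must be at least 1")
    if not specs:
        raise ConfigurationError("no treatment-effect specs supplied")
    ids = [s.intervention_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ConfigurationError("duplicate intervention ids in effect specs")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    b = rng.normal(baseline.mean, baseline.sd, n_draws)
    cols = np.empty((n_draws, len(specs)))
    for j, spec in enumerate(specs):
        d = spec.lor_mean if spec.lor_sd == 0 else rng.normal(spec.lor_mean, spec.lor_sd, n_draws)
        cols[:, j] = expit(b + d)
    # expit underflows to exactly 0/1 beyond |x| ~ 37; keep entries interior.
    tiny = np.finfo(float).tiny
    np.clip(cols, tiny, 1.0 - np.finfo(float).epsneg, out=cols)
    return RecoveryPosterior(cols, tuple(ids), seed if isinstance(seed, int) else None)


def summarize_posterior(posterior: RecoveryPosterior) -> pd.DataFrame:
    """Column-wise mean, median and 95% interval, one row per arm."""
    draws = posterior.draws
    return pd.DataFrame(
        {
            "mean": draws.mean(axis=0),
            "median": np.median(draws, axis=0),
            "cri_low": np.quantile(draws, 0.025, axis=0),
            "cri_high": np.quantile(draws, 0.975, axis=0),
        },
        index=pd.Index(posterior.interventions, name="id"),
    )


# ---------------------------------------------------------------------------
# Draw-matrix I/O
# ---------------------------------------------------------------------------

def write_posterior(posterior: RecoveryPosterior, path) -> None:
    """Export the draw matrix as CSV: header of arm ids, one row per draw."""
    frame = pd.DataFrame(posterior.draws, columns=list(posterior.interventions))
    frame.to_csv(path, index=False, float_format="%.17g")


def read_posterior(path) -> RecoveryPosterior:
    """Load a user-supplied draw matrix written by :func:`write_posterior`."""
    frame = pd.read_csv(path)
    return RecoveryPosterior(frame.to_numpy(dtype=float), tuple(frame.columns))
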