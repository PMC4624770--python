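"""Decision analytics: net monetary benefit, dominance, frontiers.

Given per-arm mean costs and QALYs the incremental analysis sorts by
effectiveness, removes absolutely dominated arms (more costly, no more
effective than another), removes extendedly dominated arms (more costly and
less effective than a convex combination of two others — the standard
increasing-ICER sweep along the efficiency frontier) and reports the ICERs
between adjacent frontier members.

The cost-effectiveness acceptability frontier (CEAF) reports, per
willingness-to-pay threshold, the arm with the highest *mean* NMB together
with the probability (across PSA iterations) that this arm has the highest
NMB of all arms; iteration-level ties split their weight equally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .effects import ConfigurationError
from .psa import PSAResult

FRONTIER = "frontier"
DOMINATED = "dominated"
EXTENDEDLY_DOMINATED = "extendedly dominated"

#: Default willingness-to-pay grid, GBP per QALY.
DEFAULT_THRESHOLDS = np.arange(0, 50_001, 250)


def net_monetary_benefit(cost, qaly, threshold: float):
    """NMB = threshold x QALYs - cost (vectorised)."""
    if threshold < 0:
        raise ConfigurationError("willingness-to-pay threshold must be nonnegative")
    return threshold * np.asarray(qaly) - np.asarray(cost)


@dataclass(frozen=True)
class FrontierResult:
    """Dominance classification plus the efficiency frontier with ICERs."""

    status: dict[str, str]
    #: frontier ids ordered by increasing QALYs
    frontier: tuple[str, ...]
    #: ICER of each frontier member versus its predecessor (first: None)
    icers: dict[str, float | None]


def incremental_frontier(
    ids: Sequence[str],
    mean_costs: Sequence[float],
    mean_qalys: Sequence[float],
) -> FrontierResult:
    """Classify arms by dominance and build the efficiency frontier.

    Ties are deterministic: at equal QALYs the cheaper arm wins; full
    cost/QALY ties collapse onto the lexicographically first id.
    """
    if len(ids) == 0:
        raise ConfigurationError("at least one intervention required")
    if not (len(ids) == len(mean_costs) == len(mean_qalys)):
        raise ConfigurationError("ids, costs and qalys must have equal length")
    table = sorted(zip(ids, map(float, mean_costs), map(float, mean_qalys)),
                   key=lambda t: (t[2], t[1], t[0]))

    status: dict[str, str] = {}
    candidates: list[tuple[str, float, float]] = []
    for name, cost, qaly in table:
        dominated = any(
            other_q >= qaly and other_c <= cost and (other_q > qaly or other_c < cost or other < name)
            for other, other_c, other_q in table
            if other != name
        )
        if dominated:
            status[name] = DOMINATED
        else:
            candidates.append((name, cost, qaly))

    # Increasing-ICER sweep: pop the previous frontier member whenever the
    # newcomer's ICER against it is no larger than its own ICER.
    frontier: list[tuple[str, float, float]] = []
    for name, cost, qaly in candidates:
        while len(frontier) >= 2:
            prev_name, prev_cost, prev_qaly = frontier[-1]
            _, prev2_cost, prev2_qaly = frontier[-2]
            icer_prev = (prev_cost - prev2_cost) / (prev_qaly - prev2_qaly)
            icer_new = (cost - prev_cost) / (qaly - prev_qaly)
            if icer_new <= icer_prev:
                status[prev_name] = EXTENDEDLY_DOMINATED
                frontier.pop()
            else:
                break
        frontier.append((name, cost, qaly))

    icers: dict[str, float | None] = {}
    for k, (name, cost, qaly) in enumerate(frontier):
        status[name] = FRONTIER
        if k == 0:
            icers[name] = None
        else:
            _, prev_cost, prev_qaly = frontier[k - 1]
            icers[name] = (cost - prev_cost) / (qaly - prev_qaly)
    return FrontierResult(status, tuple(name for name, _, _ in frontier), icers)


def rank_interventions(nmb: pd.Series) -> pd.Series:
    """Rank 1..n by descending NMB; ties broken by id."""
    order = sorted(nmb.index, key=lambda name: (-nmb[name], name))
    return pd.Series({name: rank for rank, name in enumerate(order, start=1)}, name="rank").reindex(
        nmb.index
    )


def summarize_means(
    ids: Sequence[str],
    mean_costs: Sequence[float],
    mean_qalys: Sequence[float],
    mean_fraction_well: Sequence[float] | None = None,
    threshold: float = 20_000.0,
) -> pd.DataFrame:
    """Per-arm summary table: means, NMB, rank, dominance status, ICER."""
    frame = pd.DataFrame(
        {"mean_cost": list(map(float, mean_costs)), "mean_qaly": list(map(float, mean_qalys))},
        index=pd.Index(ids, name="id"),
    )
    if mean_fraction_well is not None:
        frame["pct_well_at_horizon"] = 100.0 * np.asarray(mean_fraction_well, dtype=float)
    frame["nmb"] = net_monetary_benefit(frame["mean_cost"], frame["mean_qaly"], threshold)
    frame["rank"] = rank_interventions(frame["nmb"])
    result = incremental_frontier(list(frame.index), frame["mean_cost"], frame["mean_qaly"])
    frame["status"] = [result.status[name] for name in frame.index]
    frame["icer"] = [result.icers.get(name, np.nan) for name in frame.index]
    frame["icer"] = frame["icer"].astype(float)
    return frame.sort_values("mean_qaly", ascending=False)


def summarize(psa: PSAResult, threshold: float = 20_000.0) -> pd.DataFrame:
    """Summary table from a PSA run (means across iterations)."""
    return summarize_means(
        list(psa.interventions),
        psa.costs.mean(axis=0),
        psa.qalys.mean(axis=0),
        psa.fraction_well.mean(axis=0),
        threshold,
    )


@dataclass(frozen=True)
class CEAFPoint:
    """One threshold on the acceptability frontier."""

    threshold: float
    best: str
    probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ConfigurationError("probability must lie in [0, 1]")


def _win_weights(nmb_matrix: np.ndarray) -> np.ndarray:
    """Per-iteration winner weights; ties split equally."""
    best = nmb_matrix.max(axis=1, keepdims=True)
    winners = nmb_matrix == best
    return winners / winners.sum(axis=1, keepdims=True)


def ceaf(psa: PSAResult, thresholds: Sequence[float] = DEFAULT_THRESHOLDS) -> list[CEAFPoint]:
    """Cost-effectiveness acceptability frontier over a threshold grid.

    Per threshold: the arm with the highest mean NMB (ties to the first id),
    and the fraction of iterations in which that arm attains the highest NMB.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ConfigurationError("threshold grid must be nonempty")
    ids = list(psa.interventions)
    points = []
    for threshold in thresholds:
        nmb = net_monetary_benefit(psa.costs, psa.qalys, threshold)
        mean_nmb = nmb.mean(axis=0)
        best_j = min(
            range(len(ids)), key=lambda j: (-mean_nmb[j], ids[j])
        )
        prob = _win_weights(nmb)[:, best_j].mean()
        points.append(CEAFPoint(float(threshold), ids[best_j], float(prob)))
    return points


def ceaf_frame(points: Sequence[CEAFPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "threshold": [p.threshold for p in points],
            "best": [p.best for p in points],
            "probability": [p.probability for p in points],
        }
    )


def ce_plane(summary: pd.DataFrame, reference: str = "wait_list") -> pd.DataFrame:
    """Incremental mean costs/QALYs of every arm versus a reference arm."""
    if reference not in summary.index:
        raise ConfigurationError(f"reference arm {reference!r} not in summary")
    ref = summary.loc[reference]
    frame = pd.DataFrame(
        {
            "delta_cost": summary["mean_cost"] - ref["mean_cost"],
            "delta_qaly": summary["mean_qaly"] - ref["mean_qaly"],
            "status": summary["status"],
        }
    )
    return frame.drop(index=reference)
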