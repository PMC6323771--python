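"""Discounted accumulation, ICER/dominance frontier, NMB and price threshold.

Costs and outcomes discount at an annual rate r compounded continuously per
month: cycle t (0-based months since entry) carries the factor
(1 + r)^(-t/12), with t = 0 for the first cycle.  Rewards accrue to the
state occupied at the start of each cycle; life years and QALYs accrue at
1/12 of the (utility-weighted) alive mass per monthly cycle.

The efficiency frontier sorts strategies by discounted cost, removes strict
dominance (costlier, no more effective) and then extended dominance
(iteratively, until the frontier's incremental cost-effectiveness ratios
strictly increase).

The price threshold solver bisects on the imatinib tablet price -- rescaling
the drug cost in every imatinib-dispensing state, adjuvant and recurrence
alike -- until the ICER of one strategy over another meets the
willingness-to-pay ceiling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    CohortTrace,
    DEFAULT_HORIZON,
    HealthState,
    StateRewards,
    StrategyDefinition,
    make_strategy,
    run_cohort,
    state_rewards,
)
from .parameters import ParameterSet

__all__ = [
    "EconResult",
    "FrontierResult",
    "DOMINATED_ICER",
    "UNDEFINED_ICER",
    "accumulate",
    "evaluate_strategy",
    "evaluate_options",
    "icer",
    "efficiency_frontier",
    "nmb",
    "threshold_price",
    "ThresholdResult",
]


@dataclass(frozen=True)
class EconResult:
    """Lifetime totals for one strategy (THB, years, QALYs)."""

    strategy_id: str
    cost_undisc: float
    cost_disc: float
    ly_undisc: float
    ly_disc: float
    qaly_undisc: float
    qaly_disc: float

    def __post_init__(self):
        for name in ("cost", "ly", "qaly"):
            und = getattr(self, f"{name}_undisc")
            dis = getattr(self, f"{name}_disc")
            if und < 0 or dis < 0:
                raise ValueError(f"{name} totals must be non-negative")
            if dis > und * (1 + 1e-12) + 1e-9:
                raise ValueError(f"discounted {name} exceeds undiscounted")
        if self.qaly_undisc > self.ly_undisc * (1 + 1e-12) + 1e-9:
            raise ValueError("QALYs cannot exceed life years")


def accumulate(trace: CohortTrace, rewards: StateRewards, annual_rate: float) -> EconResult:
    """Fold a cohort trace through per-state rewards into lifetime totals."""
    if annual_rate < 0:
        raise ValueError("discount rate must be non-negative")
    occ = trace.occupancy[:-1]  # states occupied at the start of each cycle
    months = np.arange(occ.shape[0])
    df = (1.0 + annual_rate) ** (-months / 12.0)
    ones = np.ones_like(df)  # same dot-product path so rate 0 is exact

    cost_stream = occ @ rewards.cost_vector()
    alive = np.ones(occ.shape[1])
    alive[HealthState.Dead] = 0.0
    ly_stream = occ @ alive
    qaly_stream = occ @ (rewards.utility_vector() * alive)

    return EconResult(
        strategy_id=trace.strategy_id,
        cost_undisc=float(cost_stream @ ones),
        cost_disc=float(cost_stream @ df),
        ly_undisc=float(ly_stream @ ones / 12.0),
        ly_disc=float(ly_stream @ df / 12.0),
        qaly_undisc=float(qaly_stream @ ones / 12.0),
        qaly_disc=float(qaly_stream @ df / 12.0),
    )


def evaluate_strategy(
    strategy: StrategyDefinition,
    params: ParameterSet,
    life_table: dict[int, float],
    horizon_cycles: int = DEFAULT_HORIZON,
    price_override: float | None = None,
    trace: CohortTrace | None = None,
) -> EconResult:
    """Run (or reuse) the cohort trace and accumulate lifetime totals."""
    if trace is None:
        trace = run_cohort(strategy, params, life_table, horizon_cycles)
    rewards = state_rewards(strategy, params, price_override=price_override)
    return accumulate(trace, rewards, params.annual_discount_rate)


def evaluate_options(
    params: ParameterSet,
    life_table: dict[int, float],
    option_ids=("1", "4", "2.1", "3.1", "2.2", "3.2"),
    horizon_cycles: int = DEFAULT_HORIZON,
) -> dict[str, EconResult]:
    return {
        oid: evaluate_strategy(make_strategy(oid), params, life_table, horizon_cycles)
        for oid in option_ids
    }


#: sentinel ICERs returned by :func:`icer`
DOMINATED_ICER = float("-inf")  # cheaper and more effective
UNDEFINED_ICER = float("nan")  # no QALY difference


def icer(lower: EconResult, higher: EconResult) -> float:
    """Incremental cost per QALY of ``higher`` (more effective) vs ``lower``.

    Returns ``UNDEFINED_ICER`` (nan) when discounted QALYs coincide, and
    ``DOMINATED_ICER`` (-inf) when ``higher`` is both cheaper and more
    effective (dominance, not a ratio).
    """
    dq = higher.qaly_disc - lower.qaly_disc
    dc = higher.cost_disc - lower.cost_disc
    if dq == 0.0:
        return UNDEFINED_ICER
    if dc < 0.0 and dq > 0.0:
        return DOMINATED_ICER
    return dc / dq


def nmb(result: EconResult, wtp: float) -> float:
    """Net monetary benefit at a willingness-to-pay per QALY."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * result.qaly_disc - result.cost_disc


@dataclass(frozen=True)
class FrontierResult:
    """Cost-sorted strategies with dominance labels and frontier ICERs."""

    order: tuple[str, ...]  # strategy ids sorted by discounted cost
    labels: dict[str, str]  # on_frontier | strictly_dominated | extendedly_dominated
    icers: dict[str, float | None]  # frontier members: ICER vs previous member

    @property
    def frontier(self) -> tuple[str, ...]:
        return tuple(sid for sid in self.order if self.labels[sid] == "on_frontier")

    def to_frame(self, results: dict[str, EconResult] | None = None) -> pd.DataFrame:
        rows = []
        for sid in self.order:
            row = {"strategy": sid, "label": self.labels[sid], "icer_vs_previous": self.icers.get(sid)}
            if results:
                r = results[sid]
                row.update(
                    cost_disc=r.cost_disc,
                    qaly_disc=r.qaly_disc,
                    ly_undisc=r.ly_undisc,
                    ly_disc=r.ly_disc,
                )
            rows.append(row)
        return pd.DataFrame(rows)


def efficiency_frontier(results: dict[str, EconResult] | list[EconResult]) -> FrontierResult:
    """Label strict/extended dominance over a set of strategies.

    Deterministic and invariant to input order; cost ties break by QALYs
    (then id) so collinear middle points stay on the frontier.
    """
    if isinstance(results, dict):
        pool = list(results.values())
    else:
        pool = list(results)
    if len(pool) < 2:
        raise ValueError("frontier analysis needs at least two strategies")
    pool.sort(key=lambda r: (r.cost_disc, r.qaly_disc, r.strategy_id))
    order = tuple(r.strategy_id for r in pool)
    labels = {r.strategy_id: "on_frontier" for r in pool}

    # strict dominance: some cheaper-or-equal strategy is at least as effective
    for i, r in enumerate(pool):
        for other in pool[:i]:
            if other.qaly_disc >= r.qaly_disc:
                labels[r.strategy_id] = "strictly_dominated"
                break

    # extended dominance: prune until frontier ICERs strictly increase
    def survivors():
        return [r for r in pool if labels[r.strategy_id] == "on_frontier"]

    changed = True
    while changed:
        changed = False
        surv = survivors()
        for i in range(1, len(surv) - 1):
            icer_prev = icer(surv[i - 1], surv[i])
            icer_next = icer(surv[i], surv[i + 1])
            if icer_next < icer_prev:  # ties (collinear points) stay on the frontier
                labels[surv[i].strategy_id] = "extendedly_dominated"
                changed = True
                break

    icers: dict[str, float | None] = {}
    surv = survivors()
    for i, r in enumerate(surv):
        icers[r.strategy_id] = None if i == 0 else icer(surv[i - 1], r)
    return FrontierResult(order=order, labels=labels, icers=icers)


@dataclass(frozen=True)
class ThresholdResult:
    price: float
    achieved_icer: float
    iterations: int
    wtp: float
    strategy_id: str
    comparator_id: str


def threshold_price(
    params: ParameterSet,
    life_table: dict[int, float],
    strategy_id: str = "2.2",
    comparator_id: str = "1",
    wtp: float | None = None,
    price_bounds: tuple[float, float] = (1.0, 3659.40),
    horizon_cycles: int = DEFAULT_HORIZON,
    rtol: float = 1e-6,
) -> ThresholdResult:
    """Imatinib tablet price at which the strategy's ICER meets the ceiling.

    Traces do not depend on price, so they are run once; bisection then acts
    on the cost accumulation alone.  Requires the ICER to bracket ``wtp``
    over ``price_bounds``.
    """
    if wtp is None:
        wtp = params.wtp
    lo, hi = price_bounds
    if not 0 < lo < hi:
        raise ValueError("price bounds must be positive and increasing")

    strat = make_strategy(strategy_id)
    comp = make_strategy(comparator_id)
    trace_s = run_cohort(strat, params, life_table, horizon_cycles)
    trace_c = run_cohort(comp, params, life_table, horizon_cycles)

    def icer_at(price: float) -> float:
        hi_res = evaluate_strategy(strat, params, life_table, price_override=price, trace=trace_s)
        lo_res = evaluate_strategy(comp, params, life_table, price_override=price, trace=trace_c)
        value = icer(lo_res, hi_res)
        if math.isnan(value):
            raise ValueError("ICER undefined: no QALY difference between the pair")
        return value

    f_lo = icer_at(lo) - wtp
    f_hi = icer_at(hi) - wtp
    if f_lo == 0.0:
        return ThresholdResult(lo, wtp, 0, wtp, strategy_id, comparator_id)
    if f_hi == 0.0:
        return ThresholdResult(hi, wtp, 0, wtp, strategy_id, comparator_id)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"no sign change over price bounds: ICER({lo:.2f}) = {f_lo + wtp:,.0f}, "
            f"ICER({hi:.2f}) = {f_hi + wtp:,.0f}, wtp = {wtp:,.0f}"
        )

    # bisect on price until the achieved ICER is within rtol of the ceiling
    # (or the price bracket is exhausted, if the ICER steps over the target)
    lo_p, hi_p, f_lo_p = lo, hi, f_lo
    iterations = 2
    price, achieved = lo_p, f_lo + wtp
    for _ in range(200):
        price = 0.5 * (lo_p + hi_p)
        f_mid = icer_at(price) - wtp
        achieved = f_mid + wtp
        iterations += 1
        if abs(f_mid) / wtp < rtol or (hi_p - lo_p) < 1e-12 * hi:
            break
        if (f_mid < 0) == (f_lo_p < 0):
            lo_p, f_lo_p = price, f_mid
        else:
            hi_p = price
    return ThresholdResult(price, achieved, iterations, wtp, strategy_id, comparator_id)
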