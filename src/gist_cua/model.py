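"""Markov cohort engine for adjuvant imatinib after high-risk GIST resection.

The published decision problem draws three health states (no recurrence,
recurrence, dead), but treatment after recurrence depends on history -- on
whether recurrence struck while the patient was still taking adjuvant
imatinib -- so the engine expands to eight states:

    NoRec_NoAdj         no recurrence, never on adjuvant therapy
    NoRec_OnAdj         no recurrence, currently taking adjuvant imatinib
    NoRec_Completed     no recurrence, adjuvant course finished
    NoRec_Discontinued  no recurrence, stopped adjuvant early
    Rec_Imatinib        metastatic recurrence on imatinib 400 mg/day
    Rec_Sunitinib       metastatic recurrence on sunitinib 50 mg/day
    Rec_BSC             metastatic recurrence on best supportive care
    Dead                absorbing

Cycles are one month; the cohort enters at age 60 in the relevant
no-recurrence state.  Monthly exits compete as plain probabilities
(renormalised proportionally in the rare event a sampled row exceeds one).
Death in any alive state combines the state's disease-specific monthly
probability with age-specific background mortality under independence; in
recurrence states the chart-review year-banded disease mortality applies on
top of the treatment-specific one (this reading reproduces the published
lifetime costs; a parameter-set switch restores treatment-specific-only).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from .evidence import (
    apply_hazard_ratio,
    build_discontinuation_schedule,
    build_gist_death_schedule,
    build_recurrence_schedule,
)
from .parameters import ParameterSet

__all__ = [
    "HealthState",
    "Treatment",
    "StrategyDefinition",
    "StateRewards",
    "CohortTrace",
    "OPTION_IDS",
    "make_strategy",
    "monthly_drug_cost",
    "state_rewards",
    "combine_mortality",
    "monthly_background_mortality",
    "transition_matrix",
    "run_cohort",
    "overall_survival",
]

DAYS_PER_MONTH = 365.0 / 12.0
DEFAULT_HORIZON = 480  # months; age 100 from a 60-year-old cohort


class HealthState(IntEnum):
    NoRec_NoAdj = 0
    NoRec_OnAdj = 1
    NoRec_Completed = 2
    NoRec_Discontinued = 3
    Rec_Imatinib = 4
    Rec_Sunitinib = 5
    Rec_BSC = 6
    Dead = 7


N_STATES = len(HealthState)


class Treatment(IntEnum):
    """Active treatment lines after metastatic recurrence."""

    IMATINIB = HealthState.Rec_Imatinib
    SUNITINIB = HealthState.Rec_Sunitinib
    BSC = HealthState.Rec_BSC


@dataclass(frozen=True)
class StrategyDefinition:
    """One treatment option: adjuvant duration plus recurrence pathways.

    ``recurrence_during_adjuvant`` is the treatment sequence for patients
    whose recurrence strikes while on (or after stopping early) adjuvant
    imatinib; ``recurrence_after_adjuvant`` applies after course completion
    and to strategies without adjuvant therapy.  Sequences end in BSC.
    """

    option_id: str
    adjuvant_months: int
    recurrence_during_adjuvant: tuple[Treatment, ...]
    recurrence_after_adjuvant: tuple[Treatment, ...]

    def __post_init__(self):
        if self.adjuvant_months not in (0, 12, 36):
            raise ValueError(f"adjuvant_months must be 0, 12 or 36, got {self.adjuvant_months}")
        if self.recurrence_after_adjuvant[-1] is not Treatment.BSC:
            raise ValueError("recurrence sequences must end in BSC")
        if self.adjuvant_months and self.recurrence_during_adjuvant[-1] is not Treatment.BSC:
            raise ValueError("recurrence sequences must end in BSC")

    @property
    def hazard_ratio_name(self) -> str:
        if self.adjuvant_months == 12:
            return "hr_adj_1yr"
        if self.adjuvant_months == 36:
            return "hr_adj_3yr"
        raise ValueError(f"option {self.option_id} has no adjuvant hazard ratio")

    def successor(self, line: Treatment) -> Treatment | None:
        """Next treatment line after progression on ``line``, if any.

        The successor must be unambiguous across the strategy's pathways.
        """
        nxt: set[Treatment] = set()
        for seq in (self.recurrence_during_adjuvant, self.recurrence_after_adjuvant):
            if line in seq:
                i = seq.index(line)
                if i + 1 < len(seq):
                    nxt.add(seq[i + 1])
        if len(nxt) > 1:  # pragma: no cover - excluded by the published options
            raise ValueError(f"ambiguous successor of {line.name} in option {self.option_id}")
        return nxt.pop() if nxt else None


_OPTIONS = {
    "1": (0, (), (Treatment.IMATINIB, Treatment.BSC)),
    "2.1": (12, (Treatment.BSC,), (Treatment.IMATINIB, Treatment.BSC)),
    "2.2": (36, (Treatment.BSC,), (Treatment.IMATINIB, Treatment.BSC)),
    "3.1": (12, (Treatment.SUNITINIB, Treatment.BSC),
            (Treatment.IMATINIB, Treatment.SUNITINIB, Treatment.BSC)),
    "3.2": (36, (Treatment.SUNITINIB, Treatment.BSC),
            (Treatment.IMATINIB, Treatment.SUNITINIB, Treatment.BSC)),
    "4": (0, (), (Treatment.IMATINIB, Treatment.SUNITINIB, Treatment.BSC)),
}

OPTION_IDS = tuple(_OPTIONS)


def make_strategy(option_id: str | float) -> StrategyDefinition:
    """Build one of the six published treatment options by its label."""
    key = str(option_id)
    if key not in _OPTIONS:
        raise ValueError(f"unknown option {option_id!r}; expected one of {OPTION_IDS}")
    months, during, after = _OPTIONS[key]
    return StrategyDefinition(
        option_id=key,
        adjuvant_months=months,
        recurrence_during_adjuvant=during,
        recurrence_after_adjuvant=after,
    )


def monthly_drug_cost(unit_price: float, units_per_day: float, days_per_month: float = DAYS_PER_MONTH) -> int:
    """Monthly drug cost from a unit price, truncated to whole THB."""
    if unit_price <= 0 or units_per_day <= 0 or days_per_month <= 0:
        raise ValueError("all drug-cost inputs must be positive")
    return int(unit_price * units_per_day * days_per_month)


@dataclass(frozen=True)
class StateRewards:
    """Monthly cost (THB) and utility weight per health state."""

    costs: tuple[float, ...]
    utilities: tuple[float, ...]

    def __post_init__(self):
        if len(self.costs) != N_STATES or len(self.utilities) != N_STATES:
            raise ValueError("rewards must cover all health states")
        if any(c < 0 for c in self.costs):
            raise ValueError("costs must be non-negative")
        if any(not 0.0 <= u <= 1.0 for u in self.utilities):
            raise ValueError("utilities must lie in [0, 1]")
        if self.costs[HealthState.Dead] != 0 or self.utilities[HealthState.Dead] != 0:
            raise ValueError("the dead state carries no cost and no utility")

    def cost_vector(self) -> np.ndarray:
        return np.asarray(self.costs, dtype=float)

    def utility_vector(self) -> np.ndarray:
        return np.asarray(self.utilities, dtype=float)


def state_rewards(
    strategy: StrategyDefinition,
    params: ParameterSet,
    price_override: float | None = None,
) -> StateRewards:
    """Per-state monthly costs and utilities for one strategy.

    Costs stack drug cost, treatment/monitoring cost, adverse-event cost
    (on adjuvant only) and direct non-medical cost (visit rate times the sum
    of travel, food and caregiver costs per visit).  ``price_override``
    rescales the imatinib monthly drug cost proportionally to a hypothetical
    tablet price, wherever imatinib is dispensed (adjuvant and recurrence).
    """
    visit_cost = params["cost_travel_visit"] + params["cost_food_visit"] + params["cost_caregiver_visit"]
    ima_drug = params["cost_imatinib_month"]
    if price_override is not None:
        if price_override < 0:
            raise ValueError("price_override must be non-negative")
        ima_drug *= price_override / params["price_imatinib_tablet"]
    offdrug_norec = params["cost_norec_noadj"] + params["visits_norec_noadj"] * visit_cost
    costs = [0.0] * N_STATES
    costs[HealthState.NoRec_NoAdj] = offdrug_norec
    costs[HealthState.NoRec_Completed] = offdrug_norec
    costs[HealthState.NoRec_Discontinued] = offdrug_norec
    costs[HealthState.NoRec_OnAdj] = (
        ima_drug
        + params["cost_norec_onadj"]
        + params["cost_ae_adjuvant"]
        + params["visits_norec_onadj"] * visit_cost
    )
    rec_visits = params["visits_rec"] * visit_cost
    costs[HealthState.Rec_Imatinib] = ima_drug + params["cost_rec_imatinib"] + rec_visits
    costs[HealthState.Rec_Sunitinib] = (
        params["cost_sunitinib_month"] + params["cost_rec_sunitinib"] + rec_visits
    )
    costs[HealthState.Rec_BSC] = params["cost_rec_bsc"] + rec_visits

    utils = [0.0] * N_STATES
    utils[HealthState.NoRec_NoAdj] = params["u_norec_offdrug"]
    utils[HealthState.NoRec_Completed] = params["u_norec_offdrug"]
    utils[HealthState.NoRec_Discontinued] = params["u_norec_offdrug"]
    utils[HealthState.NoRec_OnAdj] = params["u_norec_onadj"]
    utils[HealthState.Rec_Imatinib] = params["u_rec_imatinib"]
    utils[HealthState.Rec_Sunitinib] = params["u_rec_sunitinib"]
    utils[HealthState.Rec_BSC] = params["u_rec_bsc"]
    return StateRewards(costs=tuple(costs), utilities=tuple(utils))


def combine_mortality(p_cause: float, p_background: float) -> float:
    """Independent competing risks: 1 - (1-p_cause)(1-p_background)."""
    if not 0.0 <= p_cause <= 1.0 or not 0.0 <= p_background <= 1.0:
        raise ValueError("probabilities must lie in [0, 1]")
    return 1.0 - (1.0 - p_cause) * (1.0 - p_background)


def monthly_background_mortality(life_table: dict[int, float], age: float) -> float:
    """Monthly all-cause probability at ``age`` from an annual life table.

    Annual q(floor(age)) converts via the constant-hazard rate transform;
    beyond table coverage the last entry applies.
    """
    key = int(math.floor(age))
    if key not in life_table:
        key = max(life_table)
    q = life_table[key]
    return 1.0 - (1.0 - q) ** (1.0 / 12.0)


_RENORM_WARNED = False


def _finish_row(matrix: np.ndarray, state: int, exits: dict[int, float], stay_state: int) -> None:
    """Place competing exits, renormalising proportionally if they exceed 1."""
    global _RENORM_WARNED
    total = sum(exits.values())
    if total > 1.0:
        if not _RENORM_WARNED:
            warnings.warn(
                f"competing exits from {HealthState(state).name} sum to {total:.4f} > 1; "
                "renormalising proportionally",
                stacklevel=3,
            )
            _RENORM_WARNED = True
        exits = {k: v / total for k, v in exits.items()}
        total = 1.0
    for target, p in exits.items():
        matrix[state, target] += p
    matrix[state, stay_state] += 1.0 - total


class _ScheduleBundle:
    """Per-strategy schedules resolved once, then queried per cycle."""

    def __init__(self, strategy: StrategyDefinition, params: ParameterSet):
        self.strategy = strategy
        self.params = params
        self.rec_on_adj = build_recurrence_schedule(params, strategy)
        self.rec_base = build_recurrence_schedule(params, make_strategy("1"))
        self.gist_death = build_gist_death_schedule(params)
        self.disc = build_discontinuation_schedule(params, strategy)


def _assemble_matrix(bundle: _ScheduleBundle, life_table, cycle: int) -> np.ndarray:
    strategy, params = bundle.strategy, bundle.params
    age = params.start_age + (cycle - 1) / 12.0
    bg = monthly_background_mortality(life_table, age) if params.background_mortality else 0.0

    d_norec = combine_mortality(bundle.gist_death(cycle), bg)
    r_base = bundle.rec_base(cycle)

    during_first = (
        int(strategy.recurrence_during_adjuvant[0]) if strategy.adjuvant_months else None
    )
    after_first = int(strategy.recurrence_after_adjuvant[0])

    m = np.zeros((N_STATES, N_STATES))
    s = HealthState
    _finish_row(m, s.NoRec_NoAdj, {after_first: r_base, s.Dead: d_norec}, s.NoRec_NoAdj)
    _finish_row(m, s.NoRec_Completed, {after_first: r_base, s.Dead: d_norec}, s.NoRec_Completed)

    if strategy.adjuvant_months and cycle <= strategy.adjuvant_months:
        # within the adjuvant window: hazard-ratio-reduced recurrence,
        # discontinuation, death; survivors of the final window cycle complete
        stay = s.NoRec_Completed if cycle == strategy.adjuvant_months else s.NoRec_OnAdj
        _finish_row(
            m,
            s.NoRec_OnAdj,
            {
                during_first: bundle.rec_on_adj(cycle),
                s.NoRec_Discontinued: bundle.disc(cycle),
                s.Dead: d_norec,
            },
            stay,
        )
        _finish_row(
            m, s.NoRec_Discontinued, {during_first: r_base, s.Dead: d_norec}, s.NoRec_Discontinued
        )
    else:
        # outside the window these states are unoccupied; keep rows stochastic
        m[s.NoRec_OnAdj, s.NoRec_Completed] = 1.0
        if strategy.adjuvant_months:
            _finish_row(
                m, s.NoRec_Discontinued, {during_first: r_base, s.Dead: d_norec}, s.NoRec_Discontinued
            )
        else:
            m[s.NoRec_Discontinued, s.NoRec_Discontinued] = 1.0

    death_by_line = {
        Treatment.IMATINIB: params["p_death_imatinib"],
        Treatment.SUNITINIB: params["p_death_sunitinib"],
        Treatment.BSC: params["p_death_bsc"],
    }
    prog_by_line = {
        Treatment.IMATINIB: params["p_prog_imatinib"],
        Treatment.SUNITINIB: params["p_prog_sunitinib"],
        Treatment.BSC: 0.0,
    }
    for line in Treatment:
        state = int(line)
        d = death_by_line[line]
        if params.gist_death_in_recurrence:
            d = combine_mortality(d, bundle.gist_death(cycle))
        d = combine_mortality(d, bg)
        exits = {int(s.Dead): d}
        nxt = strategy.successor(line)
        if nxt is not None:
            exits[int(nxt)] = prog_by_line[line]
        _finish_row(m, state, exits, state)

    m[s.Dead, s.Dead] = 1.0
    return m


def transition_matrix(
    strategy: StrategyDefinition,
    params: ParameterSet,
    life_table: dict[int, float],
    cycle: int,
) -> np.ndarray:
    """Row-stochastic monthly transition matrix for one cycle (cycle >= 1)."""
    if cycle < 1:
        raise ValueError(f"cycle must be >= 1, got {cycle}")
    return _assemble_matrix(_ScheduleBundle(strategy, params), life_table, cycle)


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy per monthly cycle, row 0 = model entry."""

    strategy_id: str
    occupancy: np.ndarray  # shape (horizon + 1, N_STATES)
    start_age: float

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def ages(self) -> np.ndarray:
        return self.start_age + np.arange(self.occupancy.shape[0]) / 12.0

    @property
    def residual_alive(self) -> float:
        """Cohort mass still alive at the horizon cap."""
        return float(1.0 - self.occupancy[-1, HealthState.Dead])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=[st.name for st in HealthState])
        df.insert(0, "age", self.ages)
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_cohort(
    strategy: StrategyDefinition,
    params: ParameterSet,
    life_table: dict[int, float],
    horizon_cycles: int = DEFAULT_HORIZON,
) -> CohortTrace:
    """Propagate the cohort for ``horizon_cycles`` months.

    Deterministic given its inputs.  Transition matrices are piecewise
    constant in time (band edges, birthdays, and the adjuvant completion
    cycle), so they are cached on their assembled probability pattern.
    """
    if horizon_cycles < 1:
        raise ValueError("horizon must be >= 1")
    bundle = _ScheduleBundle(strategy, params)
    occ = np.zeros((horizon_cycles + 1, N_STATES))
    start_state = HealthState.NoRec_OnAdj if strategy.adjuvant_months else HealthState.NoRec_NoAdj
    occ[0, start_state] = 1.0

    cache: dict[tuple, np.ndarray] = {}
    for cycle in range(1, horizon_cycles + 1):
        age_key = int(math.floor(params.start_age + (cycle - 1) / 12.0))
        if not strategy.adjuvant_months:
            window = 0  # no adjuvant phase structure
        elif cycle < strategy.adjuvant_months:
            window = 1
        elif cycle == strategy.adjuvant_months:
            window = 2  # completion cycle: survivors relabel to Completed
        else:
            window = 3
        key = (
            age_key,
            bundle.rec_base(cycle),
            bundle.gist_death(cycle),
            bundle.disc(cycle),
            window,
        )
        matrix = cache.get(key)
        if matrix is None:
            matrix = _assemble_matrix(bundle, life_table, cycle)
            cache[key] = matrix
        occ[cycle] = occ[cycle - 1] @ matrix
    return CohortTrace(strategy_id=strategy.option_id, occupancy=occ, start_age=params.start_age)


def overall_survival(trace: CohortTrace) -> pd.DataFrame:
    """Proportion of the cohort alive per month (model-level survival curve)."""
    alive = 1.0 - trace.occupancy[:, HealthState.Dead]
    return pd.DataFrame({"month": np.arange(trace.occupancy.shape[0]), "proportion_alive": alive})
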