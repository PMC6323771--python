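"""Synthetic stand-ins and hand-checkable oracles.

Two real inputs of the analysis are not reproducible from published tables
and are emulated here:

* the Thai all-cause life table, replaced by a Gompertz background-mortality
  generator (:class:`GompertzMortality`) whose defaults give annual death
  probabilities in the realistic range for an upper-middle-income country
  (q(60) ~ 1%, q(80) ~ 6%) -- a stand-in, not Thai truth;
* nothing else: every other input is a published point estimate, emitted
  verbatim by :func:`default_parameter_file`.

The module also provides miniature 3-state model instances whose traces and
economic totals are known exactly (documented as fractions in-source), used
to oracle-test the cohort engine and the accumulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .parameters import ParameterSet, load_parameters

__all__ = [
    "GompertzMortality",
    "MiniModelFixture",
    "make_life_table",
    "default_parameter_file",
    "default_parameters",
    "default_life_table",
    "make_mini_fixture",
]


@dataclass(frozen=True)
class GompertzMortality:
    """Annual all-cause death probability q(age) = min(cap, 1 - exp(-a e^{b age}))."""

    a: float = 4.0e-5
    b: float = 0.092
    cap: float = 1.0

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Gompertz parameters a and b must be positive")
        if not 0 < self.cap <= 1:
            raise ValueError("cap must be in (0, 1]")

    def annual_q(self, age: float) -> float:
        return min(self.cap, 1.0 - math.exp(-self.a * math.exp(self.b * age)))


def make_life_table(model: GompertzMortality | None = None, max_age: int = 110) -> dict[int, float]:
    """Life table mapping integer age -> annual all-cause death probability."""
    model = model or GompertzMortality()
    if max_age < 1:
        raise ValueError("max_age must be >= 1")
    return {age: model.annual_q(age) for age in range(0, max_age + 1)}


def default_life_table() -> dict[int, float]:
    return make_life_table()


def life_table_to_csv(table: dict[int, float], path) -> None:
    pd.DataFrame({"age": list(table), "annual_qx": list(table.values())}).to_csv(path, index=False)


def life_table_from_csv(path) -> dict[int, float]:
    df = pd.read_csv(path)
    return {int(a): float(q) for a, q in zip(df["age"], df["annual_qx"])}


# Transcription of the published input table.  Monthly probabilities; costs in
# THB (price year 2014); utilities dimensionless.  Three recurrence-phase cost
# cells are printed ambiguously (digits concatenated); both parses are emitted
# and `cost_parse` selects one -- default 'large', the clinically plausible
# reading (recurrence monitoring above the 2,758 THB/month of no recurrence).
_DEFAULT_CONFIG = """\
# Default model inputs: adjuvant imatinib after resection of high-risk GIST,
# Thailand, price year 2014.  Monthly cycle.
cost_parse: large
scalars:
  annual_discount_rate: 0.03
  start_age: 60
  cycle_length_months: 1
  wtp: 160000
  background_mortality: true
  gist_death_in_recurrence: true
parameters:
  # monthly probability of recurrence, no adjuvant therapy (chart review)
  p_rec_yr1:  {mean: 0.0205, se: 0.0041, family: beta, role: probability, band: "months 1-12"}
  p_rec_yr3:  {mean: 0.0154, se: 0.0031, family: beta, role: probability, band: "months 13-36"}
  p_rec_yr5:  {mean: 0.0056, se: 0.0011, family: beta, role: probability, band: "months 37+"}
  # monthly probability of GIST death, no adjuvant therapy (chart review)
  p_death_gist_yr1: {mean: 0.0017, se: 0.0003, family: beta, role: probability, band: "months 1-12"}
  p_death_gist_yr3: {mean: 0.0031, se: 0.0006, family: beta, role: probability, band: "months 13-36"}
  p_death_gist_yr5: {mean: 0.0028, se: 0.0006, family: beta, role: probability, band: "months 37-60"}
  p_death_gist_yr7: {mean: 0.0020, se: 0.0004, family: beta, role: probability, band: "months 61-84"}
  p_death_gist_yr9: {mean: 0.0038, se: 0.0008, family: beta, role: probability, band: "months 85+"}
  # hazard ratio of recurrence on adjuvant imatinib vs no adjuvant therapy
  hr_adj_1yr: {mean: 0.29,  se: 0.0995, family: lognormal, role: hazard_ratio}
  hr_adj_3yr: {mean: 0.133, se: 0.0543, family: lognormal, role: hazard_ratio}
  # monthly probabilities after recurrence, by treatment line
  p_prog_imatinib:  {mean: 0.015,  se: 0.0038, family: beta, role: probability}
  p_prog_sunitinib: {mean: 0.012,  se: 0.0010, family: beta, role: probability}
  p_death_imatinib:  {mean: 0.0056, se: 0.0009, family: beta, role: probability}
  p_death_sunitinib: {mean: 0.0289, se: 0.0087, family: beta, role: probability}
  p_death_bsc:       {mean: 0.0680, se: 0.0093, family: beta, role: probability}
  # monthly probability of discontinuing adjuvant imatinib
  p_disc_1yr_m1_6:  {mean: 0.0136, se: 0.0014, family: beta, role: probability, band: "months 1-6"}
  p_disc_1yr_m7_12: {mean: 0.0009, se: 0.0001, family: beta, role: probability, band: "months 7-12"}
  p_disc_3yr_m1_6:  {mean: 0.0097, se: 0.0001, family: beta, role: probability, band: "months 1-6"}
  p_disc_3yr_m7_36: {mean: 0.0028, se: 0.0003, family: beta, role: probability, band: "months 7-36"}
  # direct medical costs, THB per month (drug costs are reference prices)
  cost_imatinib_month:  {mean: 111306, se: 0, family: fixed, role: cost_per_month}
  cost_sunitinib_month: {mean: 82173,  se: 0, family: fixed, role: cost_per_month}
  cost_norec_noadj: {mean: 2758, se: 308, family: gamma, role: cost_per_month}
  cost_norec_onadj: {mean: 1477, se: 573, family: gamma, role: cost_per_month}
  cost_rec_imatinib:
    {mean: 4213, se: 8, family: gamma, role: cost_per_month,
     alternatives: {small: {mean: 421, se: 38}}}
  cost_rec_sunitinib:
    {mean: 7141, se: 50, family: gamma, role: cost_per_month,
     alternatives: {small: {mean: 714, se: 150}}}
  cost_rec_bsc:
    {mean: 4247, se: 8, family: gamma, role: cost_per_month,
     alternatives: {small: {mean: 424, se: 78}}}
  cost_ae_adjuvant: {mean: 570, se: 114, family: gamma, role: cost_per_month}
  # direct non-medical costs, THB per visit
  cost_travel_visit:    {mean: 296, se: 24, family: gamma, role: cost_per_visit}
  cost_food_visit:      {mean: 109, se: 11, family: gamma, role: cost_per_visit}
  cost_caregiver_visit: {mean: 99,  se: 37, family: gamma, role: cost_per_visit}
  visits_norec_noadj: {mean: 0.3, se: 0.1, family: gamma, role: visits_per_month}
  visits_norec_onadj: {mean: 0.6, se: 0.2, family: gamma, role: visits_per_month}
  visits_rec:         {mean: 1.0, se: 0,   family: fixed, role: visits_per_month}
  # utilities
  u_norec_offdrug: {mean: 0.89, se: 0.03, family: beta, role: utility}
  u_norec_onadj:   {mean: 0.79, se: 0.09, family: beta, role: utility}
  u_rec_imatinib:  {mean: 0.66, se: 0.05, family: beta, role: utility}
  u_rec_sunitinib: {mean: 0.58, se: 0.06, family: beta, role: utility}
  u_rec_bsc:       {mean: 0.42, se: 0.03, family: beta, role: utility}
  # unit drug prices, THB (2014 reference prices)
  price_imatinib_tablet:   {mean: 3659.40, se: 0, family: fixed, role: cost_per_unit}
  price_sunitinib_capsule: {mean: 1100.53, se: 0, family: fixed, role: cost_per_unit}
"""


def default_parameter_file() -> str:
    """The shipped default configuration as YAML text."""
    return _DEFAULT_CONFIG


def default_parameters(**scalar_overrides) -> ParameterSet:
    """Load the shipped defaults, optionally overriding run scalars."""
    params = load_parameters(_DEFAULT_CONFIG)
    return params.with_scalars(**scalar_overrides) if scalar_overrides else params


@dataclass(frozen=True)
class MiniModelFixture:
    """3-state toy (Alive, Sick, Dead) with exact hand-computed totals.

    ``transition`` is a row-stochastic 3x3 list; the oracle fields are exact
    values obtained by explicit matrix products and sums (fractions noted in
    the maker).
    """

    name: str
    transition: tuple[tuple[float, float, float], ...]
    costs: tuple[float, float, float]
    utilities: tuple[float, float, float]
    cycles: int
    annual_rate: float
    expected_trace: tuple[tuple[float, float, float], ...]
    expected_cost: float
    expected_ly: float
    expected_qaly: float
    notes: str = field(default="", compare=False)


def make_mini_fixture(variant: str) -> MiniModelFixture:
    """Hand-checkable miniature instances; oracle values exact.

    identity
        no transitions, utility 1, 12 cycles, no discounting: LY = QALY = 1.
    two-cycle
        P(Alive->Sick) = 1/2, P(Sick->Dead) = 1/2, cost(Sick) = 100,
        2 cycles, rate 0: trace rows (1,0,0), (1/2,1/2,0), (1/4,1/2,1/4);
        reward rows are the first two, so cost = 0*1 + 100*(1/2) = 50,
        LY = (1 + 1)/12 = 1/6, QALY = (1 + 1/2 + 1/2*3/5)/12 = 0.15.
    discounting
        same structure at 3%/year: cycle-2 contributions carry the factor
        d = 1.03^(-1/12); cost = 50 d, LY = (1 + d)/12,
        QALY = (1 + 4/5 d)/12 with utilities (1, 3/5, 0).
    """
    if variant == "identity":
        eye = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))
        return MiniModelFixture(
            name="identity",
            transition=eye,
            costs=(0.0, 0.0, 0.0),
            utilities=(1.0, 1.0, 0.0),
            cycles=12,
            annual_rate=0.0,
            expected_trace=tuple([(1.0, 0.0, 0.0)] * 13),
            expected_cost=0.0,
            expected_ly=1.0,
            expected_qaly=1.0,
            notes="12 undiscounted months fully alive normalise to one year",
        )
    half = (
        (0.5, 0.5, 0.0),
        (0.0, 0.5, 0.5),
        (0.0, 0.0, 1.0),
    )
    trace = ((1.0, 0.0, 0.0), (0.5, 0.5, 0.0), (0.25, 0.5, 0.25))
    if variant == "two-cycle":
        return MiniModelFixture(
            name="two-cycle",
            transition=half,
            costs=(0.0, 100.0, 0.0),
            utilities=(1.0, 0.6, 0.0),
            cycles=2,
            annual_rate=0.0,
            expected_trace=trace,
            expected_cost=50.0,          # 0*1 + 100*(1/2)
            expected_ly=2.0 / 12.0,      # both reward rows fully alive
            expected_qaly=(1.0 + 0.5 + 0.5 * 0.6) / 12.0,
            notes="rewards accrue on rows 0 and 1; row 2 is terminal occupancy",
        )
    if variant == "discounting":
        d = 1.03 ** (-1.0 / 12.0)
        return MiniModelFixture(
            name="discounting",
            transition=half,
            costs=(0.0, 100.0, 0.0),
            utilities=(1.0, 0.6, 0.0),
            cycles=2,
            annual_rate=0.03,
            expected_trace=trace,
            expected_cost=50.0 * d,
            expected_ly=(1.0 + d) / 12.0,
            expected_qaly=(1.0 + 0.8 * d) / 12.0,
            notes="second cycle discounted by 1.03^(-1/12)",
        )
    raise ValueError(f"unknown mini-fixture variant {variant!r}")
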