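"""Treatment-effect synthesis and per-cycle probability schedules.

The effect of three years of adjuvant imatinib versus no adjuvant therapy is
not reported by any head-to-head trial; it is obtained by a Bucher indirect
comparison of the 1-year-vs-placebo and 3-year-vs-1-year trials (hazard
ratios multiply; standard errors add in quadrature on the log scale).

Observed monthly probabilities are reported in year bands; schedules here
hold each value piecewise-constant until the next reported year.  Hazard
ratios act on monthly probabilities through the constant-within-cycle-hazard
transform p -> 1 - (1-p)^HR, and only during the months a patient is
actually taking adjuvant imatinib.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .parameters import ParameterSet

__all__ = [
    "HazardRatioEstimate",
    "ProbabilitySchedule",
    "bucher_combine",
    "apply_hazard_ratio",
    "prob_to_rate",
    "rate_to_prob",
    "build_recurrence_schedule",
    "build_gist_death_schedule",
    "build_discontinuation_schedule",
]


@dataclass(frozen=True)
class HazardRatioEstimate:
    """A hazard ratio with its SE on both the natural and the log scale.

    The two SE fields are linked by the delta method, se_log ~ se_hr / hr;
    construct with either one via :meth:`from_natural` / :meth:`from_log`.
    """

    hr: float
    se_hr: float
    se_log: float

    def __post_init__(self):
        if self.hr <= 0:
            raise ValueError(f"hazard ratio must be positive, got {self.hr}")
        if self.se_hr < 0 or self.se_log < 0:
            raise ValueError("standard errors must be non-negative")

    @classmethod
    def from_natural(cls, hr: float, se_hr: float) -> "HazardRatioEstimate":
        if hr <= 0:
            raise ValueError(f"hazard ratio must be positive, got {hr}")
        return cls(hr=hr, se_hr=se_hr, se_log=se_hr / hr)

    @classmethod
    def from_log(cls, hr: float, se_log: float) -> "HazardRatioEstimate":
        if hr <= 0:
            raise ValueError(f"hazard ratio must be positive, got {hr}")
        return cls(hr=hr, se_hr=se_log * hr, se_log=se_log)


def bucher_combine(
    ab: HazardRatioEstimate, bc: HazardRatioEstimate
) -> HazardRatioEstimate:
    """Indirectly compare A vs C from A-vs-B and B-vs-C effect estimates.

    Point estimates multiply (add on the log scale); log-scale SEs add in
    quadrature; the natural-scale SE follows by the delta method.
    """
    hr = ab.hr * bc.hr
    se_log = math.hypot(ab.se_log, bc.se_log)
    return HazardRatioEstimate.from_log(hr, se_log)


def prob_to_rate(p: float) -> float:
    """Monthly probability -> instantaneous monthly rate (constant hazard)."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"probability must be in [0, 1), got {p}")
    return -math.log1p(-p)


def rate_to_prob(rate: float) -> float:
    if rate < 0:
        raise ValueError(f"rate must be non-negative, got {rate}")
    return -math.expm1(-rate)


def apply_hazard_ratio(p: float, hr: float) -> float:
    """Scale a monthly probability by a hazard ratio: 1 - (1-p)^hr.

    Equivalent to converting to a rate, multiplying by ``hr`` and converting
    back, assuming the hazard is constant within the cycle.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError(f"probability must be in [0, 1), got {p}")
    if hr <= 0:
        raise ValueError(f"hazard ratio must be positive, got {hr}")
    return -math.expm1(hr * math.log1p(-p))


@dataclass(frozen=True)
class ProbabilitySchedule:
    """Piecewise-constant monthly probabilities over contiguous cycle bands.

    ``bands`` is an ordered tuple of (start_month, end_month, probability)
    with inclusive edges; the last band may be open-ended (end = None).
    """

    bands: tuple[tuple[int, int | None, float], ...]

    def __post_init__(self):
        if not self.bands:
            raise ValueError("schedule needs at least one band")
        expected_start = 1
        for i, (start, end, p) in enumerate(self.bands):
            if start != expected_start:
                raise ValueError(f"band {i} starts at {start}, expected {expected_start}")
            if end is None:
                if i != len(self.bands) - 1:
                    raise ValueError("only the last band may be open-ended")
            else:
                if end < start:
                    raise ValueError(f"band {i} ends before it starts")
                expected_start = end + 1
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"band {i} probability {p} outside [0, 1]")

    def __call__(self, cycle: int) -> float:
        if cycle < 1:
            raise ValueError(f"cycle must be >= 1, got {cycle}")
        for start, end, p in self.bands:
            if cycle >= start and (end is None or cycle <= end):
                return p
        raise ValueError(f"cycle {cycle} not covered by schedule")

    def to_frame(self, horizon: int) -> pd.DataFrame:
        """Cycle-by-cycle expansion for audit export."""
        cycles = range(1, horizon + 1)
        return pd.DataFrame({"cycle": list(cycles), "probability": [self(c) for c in cycles]})


def build_gist_death_schedule(params: ParameterSet) -> ProbabilitySchedule:
    """Monthly disease-specific death probability, no adjuvant therapy.

    Chart-review values reported at years 1/3/5/7/9, each held until the
    next reported year.
    """
    return ProbabilitySchedule(
        (
            (1, 12, params["p_death_gist_yr1"]),
            (13, 36, params["p_death_gist_yr3"]),
            (37, 60, params["p_death_gist_yr5"]),
            (61, 84, params["p_death_gist_yr7"]),
            (85, None, params["p_death_gist_yr9"]),
        )
    )


def _baseline_recurrence(params: ParameterSet) -> ProbabilitySchedule:
    return ProbabilitySchedule(
        (
            (1, 12, params["p_rec_yr1"]),
            (13, 36, params["p_rec_yr3"]),
            (37, None, params["p_rec_yr5"]),
        )
    )


def build_recurrence_schedule(params: ParameterSet, strategy) -> ProbabilitySchedule:
    """Monthly recurrence probability for a strategy's on-adjuvant pathway.

    The strategy's hazard ratio is applied only within the adjuvant window;
    from the first post-adjuvant cycle the unmodified baseline applies
    (patients who stop taking the drug revert to the no-adjuvant risk).
    For strategies without adjuvant therapy this is the baseline schedule.
    """
    base = _baseline_recurrence(params)
    months = getattr(strategy, "adjuvant_months", 0)
    if months == 0:
        return base
    hr = params[strategy.hazard_ratio_name]
    bands: list[tuple[int, int | None, float]] = []
    for start, end, p in base.bands:
        hi = end if end is not None else None
        if start > months:
            bands.append((start, end, p))
            continue
        in_end = months if (hi is None or hi > months) else hi
        bands.append((start, in_end, apply_hazard_ratio(p, hr)))
        if hi is None or hi > months:
            bands.append((months + 1, end, p))
    return ProbabilitySchedule(tuple(bands))


def build_discontinuation_schedule(params: ParameterSet, strategy) -> ProbabilitySchedule:
    """Monthly probability of stopping adjuvant imatinib early.

    Trial-derived, duration-specific bands; zero outside the adjuvant window
    (and identically zero for strategies without adjuvant therapy).
    """
    months = getattr(strategy, "adjuvant_months", 0)
    if months == 0:
        return ProbabilitySchedule(((1, None, 0.0),))
    if months == 12:
        return ProbabilitySchedule(
            (
                (1, 6, params["p_disc_1yr_m1_6"]),
                (7, 12, params["p_disc_1yr_m7_12"]),
                (13, None, 0.0),
            )
        )
    if months == 36:
        return ProbabilitySchedule(
            (
                (1, 6, params["p_disc_3yr_m1_6"]),
                (7, 36, params["p_disc_3yr_m7_36"]),
                (37, None, 0.0),
            )
        )
    raise ValueError(f"no discontinuation evidence for a {months}-month adjuvant course")
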