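"""One-way (tornado) and probabilistic sensitivity analysis with CEAC.

One-way analysis moves a single parameter to the ends of its 95% confidence
interval (mean +/- 1.96 SE on the natural scale, clipped to the parameter's
support) while holding everything else at base values, and records the
deterministic ICER at each end; the discount rate instead sweeps the stated
0-6% per annum policy range.

Probabilistic analysis redraws every uncertain parameter independently from
its fitted Beta/Gamma/Lognormal distribution, pushes each draw through the
full cohort model for all strategies, and summarises the iterations as
cost-effectiveness acceptability curves: at each willingness-to-pay value,
the fraction of iterations in which each strategy attains the maximal net
monetary benefit (ties split equally).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .economics import EconResult, evaluate_options, icer
from .model import DEFAULT_HORIZON
from .parameters import ParameterSet

__all__ = [
    "TornadoEntry",
    "PSASample",
    "CEACCurve",
    "DEFAULT_WTP_GRID",
    "ci_bounds",
    "owsa",
    "psa_draw",
    "run_psa",
    "ceac",
]

DEFAULT_WTP_GRID = tuple(np.arange(0, 3_000_001, 20_000, dtype=float))

_SUPPORT = {
    "probability": (0.0, 1.0),
    "utility": (0.0, 1.0),
    "hazard_ratio": (1e-9, np.inf),
    "cost_per_month": (0.0, np.inf),
    "cost_per_visit": (0.0, np.inf),
    "cost_per_unit": (0.0, np.inf),
    "visits_per_month": (0.0, np.inf),
    "rate": (0.0, np.inf),
}


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    icer_low: float
    icer_high: float

    @property
    def width(self) -> float:
        return abs(self.icer_high - self.icer_low)


def ci_bounds(params: ParameterSet, name: str) -> tuple[float, float]:
    """Natural-scale 95% CI of a parameter, clipped to its support."""
    spec = params.specs[name]
    lo, hi = _SUPPORT[spec.role]
    return (
        float(np.clip(spec.mean - 1.96 * spec.se, lo, hi)),
        float(np.clip(spec.mean + 1.96 * spec.se, lo, hi)),
    )


def _pair_icer(params, life_table, pair, horizon) -> float:
    results = evaluate_options(params, life_table, option_ids=pair, horizon_cycles=horizon)
    return icer(results[pair[1]], results[pair[0]])


def owsa(
    base_params: ParameterSet,
    life_table: dict[int, float],
    targets: list[str] | None = None,
    strategy_pair: tuple[str, str] = ("2.2", "1"),
    horizon_cycles: int = DEFAULT_HORIZON,
    discount_range: tuple[float, float] = (0.0, 0.06),
) -> list[TornadoEntry]:
    """Tornado entries for each target parameter, widest bar first.

    ``targets`` defaults to every parameter with positive SE plus the
    discount rate.  ``strategy_pair`` is (more effective, comparator).
    """
    if targets is None:
        targets = [n for n, s in sorted(base_params.specs.items()) if s.varies]
        targets.append("annual_discount_rate")
    entries = []
    for name in targets:
        if name == "annual_discount_rate":
            lo, hi = discount_range
            icer_lo = _pair_icer(
                base_params.with_scalars(annual_discount_rate=lo), life_table, strategy_pair, horizon_cycles
            )
            icer_hi = _pair_icer(
                base_params.with_scalars(annual_discount_rate=hi), life_table, strategy_pair, horizon_cycles
            )
        else:
            if name not in base_params.specs:
                raise KeyError(f"unknown parameter {name!r}")
            lo, hi = ci_bounds(base_params, name)
            icer_lo = _pair_icer(
                base_params.with_values(**{name: lo}), life_table, strategy_pair, horizon_cycles
            )
            icer_hi = _pair_icer(
                base_params.with_values(**{name: hi}), life_table, strategy_pair, horizon_cycles
            )
        entries.append(TornadoEntry(name, lo, hi, icer_lo, icer_hi))
    entries.sort(key=lambda e: (-e.width, e.parameter))
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "low": [e.low for e in entries],
            "high": [e.high for e in entries],
            "icer_low": [e.icer_low for e in entries],
            "icer_high": [e.icer_high for e in entries],
            "width": [e.width for e in entries],
        }
    )


def psa_draw(params: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """One joint draw of all uncertain parameters (independent sampling).

    Fixed parameters and those with zero SE keep their means.  Draw order is
    the sorted parameter name order, so a seeded generator reproduces the
    same ParameterSet.
    """
    values = {}
    for name in sorted(params.values):
        spec = params.specs.get(name)
        if spec is None or not spec.varies:
            continue
        if spec.family == "beta":
            a, b = spec.hyperparameters()
            values[name] = float(rng.beta(a, b))
        elif spec.family == "gamma":
            shape, scale = spec.hyperparameters()
            values[name] = float(rng.gamma(shape, scale))
        elif spec.family == "lognormal":
            mu, sigma = spec.hyperparameters()
            values[name] = float(rng.lognormal(mu, sigma))
    return params.with_values(**values) if values else params


@dataclass(frozen=True)
class PSASample:
    iteration: int
    params: ParameterSet
    results: dict[str, EconResult]


def run_psa(
    n: int,
    seed: int,
    params: ParameterSet,
    life_table: dict[int, float],
    option_ids=("1", "4", "2.1", "3.1", "2.2", "3.2"),
    horizon_cycles: int = DEFAULT_HORIZON,
) -> list[PSASample]:
    """n Monte Carlo iterations through the full model, deterministic per seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n):
        drawn = psa_draw(params, rng)
        results = evaluate_options(drawn, life_table, option_ids=option_ids, horizon_cycles=horizon_cycles)
        samples.append(PSASample(iteration=i, params=drawn, results=results))
    return samples


def psa_frame(samples: list[PSASample]) -> pd.DataFrame:
    """Long-format (iteration, strategy, cost_disc, qaly_disc) table."""
    rows = []
    for s in samples:
        for sid, r in s.results.items():
            rows.append(
                {"iteration": s.iteration, "strategy": sid, "cost_disc": r.cost_disc, "qaly_disc": r.qaly_disc}
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CEACCurve:
    wtp: np.ndarray
    strategies: tuple[str, ...]
    probability: np.ndarray  # shape (len(wtp), len(strategies))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probability, columns=list(self.strategies))
        df.insert(0, "wtp", self.wtp)
        return df

    def at(self, wtp: float, strategy: str) -> float:
        idx = int(np.argmin(np.abs(self.wtp - wtp)))
        if abs(self.wtp[idx] - wtp) > 1e-9:
            raise KeyError(f"wtp {wtp} not on the grid")
        return float(self.probability[idx, self.strategies.index(strategy)])


def ceac(samples: list[PSASample], wtp_grid=DEFAULT_WTP_GRID) -> CEACCurve:
    """Probability each strategy maximises net monetary benefit, per WTP."""
    if not samples:
        raise ValueError("no PSA samples")
    wtp = np.asarray(list(wtp_grid), dtype=float)
    if wtp.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    strategies = tuple(samples[0].results)
    costs = np.array([[s.results[sid].cost_disc for sid in strategies] for s in samples])
    qalys = np.array([[s.results[sid].qaly_disc for sid in strategies] for s in samples])

    # nmb[iteration, strategy, wtp]; winners share ties equally
    nmb = qalys[:, :, None] * wtp[None, None, :] - costs[:, :, None]
    best = nmb.max(axis=1, keepdims=True)
    wins = np.isclose(nmb, best, rtol=0.0, atol=1e-9)
    shares = wins / wins.sum(axis=1, keepdims=True)
    prob = shares.mean(axis=0).T  # (wtp, strategy)
    return CEACCurve(wtp=wtp, strategies=strategies, probability=prob)
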