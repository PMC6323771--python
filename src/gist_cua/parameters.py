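"""Model inputs and their uncertainty distributions.

Every quantity that drives the cohort model -- monthly transition
probabilities, hazard ratios of recurrence under adjuvant therapy, monthly
and per-visit costs (THB, year-2014), visit rates and utilities -- is held
as a :class:`ParamSpec` carrying its mean, standard error and distribution
family, and resolved into a :class:`ParameterSet` of point values.

Distribution hyperparameters are obtained by the method of moments, because
the source evidence reports each quantity only as a (mean, SE) pair:

* Beta for probabilities and utilities,
* Gamma for costs and visit rates,
* Lognormal (moments matched on the natural scale) for hazard ratios.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import pandas as pd
import yaml

__all__ = [
    "ParamSpec",
    "ParameterSet",
    "ParameterValidationError",
    "beta_from_moments",
    "gamma_from_moments",
    "lognormal_from_moments",
    "cpi_adjust",
    "load_parameters",
]

FAMILIES = {"beta", "gamma", "lognormal", "fixed"}
ROLES = {
    "probability",
    "cost_per_month",
    "cost_per_visit",
    "cost_per_unit",
    "utility",
    "hazard_ratio",
    "visits_per_month",
    "rate",
}

#: families admissible for each role
_ROLE_FAMILIES = {
    "probability": {"beta", "fixed"},
    "utility": {"beta", "fixed"},
    "cost_per_month": {"gamma", "fixed"},
    "cost_per_visit": {"gamma", "fixed"},
    "cost_per_unit": {"gamma", "fixed"},
    "visits_per_month": {"gamma", "fixed"},
    "hazard_ratio": {"lognormal", "fixed"},
    "rate": {"gamma", "fixed"},
}


class ParameterValidationError(ValueError):
    """Raised with the full list of validation failures."""

    def __init__(self, failures: list[str]):
        self.failures = list(failures)
        super().__init__("parameter validation failed:\n  " + "\n  ".join(failures))


def _check_spec(name, mean, se, family, role) -> list[str]:
    errs = []
    if family not in FAMILIES:
        errs.append(f"{name}: unknown family {family!r}")
    if role not in ROLES:
        errs.append(f"{name}: unknown role {role!r}")
    if se < 0:
        errs.append(f"{name}: negative SE {se}")
    if role in ("probability", "utility") and not (0.0 <= mean <= 1.0):
        errs.append(f"{name}: {role} mean {mean} outside [0, 1]")
    if role.startswith("cost") and mean < 0:
        errs.append(f"{name}: cost mean {mean} < 0")
    if role == "visits_per_month" and mean < 0:
        errs.append(f"{name}: visit rate mean {mean} < 0")
    if role == "hazard_ratio" and mean <= 0:
        errs.append(f"{name}: hazard ratio mean {mean} <= 0")
    if family in FAMILIES and role in _ROLE_FAMILIES and family not in _ROLE_FAMILIES[role]:
        errs.append(f"{name}: family {family!r} not admissible for role {role!r}")
    return errs


@dataclass(frozen=True)
class ParamSpec:
    """One model input: point estimate, uncertainty and sampling family."""

    name: str
    mean: float
    se: float
    family: str
    role: str
    band: str | None = None

    def __post_init__(self):
        errs = _check_spec(self.name, self.mean, self.se, self.family, self.role)
        if errs:
            raise ParameterValidationError(errs)

    @property
    def varies(self) -> bool:
        """Whether the parameter is resampled in probabilistic analyses."""
        return self.se > 0 and self.family != "fixed"

    def hyperparameters(self) -> tuple[float, ...]:
        """Method-of-moments hyperparameters for the sampling family."""
        if self.family == "beta":
            return beta_from_moments(self.mean, self.se)
        if self.family == "gamma":
            return gamma_from_moments(self.mean, self.se)
        if self.family == "lognormal":
            return lognormal_from_moments(self.mean, self.se)
        raise ValueError(f"{self.name}: fixed parameters have no hyperparameters")


def beta_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Beta(alpha, beta) with the given mean and standard error.

    alpha + beta = m(1-m)/se^2 - 1 and alpha = m (alpha + beta).

    Raises ValueError if mean is degenerate (0 or 1) or the variance exceeds
    the Bernoulli bound se^2 >= m(1-m).
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"degenerate mean {mean}; use family='fixed'")
    if se <= 0.0:
        raise ValueError(f"se must be positive, got {se}")
    var = se * se
    if var >= mean * (1.0 - mean):
        raise ValueError(
            f"infeasible moments: se^2 = {var:g} >= mean(1-mean) = {mean * (1 - mean):g}"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Gamma(shape, scale) with the given mean and standard error."""
    if mean <= 0 or se <= 0:
        raise ValueError(f"mean and se must be positive, got ({mean}, {se})")
    shape = (mean / se) ** 2
    scale = se * se / mean
    return shape, scale


def lognormal_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Lognormal(mu, sigma) whose natural-scale mean and SD match the inputs.

    sigma^2 = ln(1 + (se/mean)^2), mu = ln(mean) - sigma^2 / 2.
    """
    if mean <= 0 or se <= 0:
        raise ValueError(f"mean and se must be positive, got ({mean}, {se})")
    sigma2 = math.log1p((se / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def cpi_adjust(cost: float, cpi_source_year: float, cpi_target_year: float) -> float:
    """Inflate a cost between price years via consumer price indices."""
    if cpi_source_year <= 0 or cpi_target_year <= 0:
        raise ValueError("CPI indices must be positive")
    return cost * cpi_target_year / cpi_source_year


# names every strategy evaluation resolves; load_parameters enforces completeness
REQUIRED_NAMES = (
    "p_rec_yr1",
    "p_rec_yr3",
    "p_rec_yr5",
    "p_death_gist_yr1",
    "p_death_gist_yr3",
    "p_death_gist_yr5",
    "p_death_gist_yr7",
    "p_death_gist_yr9",
    "hr_adj_1yr",
    "hr_adj_3yr",
    "p_prog_imatinib",
    "p_prog_sunitinib",
    "p_death_imatinib",
    "p_death_sunitinib",
    "p_death_bsc",
    "p_disc_1yr_m1_6",
    "p_disc_1yr_m7_12",
    "p_disc_3yr_m1_6",
    "p_disc_3yr_m7_36",
    "cost_imatinib_month",
    "cost_sunitinib_month",
    "cost_norec_noadj",
    "cost_norec_onadj",
    "cost_rec_imatinib",
    "cost_rec_sunitinib",
    "cost_rec_bsc",
    "cost_ae_adjuvant",
    "cost_travel_visit",
    "cost_food_visit",
    "cost_caregiver_visit",
    "visits_norec_noadj",
    "visits_norec_onadj",
    "visits_rec",
    "u_norec_offdrug",
    "u_norec_onadj",
    "u_rec_imatinib",
    "u_rec_sunitinib",
    "u_rec_bsc",
    "price_imatinib_tablet",
    "price_sunitinib_capsule",
)


@dataclass(frozen=True)
class ParameterSet:
    """Resolved point values for every model input plus run scalars."""

    specs: dict[str, ParamSpec]
    values: dict[str, float]
    annual_discount_rate: float = 0.03
    start_age: float = 60.0
    cycle_length_months: float = 1.0
    wtp: float = 160_000.0
    background_mortality: bool = True
    gist_death_in_recurrence: bool = True
    source: str | None = field(default=None, compare=False)

    def __post_init__(self):
        errs = []
        for name in REQUIRED_NAMES:
            if name not in self.values:
                errs.append(f"missing required parameter {name!r}")
        for name, value in self.values.items():
            spec = self.specs.get(name)
            if spec is None:
                continue
            errs.extend(_check_spec(name, value, 0.0, "fixed", spec.role))
        if self.annual_discount_rate < 0:
            errs.append(f"annual_discount_rate {self.annual_discount_rate} < 0")
        if self.start_age < 0:
            errs.append(f"start_age {self.start_age} < 0")
        if self.wtp < 0:
            errs.append(f"wtp {self.wtp} < 0")
        if errs:
            raise ParameterValidationError(errs)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def with_values(self, **overrides: float) -> "ParameterSet":
        """Copy with some point values replaced (specs unchanged)."""
        unknown = set(overrides) - set(self.values)
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        return replace(self, values={**self.values, **overrides})

    def with_scalars(self, **overrides) -> "ParameterSet":
        return replace(self, **overrides)

    def at_means(self) -> "ParameterSet":
        """Reset every value to its spec mean (the deterministic base case)."""
        return replace(
            self, values={n: (self.specs[n].mean if n in self.specs else v) for n, v in self.values.items()}
        )

    def to_frame(self) -> pd.DataFrame:
        """Audit table of the resolved set (one row per parameter)."""
        rows = []
        for name in sorted(self.values):
            spec = self.specs.get(name)
            rows.append(
                {
                    "name": name,
                    "value": self.values[name],
                    "mean": spec.mean if spec else float("nan"),
                    "se": spec.se if spec else float("nan"),
                    "family": spec.family if spec else "",
                    "role": spec.role if spec else "",
                    "band": (spec.band or "") if spec else "",
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


_SCALAR_KEYS = {
    "annual_discount_rate": 0.03,
    "start_age": 60.0,
    "cycle_length_months": 1.0,
    "wtp": 160_000.0,
    "background_mortality": True,
    "gist_death_in_recurrence": True,
}


def load_parameters(config) -> ParameterSet:
    """Parse and validate a parameter configuration.

    ``config`` may be YAML text, a path to a YAML file, or an already-parsed
    mapping.  The schema is::

        cost_parse: large            # which parse of ambiguous cost cells
        scalars: {annual_discount_rate: 0.03, ...}
        parameters:
          <name>: {mean: ..., se: ..., family: ..., role: ..., band: ...,
                   alternatives: {small: {mean: ..., se: ...}}}

    All violations are collected and reported together.
    """
    source = None
    if isinstance(config, dict):
        doc = config
    else:
        text = str(config)
        if "\n" not in text and text.endswith((".yaml", ".yml")):
            source = text
            with open(text, "r") as fh:
                text = fh.read()
        doc = yaml.safe_load(io.StringIO(text))
    if not isinstance(doc, dict) or "parameters" not in doc:
        raise ParameterValidationError(["config must be a mapping with a 'parameters' section"])

    cost_parse = doc.get("cost_parse", "large")
    if cost_parse not in ("large", "small"):
        raise ParameterValidationError([f"cost_parse must be 'large' or 'small', got {cost_parse!r}"])

    failures: list[str] = []
    specs: dict[str, ParamSpec] = {}
    values: dict[str, float] = {}
    for name, entry in doc["parameters"].items():
        if not isinstance(entry, dict):
            failures.append(f"{name}: entry must be a mapping")
            continue
        body = dict(entry)
        alts = body.pop("alternatives", None)
        if alts and cost_parse in alts:
            body.update(alts[cost_parse])
        try:
            spec = ParamSpec(
                name=name,
                mean=float(body["mean"]),
                se=float(body.get("se", 0.0)),
                family=str(body.get("family", "fixed")),
                role=str(body["role"]),
                band=body.get("band"),
            )
        except ParameterValidationError as exc:
            failures.extend(exc.failures)
            continue
        except KeyError as exc:
            failures.append(f"{name}: missing field {exc}")
            continue
        if spec.varies:
            try:
                spec.hyperparameters()
            except ValueError as exc:
                failures.append(f"{name}: {exc}")
        specs[name] = spec
        values[name] = spec.mean

    for name in REQUIRED_NAMES:
        if name not in values:
            failures.append(f"missing required parameter {name!r}")
    if failures:
        raise ParameterValidationError(failures)

    scalars = {**_SCALAR_KEYS, **doc.get("scalars", {})}
    unknown = set(scalars) - set(_SCALAR_KEYS)
    if unknown:
        raise ParameterValidationError([f"unknown scalar(s): {sorted(unknown)}"])
    return ParameterSet(specs=specs, values=values, source=source, **scalars)
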