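"""Parameter model for the cryoablation-vs-surgery cost-effectiveness analysis.

All model inputs are expressed as :class:`UncertainParam` objects: a base
(point-estimate) value used for deterministic runs, plus a
:class:`DistributionSpec` describing second-order uncertainty for the
probabilistic sensitivity analysis.  Conventions follow standard health
economic practice:

* probabilities are Beta distributed,
* costs are Gamma distributed (moment-matched from a printed mean and SD),
* utilities are Normal distributed and truncated to ``[0, 1]`` on sampling.

Scenarios are plain pydantic models and round-trip losslessly through YAML
(JSON is a YAML subset, so both dialects load through the same entry point).
"""

from __future__ import annotations

import math
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

__all__ = [
    "DistributionSpec",
    "UncertainParam",
    "StrategyParams",
    "SharedParams",
    "EconSettings",
    "VariantFlags",
    "Scenario",
    "beta_mean",
    "gamma_from_mean_sd",
    "beta_from_mean_n",
    "rescale_to_mean",
    "cumulative_to_annual",
    "point",
    "load_scenario",
    "load_scenario_file",
    "write_scenario",
    "write_scenario_file",
]

DistKind = Literal["beta", "gamma", "normal", "point", "beta_sum"]


class DistributionSpec(BaseModel):
    """One uncertain parameter's sampling distribution.

    ``a``/``b`` are overloaded by ``kind``: Beta(alpha, beta), Gamma(shape,
    scale), Normal(mean, sd), or a degenerate point mass at ``a``.  The extra
    ``beta_sum`` kind models a probability that is the sum of independent
    Beta components (used for the surgery arm's composite complication risk);
    its draws are capped at 1.

    ``truncation`` bounds are enforced by rejection sampling (with a clip
    fallback after 100 rounds, which in practice never triggers for the
    distributions used here).
    """

    model_config = ConfigDict(extra="forbid")

    kind: DistKind
    a: float = 0.0
    b: float = 0.0
    components: Optional[list["DistributionSpec"]] = None
    truncation: Optional[tuple[float, float]] = None

    @model_validator(mode="after")
    def _validate(self) -> "DistributionSpec":
        if self.kind == "beta":
            if not (self.a > 0.0 and self.b > 0.0):
                raise ValueError("beta requires a > 0 and b > 0")
        elif self.kind == "gamma":
            if not (self.a > 0.0 and self.b > 0.0):
                raise ValueError("gamma requires shape > 0 and scale > 0")
        elif self.kind == "normal":
            if self.b < 0.0:
                raise ValueError("normal requires sd >= 0")
        elif self.kind == "beta_sum":
            if not self.components:
                raise ValueError("beta_sum requires at least one component")
            for c in self.components:
                if c.kind != "beta":
                    raise ValueError("beta_sum components must be beta")
        if self.kind != "beta_sum" and self.components is not None:
            raise ValueError("components are only valid for beta_sum")
        if self.truncation is not None and not (
            self.truncation[0] < self.truncation[1]
        ):
            raise ValueError("truncation interval must satisfy lo < hi")
        if not math.isfinite(self.mean()):
            raise ValueError("distribution mean must be finite")
        return self

    def mean(self) -> float:
        """Analytic mean of the (untruncated) distribution."""
        if self.kind == "beta":
            return self.a / (self.a + self.b)
        if self.kind == "gamma":
            return self.a * self.b
        if self.kind in ("normal", "point"):
            return self.a
        # beta_sum: linearity of expectation; the cap at 1 is ignorable for
        # the small component means used in practice.
        return sum(c.mean() for c in self.components)  # type: ignore[union-attr]

    def sd(self) -> float:
        if self.kind == "beta":
            n = self.a + self.b
            return math.sqrt(self.a * self.b / (n * n * (n + 1.0)))
        if self.kind == "gamma":
            return math.sqrt(self.a) * self.b
        if self.kind == "normal":
            return self.b
        if self.kind == "point":
            return 0.0
        return math.sqrt(sum(c.sd() ** 2 for c in self.components))  # type: ignore[union-attr]

    def is_point(self) -> bool:
        return self.kind == "point" or self.sd() == 0.0

    def _draw_raw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "beta":
            return rng.beta(self.a, self.b, size)
        if self.kind == "gamma":
            return rng.gamma(self.a, self.b, size)
        if self.kind == "normal":
            return rng.normal(self.a, self.b, size)
        if self.kind == "point":
            return np.full(size, self.a)
        out = np.zeros(size)
        for c in self.components:  # type: ignore[union-attr]
            out += rng.beta(c.a, c.b, size)
        return np.minimum(out, 1.0)

    def draw(self, rng: np.random.Generator, size: int | None = None):
        """Sample from the distribution, honouring ``truncation``."""
        n = 1 if size is None else int(size)
        x = self._draw_raw(rng, n)
        if self.truncation is not None and self.kind != "point":
            lo, hi = self.truncation
            for _ in range(100):
                bad = (x < lo) | (x > hi)
                if not bad.any():
                    break
                x[bad] = self._draw_raw(rng, int(bad.sum()))
            x = np.clip(x, lo, hi)
        return float(x[0]) if size is None else x

    def ppf(self, q: float) -> float:
        """Quantile of the untruncated distribution, clipped to the
        truncation bounds.  For ``beta_sum`` the component quantiles are
        summed — a conservative (wide) approximation documented in the
        methods note."""
        if self.kind == "beta":
            v = float(stats.beta.ppf(q, self.a, self.b))
        elif self.kind == "gamma":
            v = float(stats.gamma.ppf(q, self.a, scale=self.b))
        elif self.kind == "normal":
            v = float(stats.norm.ppf(q, self.a, self.b))
        elif self.kind == "point":
            v = self.a
        else:
            v = min(sum(c.ppf(q) for c in self.components), 1.0)  # type: ignore[union-attr]
        if self.truncation is not None:
            v = min(max(v, self.truncation[0]), self.truncation[1])
        return v


def point(value: float) -> DistributionSpec:
    """Degenerate (point-mass) distribution at ``value``."""
    return DistributionSpec(kind="point", a=value)


def beta_mean(spec: DistributionSpec) -> float:
    """Mean alpha / (alpha + beta) of a Beta specification.

    Raises ``TypeError`` for any other kind — callers use this to assert a
    probability parameter really is Beta distributed.
    """
    if spec.kind != "beta":
        raise TypeError(f"beta_mean requires a beta spec, got {spec.kind!r}")
    return spec.a / (spec.a + spec.b)


def gamma_from_mean_sd(mean: float, sd: float) -> DistributionSpec:
    """Moment-matched Gamma spec: shape = (mean/sd)^2, scale = sd^2/mean."""
    if not (mean > 0.0 and sd > 0.0):
        raise ValueError("gamma_from_mean_sd requires mean > 0 and sd > 0")
    return DistributionSpec(kind="gamma", a=(mean / sd) ** 2, b=sd * sd / mean)


def beta_from_mean_n(mean: float, n: float) -> DistributionSpec:
    """Beta spec with the given mean and effective sample size alpha+beta = n."""
    if not (0.0 < mean < 1.0 and n > 0.0):
        raise ValueError("beta_from_mean_n requires 0 < mean < 1 and n > 0")
    return DistributionSpec(kind="beta", a=mean * n, b=(1.0 - mean) * n)


def rescale_to_mean(spec: DistributionSpec, target_mean: float) -> DistributionSpec:
    """Shift a distribution so its mean equals ``target_mean`` while keeping
    its dispersion structure: Beta keeps alpha+beta, Gamma keeps its
    coefficient of variation (shape), Normal keeps its SD.

    Used when a published distribution's implied mean disagrees with the
    published point estimate that drives the base case; the base-case value
    wins and the distribution is re-centred on it.
    """
    if spec.kind == "beta":
        return beta_from_mean_n(target_mean, spec.a + spec.b).model_copy(
            update={"truncation": spec.truncation}
        )
    if spec.kind == "gamma":
        if target_mean <= 0:
            raise ValueError("gamma mean must be positive")
        return DistributionSpec(
            kind="gamma", a=spec.a, b=target_mean / spec.a, truncation=spec.truncation
        )
    if spec.kind == "normal":
        return spec.model_copy(update={"a": target_mean})
    if spec.kind == "point":
        return point(target_mean)
    raise TypeError("cannot rescale a beta_sum spec; rescale its components")


def cumulative_to_annual(
    p_cum: float, years: float, method: Literal["linear", "exponential"] = "linear"
) -> float:
    """Convert a cumulative risk over ``years`` to an annual probability.

    ``linear`` divides (the arithmetic convention used throughout the source
    tables, e.g. 4.3% over 5 years -> 0.86%/yr); ``exponential`` assumes a
    constant hazard, 1 - (1 - p)^(1/years).  For the small risks in this
    model the two agree to well under 10%.
    """
    if not 0.0 <= p_cum <= 1.0:
        raise ValueError("p_cum must lie in [0, 1]")
    if years <= 0.0:
        raise ValueError("years must be positive")
    if method == "linear":
        return min(p_cum / years, 1.0)
    if method == "exponential":
        # -expm1(log1p(-p)/y): numerically stable for small risks
        return -math.expm1(math.log1p(-p_cum) / years) if p_cum < 1.0 else 1.0
    raise ValueError(f"unknown method {method!r}")


ParamUnit = Literal["probability_per_year", "usd", "utility"]


class UncertainParam(BaseModel):
    """A model input: base-case value plus sampling distribution."""

    model_config = ConfigDict(extra="forbid")

    base_value: float
    dist: Optional[DistributionSpec] = None
    unit: ParamUnit

    @model_validator(mode="after")
    def _validate(self) -> "UncertainParam":
        if self.dist is None:
            object.__setattr__(self, "dist", point(self.base_value))
        v = self.base_value
        if self.unit == "probability_per_year" and not 0.0 <= v <= 1.0:
            raise ValueError("probability_per_year base_value must lie in [0, 1]")
        if self.unit == "usd" and v < 0.0:
            raise ValueError("usd base_value must be >= 0")
        if self.unit == "utility" and not -1.0 <= v <= 1.0:
            raise ValueError("utility base_value must lie in [-1, 1]")
        return self


def _usd(value: float, dist: DistributionSpec | None = None) -> UncertainParam:
    return UncertainParam(base_value=value, dist=dist, unit="usd")


def _prob(value: float, dist: DistributionSpec | None = None) -> UncertainParam:
    return UncertainParam(base_value=value, dist=dist, unit="probability_per_year")


def _util(value: float, dist: DistributionSpec | None = None) -> UncertainParam:
    return UncertainParam(base_value=value, dist=dist, unit="utility")


class StrategyParams(BaseModel):
    """Everything specific to one treatment arm.

    ``routine_cost_increment`` is an additive per-cycle surcharge on the
    shared routine surveillance cost (base 0); it exists so the follow-up
    cost sensitivity analysis can raise one arm's surveillance spending
    without touching the shared parameter.
    """

    model_config = ConfigDict(extra="forbid")

    name: str
    procedure_cost: UncertainParam
    complication_prob: UncertainParam
    complication_cost: UncertainParam
    treatment_disutility: UncertainParam
    complication_disutility: UncertainParam
    p_local_annual: UncertainParam
    p_distant_annual: UncertainParam
    p_mortality_annual: UncertainParam
    routine_cost_increment: UncertainParam = Field(
        default_factory=lambda: _usd(0.0)
    )

    @model_validator(mode="after")
    def _validate(self) -> "StrategyParams":
        total = (
            self.p_local_annual.base_value
            + self.p_distant_annual.base_value
            + self.p_mortality_annual.base_value
        )
        if total > 1.0 + 1e-12:
            raise ValueError(
                f"annual event probabilities sum to {total:.4f} > 1"
            )
        return self


class SharedParams(BaseModel):
    """Costs and utilities common to both arms (drawn once per PSA iteration)."""

    model_config = ConfigDict(extra="forbid")

    routine_annual_cost: UncertainParam
    local_recurrence_cost: UncertainParam
    advanced_disease_cost: UncertainParam
    u_first_year: UncertainParam
    u_subsequent: UncertainParam
    u_local: UncertainParam
    u_distant: UncertainParam
    u_dead: float = 0.0

    @model_validator(mode="after")
    def _validate(self) -> "SharedParams":
        if self.u_dead != 0.0:
            raise ValueError("u_dead is fixed at 0")
        for name in ("u_first_year", "u_subsequent", "u_local", "u_distant"):
            p: UncertainParam = getattr(self, name)
            if not 0.0 <= p.base_value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        return self


class EconSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    discount_rate: float = 0.03
    wtp: float = 100_000.0
    horizon_cycles: int = 5
    cycle_length_years: float = 1.0

    @model_validator(mode="after")
    def _validate(self) -> "EconSettings":
        if self.discount_rate < 0.0:
            raise ValueError("discount_rate must be >= 0")
        if self.wtp < 0.0:
            raise ValueError("wtp must be >= 0")
        if self.horizon_cycles < 1:
            raise ValueError("horizon_cycles must be >= 1")
        if self.cycle_length_years != 1.0:
            raise ValueError("cycle_length_years is fixed at 1 year")
        return self


CostMode = Literal["one_time_on_entry", "per_cycle", "on_entry_plus_routine"]


class VariantFlags(BaseModel):
    """Structural readings of the state diagram that the narrative leaves open.

    The shipped defaults are the calibrated combination selected by
    :mod:`cryocea.calibration` (see docs/methods.md for the score table).

    * ``lr_cost_mode`` / ``dr_cost_mode`` — how the recurrence-state cost is
      charged: once on entry, every occupied cycle, or once on entry with
      routine care continuing per cycle.
    * ``event_timing`` — whether the destination state's cost/utility applies
      in the cycle of transition (``entry_cycle``) or the following one.
    * ``dead_accrues_routine`` — whether the routine annual cost keeps being
      charged for the dead fraction of the cohort (a payer-ledger reading in
      which the annualized care cost is not censored at death).
    * ``mortality_source_states`` — whether cancer mortality applies from all
      alive states or from the disease-free state only.
    """

    model_config = ConfigDict(extra="forbid")

    lr_cost_mode: CostMode = "on_entry_plus_routine"
    dr_cost_mode: CostMode = "per_cycle"
    event_timing: Literal["entry_cycle", "next_cycle"] = "entry_cycle"
    dead_accrues_routine: bool = True
    mortality_source_states: Literal["all_alive", "disease_free_only"] = "all_alive"


class Scenario(BaseModel):
    """A complete two-strategy comparison: both arms, shared economics and
    the structural variant under which the cohort model is run."""

    model_config = ConfigDict(extra="forbid")

    name: str
    bca: StrategyParams
    bcs: StrategyParams
    shared: SharedParams
    econ: EconSettings = Field(default_factory=EconSettings)
    structural_variant: VariantFlags = Field(default_factory=VariantFlags)


def load_scenario(text: str) -> Scenario:
    """Parse a YAML or JSON scenario document into a validated Scenario.

    Unknown keys are rejected; violations report the offending field path.
    """
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("scenario document must be a mapping")
    return Scenario.model_validate(data)


def load_scenario_file(path) -> Scenario:
    with open(path, "r", encoding="utf-8") as fh:
        return load_scenario(fh.read())


def write_scenario(scenario: Scenario) -> str:
    """Serialize to YAML such that ``load_scenario`` round-trips exactly."""
    return yaml.safe_dump(scenario.model_dump(mode="json"), sort_keys=False)


def write_scenario_file(scenario: Scenario, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_scenario(scenario))
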