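"""Model parameters: typed inputs, survival-to-probability conversion, cycle
costs and the probability distributions used for probabilistic sensitivity
analysis.

The model compares two treatment strategies for chemorefractory metastatic
colorectal cancer: oral trifluridine/tipiracil (TAS-102) alone and TAS-102
combined with bevacizumab.  Every input is a triplet (base, min, max) with a
named sampling distribution; in the built-in scenario min and max are
base x 0.75 and base x 1.25, the ranges used by the one-way sensitivity
analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .errors import ConfigurationError, InputDomainError

__all__ = [
    "ProbParam",
    "ArmTransitionParams",
    "CostItem",
    "CostInputs",
    "CycleCost",
    "UtilitySet",
    "Arm",
    "Scenario",
    "COUNTING_CONVENTIONS",
    "DISCOUNT_CONVENTIONS",
    "median_to_transition_prob",
    "prob_rescale",
    "assemble_cycle_cost",
    "jpy_to_usd",
    "build_psa_distribution",
    "PointMassSampler",
    "BetaSampler",
    "GammaSampler",
]

COUNTING_CONVENTIONS = ("cycle_start", "cycle_end", "half_cycle")
DISCOUNT_CONVENTIONS = ("annualized", "per_cycle")

#: Yen per US dollar used to express all costs (2019 exchange rate).
DEFAULT_EXCHANGE_RATE = 110.05


@dataclass(frozen=True)
class ProbParam:
    """A per-cycle probability (or a 0-1 utility) with its sensitivity range.

    ``dist_label`` names the family used in probabilistic sensitivity
    analysis; bounded 0-1 quantities are sampled from a moment-matched beta
    ("beta_like").
    """

    base: float
    min: float = None  # type: ignore[assignment]
    max: float = None  # type: ignore[assignment]
    dist_label: str = "beta_like"

    def __post_init__(self):
        if self.min is None:
            object.__setattr__(self, "min", 0.75 * self.base)
        if self.max is None:
            object.__setattr__(self, "max", min(1.25 * self.base, 1.0))
        if not (0.0 <= self.min <= self.base <= self.max <= 1.0):
            raise InputDomainError(
                f"probability parameter violates 0 <= min <= base <= max <= 1: "
                f"base={self.base}, min={self.min}, max={self.max}"
            )
        if self.dist_label not in ("beta_like", "gamma_like"):
            raise ConfigurationError(f"unknown distribution label {self.dist_label!r}")


@dataclass(frozen=True)
class ArmTransitionParams:
    """Per-cycle transition probabilities for one treatment arm.

    ``p_progression``: stable disease -> progression; ``p_death``:
    progression -> death; ``p_complication``: onset of a grade 3-4
    complication (applied both before and after progression).
    """

    p_progression: ProbParam
    p_death: ProbParam
    p_complication: ProbParam

    def __post_init__(self):
        excess = self.p_progression.base + self.p_complication.base - 1.0
        if excess > 1e-12:
            raise InputDomainError(
                f"stable-state row infeasible: p_progression + p_complication "
                f"exceeds 1 by {excess:.6g}"
            )


@dataclass(frozen=True)
class CostItem:
    """A direct medical cost item in US dollars with its sensitivity range."""

    label: str
    base: float
    min: float = None  # type: ignore[assignment]
    max: float = None  # type: ignore[assignment]
    dist_label: str = "gamma_like"

    def __post_init__(self):
        if self.min is None:
            object.__setattr__(self, "min", 0.75 * self.base)
        if self.max is None:
            object.__setattr__(self, "max", 1.25 * self.base)
        if not (0.0 <= self.min <= self.base <= self.max):
            raise InputDomainError(
                f"cost item {self.label!r} violates 0 <= min <= base <= max: "
                f"base={self.base}, min={self.min}, max={self.max}"
            )


@dataclass
class CostInputs:
    """Cost items for one arm plus how often each is incurred per cycle.

    ``multiplicities`` maps item labels to integer counts per 8-week Markov
    cycle (e.g. two 4-week TAS-102 courses, four biweekly bevacizumab doses).
    The item named by ``complication_label`` is a once-only cost charged when
    a patient first enters a complication state, not a per-cycle cost.
    """

    items: tuple[CostItem, ...]
    multiplicities: dict[str, int]
    complication_label: str = "complication management"
    exchange_rate: float = DEFAULT_EXCHANGE_RATE
    body_weight_kg: float = 65.0
    body_surface_area_m2: float = 1.72

    def item(self, label: str) -> CostItem:
        for it in self.items:
            if it.label == label:
                return it
        raise ConfigurationError(f"unknown cost item label {label!r}")

    def labels(self) -> list[str]:
        return [it.label for it in self.items]


@dataclass(frozen=True)
class CycleCost:
    """Per-cycle state costs for one arm, split by role."""

    on_treatment: float
    complication_once: float
    progression: float = 0.0


@dataclass
class UtilitySet:
    """Annual health-state utilities for one arm.

    Each utility carries its own sensitivity range.  In the built-in scenario
    the complication states inherit the utility of their parent state and the
    death utility is 0.
    """

    stable: ProbParam
    complication: ProbParam
    progression: ProbParam
    progression_complication: ProbParam
    death: ProbParam = field(default_factory=lambda: ProbParam(0.0, 0.0, 0.0))


@dataclass
class Arm:
    name: str
    transitions: ArmTransitionParams
    costs: CostInputs
    utilities: UtilitySet


@dataclass
class Scenario:
    """Complete specification of a two-arm cost-effectiveness comparison."""

    reference: Arm
    comparator: Arm
    cycle_length_weeks: float = 8.0
    n_cycles: int = 30
    annual_discount: float = 0.035
    wtp_threshold: float = 117746.0
    counting_convention: str = "cycle_start"
    discount_convention: str = "annualized"
    psa_seed: int = 20210420
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_cycles < 1:
            raise ConfigurationError("n_cycles must be >= 1")
        if not (0.0 <= self.annual_discount < 1.0):
            raise ConfigurationError("annual_discount must be in [0, 1)")
        if self.cycle_length_weeks <= 0:
            raise ConfigurationError("cycle_length_weeks must be positive")
        if self.counting_convention not in COUNTING_CONVENTIONS:
            raise ConfigurationError(
                f"unknown counting convention {self.counting_convention!r}"
            )
        if self.discount_convention not in DISCOUNT_CONVENTIONS:
            raise ConfigurationError(
                f"unknown discount convention {self.discount_convention!r}"
            )

    @property
    def arms(self) -> dict[str, Arm]:
        return {self.reference.name: self.reference, self.comparator.name: self.comparator}


def median_to_transition_prob(median: float, cycle_length: float) -> float:
    """Convert a median survival time to a per-cycle transition probability.

    Survival is treated as exponential (declining exponential approximation
    of life expectancy), so the event rate is ln 2 / median and the
    probability of the event within one cycle is ``1 - exp(-rate * cycle)``.
    ``median`` and ``cycle_length`` must be in the same time unit.
    """
    if median <= 0:
        raise InputDomainError(f"median must be positive, got {median}")
    if cycle_length <= 0:
        raise InputDomainError(f"cycle_length must be positive, got {cycle_length}")
    return -math.expm1(-math.log(2.0) / median * cycle_length)


def prob_rescale(p: float, from_len: float, to_len: float) -> float:
    """Rescale a per-cycle probability to a different cycle length assuming a
    constant underlying rate: ``1 - (1-p)**(to_len/from_len)``."""
    if from_len <= 0 or to_len <= 0:
        raise InputDomainError("cycle lengths must be positive")
    if p == 1.0:
        return 1.0
    if not (0.0 <= p < 1.0):
        raise InputDomainError(f"probability must be in [0, 1], got {p}")
    return -math.expm1(math.log1p(-p) * to_len / from_len)


def assemble_cycle_cost(cost_inputs: CostInputs) -> CycleCost:
    """Assemble the per-cycle cost of the treated (pre-progression) states and
    the once-only complication-management cost.

    Post-progression routine care carries no cost: after progression only the
    one-time complication cost can accrue.
    """
    labels = set(cost_inputs.labels())
    unknown = [k for k in cost_inputs.multiplicities if k not in labels]
    if unknown:
        raise ConfigurationError(
            "multiplicities name unknown cost item(s): " + ", ".join(sorted(unknown))
        )
    for label, count in cost_inputs.multiplicities.items():
        if count < 0 or int(count) != count:
            raise ConfigurationError(
                f"multiplicity for {label!r} must be a non-negative integer, got {count}"
            )
    on_treatment = sum(
        cost_inputs.item(label).base * count
        for label, count in cost_inputs.multiplicities.items()
        if label != cost_inputs.complication_label
    )
    complication_once = cost_inputs.item(cost_inputs.complication_label).base
    return CycleCost(on_treatment=float(on_treatment), complication_once=float(complication_once))


def jpy_to_usd(amount: float, rate: float = DEFAULT_EXCHANGE_RATE) -> float:
    """Convert Japanese yen to US dollars at the scenario exchange rate."""
    if not math.isfinite(amount):
        raise InputDomainError("amount must be finite")
    return amount / rate


# ---------------------------------------------------------------------------
# Samplers for probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


class PointMassSampler:
    """Degenerate sampler returning a constant."""

    def __init__(self, value: float):
        self.mean = float(value)

    def sample(self, rng: np.random.Generator, size=None):
        if size is None:
            return self.mean
        return np.full(size, self.mean)


class BetaSampler:
    """Beta distribution moment-matched to mean = base with the central 95%
    mass approximately spanning [min, max]."""

    def __init__(self, base: float, lo: float, hi: float):
        m = base
        sd = (hi - lo) / (2.0 * 1.96)
        # a valid beta requires var < m(1-m); cap dispersion just inside that
        sd = min(sd, 0.95 * math.sqrt(m * (1.0 - m)))
        k = m * (1.0 - m) / (sd * sd) - 1.0
        self.mean = m
        self._dist = stats.beta(m * k, (1.0 - m) * k)

    def sample(self, rng: np.random.Generator, size=None):
        return self._dist.rvs(size=size, random_state=rng)


class GammaSampler:
    """Gamma distribution with mean = base and sd = (max - min) / (2 * 1.96)."""

    def __init__(self, base: float, lo: float, hi: float):
        sd = (hi - lo) / (2.0 * 1.96)
        shape = (base / sd) ** 2
        self.mean = base
        self._dist = stats.gamma(shape, scale=sd * sd / base)

    def sample(self, rng: np.random.Generator, size=None):
        return self._dist.rvs(size=size, random_state=rng)


def build_psa_distribution(param: ProbParam | CostItem):
    """Build a seeded sampler for one parameter.

    Probabilities and utilities get a beta distribution (support [0, 1]),
    costs a gamma distribution (support [0, inf)), both moment-matched so the
    sample mean equals the base value and the central 95% mass approximately
    covers [min, max].  A zero-width range yields a point mass.
    """
    base, lo, hi = param.base, param.min, param.max
    if hi <= lo or hi == lo == base:
        return PointMassSampler(base)
    if param.dist_label == "beta_like":
        if base <= 0.0 or base >= 1.0:
            return PointMassSampler(base)
        return BetaSampler(base, lo, hi)
    if base == 0.0:
        warnings.warn(
            f"gamma-like parameter with base 0 and max {hi} degenerates to a point mass at 0"
        )
        return PointMassSampler(0.0)
    return GammaSampler(base, lo, hi)


def scaled_param(param, factor: float):
    """Return a copy of a ProbParam/CostItem with all of base/min/max scaled
    (probabilities capped at 1). Used by scale-equivariance checks."""
    if isinstance(param, ProbParam):
        return replace(
            param,
            base=min(param.base * factor, 1.0),
            min=min(param.min * factor, 1.0),
            max=min(param.max * factor, 1.0),
        )
    return replace(param, base=param.base * factor, min=param.min * factor, max=param.max * factor)
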