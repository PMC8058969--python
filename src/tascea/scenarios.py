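"""Built-in and synthetic scenarios.

``paper_scenario`` returns the bundled comparison of TAS-102 plus bevacizumab
against TAS-102 monotherapy in chemorefractory metastatic colorectal cancer,
with every published parameter triplet verbatim.  ``random_scenario``
generates structurally identical random scenarios (two arms, probability /
cost / utility triplets with min = base x (1 - f), max = base x (1 + f)) for
property-based testing, and ``degenerate_scenarios`` provides edge-case
fixtures for the invariant suite.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np

from .params import (
    Arm,
    ArmTransitionParams,
    CostInputs,
    CostItem,
    ProbParam,
    Scenario,
    UtilitySet,
)

__all__ = [
    "paper_scenario",
    "ScenarioBlueprint",
    "random_scenario",
    "degenerate_scenarios",
    "PAPER_BASE_CASE",
]

#: Published base-case totals (reference arm = monotherapy).  Used as the
#: calibration target for the undocumented run configuration.  Note the
#: printed incremental QALY, per-arm QALYs and ICER are mutually rounded.
PAPER_BASE_CASE = {
    "reference_cost": 3434.834,
    "reference_qaly": 0.501,
    "comparator_cost": 8424.188,
    "comparator_qaly": 0.73,
    "incremental_cost": 4989.354,
    "incremental_qaly": 0.231,
    "icer": 21553.630,
}

_SCENARIO_RESOURCE = "tas102_bevacizumab.yaml"


def paper_scenario() -> Scenario:
    """The bundled two-arm scenario with the published parameter tables.

    Counting/discount conventions and per-cycle item multiplicities are those
    recovered by :func:`tascea.outcomes.calibrate_conventions` against the
    published base-case totals (the source analysis does not document them).
    """
    from .reporting import validate_scenario

    text = resources.files("tascea").joinpath("data", _SCENARIO_RESOURCE).read_text()
    return validate_scenario(text)


@dataclass
class ScenarioBlueprint:
    """Ranges for random scenario generation.

    ``range_fraction`` sets min/max at base x (1 -/+ fraction), mirroring the
    built-in scenario's +/-25% sensitivity ranges.  Probabilities are drawn so
    every transition row stays feasible with margin ``feasibility_margin``.
    """

    p_progression: tuple[float, float] = (0.10, 0.70)
    p_death: tuple[float, float] = (0.05, 0.60)
    p_complication: tuple[float, float] = (0.0, 0.20)
    u_stable: tuple[float, float] = (0.50, 0.95)
    u_progression_floor: float = 0.30
    treatment_cost: tuple[float, float] = (100.0, 5000.0)
    complication_cost: tuple[float, float] = (10.0, 500.0)
    n_fee_items: tuple[int, int] = (0, 3)
    fee_cost: tuple[float, float] = (5.0, 250.0)
    range_fraction: float = 0.25
    feasibility_margin: float = 0.05
    randomize_conventions: bool = True


def _prob(rng, lo, hi, frac) -> ProbParam:
    base = float(rng.uniform(lo, hi))
    return ProbParam(base, base * (1 - frac), min(base * (1 + frac), 1.0))


def _cost(label, rng, lo, hi, frac) -> CostItem:
    base = float(rng.uniform(lo, hi))
    return CostItem(label, base, base * (1 - frac), base * (1 + frac))


def _random_arm(name: str, rng: np.random.Generator, bp: ScenarioBlueprint) -> Arm:
    frac = bp.range_fraction
    # draw progression/complication jointly until the stable row is feasible
    # with margin even at the +25% extreme of progression
    for _ in range(1000):
        p_prog = _prob(rng, *bp.p_progression, frac)
        p_comp = _prob(rng, *bp.p_complication, frac)
        if p_prog.base + p_comp.base <= 1.0 - bp.feasibility_margin:
            break
    else:  # pragma: no cover - constructive ranges make this unreachable
        raise RuntimeError("could not draw a feasible transition row")
    p_death = _prob(rng, *bp.p_death, frac)

    u_stable = _prob(rng, *bp.u_stable, frac)
    u_prog_base = float(rng.uniform(bp.u_progression_floor, u_stable.base))
    u_prog = ProbParam(u_prog_base, u_prog_base * (1 - frac), min(u_prog_base * (1 + frac), 1.0))

    items = [
        _cost("treatment", rng, *bp.treatment_cost, frac),
        _cost("complication management", rng, *bp.complication_cost, frac),
    ]
    mults = {"treatment": int(rng.integers(1, 5))}
    for i in range(int(rng.integers(bp.n_fee_items[0], bp.n_fee_items[1] + 1))):
        label = f"fee_{i}"
        items.append(_cost(label, rng, *bp.fee_cost, frac))
        mults[label] = int(rng.integers(0, 5))

    return Arm(
        name=name,
        transitions=ArmTransitionParams(p_prog, p_death, p_comp),
        utilities=UtilitySet(
            stable=u_stable,
            complication=u_stable,
            progression=u_prog,
            progression_complication=u_prog,
        ),
        costs=CostInputs(items=tuple(items), multiplicities=mults),
    )


def random_scenario(seed: int, blueprint: ScenarioBlueprint | None = None) -> Scenario:
    """Generate a random valid scenario; deterministic for a given seed."""
    bp = blueprint or ScenarioBlueprint()
    rng = np.random.default_rng(seed)
    ref = _random_arm("reference", rng, bp)
    cmp_ = _random_arm("comparator", rng, bp)
    kwargs = {}
    if bp.randomize_conventions:
        kwargs["counting_convention"] = ["cycle_start", "cycle_end", "half_cycle"][
            int(rng.integers(3))]
        kwargs["discount_convention"] = ["annualized", "per_cycle"][int(rng.integers(2))]
    return Scenario(
        reference=ref,
        comparator=cmp_,
        annual_discount=float(rng.uniform(0.0, 0.08)),
        psa_seed=int(rng.integers(2**31 - 1)),
        **kwargs,
    )


def _point(value: float) -> ProbParam:
    return ProbParam(value, value, value)


def degenerate_scenarios() -> dict[str, Scenario]:
    """Edge-case fixtures derived from the bundled scenario.

    ``zero_discount``: no time preference; ``immortal``: death probability 0
    in both arms; ``instant_progression``: the whole cohort progresses at the
    first cycle (complications off to keep the row feasible);
    ``no_complication``: complication probability 0; ``equal_arms``: the
    comparator duplicates the reference arm.
    """
    base = paper_scenario()
    out: dict[str, Scenario] = {}

    s = copy.deepcopy(base)
    s.annual_discount = 0.0
    out["zero_discount"] = s

    s = copy.deepcopy(base)
    for arm in s.arms.values():
        arm.transitions = replace(arm.transitions, p_death=_point(0.0))
    out["immortal"] = s

    s = copy.deepcopy(base)
    for arm in s.arms.values():
        arm.transitions = ArmTransitionParams(
            p_progression=_point(1.0),
            p_death=arm.transitions.p_death,
            p_complication=_point(0.0),
        )
    out["instant_progression"] = s

    s = copy.deepcopy(base)
    for arm in s.arms.values():
        arm.transitions = replace(arm.transitions, p_complication=_point(0.0))
    out["no_complication"] = s

    s = copy.deepcopy(base)
    clone = copy.deepcopy(s.reference)
    clone.name = s.comparator.name
    s.comparator = clone
    out["equal_arms"] = s

    return out
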