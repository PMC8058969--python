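"""Deterministic and probabilistic sensitivity analysis.

One-way deterministic analysis (tornado): every tabulated parameter is set to
its minimum and maximum (base ∓/± 25% in the built-in scenario) with all
others at base, the full base case is rerun, and parameters are ranked by the
induced ICER range.

Probabilistic analysis: all parameters are resampled simultaneously and
independently from their fitted distributions, the model is rerun per draw,
and the paired incremental cost/QALY draws feed the cost-effectiveness plane
and the cost-effectiveness acceptability curve (CEAC).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace
from types import SimpleNamespace

import numpy as np
import pandas as pd

from .engine import accrue_values, build_transition_matrix_from_probs, run_cohort_trace
from .errors import ConfigurationError, InputDomainError
from .outcomes import base_case_report
from .params import (
    CostItem,
    CycleCost,
    ProbParam,
    Scenario,
    build_psa_distribution,
)

__all__ = [
    "ParameterRef",
    "TornadoEntry",
    "PSAResult",
    "CEACCurve",
    "dsa_parameters",
    "psa_parameters",
    "dsa_tornado",
    "psa_run",
    "ceac",
    "ce_plane_export",
    "DEFAULT_WTP_GRID",
]

#: Default willingness-to-pay grid: $0 to $150,000/QALY in $1,000 steps,
#: covering the published acceptability-curve range and both printed
#: threshold figures.
DEFAULT_WTP_GRID = tuple(float(x) for x in range(0, 150001, 1000))

_TRANSITION_KEYS = ("p_progression", "p_death", "p_complication")
_UTILITY_KEYS = ("stable", "complication", "progression", "progression_complication")


@dataclass(frozen=True)
class ParameterRef:
    """Addresses one scalar model parameter inside a scenario."""

    arm: str
    category: str  # "transition" | "utility" | "utility_phase" | "cost"
    key: str

    @property
    def label(self) -> str:
        return f"{self.arm}.{self.category}.{self.key}"

    def get(self, scenario: Scenario):
        arm = scenario.arms[self.arm]
        if self.category == "transition":
            return getattr(arm.transitions, self.key)
        if self.category in ("utility", "utility_phase"):
            key = "stable" if self.key == "stable_phase" else (
                "progression" if self.key == "progression_phase" else self.key)
            return getattr(arm.utilities, key)
        if self.category == "cost":
            return arm.costs.item(self.key)
        raise ConfigurationError(f"unknown parameter category {self.category!r}")

    def set_base(self, scenario: Scenario, value: float) -> None:
        """Point-set the parameter's base value in place (collapses its
        range; the modified scenario is only meant for a base-case rerun)."""
        arm = scenario.arms[self.arm]
        if self.category == "transition":
            new = ProbParam(value, value, value)
            arm.transitions = replace(arm.transitions, **{self.key: new})
        elif self.category == "utility_phase":
            new = ProbParam(value, value, value)
            if self.key == "stable_phase":
                arm.utilities.stable = new
                arm.utilities.complication = new
            else:
                arm.utilities.progression = new
                arm.utilities.progression_complication = new
        elif self.category == "utility":
            setattr(arm.utilities, self.key, ProbParam(value, value, value))
        elif self.category == "cost":
            item = arm.costs.item(self.key)
            items = tuple(
                CostItem(it.label, value, value, value, it.dist_label)
                if it.label == item.label else it
                for it in arm.costs.items
            )
            arm.costs.items = items
        else:
            raise ConfigurationError(f"unknown parameter category {self.category!r}")


def dsa_parameters(scenario: Scenario) -> list[ParameterRef]:
    """Parameters varied one-way: per arm, the three transition
    probabilities, the stable-phase and progressed-phase utilities (the
    complication twin moves with its parent, as the published ranges tie
    them), and every cost item."""
    refs: list[ParameterRef] = []
    for arm_name, arm in scenario.arms.items():
        for key in _TRANSITION_KEYS:
            refs.append(ParameterRef(arm_name, "transition", key))
        refs.append(ParameterRef(arm_name, "utility_phase", "stable_phase"))
        refs.append(ParameterRef(arm_name, "utility_phase", "progression_phase"))
        for item in arm.costs.items:
            refs.append(ParameterRef(arm_name, "cost", item.label))
    return refs


def psa_parameters(scenario: Scenario) -> list[ParameterRef]:
    """Parameters resampled jointly: every tabulated row with a non-zero
    range, sampled independently (the published analysis states no
    correlation structure)."""
    refs: list[ParameterRef] = []
    for arm_name, arm in scenario.arms.items():
        for key in _TRANSITION_KEYS:
            refs.append(ParameterRef(arm_name, "transition", key))
        for key in _UTILITY_KEYS:
            param = getattr(arm.utilities, key)
            if param.max > param.min:
                refs.append(ParameterRef(arm_name, "utility", key))
        for item in arm.costs.items:
            refs.append(ParameterRef(arm_name, "cost", item.label))
    return refs


@dataclass
class TornadoEntry:
    parameter: str
    icer_at_min: float
    icer_at_max: float
    infeasible: bool = False

    @property
    def width(self) -> float:
        if self.infeasible:
            return float("nan")
        return abs(self.icer_at_max - self.icer_at_min)


def dsa_tornado(
    scenario: Scenario, varied_parameters: list[ParameterRef] | None = None
) -> list[TornadoEntry]:
    """One-way deterministic sensitivity analysis.

    Returns one entry per parameter, sorted by decreasing ICER range.  A
    parameter whose extreme makes a transition row infeasible is flagged
    rather than silently clipped.
    """
    refs = varied_parameters if varied_parameters is not None else dsa_parameters(scenario)
    entries = []
    for ref in refs:
        param = ref.get(scenario)
        icers = {}
        infeasible = False
        for which, value in (("min", param.min), ("max", param.max)):
            modified = copy.deepcopy(scenario)
            try:
                ref.set_base(modified, value)
                icers[which] = base_case_report(modified).icer
            except InputDomainError:
                infeasible = True
                icers[which] = float("nan")
        entries.append(
            TornadoEntry(ref.label, icers["min"], icers["max"], infeasible=infeasible)
        )
    entries.sort(key=lambda e: (-(e.width if np.isfinite(e.width) else -np.inf), e.parameter))
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "icer_at_min": e.icer_at_min,
                "icer_at_max": e.icer_at_max,
                "width": e.width,
                "infeasible": e.infeasible,
            }
            for e in entries
        ]
    )


@dataclass
class PSAResult:
    """Paired per-draw outcomes of a probabilistic sensitivity analysis."""

    n_draws: int
    seed: int
    reference_name: str
    comparator_name: str
    draws: pd.DataFrame
    n_renormalized: int

    @property
    def d_cost(self) -> np.ndarray:
        return self.draws["d_cost"].to_numpy()

    @property
    def d_qaly(self) -> np.ndarray:
        return self.draws["d_qaly"].to_numpy()


def _arm_draw_values(scenario, arm_name, p, d, c, on_treatment, comp_once, u4):
    matrix = build_transition_matrix_from_probs(p, d, c, infeasible="renormalize")
    renorm = matrix.renormalized_rows
    trace = run_cohort_trace(matrix, scenario.n_cycles)
    utilities = SimpleNamespace(
        stable=SimpleNamespace(base=u4[0]),
        complication=SimpleNamespace(base=u4[1]),
        progression=SimpleNamespace(base=u4[2]),
        progression_complication=SimpleNamespace(base=u4[3]),
        death=SimpleNamespace(base=0.0),
    )
    totals = accrue_values(
        trace,
        CycleCost(on_treatment=on_treatment, complication_once=comp_once),
        utilities,
        cycle_length_weeks=scenario.cycle_length_weeks,
        annual_discount=scenario.annual_discount,
        counting_convention=scenario.counting_convention,
        discount_convention=scenario.discount_convention,
        with_ledger=False,
    )
    return totals.discounted_cost, totals.discounted_qaly, renorm


def psa_run(scenario: Scenario, n_draws: int = 1000, seed: int | None = None) -> PSAResult:
    """Probabilistic sensitivity analysis: resample every parameter, rerun
    both arms per draw, record the incremental outcomes.  Deterministic for a
    given seed.  Sampled transition rows that would exceed probability 1 are
    renormalized proportionally and counted in ``n_renormalized``."""
    if seed is None:
        seed = scenario.psa_seed
    refs = psa_parameters(scenario)
    rng = np.random.default_rng(seed)
    samples: dict[str, np.ndarray] = {}
    for ref in refs:
        sampler = build_psa_distribution(ref.get(scenario))
        samples[ref.label] = np.asarray(sampler.sample(rng, size=n_draws), dtype=float)

    arm_rows = {}
    n_renormalized = 0
    for arm_name, arm in scenario.arms.items():
        mult = arm.costs.multiplicities
        comp_label = arm.costs.complication_label
        cost_labels = [
            (it.label, mult.get(it.label, 0)) for it in arm.costs.items if it.label != comp_label
        ]
        u_cols = []
        for key in _UTILITY_KEYS:
            name = f"{arm_name}.utility.{key}"
            u_cols.append(samples[name] if name in samples
                          else np.full(n_draws, getattr(arm.utilities, key).base))
        costs_arr = np.zeros(n_draws)
        for label, count in cost_labels:
            name = f"{arm_name}.cost.{label}"
            vals = samples[name] if name in samples else np.full(n_draws, arm.costs.item(label).base)
            costs_arr = costs_arr + count * vals
        comp_name = f"{arm_name}.cost.{comp_label}"
        comp_arr = samples[comp_name] if comp_name in samples else np.full(
            n_draws, arm.costs.item(comp_label).base)

        cost_out = np.empty(n_draws)
        qaly_out = np.empty(n_draws)
        for i in range(n_draws):
            p = samples[f"{arm_name}.transition.p_progression"][i]
            dd = samples[f"{arm_name}.transition.p_death"][i]
            cc = samples[f"{arm_name}.transition.p_complication"][i]
            cost_out[i], qaly_out[i], renorm = _arm_draw_values(
                scenario, arm_name, p, dd, cc, costs_arr[i], comp_arr[i],
                [u[i] for u in u_cols],
            )
            n_renormalized += renorm
        arm_rows[arm_name] = (cost_out, qaly_out)

    ref_c, ref_q = arm_rows[scenario.reference.name]
    cmp_c, cmp_q = arm_rows[scenario.comparator.name]
    draws = pd.DataFrame({"draw": np.arange(n_draws)})
    for name, vals in samples.items():
        draws[name] = vals
    draws["reference_cost"] = ref_c
    draws["reference_qaly"] = ref_q
    draws["comparator_cost"] = cmp_c
    draws["comparator_qaly"] = cmp_q
    draws["d_cost"] = cmp_c - ref_c
    draws["d_qaly"] = cmp_q - ref_q
    return PSAResult(
        n_draws=n_draws,
        seed=seed,
        reference_name=scenario.reference.name,
        comparator_name=scenario.comparator.name,
        draws=draws,
        n_renormalized=n_renormalized,
    )


@dataclass
class CEACCurve:
    """Probability each strategy is cost-effective across a WTP grid."""

    wtp: np.ndarray
    p_comparator: np.ndarray
    reference_name: str
    comparator_name: str

    @property
    def p_reference(self) -> np.ndarray:
        return 1.0 - self.p_comparator

    def at(self, wtp: float) -> float:
        idx = int(np.argmin(np.abs(self.wtp - wtp)))
        return float(self.p_comparator[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wtp": self.wtp,
                f"p_{self.reference_name}": self.p_reference,
                f"p_{self.comparator_name}": self.p_comparator,
            }
        )


def ceac(psa: PSAResult, wtp_grid=DEFAULT_WTP_GRID) -> CEACCurve:
    """Cost-effectiveness acceptability curve.

    At each willingness-to-pay λ the comparator wins a draw when its
    incremental net monetary benefit λ·ΔQALY − Δcost is strictly positive
    (ties go to the reference), so the two strategies' probabilities sum
    to 1 at every grid point.
    """
    wtp = np.asarray(list(wtp_grid), dtype=float)
    if wtp.size == 0:
        raise InputDomainError("willingness-to-pay grid must be non-empty")
    if psa.n_draws == 0:
        raise InputDomainError("empty probabilistic sensitivity analysis")
    inmb = wtp[:, None] * psa.d_qaly[None, :] - psa.d_cost[None, :]
    return CEACCurve(
        wtp=wtp,
        p_comparator=(inmb > 0).mean(axis=1),
        reference_name=psa.reference_name,
        comparator_name=psa.comparator_name,
    )


def ce_plane_export(psa: PSAResult) -> tuple[pd.DataFrame, dict[str, int]]:
    """Cost-effectiveness plane: one (ΔQALY, Δcost) row per draw plus counts
    of draws per quadrant (northeast = more effective and more costly)."""
    table = psa.draws[["draw", "d_qaly", "d_cost"]].copy()
    dq, dc = psa.d_qaly, psa.d_cost
    quadrants = {
        "northeast": int(((dq > 0) & (dc > 0)).sum()),
        "northwest": int(((dq <= 0) & (dc > 0)).sum()),
        "southeast": int(((dq > 0) & (dc <= 0)).sum()),
        "southwest": int(((dq <= 0) & (dc <= 0)).sum()),
    }
    return table, quadrants
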