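"""Markov cohort engine.

The published model has five health states: stable disease (SD), treatment
complication (TC), progression (PROG), progression with complication (PC) and
death.  Complication-management costs are charged at most once per
complication episode; to keep that accounting inside a pure Markov chain the
engine expands the state space with two "post-complication" twin states
(SD_postC, PROG_postC) that patients occupy after their one complication
cycle.  TC and PC are one-cycle tunnels, so their occupancy at a given cycle
equals the fresh inflow at that cycle, and the chain never re-enters them.

Death is absorbing and is reachable only from the progressed phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputDomainError
from .params import (
    ArmTransitionParams,
    COUNTING_CONVENTIONS,
    CycleCost,
    Scenario,
    UtilitySet,
    assemble_cycle_cost,
)

__all__ = [
    "STATES",
    "REPORTED_STATES",
    "REPORT_MAP",
    "STABLE_PHASE",
    "PROGRESSED_PHASE",
    "CohortTrace",
    "ArmTotals",
    "build_transition_matrix",
    "validate_transition_matrix",
    "run_cohort_trace",
    "cycle_qaly",
    "discount_factor",
    "accrue_values",
    "run_arm",
    "microsim_oracle",
]

#: Expanded state space (order fixed; all arrays use these indices).
STATES = ("SD", "SD_postC", "TC", "PROG", "PROG_postC", "PC", "DEATH")
SD, SD_POSTC, TC, PROG, PROG_POSTC, PC, DEATH = range(7)

#: The five states the model reports; the twins collapse onto their parents.
REPORTED_STATES = ("SD", "TC", "PROG", "PC", "DEATH")
REPORT_MAP = {
    "SD": "SD",
    "SD_postC": "SD",
    "TC": "TC",
    "PROG": "PROG",
    "PROG_postC": "PROG",
    "PC": "PC",
    "DEATH": "DEATH",
}

STABLE_PHASE = (SD, SD_POSTC, TC)
PROGRESSED_PHASE = (PROG, PROG_POSTC, PC)
COMPLICATION_ENTRY = (TC, PC)  # one-cycle tunnels: occupancy == fresh inflow


def build_transition_matrix(
    arm: ArmTransitionParams, infeasible: str = "error"
) -> np.ndarray:
    """Build the 7x7 per-cycle transition matrix for one arm.

    ``infeasible`` controls what happens when a probability row would exceed
    1 (possible for resampled parameters): ``"error"`` raises, while
    ``"renormalize"`` zeroes the self-loop and rescales the exit
    probabilities proportionally.
    """
    p = float(arm.p_progression.base if hasattr(arm.p_progression, "base") else arm.p_progression)
    d = float(arm.p_death.base if hasattr(arm.p_death, "base") else arm.p_death)
    c = float(arm.p_complication.base if hasattr(arm.p_complication, "base") else arm.p_complication)
    return build_transition_matrix_from_probs(p, d, c, infeasible=infeasible)


def build_transition_matrix_from_probs(
    p_progression: float,
    p_death: float,
    p_complication: float,
    infeasible: str = "error",
) -> np.ndarray:
    p, d, c = p_progression, p_death, p_complication
    renormalized = 0

    def row_exits(*pairs):
        nonlocal renormalized
        total = sum(v for _, v in pairs)
        if total > 1.0 + 1e-12:
            if infeasible == "error":
                raise InputDomainError(
                    f"transition row infeasible: exit probabilities sum to {total:.6g} > 1"
                )
            renormalized += 1
            pairs = [(j, v / total) for j, v in pairs]
            total = 1.0
        return pairs, max(1.0 - total, 0.0)

    M = np.zeros((7, 7))
    exits, stay = row_exits((TC, c), (PROG, p))
    for j, v in exits:
        M[SD, j] = v
    M[SD, SD] = stay

    M[TC, PROG] = p
    M[TC, SD_POSTC] = 1.0 - p
    M[SD_POSTC, PROG] = p
    M[SD_POSTC, SD_POSTC] = 1.0 - p

    exits, stay = row_exits((PC, c), (DEATH, d))
    for j, v in exits:
        M[PROG, j] = v
    M[PROG, PROG] = stay

    M[PC, DEATH] = d
    M[PC, PROG_POSTC] = 1.0 - d
    M[PROG_POSTC, DEATH] = d
    M[PROG_POSTC, PROG_POSTC] = 1.0 - d
    M[DEATH, DEATH] = 1.0

    M = validate_transition_matrix(M)
    M.renormalized_rows = renormalized  # type: ignore[attr-defined]
    return M


class _Matrix(np.ndarray):
    renormalized_rows: int = 0


def validate_transition_matrix(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.shape != (7, 7):
        raise ConfigurationError(f"transition matrix must be 7x7, got {M.shape}")
    if (M < -1e-15).any():
        raise InputDomainError("transition matrix has negative entries")
    rows = M.sum(axis=1)
    bad = np.where(np.abs(rows - 1.0) > 1e-12)[0]
    if bad.size:
        raise InputDomainError(
            f"transition rows {[STATES[i] for i in bad]} do not sum to 1 "
            f"(sums {rows[bad]})"
        )
    if M[DEATH, DEATH] != 1.0:
        raise InputDomainError("death state must be absorbing")
    for i in STABLE_PHASE:
        if M[i, DEATH] != 0.0:
            raise InputDomainError("death is reachable only through progression")
    return M.view(_Matrix)


@dataclass
class CohortTrace:
    """State occupancy fractions for cycles 0..n_cycles (rows) by state."""

    occupancy: np.ndarray

    def __post_init__(self):
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.ndim != 2 or occ.shape[1] != 7:
            raise ConfigurationError("trace must have 7 state columns")
        self.occupancy = occ

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def stable_phase(self) -> np.ndarray:
        return self.occupancy[:, list(STABLE_PHASE)].sum(axis=1)

    @property
    def progressed_phase(self) -> np.ndarray:
        return self.occupancy[:, list(PROGRESSED_PHASE)].sum(axis=1)

    @property
    def death(self) -> np.ndarray:
        return self.occupancy[:, DEATH]

    @property
    def complication_entries(self) -> np.ndarray:
        """Fraction of the cohort entering a complication state at each cycle."""
        return self.occupancy[:, list(COMPLICATION_ENTRY)].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.index.name = "cycle"
        for rep in REPORTED_STATES:
            cols = [s for s, r in REPORT_MAP.items() if r == rep]
            df[f"reported_{rep}"] = df[cols].sum(axis=1)
        return df


def run_cohort_trace(matrix: np.ndarray, n_cycles: int) -> CohortTrace:
    """Propagate a cohort starting entirely in SD through ``n_cycles`` cycles."""
    matrix = validate_transition_matrix(matrix)
    occ = np.zeros((n_cycles + 1, 7))
    occ[0, SD] = 1.0
    for t in range(1, n_cycles + 1):
        occ[t] = occ[t - 1] @ matrix
    return CohortTrace(occ)


def cycle_qaly(utility: float, cycle_length_weeks: float) -> float:
    """QALYs accrued in one cycle by a patient with an annual utility."""
    if not (0.0 <= utility <= 1.0):
        raise InputDomainError(f"utility must be in [0, 1], got {utility}")
    return utility * cycle_length_weeks / 52.0


def discount_factor(
    cycle_index: int,
    annual_rate: float,
    cycle_length_weeks: float,
    convention: str = "annualized",
) -> float:
    """Discount weight for a given cycle.

    ``annualized`` compounds the annual rate over the elapsed model time
    (cycle_index x cycle_length / 52 years); ``per_cycle`` applies the rate
    once per cycle regardless of cycle length.
    """
    if cycle_index < 0:
        raise InputDomainError("cycle_index must be >= 0")
    if convention == "annualized":
        return float((1.0 + annual_rate) ** (-(cycle_index * cycle_length_weeks / 52.0)))
    if convention == "per_cycle":
        return float((1.0 + annual_rate) ** (-cycle_index))
    raise ConfigurationError(f"unknown discount convention {convention!r}")


@dataclass
class ArmTotals:
    """Discounted and undiscounted cost/QALY totals plus the per-cycle ledger."""

    discounted_cost: float
    discounted_qaly: float
    undiscounted_cost: float
    undiscounted_qaly: float
    ledger: pd.DataFrame


def _state_utilities(utilities: UtilitySet) -> np.ndarray:
    u = np.zeros(7)
    u[SD] = utilities.stable.base
    u[SD_POSTC] = utilities.stable.base
    u[TC] = utilities.complication.base
    u[PROG] = utilities.progression.base
    u[PROG_POSTC] = utilities.progression.base
    u[PC] = utilities.progression_complication.base
    u[DEATH] = utilities.death.base
    return u


def accrue_values(
    trace: CohortTrace,
    cycle_costs: CycleCost,
    utilities: UtilitySet,
    *,
    n_cycles: int | None = None,
    cycle_length_weeks: float = 8.0,
    annual_discount: float = 0.035,
    counting_convention: str = "cycle_start",
    discount_convention: str = "annualized",
    with_ledger: bool = True,
) -> ArmTotals:
    """Accrue discounted costs and QALYs over a cohort trace.

    Treatment cost accrues while the cohort is in the stable phase (SD, its
    post-complication twin, and the complication cycle itself); progressed
    states carry no routine cost.  The once-only complication-management cost
    is an event cost charged at the cycle of entry into TC or PC, discounted
    at that cycle, independent of the membership-counting convention.

    Counting conventions weight state membership at the start of each cycle,
    the end of each cycle, or the average of the two (half-cycle correction).
    """
    if counting_convention not in COUNTING_CONVENTIONS:
        raise ConfigurationError(f"unknown counting convention {counting_convention!r}")
    n = trace.n_cycles if n_cycles is None else n_cycles
    occ = trace.occupancy
    if n > trace.n_cycles:
        raise ConfigurationError("trace shorter than requested horizon")

    u = _state_utilities(utilities)
    qaly_per_cycle = occ @ (u * cycle_length_weeks / 52.0)
    cost_per_cycle = trace.stable_phase * cycle_costs.on_treatment
    cost_per_cycle = cost_per_cycle + trace.progressed_phase * cycle_costs.progression

    df = np.array(
        [discount_factor(t, annual_discount, cycle_length_weeks, discount_convention)
         for t in range(n + 1)]
    )
    ones = np.ones(n + 1)

    def combine(values, weights):
        if counting_convention == "cycle_start":
            per = values[:n] * weights[:n]
            idx = np.arange(n)
        elif counting_convention == "cycle_end":
            per = values[1 : n + 1] * weights[1 : n + 1]
            idx = np.arange(1, n + 1)
        else:  # half_cycle
            per = 0.5 * (values[:n] + values[1 : n + 1]) * weights[:n]
            idx = np.arange(n)
        return per, idx

    dq, idx = combine(qaly_per_cycle, df)
    uq, _ = combine(qaly_per_cycle, ones)
    dc, _ = combine(cost_per_cycle, df)
    uc, _ = combine(cost_per_cycle, ones)

    # once-only complication cost at entry cycles 1..n
    entries = trace.complication_entries[1 : n + 1]
    comp_d = entries * cycle_costs.complication_once * df[1 : n + 1]
    comp_u = entries * cycle_costs.complication_once

    if with_ledger:
        ledger = pd.DataFrame(
            {
                "cycle": idx,
                "discount_weight": df[idx],
                "qaly": dq,
                "treatment_cost": dc,
            }
        ).set_index("cycle")
        comp_ledger = pd.Series(comp_d, index=np.arange(1, n + 1), name="complication_cost")
        ledger = ledger.join(comp_ledger, how="outer").fillna(0.0)
        ledger["cost"] = ledger["treatment_cost"] + ledger["complication_cost"]
    else:
        ledger = None

    return ArmTotals(
        discounted_cost=float(dc.sum() + comp_d.sum()),
        discounted_qaly=float(dq.sum()),
        undiscounted_cost=float(uc.sum() + comp_u.sum()),
        undiscounted_qaly=float(uq.sum()),
        ledger=ledger,
    )


def run_arm(scenario: Scenario, arm_name: str, infeasible: str = "error"):
    """Run one arm of a scenario: returns (trace, totals)."""
    arm = scenario.arms[arm_name]
    matrix = build_transition_matrix(arm.transitions, infeasible=infeasible)
    trace = run_cohort_trace(matrix, scenario.n_cycles)
    totals = accrue_values(
        trace,
        assemble_cycle_cost(arm.costs),
        arm.utilities,
        cycle_length_weeks=scenario.cycle_length_weeks,
        annual_discount=scenario.annual_discount,
        counting_convention=scenario.counting_convention,
        discount_convention=scenario.discount_convention,
    )
    return trace, totals


def microsim_oracle(
    matrix: np.ndarray,
    cycle_costs: CycleCost,
    utilities: UtilitySet,
    n_patients: int,
    seed: int,
    *,
    n_cycles: int = 30,
    cycle_length_weeks: float = 8.0,
    annual_discount: float = 0.035,
    counting_convention: str = "cycle_start",
    discount_convention: str = "annualized",
):
    """Individual-level microsimulation of the same chain and value rules.

    Simulates ``n_patients`` independent paths and accrues values with the
    same counting and discounting conventions as the cohort engine.  Returns
    a dict with mean cost/QALY and their Monte-Carlo standard errors; serves
    as an independent check on the cohort accrual.
    """
    if n_patients < 1:
        raise InputDomainError("n_patients must be >= 1")
    matrix = validate_transition_matrix(matrix)
    rng = np.random.default_rng(seed)
    cum = np.cumsum(matrix, axis=1)
    cum[:, -1] = 1.0

    states = np.zeros((n_cycles + 1, n_patients), dtype=np.int8)
    current = np.zeros(n_patients, dtype=np.int64)
    for t in range(1, n_cycles + 1):
        u = rng.random(n_patients)
        current = (u[:, None] > cum[current]).sum(axis=1)
        states[t] = current

    u_state = _state_utilities(utilities) * cycle_length_weeks / 52.0
    c_state = np.zeros(7)
    for i in STABLE_PHASE:
        c_state[i] = cycle_costs.on_treatment
    for i in PROGRESSED_PHASE:
        c_state[i] += cycle_costs.progression

    df = np.array(
        [discount_factor(t, annual_discount, cycle_length_weeks, discount_convention)
         for t in range(n_cycles + 1)]
    )
    qal = u_state[states]  # (n_cycles+1, n_patients)
    cst = c_state[states]
    if counting_convention == "cycle_start":
        q = df[:n_cycles, None] * qal[:n_cycles]
        c = df[:n_cycles, None] * cst[:n_cycles]
    elif counting_convention == "cycle_end":
        q = df[1:, None] * qal[1:]
        c = df[1:, None] * cst[1:]
    else:
        q = df[:n_cycles, None] * 0.5 * (qal[:n_cycles] + qal[1:])
        c = df[:n_cycles, None] * 0.5 * (cst[:n_cycles] + cst[1:])
    per_q = q.sum(axis=0)
    per_c = c.sum(axis=0)

    comp = np.isin(states[1:], COMPLICATION_ENTRY)
    per_c = per_c + (df[1:, None] * comp).sum(axis=0) * cycle_costs.complication_once

    return {
        "mean_cost": float(per_c.mean()),
        "mean_qaly": float(per_q.mean()),
        "se_cost": float(per_c.std(ddof=1) / np.sqrt(n_patients)) if n_patients > 1 else 0.0,
        "se_qaly": float(per_q.std(ddof=1) / np.sqrt(n_patients)) if n_patients > 1 else 0.0,
        "n_patients": n_patients,
        "seed": seed,
    }
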