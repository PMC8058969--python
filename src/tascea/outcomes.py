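"""Comparative cost-effectiveness outcomes.

Turns two arms' discounted totals into incremental cost, incremental QALYs,
the incremental cost-effectiveness ratio (ICER) with dominance
classification, and net monetary benefit.  Also provides the calibration
sweep that searches counting/discount conventions and per-cycle item
multiplicities against a set of published base-case totals; the published
model left those choices undocumented, so they must be recovered by fit.
"""

from __future__ import annotations

import copy
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import ArmTotals, build_transition_matrix, run_arm, run_cohort_trace
from .errors import ConfigurationError
from .params import COUNTING_CONVENTIONS, DISCOUNT_CONVENTIONS, Scenario

__all__ = [
    "CEAResult",
    "icer",
    "nmb",
    "base_case_report",
    "Table5Targets",
    "CalibrationResult",
    "calibrate_conventions",
]

DOMINANT = "dominant"
DOMINATED = "dominated"
COMPARABLE = "comparable"


@dataclass
class CEAResult:
    """Base-case comparison of a comparator strategy against a reference."""

    reference_name: str
    comparator_name: str
    reference_cost: float
    reference_qaly: float
    comparator_cost: float
    comparator_qaly: float
    wtp_threshold: float
    incremental_cost: float = field(init=False)
    incremental_qaly: float = field(init=False)

    def __post_init__(self):
        self.incremental_cost = self.comparator_cost - self.reference_cost
        self.incremental_qaly = self.comparator_qaly - self.reference_qaly

    @property
    def dominance(self) -> str:
        if self.incremental_cost < 0 and self.incremental_qaly > 0:
            return DOMINANT
        if self.incremental_cost > 0 and self.incremental_qaly < 0:
            return DOMINATED
        return COMPARABLE

    @property
    def icer(self) -> float:
        """Incremental cost per QALY gained; NaN when ΔQALY = 0 or the
        comparison is resolved by dominance."""
        if self.incremental_qaly == 0 or self.dominance != COMPARABLE:
            return float("nan")
        return self.incremental_cost / self.incremental_qaly

    @property
    def cost_effective(self) -> bool:
        if self.dominance == DOMINANT:
            return True
        if self.dominance == DOMINATED:
            return False
        if self.incremental_qaly == 0:
            return self.incremental_cost <= 0
        if self.incremental_qaly > 0:
            return self.icer <= self.wtp_threshold
        # fewer QALYs at lower cost: cost-effective if savings per QALY
        # forgone exceed the threshold
        return (self.incremental_cost / self.incremental_qaly) >= self.wtp_threshold

    def to_frame(self) -> pd.DataFrame:
        """Base-case table: one row per strategy, comparator vs reference."""
        rows = [
            {
                "strategy": self.reference_name,
                "cost": self.reference_cost,
                "qaly": self.reference_qaly,
                "incremental_cost": np.nan,
                "incremental_qaly": np.nan,
                "icer": np.nan,
                "dominance": "",
                "reference": "-",
            },
            {
                "strategy": self.comparator_name,
                "cost": self.comparator_cost,
                "qaly": self.comparator_qaly,
                "incremental_cost": self.incremental_cost,
                "incremental_qaly": self.incremental_qaly,
                "icer": self.icer,
                "dominance": self.dominance,
                "reference": self.reference_name,
            },
        ]
        return pd.DataFrame(rows)


def icer(ref_totals: ArmTotals, new_totals: ArmTotals, wtp: float,
         reference_name: str = "reference", comparator_name: str = "comparator") -> CEAResult:
    """Compare two arms' discounted totals."""
    return CEAResult(
        reference_name=reference_name,
        comparator_name=comparator_name,
        reference_cost=ref_totals.discounted_cost,
        reference_qaly=ref_totals.discounted_qaly,
        comparator_cost=new_totals.discounted_cost,
        comparator_qaly=new_totals.discounted_qaly,
        wtp_threshold=wtp,
    )


def nmb(cost: float, qaly: float, wtp: float) -> float:
    """Net monetary benefit: wtp x QALYs - cost."""
    if wtp < 0:
        raise ConfigurationError("willingness-to-pay must be >= 0")
    return wtp * qaly - cost


def base_case_report(scenario: Scenario) -> CEAResult:
    """Run both arms of a scenario and compare them."""
    _, ref = run_arm(scenario, scenario.reference.name)
    _, new = run_arm(scenario, scenario.comparator.name)
    return icer(
        ref, new, scenario.wtp_threshold,
        reference_name=scenario.reference.name,
        comparator_name=scenario.comparator.name,
    )


# ---------------------------------------------------------------------------
# Convention / multiplicity calibration against published totals
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Table5Targets:
    """Published base-case totals to calibrate against (reference arm first)."""

    reference_cost: float
    reference_qaly: float
    comparator_cost: float
    comparator_qaly: float
    incremental_cost: float
    incremental_qaly: float
    icer: float


@dataclass
class CalibrationResult:
    counting_convention: str
    discount_convention: str
    multiplicities: dict[str, dict[str, int]]
    qaly_deviations: dict[str, float]
    cost_deviations: dict[str, float]
    report: pd.DataFrame

    @property
    def max_qaly_deviation(self) -> float:
        return max(abs(v) for v in self.qaly_deviations.values())

    @property
    def max_cost_deviation(self) -> float:
        return max(abs(v) for v in self.cost_deviations.values())

    def apply(self, scenario: Scenario) -> Scenario:
        """Return a copy of the scenario with the calibrated configuration."""
        out = copy.deepcopy(scenario)
        out.counting_convention = self.counting_convention
        out.discount_convention = self.discount_convention
        for arm_name, mults in self.multiplicities.items():
            out.arms[arm_name].costs.multiplicities = dict(mults)
        return out


def _arm_cost_weights(scenario: Scenario, arm_name: str, counting: str, discounting: str):
    """Discounted weights so that arm cost = W x per-cycle cost + K x comp cost.

    Cost is linear in the per-cycle treatment cost and the once-only
    complication cost, so the multiplicity search never needs to rerun the
    trace.
    """
    arm = scenario.arms[arm_name]
    matrix = build_transition_matrix(arm.transitions)
    trace = run_cohort_trace(matrix, scenario.n_cycles)
    n = scenario.n_cycles
    from .engine import discount_factor

    df = np.array(
        [discount_factor(t, scenario.annual_discount, scenario.cycle_length_weeks, discounting)
         for t in range(n + 1)]
    )
    stable = trace.stable_phase
    if counting == "cycle_start":
        W = float((stable[:n] * df[:n]).sum())
    elif counting == "cycle_end":
        W = float((stable[1 : n + 1] * df[1 : n + 1]).sum())
    else:
        W = float((0.5 * (stable[:n] + stable[1 : n + 1]) * df[:n]).sum())
    K = float((trace.complication_entries[1 : n + 1] * df[1 : n + 1]).sum())
    return W, K


DEFAULT_COUNT_GRID = (0, 1, 2, 4)


def _default_multiplicity_grid(scenario: Scenario) -> dict[str, dict[str, tuple[int, ...]]]:
    """Bounded integer grid per arm: drug items in plausible dose counts,
    fee items in 0..4 per cycle; the complication item is once-only and has
    no multiplicity."""
    grid: dict[str, dict[str, tuple[int, ...]]] = {}
    for arm_name, arm in scenario.arms.items():
        g: dict[str, tuple[int, ...]] = {}
        for item in arm.costs.items:
            if item.label == arm.costs.complication_label:
                continue
            low = item.label.lower()
            if "tas-102" in low:
                g[item.label] = (1, 2)
            elif "bevacizumab" in low:
                g[item.label] = (1, 2, 4)
            else:
                g[item.label] = DEFAULT_COUNT_GRID
        grid[arm_name] = g
    return grid


def _enumerate_costs(arm, grid: dict[str, tuple[int, ...]]):
    labels = sorted(grid)
    bases = np.array([arm.costs.item(lb).base for lb in labels])
    combos = np.array(list(itertools.product(*(grid[lb] for lb in labels))), dtype=float)
    costs = combos @ bases
    return labels, combos.astype(int), costs


def calibrate_conventions(
    scenario: Scenario,
    targets: Table5Targets,
    *,
    multiplicity_grid: dict[str, dict[str, tuple[int, ...]]] | None = None,
    conventions: tuple[tuple[str, str], ...] | None = None,
) -> CalibrationResult:
    """Recover the undocumented run configuration by fit to published totals.

    Stage 1 selects the (counting, discounting) convention pair minimizing
    the maximum relative deviation from the published per-arm QALYs and the
    incremental QALY (QALYs do not depend on cost multiplicities).  Stage 2,
    under the selected conventions, selects integer per-cycle multiplicities
    for every non-complication cost item by lexicographic minimax over the
    relative deviations of the four cost-side quantities (per-arm costs,
    incremental cost, ICER).  Fully deterministic.
    """
    if conventions is None:
        conventions = tuple(itertools.product(COUNTING_CONVENTIONS, DISCOUNT_CONVENTIONS))
    if not conventions:
        raise ConfigurationError("empty convention grid")

    ref_name = scenario.reference.name
    cmp_name = scenario.comparator.name

    # ---- stage 1: conventions by QALY fit -------------------------------
    best_conv = None
    qaly_rows = []
    for counting, discounting in conventions:
        s = copy.deepcopy(scenario)
        s.counting_convention = counting
        s.discount_convention = discounting
        _, ref_tot = run_arm(s, ref_name)
        _, cmp_tot = run_arm(s, cmp_name)
        dq = cmp_tot.discounted_qaly - ref_tot.discounted_qaly
        devs = {
            "reference_qaly": ref_tot.discounted_qaly / targets.reference_qaly - 1.0,
            "comparator_qaly": cmp_tot.discounted_qaly / targets.comparator_qaly - 1.0,
            "incremental_qaly": dq / targets.incremental_qaly - 1.0,
        }
        key = (max(abs(v) for v in devs.values()), counting, discounting)
        qaly_rows.append(
            dict(counting=counting, discounting=discounting,
                 reference_qaly=ref_tot.discounted_qaly,
                 comparator_qaly=cmp_tot.discounted_qaly,
                 incremental_qaly=dq, max_abs_deviation=key[0])
        )
        if best_conv is None or key < best_conv[0]:
            best_conv = (key, counting, discounting, devs, dq)
    _, counting, discounting, qaly_devs, dq = best_conv

    # ---- stage 2: multiplicities by cost fit -----------------------------
    grid = multiplicity_grid or _default_multiplicity_grid(scenario)
    if not grid.get(ref_name) or not grid.get(cmp_name):
        raise ConfigurationError("empty multiplicity grid")

    Wr, Kr = _arm_cost_weights(scenario, ref_name, counting, discounting)
    Wc, Kc = _arm_cost_weights(scenario, cmp_name, counting, discounting)
    comp_r = scenario.arms[ref_name].costs.item(
        scenario.arms[ref_name].costs.complication_label).base
    comp_c = scenario.arms[cmp_name].costs.item(
        scenario.arms[cmp_name].costs.complication_label).base

    labels_r, combos_r, cyc_r = _enumerate_costs(scenario.arms[ref_name], grid[ref_name])
    labels_c, combos_c, cyc_c = _enumerate_costs(scenario.arms[cmp_name], grid[cmp_name])
    cost_r = Wr * cyc_r + Kr * comp_r  # (nr,)
    cost_c = Wc * cyc_c + Kc * comp_c  # (nc,)

    dev_r = np.abs(cost_r / targets.reference_cost - 1.0)
    dev_c = np.abs(cost_c / targets.comparator_cost - 1.0)

    best = None
    chunk = 64
    for i0 in range(0, len(cost_r), chunk):
        cr = cost_r[i0 : i0 + chunk]
        dr = dev_r[i0 : i0 + chunk]
        dcost = cost_c[None, :] - cr[:, None]
        dev_dc = np.abs(dcost / targets.incremental_cost - 1.0)
        dev_icer = np.abs((dcost / dq) / targets.icer - 1.0)
        devs = np.stack(
            [np.broadcast_to(dr[:, None], dev_dc.shape),
             np.broadcast_to(dev_c[None, :], dev_dc.shape),
             dev_dc, dev_icer],
            axis=-1,
        )
        ordered = np.sort(devs, axis=-1)[..., ::-1]  # sorted descending
        flat = ordered.reshape(-1, 4)
        order = np.lexsort((flat[:, 3], flat[:, 2], flat[:, 1], flat[:, 0]))
        j = int(order[0])
        cand = (tuple(flat[j]), i0 + j // dev_dc.shape[1], j % dev_dc.shape[1])
        if best is None or cand < best:
            best = cand
    _, ir, ic = best

    mults = {
        ref_name: dict(zip(labels_r, (int(v) for v in combos_r[ir]))),
        cmp_name: dict(zip(labels_c, (int(v) for v in combos_c[ic]))),
    }
    cost_devs = {
        "reference_cost": float(cost_r[ir] / targets.reference_cost - 1.0),
        "comparator_cost": float(cost_c[ic] / targets.comparator_cost - 1.0),
        "incremental_cost": float((cost_c[ic] - cost_r[ir]) / targets.incremental_cost - 1.0),
        "icer": float(((cost_c[ic] - cost_r[ir]) / dq) / targets.icer - 1.0),
    }

    report = pd.DataFrame(qaly_rows)
    report["selected"] = [
        (r["counting"] == counting and r["discounting"] == discounting) for r in qaly_rows
    ]
    return CalibrationResult(
        counting_convention=counting,
        discount_convention=discounting,
        multiplicities=mults,
        qaly_deviations={k: float(v) for k, v in qaly_devs.items()},
        cost_deviations=cost_devs,
        report=report,
    )
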