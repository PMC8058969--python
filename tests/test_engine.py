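"""Markov engine: transition structure, cohort propagation, value accrual
and the microsimulation cross-check."""

import numpy as np
import pytest

from tascea import (
    CycleCost,
    InputDomainError,
    ProbParam,
    UtilitySet,
    accrue_values,
    build_transition_matrix,
    cycle_qaly,
    discount_factor,
    microsim_oracle,
    run_arm,
    run_cohort_trace,
)
from tascea.engine import (
    DEATH,
    PROG,
    SD,
    STATES,
    build_transition_matrix_from_probs,
)
from tascea.errors import ConfigurationError
from tascea.params import ArmTransitionParams, assemble_cycle_cost


def _arm(p, d, c):
    return ArmTransitionParams(
        ProbParam(p, p, p), ProbParam(d, d, d), ProbParam(c, c, c)
    )


def _utils(u_stable, u_prog):
    s = ProbParam(u_stable, u_stable, u_stable)
    p = ProbParam(u_prog, u_prog, u_prog)
    return UtilitySet(stable=s, complication=s, progression=p, progression_complication=p)


class TestTransitionMatrix:
    def test_zero_probabilities_keep_cohort_in_stable_disease(self):
        # the tunnel states still exit (they are one-cycle by construction),
        # but a cohort starting in SD with all probabilities zero never moves
        M = build_transition_matrix(_arm(0.0, 0.0, 0.0))
        assert M[SD, SD] == 1.0
        trace = run_cohort_trace(M, 10)
        assert np.allclose(trace.occupancy[:, SD], 1.0)

    def test_rows_sum_to_one_and_death_absorbing(self, paper):
        for arm in paper.arms.values():
            M = build_transition_matrix(arm.transitions)
            assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)
            assert M[DEATH, DEATH] == 1.0
            # death reachable only through the progressed phase
            assert M[SD, DEATH] == 0.0

    def test_monotherapy_stable_self_loop(self, paper):
        M = build_transition_matrix(paper.arms["monotherapy"].transitions)
        assert M[SD, SD] == pytest.approx(1 - 0.55459395 - 0.1126958, abs=1e-12)

    def test_infeasible_row_raises(self):
        with pytest.raises(InputDomainError):
            build_transition_matrix_from_probs(0.95, 0.2, 0.11)

    def test_renormalize_mode_rescales_exits(self):
        M = build_transition_matrix_from_probs(0.95, 0.2, 0.11, infeasible="renormalize")
        assert M.renormalized_rows == 1
        assert M[SD, SD] == 0.0
        assert M[SD, PROG] == pytest.approx(0.95 / 1.06)

    def test_certain_death_after_progression(self):
        M = build_transition_matrix(_arm(0.5, 1.0, 0.0))
        trace = run_cohort_trace(M, 60)
        assert trace.death[-1] == pytest.approx(1.0, abs=1e-6)


class TestCohortTrace:
    def test_identity_matrix_is_static(self):
        trace = run_cohort_trace(np.eye(7), 10)
        assert np.allclose(trace.occupancy, trace.occupancy[0])

    def test_two_state_geometric_decay(self):
        # progression only: SD occupancy decays as (1-p)^t
        M = build_transition_matrix(_arm(0.5, 0.0, 0.0))
        trace = run_cohort_trace(M, 20)
        assert np.allclose(trace.occupancy[:, SD], 0.5 ** np.arange(21))

    def test_stable_phase_untouched_by_complication_shuffling(self, paper):
        """Complication states shuffle patients within the stable phase; the
        phase total still decays geometrically with the progression rate."""
        arm = paper.arms["monotherapy"].transitions
        M = build_transition_matrix(arm)
        trace = run_cohort_trace(M, 30)
        expected = (1 - arm.p_progression.base) ** np.arange(31)
        assert np.allclose(trace.stable_phase, expected, atol=1e-12)

    def test_conservation_and_death_monotone(self, paper):
        for arm in paper.arms.values():
            trace = run_cohort_trace(build_transition_matrix(arm.transitions), 30)
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
            assert (np.diff(trace.death) >= -1e-15).all()
            assert np.all(trace.occupancy >= -1e-15)

    def test_starts_in_stable_disease(self, paper):
        trace = run_cohort_trace(
            build_transition_matrix(paper.arms["combination"].transitions), 5)
        assert trace.occupancy[0, SD] == 1.0

    def test_frame_reports_collapsed_states(self, paper):
        trace = run_cohort_trace(
            build_transition_matrix(paper.arms["combination"].transitions), 5)
        df = trace.to_frame()
        assert list(df.columns[:7]) == list(STATES)
        assert np.allclose(
            df["reported_SD"], df["SD"] + df["SD_postC"])


class TestCycleValues:
    @pytest.mark.parametrize(
        "utility,expected",
        [(0.72, 0.11076923), (0.73, 0.11230769), (0.59, 0.09076923), (0.0, 0.0)],
    )
    def test_cycle_qaly_printed_values(self, utility, expected):
        # published per-8-week-cycle QALY table pins the x 8/52 conversion
        assert cycle_qaly(utility, 8.0) == pytest.approx(expected, abs=5e-9)

    def test_discount_factor(self):
        assert discount_factor(0, 0.035, 8.0, "annualized") == 1.0
        assert discount_factor(17, 0.0, 8.0, "per_cycle") == 1.0
        # 13 cycles x 8/52 weeks = exactly 2 years
        assert discount_factor(13, 0.035, 8.0, "annualized") == pytest.approx(
            1.035 ** -2, abs=1e-12)
        assert discount_factor(3, 0.035, 8.0, "per_cycle") == pytest.approx(1.035 ** -3)
        with pytest.raises(ConfigurationError):
            discount_factor(1, 0.035, 8.0, "weekly")


class TestAccrual:
    def test_zero_values_zero_totals(self, paper):
        trace = run_cohort_trace(
            build_transition_matrix(paper.arms["monotherapy"].transitions), 30)
        totals = accrue_values(trace, CycleCost(0.0, 0.0), _utils(0.0, 0.0))
        assert totals.discounted_cost == 0.0 and totals.discounted_qaly == 0.0

    def test_static_cohort_accrues_full_horizon(self):
        trace = run_cohort_trace(np.eye(7), 30)
        totals = accrue_values(
            trace, CycleCost(0.0, 0.0), _utils(0.8, 0.0),
            annual_discount=0.0, counting_convention="cycle_start")
        assert totals.discounted_qaly == pytest.approx(30 * 0.8 * 8 / 52, rel=1e-12)

    @pytest.mark.parametrize("counting", ["cycle_start", "cycle_end", "half_cycle"])
    def test_discounted_not_above_undiscounted(self, paper, counting):
        trace, _ = run_arm(paper, "combination")
        arm = paper.arms["combination"]
        totals = accrue_values(
            trace, assemble_cycle_cost(arm.costs), arm.utilities,
            counting_convention=counting)
        assert totals.discounted_cost <= totals.undiscounted_cost
        assert totals.discounted_qaly <= totals.undiscounted_qaly

    def test_discount_monotonicity(self, paper):
        arm = paper.arms["monotherapy"]
        trace, _ = run_arm(paper, "monotherapy")
        costs, qalys = [], []
        for rate in (0.0, 0.02, 0.035, 0.08):
            totals = accrue_values(
                trace, assemble_cycle_cost(arm.costs), arm.utilities,
                annual_discount=rate,
                counting_convention=paper.counting_convention)
            costs.append(totals.discounted_cost)
            qalys.append(totals.discounted_qaly)
        assert costs == sorted(costs, reverse=True)
        assert qalys == sorted(qalys, reverse=True)

    @pytest.mark.parametrize("arm_name", ["monotherapy", "combination"])
    def test_complication_neutral_for_qalys_and_adds_once_only_cost(
        self, paper, arm_name, degenerate
    ):
        """Complication twins inherit their parent-state utility, so turning
        complications off leaves QALYs unchanged; the cost difference is
        exactly the discounted once-only complication-management cost."""
        _, with_c = run_arm(paper, arm_name)
        _, without_c = run_arm(degenerate["no_complication"], arm_name)
        assert with_c.discounted_qaly == pytest.approx(
            without_c.discounted_qaly, abs=1e-12)
        expected_comp = with_c.ledger["complication_cost"].sum()
        assert expected_comp > 0
        assert with_c.discounted_cost - without_c.discounted_cost == pytest.approx(
            expected_comp, rel=1e-12)

    def test_expected_time_in_stable_matches_closed_form(self):
        # no complications, no death, no discount: mean cycles in SD = 1/p
        p = 0.2
        M = build_transition_matrix(_arm(p, 0.0, 0.0))
        trace = run_cohort_trace(M, 200)
        totals = accrue_values(
            trace, CycleCost(1.0, 0.0), _utils(0.0, 0.0),
            annual_discount=0.0, counting_convention="cycle_start")
        assert totals.discounted_cost == pytest.approx(1.0 / p, abs=1e-8)


class TestMicrosimOracle:
    def test_identity_matrix_zero_variance(self):
        trace = run_cohort_trace(np.eye(7), 30)
        cohort = accrue_values(trace, CycleCost(100.0, 50.0), _utils(0.8, 0.4))
        sim = microsim_oracle(np.eye(7), CycleCost(100.0, 50.0), _utils(0.8, 0.4),
                              n_patients=500, seed=7)
        # every simulated patient follows the same path; the standard error
        # is zero up to float accumulation order
        assert sim["se_cost"] < 1e-9 and sim["se_qaly"] < 1e-12
        assert sim["mean_cost"] == pytest.approx(cohort.discounted_cost, rel=1e-12)
        assert sim["mean_qaly"] == pytest.approx(cohort.discounted_qaly, rel=1e-12)

    def test_deterministic_given_seed(self, paper):
        arm = paper.arms["combination"]
        M = build_transition_matrix(arm.transitions)
        kwargs = dict(n_patients=2000, seed=42)
        a = microsim_oracle(M, assemble_cycle_cost(arm.costs), arm.utilities, **kwargs)
        b = microsim_oracle(M, assemble_cycle_cost(arm.costs), arm.utilities, **kwargs)
        assert a == b

    @pytest.mark.parametrize("arm_name", ["monotherapy", "combination"])
    def test_agrees_with_cohort_within_three_se(self, paper, arm_name):
        arm = paper.arms[arm_name]
        M = build_transition_matrix(arm.transitions)
        _, cohort = run_arm(paper, arm_name)
        sim = microsim_oracle(
            M, assemble_cycle_cost(arm.costs), arm.utilities,
            n_patients=100_000, seed=11,
            counting_convention=paper.counting_convention,
            discount_convention=paper.discount_convention,
        )
        assert abs(sim["mean_qaly"] - cohort.discounted_qaly) < 3 * sim["se_qaly"]
        assert abs(sim["mean_cost"] - cohort.discounted_cost) < 3 * sim["se_cost"]
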