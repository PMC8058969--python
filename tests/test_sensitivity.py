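"""Deterministic (tornado) and probabilistic sensitivity analysis, CEAC and
cost-effectiveness plane exports."""

import numpy as np
import pytest

from tascea import (
    ParameterRef,
    ceac,
    ce_plane_export,
    dsa_parameters,
    dsa_tornado,
    psa_parameters,
    psa_run,
    tornado_frame,
)
from tascea.errors import InputDomainError
from tascea.sensitivity import DEFAULT_WTP_GRID


@pytest.fixture(scope="module")
def tornado(paper):
    return dsa_tornado(paper)


@pytest.fixture(scope="module")
def psa(paper):
    return psa_run(paper, n_draws=400)


class TestParameterRef:
    def test_get_and_label(self, paper):
        ref = ParameterRef("monotherapy", "transition", "p_death")
        assert ref.label == "monotherapy.transition.p_death"
        assert ref.get(paper).base == pytest.approx(0.26230083)
        cost_ref = ParameterRef("combination", "cost", "Bevacizumab")
        assert cost_ref.get(paper).base == pytest.approx(767.945701)

    def test_set_base_transition(self, paper):
        import copy

        s = copy.deepcopy(paper)
        ParameterRef("monotherapy", "transition", "p_death").set_base(s, 0.4)
        assert s.arms["monotherapy"].transitions.p_death.base == 0.4
        assert paper.arms["monotherapy"].transitions.p_death.base != 0.4

    def test_set_base_utility_phase_moves_twin(self, paper):
        import copy

        s = copy.deepcopy(paper)
        ParameterRef("combination", "utility_phase", "stable_phase").set_base(s, 0.9)
        assert s.arms["combination"].utilities.stable.base == 0.9
        assert s.arms["combination"].utilities.complication.base == 0.9

    def test_set_base_cost(self, paper):
        import copy

        s = copy.deepcopy(paper)
        ParameterRef("combination", "cost", "TAS-102").set_base(s, 999.0)
        assert s.arms["combination"].costs.item("TAS-102").base == 999.0

    def test_parameter_lists(self, paper):
        dsa = dsa_parameters(paper)
        # 3 transitions + 2 phase utilities per arm, plus 6 and 8 cost items
        assert len(dsa) == 2 * 5 + 6 + 8
        assert len({r.label for r in dsa}) == len(dsa)
        psa_refs = psa_parameters(paper)
        # death utility has zero range and is excluded from resampling
        assert all(r.key != "death" for r in psa_refs)
        assert len({r.label for r in psa_refs}) == len(psa_refs)


class TestTornado:
    def test_one_entry_per_parameter(self, tornado, paper):
        assert len(tornado) == len(dsa_parameters(paper))

    def test_sorted_by_width(self, tornado):
        widths = [e.width for e in tornado if np.isfinite(e.width)]
        assert widths == sorted(widths, reverse=True)

    def test_survival_parameters_dominate(self, tornado):
        """The most influential inputs are the survival transitions and the
        comparator's stable-phase utility — the expected drivers of an ICER
        whose denominator is survival-weighted utility."""
        top5 = {e.parameter for e in tornado[:5]}
        assert "monotherapy.transition.p_death" in top5
        assert "combination.transition.p_death" in top5
        assert "combination.utility_phase.stable_phase" in top5

    def test_zero_multiplicity_item_has_zero_width(self, tornado):
        entry = {e.parameter: e for e in tornado}["combination.cost.IV drip fee"]
        assert entry.width == 0.0
        # and therefore sorts at the bottom of the finite-width entries
        finite = [e for e in tornado if np.isfinite(e.width)]
        assert finite[-1].width == 0.0

    def test_directionality(self, tornado):
        """Raising the comparator's drug price raises the ICER."""
        entry = {e.parameter: e for e in tornado}["combination.cost.Bevacizumab"]
        assert entry.icer_at_max > entry.icer_at_min

    def test_infeasible_extreme_flagged(self, paper):
        import copy

        from tascea.params import ProbParam

        s = copy.deepcopy(paper)
        # push progression so that its +25% extreme breaks the stable row
        arm = s.arms["monotherapy"]
        from dataclasses import replace

        arm.transitions = replace(
            arm.transitions, p_progression=ProbParam(0.85, 0.6375, 1.0))
        refs = [ParameterRef("monotherapy", "transition", "p_progression")]
        entries = dsa_tornado(s, varied_parameters=refs)
        assert entries[0].infeasible
        assert np.isnan(entries[0].width)

    def test_frame_roundtrip(self, tornado):
        df = tornado_frame(tornado)
        assert list(df.columns) == [
            "parameter", "icer_at_min", "icer_at_max", "width", "infeasible"]
        assert len(df) == len(tornado)


class TestPSA:
    def test_shape_and_seed_default(self, psa, paper):
        assert psa.n_draws == 400
        assert psa.seed == paper.psa_seed
        assert len(psa.draws) == 400
        assert psa.d_cost.shape == (400,)

    def test_deterministic_given_seed(self, paper):
        a = psa_run(paper, n_draws=50, seed=123)
        b = psa_run(paper, n_draws=50, seed=123)
        assert a.draws.equals(b.draws)
        c = psa_run(paper, n_draws=50, seed=124)
        assert not a.draws["d_cost"].equals(c.draws["d_cost"])

    def test_sampled_columns_within_support(self, psa, paper):
        for ref in psa_parameters(paper):
            col = psa.draws[ref.label].to_numpy()
            param = ref.get(paper)
            lo = 0.0
            hi = 1.0 if ref.category in ("transition", "utility") else np.inf
            assert (col >= lo).all() and (col <= hi).all()
            # moment-matched mean close to base
            assert col.mean() == pytest.approx(param.base, rel=0.12)

    def test_no_renormalization_needed_for_bundled_ranges(self, psa):
        assert psa.n_renormalized == 0

    def test_draw_means_near_base_case(self, psa, paper):
        from tascea import base_case_report

        base = base_case_report(paper)
        assert psa.d_qaly.mean() == pytest.approx(base.incremental_qaly, rel=0.15)
        assert psa.d_cost.mean() == pytest.approx(base.incremental_cost, rel=0.15)

    def test_zero_draws_rejected_by_ceac(self, paper):
        empty = psa_run(paper, n_draws=0)
        with pytest.raises(InputDomainError):
            ceac(empty)


class TestCEAC:
    def test_probabilities_valid_and_complementary(self, psa):
        curve = ceac(psa)
        assert ((curve.p_comparator >= 0) & (curve.p_comparator <= 1)).all()
        assert np.allclose(curve.p_comparator + curve.p_reference, 1.0)

    def test_monotone_when_comparator_always_gains_qalys(self, psa):
        """With ΔQALY > 0 in every draw the comparator's acceptability is
        non-decreasing in willingness-to-pay."""
        keep = psa.d_qaly > 0
        if keep.mean() == 1.0:
            curve = ceac(psa)
            assert (np.diff(curve.p_comparator) >= 0).all()
        else:
            import copy

            sub = copy.copy(psa)
            sub.draws = psa.draws[keep].reset_index(drop=True)
            curve = ceac(sub)
            assert (np.diff(curve.p_comparator) >= 0).all()

    def test_at_zero_wtp_cheaper_strategy_wins(self, psa):
        curve = ceac(psa)
        expected = float((psa.d_cost < 0).mean())
        assert curve.at(0.0) == pytest.approx(expected)

    def test_grid_and_frame(self, psa):
        curve = ceac(psa, wtp_grid=DEFAULT_WTP_GRID)
        df = curve.to_frame()
        assert len(df) == len(DEFAULT_WTP_GRID)
        assert f"p_{psa.comparator_name}" in df.columns
        with pytest.raises(InputDomainError):
            ceac(psa, wtp_grid=())


class TestCEPlane:
    def test_quadrant_counts_partition_draws(self, psa):
        table, quadrants = ce_plane_export(psa)
        assert len(table) == psa.n_draws
        assert sum(quadrants.values()) == psa.n_draws

    def test_northeast_matches_sign_pattern(self, psa):
        _, quadrants = ce_plane_export(psa)
        expected = int(((psa.d_qaly > 0) & (psa.d_cost > 0)).sum())
        assert quadrants["northeast"] == expected
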