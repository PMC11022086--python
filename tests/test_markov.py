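"""Transition-matrix construction, cohort propagation, and accounting."""

import numpy as np
import pytest

from cvdprev.markov import (
    Scenario,
    State,
    build_transition_matrix,
    discount_weights,
    evaluate_strategy,
    run_cohort,
    state_cost_vector,
)
from cvdprev.parameters import ParameterError

ALL = list(Scenario)


def zero_flow(ps):
    """Switch off every transition: no mortality, no events, no risk entry."""
    for sex in ("M", "F"):
        for ab in ps.risk_incidence[sex]:
            for rb in ps.risk_incidence[sex][ab]:
                ps.risk_incidence[sex][ab][rb] = 0.0
        for ab in ps.background_mortality[sex]:
            ps.background_mortality[sex][ab] = 0.0
    ps.acvd_tp = dict.fromkeys(ps.acvd_tp, 0.0)
    for ab in ps.recurrent_acvd_tp:
        ps.recurrent_acvd_tp[ab] = 0.0
    return ps


class TestTransitionMatrix:
    def test_general_population_row_for_men_at_fifty(self, ps):
        M = build_transition_matrix(ps, Scenario.BASE, "M", 50)
        row = M[State.GEN]
        assert row[State.R10] == 0.0025
        assert row[State.R20] == 0.0008
        assert row[State.R30] == 0.0006
        assert row[State.R40] == 0.0007
        assert row[State.NONCVD_DEATH] == 0.0113
        assert row[State.GEN] == pytest.approx(1 - 0.0025 - 0.0008 - 0.0006 - 0.0007 - 0.0113)

    def test_primary_prevention_scales_event_probability(self, ps):
        M = build_transition_matrix(ps, Scenario.SC_PP_SP, "F", 50)
        assert M[State.R20, State.ACVD] == pytest.approx(0.0284 * 0.47)
        M = build_transition_matrix(ps, Scenario.BASE, "F", 50)
        assert M[State.R20, State.ACVD] == pytest.approx(0.0284)

    def test_secondary_prevention_applies_only_to_recurrent_events(self, ps):
        sp = build_transition_matrix(ps, Scenario.SP, "M", 50)
        base = build_transition_matrix(ps, Scenario.BASE, "M", 50)
        assert sp[State.CHRONIC, State.ACVD] == pytest.approx(0.0661 * 0.29)
        np.testing.assert_allclose(sp[:5], base[:5])  # risk rows untouched

    @pytest.mark.parametrize("scenario", ALL)
    @pytest.mark.parametrize("sex", ["M", "F"])
    def test_rows_sum_to_one_everywhere(self, ps, scenario, sex):
        for age in range(45, 100, 7):
            M = build_transition_matrix(ps, scenario, sex, age)
            np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)
            assert M.min() >= 0.0

    def test_structural_zeros_and_absorbing_rows(self, ps):
        M = build_transition_matrix(ps, Scenario.SC_PP_SP, "M", 60)
        assert M[State.GEN, State.ACVD] == 0.0       # events only from risk states
        assert M[State.R20, State.R30] == 0.0        # no movement between profiles
        assert M[State.CHRONIC, State.GEN] == 0.0    # no recovery
        assert M[State.ACVD, State.ACVD] == 0.0      # one-cycle tunnel
        for d in (State.CVD_DEATH, State.NONCVD_DEATH):
            expected = np.zeros(9)
            expected[d] = 1.0
            np.testing.assert_array_equal(M[d], expected)

    def test_acute_row_competing_risks(self, ps):
        M = build_transition_matrix(ps, Scenario.BASE, "M", 55)
        c = ps.case_fatality("M", 55)
        m = ps.mortality("M", 55)
        assert M[State.ACVD, State.CVD_DEATH] == pytest.approx(c)
        assert M[State.ACVD, State.NONCVD_DEATH] == pytest.approx((1 - c) * m)
        assert M[State.ACVD, State.CHRONIC] == pytest.approx((1 - c) * (1 - m))

    def test_infeasible_parameters_raise(self, ps_copy):
        ps_copy.risk_incidence["M"]["45-54"]["R10"] = 0.999
        with pytest.raises(ParameterError):
            build_transition_matrix(ps_copy, Scenario.BASE, "M", 50)


class TestRunCohort:
    def test_no_flow_cohort_stays_put(self, ps_copy):
        trace = run_cohort(zero_flow(ps_copy), Scenario.BASE, "M", 45, 100)
        np.testing.assert_array_equal(trace.occupancy[:, 0], 1.0)
        assert trace.new_acvd_events.sum() == 0.0

    @pytest.mark.parametrize("scenario", ALL)
    def test_occupancy_conserved_each_cycle(self, ps, scenario):
        trace = run_cohort(ps, scenario, "F", 45)
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
        assert trace.occupancy.min() >= 0.0

    def test_death_states_absorb_monotonically(self, ps):
        trace = run_cohort(ps, Scenario.BASE, "M", 45)
        for col in (State.CVD_DEATH, State.NONCVD_DEATH):
            assert np.all(np.diff(trace.occupancy[:, col]) >= -1e-15)

    def test_nearly_everyone_dead_by_one_hundred(self, ps):
        # independent bound: background mortality alone leaves <5% alive
        survival = 1.0
        for age in range(45, 100):
            survival *= 1.0 - ps.mortality("M", age)
        assert survival < 0.05
        trace = run_cohort(ps, Scenario.BASE, "M", 45)
        dead = trace.occupancy[-1, State.CVD_DEATH] + trace.occupancy[-1, State.NONCVD_DEATH]
        assert dead > 0.95
        assert dead >= 1.0 - survival - 1e-9

    def test_event_flow_matches_acute_inflow(self, ps):
        trace = run_cohort(ps, Scenario.BASE, "F", 45)
        np.testing.assert_allclose(trace.new_acvd_events, trace.occupancy[1:, State.ACVD])
        np.testing.assert_allclose(trace.cvd_deaths,
                                   np.diff(trace.occupancy[:, State.CVD_DEATH]))

    def test_degenerate_horizon_rejected(self, ps):
        with pytest.raises(ParameterError):
            run_cohort(ps, Scenario.BASE, "M", 45, 45)

    def test_trace_frame_export(self, ps):
        df = run_cohort(ps, Scenario.BASE, "M", 45, 48).to_frame()
        assert set(df.state.unique()) == {s.name for s in State}
        assert df.age.max() == 48


class TestEvaluateStrategy:
    def test_annuity_closed_form_without_mortality(self, ps_copy):
        ps = zero_flow(ps_copy)
        for k in ps.utilities:
            if k not in ("cvd_death", "noncvd_death"):
                ps.utilities[k] = 1.0
        r = evaluate_strategy(ps, Scenario.BASE, "M", "provider", 45, 100)
        expected = sum(1.03 ** -t for t in range(55))
        assert r.discounted_qaly == pytest.approx(expected, abs=1e-9)
        assert round(expected, 2) == 27.58

    def test_null_intervention_equals_base_exactly(self, ps_copy):
        ps_copy.effects["rr_sp"] = 1.0
        ps_copy.costs["sp"] = 0.0
        for persp in ("provider", "societal"):
            base = evaluate_strategy(ps_copy, Scenario.BASE, "F", persp)
            sp = evaluate_strategy(ps_copy, Scenario.SP, "F", persp)
            assert sp.discounted_cost == base.discounted_cost
            assert sp.discounted_qaly == base.discounted_qaly

    def test_three_cycle_hand_unrolled_oracle(self, ps):
        # independent accumulation: explicit matrix products and per-cycle sums
        sc, sex, a0 = Scenario.SC_PP_SP, "M", 45
        occ = np.zeros(9)
        occ[State.GEN] = 1.0
        u = np.array([ps.utilities[k] for k in
                      ("general", "R10", "R20", "R30", "R40", "acvd", "chronic",
                       "cvd_death", "noncvd_death")])
        c_state = state_cost_vector(ps, sc)
        cost = qaly = 0.0
        for t in range(3):
            d = 1.03 ** -t
            qaly += d * occ @ u
            nxt = occ @ build_transition_matrix(ps, sc, sex, a0 + t)
            events = nxt[State.ACVD]
            cost += d * (occ @ c_state + events * ps.costs["acvd_event"])
            occ = nxt
        r = evaluate_strategy(ps, sc, sex, "provider", a0, a0 + 3)
        assert r.discounted_cost == pytest.approx(cost, abs=1e-12)
        assert r.discounted_qaly == pytest.approx(qaly, abs=1e-12)

    def test_effective_prevention_never_loses_qalys(self, ps):
        base = evaluate_strategy(ps, Scenario.BASE, "M", "provider")
        for sc in (Scenario.SC_PP_SP, Scenario.SC_PP, Scenario.SP):
            assert evaluate_strategy(ps, sc, "M", "provider").discounted_qaly \
                >= base.discounted_qaly

    def test_discounting_monotonicity(self, ps_copy):
        lo = evaluate_strategy(ps_copy, Scenario.BASE, "F", "societal")
        ps_copy.discount_rate = 0.06
        hi = evaluate_strategy(ps_copy, Scenario.BASE, "F", "societal")
        assert hi.discounted_qaly < lo.discounted_qaly
        assert hi.discounted_cost < lo.discounted_cost

    def test_first_cycle_discount_flag(self, ps_copy):
        base = discount_weights(ps_copy, 5)
        ps_copy.config.discount_first_cycle = True
        shifted = discount_weights(ps_copy, 5)
        np.testing.assert_allclose(shifted, base / 1.03)

    def test_later_start_ages_yield_fewer_qalys(self, ps):
        qalys = [evaluate_strategy(ps, Scenario.SC_PP_SP, "M", "provider", a).discounted_qaly
                 for a in (45, 55, 65)]
        assert qalys[0] > qalys[1] > qalys[2]

    def test_societal_adds_productivity_loss_per_event(self, ps):
        prov = evaluate_strategy(ps, Scenario.BASE, "M", "provider")
        soc = evaluate_strategy(ps, Scenario.BASE, "M", "societal")
        assert soc.discounted_qaly == prov.discounted_qaly
        assert soc.discounted_cost > prov.discounted_cost
        # the gap equals the discounted event stream times the loss per event
        trace = run_cohort(ps, Scenario.BASE, "M", 45)
        d = discount_weights(ps, trace.cycles)
        gap = ps.costs["productivity_loss"] * float(d @ trace.new_acvd_events)
        assert soc.discounted_cost - prov.discounted_cost == pytest.approx(gap)

    def test_unknown_perspective_rejected(self, ps):
        with pytest.raises(ParameterError):
            evaluate_strategy(ps, Scenario.BASE, "M", "payer")
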