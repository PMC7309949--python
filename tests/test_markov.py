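"""Markov engine: transitions, cohort runs, accruals, ICER logic.

The central check is a spreadsheet-style oracle: a short cohort run written
out as literal arithmetic on the calibration-table numbers, compared with
the engine to 1e-9.
"""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from taicea import (
    CostEffectivenessModel,
    HealthState,
    build_transition_matrix,
    compute_icer,
    default_parameters,
    discount_factor,
    load_parameters,
    run_cohort,
)
from taicea.sensitivity import set_param


def params_with(flat_mortality, q_annual, n_cycles=None, **overrides):
    params = load_parameters(overrides or None)
    if n_cycles is not None:
        cutoff = params.settings.start_age + 0.5 * n_cycles
        params = params.replace(
            settings=dataclasses.replace(params.settings, age_cutoff=cutoff)
        )
    return params.replace(mortality=flat_mortality(q_annual))


class TestDiscounting:
    def test_zero_time_is_identity(self):
        assert discount_factor(0.0, 0.02) == 1.0

    def test_one_year_at_two_percent(self):
        assert discount_factor(1.0, 0.02) == pytest.approx(1 / 1.02, rel=1e-12)

    def test_half_year_at_two_percent(self):
        assert discount_factor(0.5, 0.02) == pytest.approx(1.02 ** -0.5, rel=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(1.0, -0.01)


class TestTransitionMatrix:
    def test_nonresponder_withdrawal_row_at_zero_mortality(self, flat_mortality):
        params = params_with(flat_mortality, 0.0)
        m = build_transition_matrix(params, "TAI", 60.0)
        row = m[HealthState.TAI_NONRESPONDER]
        assert row == pytest.approx([0.0, 0.40, 0.60, 0.0, 0.0, 0.0], abs=1e-15)

    def test_sbc_stoma_construction_row_at_zero_mortality(self, flat_mortality):
        params = params_with(flat_mortality, 0.0)
        m = build_transition_matrix(params, "SBC", 60.0)
        assert m[HealthState.SBC, HealthState.STOMA] == pytest.approx(0.00033)
        assert m[HealthState.SBC, HealthState.SBC] == pytest.approx(0.99967)

    def test_certain_death_sends_all_mass_to_dead(self, flat_mortality):
        params = params_with(flat_mortality, 1.0)
        m = build_transition_matrix(params, "TAI", 60.0)
        for state in HealthState:
            assert m[state, HealthState.DEAD] == pytest.approx(1.0)

    def test_rows_are_stochastic_at_base_case(self, base_params):
        for age in (52.0, 75.5, 104.0):
            for arm in ("TAI", "SBC"):
                m = build_transition_matrix(base_params, arm, age)
                assert np.abs(m.sum(axis=1) - 1.0).max() <= 1e-12
                assert (m >= 0).all()


class TestCohortRun:
    def test_initial_conditions(self, base_params):
        tai = run_cohort(base_params, "TAI")
        sbc = run_cohort(base_params, "SBC")
        assert tai.occupancy[0] == pytest.approx([0.6, 0.4, 0, 0, 0, 0])
        assert sbc.occupancy[0] == pytest.approx([0, 0, 0, 1, 0, 0])

    def test_one_step_nonresponder_occupancy_by_hand(self, flat_mortality):
        # 40% start as non-responders; 60% of them withdraw: 0.4 * 0.4 remain
        params = params_with(flat_mortality, 0.0)
        trace = run_cohort(params, "TAI")
        assert trace.occupancy[1, HealthState.TAI_NONRESPONDER] == pytest.approx(
            0.16, abs=1e-15
        )

    def test_occupancy_conservation_and_dead_monotone(self, base_params):
        for arm in ("TAI", "SBC"):
            trace = run_cohort(base_params, arm)
            row_sums = trace.occupancy.sum(axis=1)
            assert np.abs(row_sums - 1.0).max() <= 1e-12
            dead = trace.occupancy[:, HealthState.DEAD]
            assert (np.diff(dead) >= -1e-15).all()
            assert trace.occupancy.min() >= 0.0

    def test_closed_form_qalys_without_mortality_or_discounting(self, flat_mortality):
        # pure SBC cohort, no deaths, no discounting, no stoma exits:
        # total QALYs are n_cycles times the per-cycle accrual
        n = 20
        params = params_with(
            flat_mortality,
            0.0,
            n_cycles=n,
            settings={"annual_discount_rate": 0.0},
            clinical={"stoma_rate_per_cycle": 0.0},
        )
        trace = run_cohort(params, "SBC")
        per_cycle = 0.479 * 0.5 - 0.512 * 0.060 - ((0.31 + 1.73) / 17.0) * 0.010
        assert trace.total_qaly == pytest.approx(n * per_cycle, rel=1e-12)

    @pytest.mark.parametrize("n_cycles", [3, 5])
    def test_short_run_matches_spreadsheet_oracle(self, flat_mortality, n_cycles):
        """Literal arithmetic re-computation of a short cohort run.

        Written independently from the engine: state costs and QALYs are
        spelled out from the calibration tables, the occupancy recursion and
        stoma-tenure bookkeeping are redone with plain floats, and the
        discounted totals must agree to 1e-9.
        """
        qa = 0.02
        params = params_with(flat_mortality, qa, n_cycles=n_cycles)

        e_uti = 0.086 * 163113 + 0.811 * 14126 + 0.103 * 10293
        hosp_tai = (0.14 * 1512630 + 0.77 * 630960) / 17.0
        hosp_sbc = (0.31 * 1512630 + 1.73 * 630960) / 17.0
        nurse_week = 2 * 5800 + 5200
        c_tai = 280945 * 0.5 + 18000 * 6 + 0.195 * e_uti + hosp_tai + 0.1941 * nurse_week * 26
        c_sbc = 4151 * 6 + 0.512 * e_uti + hosp_sbc + 0.318 * nurse_week * 26
        sbc_events = 0.512 * e_uti + hosp_sbc + 0.318 * nurse_week * 26
        c_stoma_y1 = 4131 * 6 + sbc_events
        c_stoma_after = 1621 * 6 + sbc_events
        one_off = (0.575 * 139200 + 0.425 * 79800) + (0.575 * 236311 + 0.425 * 242686)

        q_r = 0.533 * 0.5 - 0.195 * 0.060 - ((0.14 + 0.77) / 17.0) * 0.010
        q_nr = 0.470 * 0.5 - 0.195 * 0.060 - ((0.14 + 0.77) / 17.0) * 0.010
        q_sbc = 0.479 * 0.5 - 0.512 * 0.060 - ((0.31 + 1.73) / 17.0) * 0.010
        q_st = 0.564 * 0.5 - 0.512 * 0.060 - ((0.31 + 1.73) / 17.0) * 0.010

        q = 1.0 - (1.0 - qa) ** 0.5  # per-cycle death probability
        w, stoma = 0.60, 0.00033

        r, nr, rs, sbc, st = 0.6, 0.4, 0.0, 0.0, 0.0
        entry, m0, m1 = 0.0, 0.0, 0.0
        total_cost = total_qaly = 0.0
        for t in range(n_cycles):
            disc = 1.02 ** (-0.5 * (t + 1))
            y1 = m0 + m1
            est = st - y1
            cost_t = (
                (r + nr) * c_tai
                + (rs + sbc) * c_sbc
                + y1 * c_stoma_y1
                + est * c_stoma_after
                + entry * one_off
            )
            qaly_t = r * q_r + nr * q_nr + (rs + sbc) * q_sbc + st * q_st
            total_cost += cost_t * disc
            total_qaly += qaly_t * disc
            # transition to the next cycle
            new_entry = (rs + sbc) * stoma * (1 - q)
            r, nr, rs, sbc, st = (
                r * (1 - q),
                nr * (1 - w) * (1 - q),
                nr * w * (1 - q) + rs * (1 - stoma) * (1 - q),
                sbc * (1 - stoma) * (1 - q),
                st * (1 - q) + new_entry,
            )
            m1 = m0 * (1 - q)
            m0 = new_entry
            entry = new_entry

        trace = run_cohort(params, "TAI")
        assert trace.total_cost == pytest.approx(total_cost, rel=1e-9)
        assert trace.total_qaly == pytest.approx(total_qaly, rel=1e-9)

    def test_half_cycle_correction_discounts_midcycle(self, flat_mortality):
        plain = params_with(flat_mortality, 0.02, n_cycles=10)
        hcc = plain.replace(
            settings=dataclasses.replace(plain.settings, half_cycle_correction=True)
        )
        c0 = run_cohort(plain, "SBC").total_cost
        c1 = run_cohort(hcc, "SBC").total_cost
        # mid-cycle discounting shifts costs a quarter-year earlier
        assert c1 == pytest.approx(c0 * 1.02 ** 0.25, rel=1e-12)


class TestMonotonicity:
    COST_PATHS = [
        "cost.device_cost_per_year",
        "cost.sbc_cost_per_month",
        "cost.uti_cost_hospitalized",
        "cost.nursing_cost_per_visit",
        "cost.hosp_cost_decubitus",
        "cost.stoma_mgmt_month_after",
    ]
    UTILITY_PATHS = ["utility.u_responder", "utility.u_nonresponder", "utility.u_sbc",
                     "utility.u_stoma"]

    @pytest.mark.parametrize("path", COST_PATHS)
    def test_raising_any_cost_weakly_increases_arm_cost(self, base_params, path):
        from taicea.sensitivity import get_param

        bumped = set_param(base_params, path, get_param(base_params, path) * 1.5)
        for arm in ("TAI", "SBC"):
            assert (
                run_cohort(bumped, arm).total_cost
                >= run_cohort(base_params, arm).total_cost - 1e-9
            )

    @pytest.mark.parametrize("path", UTILITY_PATHS)
    def test_raising_any_state_utility_weakly_increases_qalys(self, base_params, path):
        from taicea.sensitivity import get_param

        bumped = set_param(
            base_params, path, min(1.0, get_param(base_params, path) + 0.1)
        )
        for arm in ("TAI", "SBC"):
            assert (
                run_cohort(bumped, arm).total_qaly
                >= run_cohort(base_params, arm).total_qaly - 1e-12
            )

    def test_tai_gains_qalys_at_base_case(self, base_params):
        res = CostEffectivenessModel(base_params).fit()
        assert res.qaly_tai > res.qaly_sbc


class TestICER:
    def test_cost_saving_with_gain_is_dominant(self):
        assert compute_icer(-522293.0, 0.80) == "dominant"

    def test_ratio_of_positive_increments(self):
        assert compute_icer(3198687.0, 0.80) == pytest.approx(3998358.75)

    def test_both_zero_is_indifferent(self):
        assert compute_icer(0.0, 0.0) == "indifferent"

    def test_costlier_and_less_effective_is_dominated(self):
        assert compute_icer(100.0, -0.1) == "dominated"

    def test_extra_cost_without_gain_is_undefined(self):
        assert compute_icer(100.0, 0.0) == "undefined"

    @given(
        dc=st.floats(1.0, 1e8),
        dq=st.floats(1e-6, 10.0),
    )
    def test_ratio_definition_in_the_northeast_quadrant(self, dc, dq):
        assert compute_icer(dc, dq) == pytest.approx(dc / dq)


def test_results_dict_and_summary(base_params):
    res = CostEffectivenessModel(base_params).fit()
    d = res.to_dict()
    assert d["delta_cost"] == round(res.cost_tai - res.cost_sbc)
    assert "ICER" in res.summary()
    assert d["icer"] == pytest.approx(res.delta_cost / res.delta_qaly)
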