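"""EQ-5D-5L mapping: level assignment, MNLogit fits, Monte Carlo utility."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from taicea import EQ5DMapping, assign_level, state_utilities_from_curve
from taicea.mapping import (
    DIMENSIONS,
    EQ5DMappingResults,
    UtilityCurve,
    ValueSet,
)
from taicea.survey import default_mapping_truth


def five_branch_level(u, p):
    """The case expression for level selection, written out branch by branch."""
    if u <= p[0]:
        return 1
    if u <= p[0] + p[1]:
        return 2
    if u <= p[0] + p[1] + p[2]:
        return 3
    if u <= 1.0 - p[4]:
        return 4
    return 5


class TestAssignLevel:
    def test_zero_draw_gives_level_one(self):
        assert assign_level(0.0, np.cumsum([0.2] * 5)) == 1
        assert assign_level(0.0, np.cumsum([0.0, 0.0, 1.0, 0.0, 0.0])) == 1

    def test_upper_tail_gives_level_five(self):
        assert assign_level(0.95, np.cumsum([0.2] * 5)) == 5

    def test_interior_inversion_by_hand(self):
        cum = np.cumsum([0.1, 0.3, 0.3, 0.2, 0.1])
        assert assign_level(0.05, cum) == 1
        assert assign_level(0.10, cum) == 1  # boundary included below
        assert assign_level(0.11, cum) == 2
        assert assign_level(0.71, cum) == 4

    def test_malformed_cumulative_vector_rejected(self):
        with pytest.raises(ValueError):
            assign_level(0.5, [0.5, 0.4, 0.6, 0.8, 1.0])  # decreasing
        with pytest.raises(ValueError):
            assign_level(0.5, [0.1, 0.2, 0.3, 0.4, 0.8])  # does not end at 1

    @given(
        u=st.floats(0.0, 1.0, exclude_max=True),
        raw=st.lists(st.floats(0.01, 1.0), min_size=5, max_size=5),
    )
    def test_equivalent_to_five_branch_conditional(self, u, raw):
        p = np.asarray(raw) / np.sum(raw)
        cum = np.cumsum(p)
        cum[-1] = 1.0
        assert assign_level(u, cum) == five_branch_level(u, p)

    def test_exhaustive_grid_against_conditional(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.dirichlet(np.ones(5))
            cum = np.cumsum(p)
            cum[-1] = 1.0
            for u in rng.random(100):
                assert assign_level(u, cum) == five_branch_level(u, p)


class TestValueSet:
    def test_full_health_anchor(self, value_set):
        assert value_set.utility([1, 1, 1, 1, 1]) == 1.0

    def test_no_profile_exceeds_one_and_worse_is_not_better(self, value_set):
        assert value_set.utility([5, 5, 5, 5, 5]) < value_set.utility([1, 1, 1, 1, 1])
        for d in range(5):
            for lvl in range(1, 5):
                a = np.ones(5, int)
                b = a.copy()
                a[d], b[d] = lvl, lvl + 1
                assert value_set.utility(b) <= value_set.utility(a) <= 1.0

    def test_rejects_invalid_levels(self, value_set):
        with pytest.raises(ValueError):
            value_set.utility([0, 1, 1, 1, 1])


class TestMonteCarloUtility:
    def test_degenerate_model_full_health(self, value_set):
        coefs = {dim: np.zeros((5, 4)) for dim in DIMENSIONS}
        for c in coefs.values():
            c[1:, 0] = -60.0  # intercepts push all mass to level 1
        model = EQ5DMappingResults.from_coefficients(coefs)
        mean, se = model.simulate_expected_utility(10, value_set, trials=500, seed=0)
        assert mean == 1.0
        assert se == 0.0

    def test_same_seed_reproduces_exactly(self, value_set):
        model = EQ5DMappingResults.from_coefficients(default_mapping_truth())
        a = model.simulate_expected_utility(17, value_set, trials=2000, seed=5)
        b = model.simulate_expected_utility(17, value_set, trials=2000, seed=5)
        assert a == b
        c = model.simulate_expected_utility(17, value_set, trials=2000, seed=6)
        assert a != c

    @pytest.mark.parametrize("nbds", [0, 11, 17, 30, 47])
    def test_within_three_se_of_exhaustive_expectation(self, value_set, nbds):
        model = EQ5DMappingResults.from_coefficients(default_mapping_truth())
        mc, se = model.simulate_expected_utility(nbds, value_set, trials=10_000, seed=0)
        exact = model.exact_expected_utility(nbds, value_set)
        assert abs(mc - exact) <= 3 * se

    def test_convergence_rate_scales_with_trials(self, value_set):
        model = EQ5DMappingResults.from_coefficients(default_mapping_truth())
        _, se_small = model.simulate_expected_utility(17, value_set, trials=1000, seed=1)
        _, se_big = model.simulate_expected_utility(17, value_set, trials=16_000, seed=1)
        assert se_big == pytest.approx(se_small / 4.0, rel=0.25)

    def test_curve_decreasing_when_worse_nbds_means_worse_levels(self, value_set):
        model = EQ5DMappingResults.from_coefficients(default_mapping_truth())
        curve = model.utility_curve(value_set, trials=3000, seed=2)
        # exact expectation is monotone; MC noise allowed within a few SE
        diffs = np.diff(curve.utility)
        assert (diffs <= 3 * (curve.mc_se[:-1] + curve.mc_se[1:])).all()
        assert curve.utility[0] > curve.utility[-1]


class TestMappingFit:
    def test_recovers_generator_slopes_within_15_percent(self, survey_5000):
        results = EQ5DMapping.from_dataframe(survey_5000).fit()
        truth = default_mapping_truth()
        for dim in DIMENSIONS:
            true_l5 = truth[dim][4, 1]  # level-5 vs level-1 NBDS coefficient
            fit_l5 = results.fits[dim].coef[4, 1]
            assert fit_l5 == pytest.approx(true_l5, rel=0.15), dim

    def test_level_probs_sum_to_one(self, survey_5000):
        results = EQ5DMapping.from_dataframe(survey_5000).fit()
        for nbds in (0, 17, 47):
            probs = results.profile_prob_matrix(nbds, 51.46, 1.0)
            assert probs.sum(axis=1) == pytest.approx(np.ones(5), abs=1e-9)
            assert (probs >= 0).all()

    def test_constant_dimension_yields_degenerate_model(self, survey_5000):
        df = survey_5000.copy()
        df["eq5d_mo"] = 1
        results = EQ5DMapping.from_dataframe(df).fit()
        probs = results.level_probs("mobility", 20, 51.46, 1.0)
        assert probs[0] == pytest.approx(1.0)
        assert probs[1:] == pytest.approx(np.zeros(4), abs=1e-12)

    def test_too_few_records_rejected(self, survey_5000):
        with pytest.raises(ValueError, match=">= 50"):
            EQ5DMapping.from_dataframe(survey_5000.head(10))


class TestStateUtilitiesFromCurve:
    def _linear_curve(self):
        nbds = np.arange(48)
        return UtilityCurve(
            nbds=nbds, utility=0.9 - 0.01 * nbds, mc_se=np.zeros(48), trials=1
        )

    def test_responder_lookup_at_rounded_shifted_score(self):
        curve = self._linear_curve()
        u = state_utilities_from_curve(curve, nbds_baseline=16.74, delta_responder=-6)
        # 16.74 - 6 = 10.74 rounds to 11
        assert u.u_responder == pytest.approx(0.9 - 0.11)
        assert u.u_sbc == pytest.approx(0.9 - 0.17)  # baseline rounds to 17

    def test_zero_shift_matches_sbc_state(self):
        curve = self._linear_curve()
        u = state_utilities_from_curve(curve, delta_responder=0.0)
        assert u.u_responder == u.u_sbc

    def test_monotone_curve_orders_responder_above_nonresponder(self):
        u = state_utilities_from_curve(self._linear_curve())
        assert u.u_responder > u.u_nonresponder

    def test_out_of_range_score_clamped_with_warning(self):
        curve = self._linear_curve()
        with pytest.warns(UserWarning, match="clamping"):
            u = state_utilities_from_curve(curve, nbds_baseline=2.0, delta_responder=-6)
        assert u.u_responder == pytest.approx(0.9)  # clamped to score 0
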