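"""Markov engine: probability conversion, relative effects, traces."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from asthmace import (
    HealthState,
    StrategySpec,
    TransitionMatrix,
    annual_prob_to_cycle_prob,
    apply_relative_effects,
    half_cycle_occupancy,
    run_trace,
)
from asthmace.errors import InfeasibleParametersError, MatrixValidationError
from asthmace.markov import cycle_prob_to_annual_prob

from conftest import random_transition_matrix

C, U, E, D = range(4)


class TestHazardConversion:
    @pytest.mark.parametrize(
        "p_annual, weeks, expected",
        [
            (0.0, 1, 0.0),
            (0.37, 52, 0.37),  # cycle equal to the horizon year is the identity
            (0.40, 1, 1.0 - 0.60 ** (1.0 / 52.0)),
        ],
    )
    def test_closed_form(self, p_annual, weeks, expected):
        assert annual_prob_to_cycle_prob(p_annual, weeks) == pytest.approx(
            expected, abs=1e-15
        )

    def test_agrees_with_rate_form(self):
        # p_w = 1 - exp(-h/52) with h = -ln(1 - p_annual)
        h = -np.log(1.0 - 0.40)
        assert annual_prob_to_cycle_prob(0.40, 1) == pytest.approx(
            1.0 - np.exp(-h / 52.0), abs=1e-12
        )

    @given(st.floats(min_value=0.0, max_value=0.999), st.floats(min_value=0.01, max_value=52.0))
    def test_round_trip_and_bounds(self, p_annual, weeks):
        p_cycle = annual_prob_to_cycle_prob(p_annual, weeks)
        assert 0.0 <= p_cycle <= p_annual + 1e-12
        assert cycle_prob_to_annual_prob(p_cycle, weeks) == pytest.approx(
            p_annual, abs=1e-12
        )

    @given(st.floats(min_value=0.0, max_value=0.999))
    def test_weekly_bernoulli_composition_recovers_annual(self, p_annual):
        # surviving 52 independent weekly draws equals surviving the year
        p_w = annual_prob_to_cycle_prob(p_annual, 1)
        assert 1.0 - (1.0 - p_w) ** 52 == pytest.approx(p_annual, abs=1e-12)

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
    def test_rejects_bad_probability(self, bad):
        with pytest.raises(ValueError):
            annual_prob_to_cycle_prob(bad, 1)

    @pytest.mark.parametrize("bad_weeks", [0.0, -1.0, 53.0])
    def test_rejects_bad_cycle_length(self, bad_weeks):
        with pytest.raises(ValueError):
            annual_prob_to_cycle_prob(0.1, bad_weeks)


class TestTransitionMatrix:
    def test_rejects_bad_row_sum_naming_row(self):
        P = np.eye(4)
        P[1, 1] = 0.8
        with pytest.raises(MatrixValidationError, match="uncontrolled"):
            TransitionMatrix(P)

    def test_renormalises_small_rounding_only(self):
        P = np.eye(4)
        P[0, 0] = 1.0 + 5e-7  # within the forgiveness band
        m = TransitionMatrix(P)
        assert m.probs[0].sum() == pytest.approx(1.0, abs=1e-12)

    def test_death_must_be_absorbing(self):
        P = np.eye(4)
        P[3] = [0.1, 0.0, 0.0, 0.9]
        with pytest.raises(MatrixValidationError, match="absorbing"):
            TransitionMatrix(P)


class TestApplyRelativeEffects:
    def reference(self):
        P = np.array(
            [
                [0.90, 0.07, 0.029, 0.001],
                [0.10, 0.85, 0.049, 0.001],
                [0.20, 0.70, 0.098, 0.002],
                [0.0, 0.0, 0.0, 1.0],
            ]
        )
        return TransitionMatrix(P)

    def test_unit_effects_is_bitwise_identity(self):
        ref = self.reference()
        out = apply_relative_effects(ref, StrategySpec("same"))
        assert (out.probs == ref.probs).all()

    def test_hand_computed_uncontrolled_row(self):
        # scale into-control by 2 and into-exacerbation by 0.5; the stay
        # probability absorbs the residual and death is untouched
        P = np.array(
            [
                [0.90, 0.07, 0.029, 0.001],
                [0.10, 0.85, 0.049, 0.001],
                [0.20, 0.70, 0.098, 0.002],
                [0.0, 0.0, 0.0, 1.0],
            ]
        )
        ref = TransitionMatrix(P)
        out = apply_relative_effects(
            ref, StrategySpec("x", rr_control=2.0, rr_exacerbation=0.5)
        )
        np.testing.assert_allclose(
            out.probs[U], [0.20, 0.7745, 0.0245, 0.001], atol=1e-12
        )

    def test_death_entries_never_rescaled(self, rng):
        for _ in range(20):
            ref = random_transition_matrix(rng)
            try:
                out = apply_relative_effects(
                    ref, StrategySpec("x", rr_control=1.3, rr_exacerbation=0.7)
                )
            except InfeasibleParametersError:
                continue
            np.testing.assert_array_equal(out.probs[:, D][:3], ref.probs[:, D][:3])

    def test_infeasible_scaling_rejected(self):
        ref = self.reference()
        with pytest.raises(InfeasibleParametersError):
            apply_relative_effects(ref, StrategySpec("big", rr_control=12.0))

    def test_odds_ratio_scale(self):
        ref = self.reference()
        out = apply_relative_effects(
            ref, StrategySpec("or", rr_control=0.44, effect_scale="odds_ratio")
        )
        p = 0.10
        expected = 0.44 * p / (1 - p) / (1 + 0.44 * p / (1 - p))
        assert out.probs[U, C] == pytest.approx(expected, abs=1e-15)
        assert out.probs[U].sum() == pytest.approx(1.0, abs=1e-12)


class TestRunTrace:
    def test_identity_matrix_constant_trace(self):
        trace = run_trace(TransitionMatrix.identity(), [0.3, 0.4, 0.2, 0.1], 5)
        np.testing.assert_allclose(trace.occupancy, [[0.3, 0.4, 0.2, 0.1]] * 6)

    def test_death_is_absorbing_forever(self, rng):
        m = random_transition_matrix(rng)
        trace = run_trace(m, [0.0, 0.0, 0.0, 1.0], 10)
        np.testing.assert_allclose(trace.occupancy[:, D], 1.0, atol=1e-12)

    def test_matches_matrix_power_oracle(self, rng):
        # brute-force oracle: occupancy(t) = initial @ P^t
        for _ in range(25):
            m = random_transition_matrix(rng)
            init = rng.dirichlet(np.ones(4))
            trace = run_trace(m, init, 4)
            for t in range(5):
                expected = init @ np.linalg.matrix_power(m.probs, t)
                np.testing.assert_allclose(trace.occupancy[t], expected, atol=1e-12)

    def test_conservation_and_monotone_death_fuzz(self, rng):
        for _ in range(200):
            m = random_transition_matrix(rng)
            trace = run_trace(m, [0.0, 1.0, 0.0, 0.0], 52)
            sums = trace.occupancy.sum(axis=1)
            np.testing.assert_allclose(sums, 1.0, atol=1e-9)
            assert (np.diff(trace.occupancy[:, D]) >= -1e-12).all()

    def test_rejects_bad_initial(self):
        with pytest.raises(ValueError):
            run_trace(TransitionMatrix.identity(), [0.5, 0.4, 0.0, 0.0], 2)


class TestHalfCycle:
    def test_constant_trace_unchanged(self):
        trace = run_trace(TransitionMatrix.identity(), [0.25, 0.25, 0.25, 0.25], 3)
        np.testing.assert_allclose(half_cycle_occupancy(trace), 0.25)

    def test_midpoint_of_step(self):
        from asthmace import CohortTrace

        trace = CohortTrace(np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0]]))
        np.testing.assert_allclose(
            half_cycle_occupancy(trace)[0], [0.5, 0.5, 0.0, 0.0]
        )

    def test_between_start_and_end_counting(self, rng):
        # trapezoidal accrual lies between counting state membership at
        # cycle starts and at cycle ends
        for _ in range(20):
            m = random_transition_matrix(rng)
            trace = run_trace(m, [0.0, 1.0, 0.0, 0.0], 52)
            occ = trace.occupancy
            eff = half_cycle_occupancy(trace).sum(axis=0)
            start = occ[:-1].sum(axis=0)
            end = occ[1:].sum(axis=0)
            lo = np.minimum(start, end)
            hi = np.maximum(start, end)
            assert ((eff >= lo - 1e-12) & (eff <= hi + 1e-12)).all()
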