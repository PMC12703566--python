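"""Deterministic one-way, scenario, threshold and structural analyses."""

import numpy as np
import pytest

from asthmace import (
    config_digest,
    exacerbation_shift_scenario,
    one_way_utility,
    price_discount_scenario,
    run_base_case,
    structural_scenarios,
    threshold_price,
)
from asthmace.errors import ThresholdNotFoundError
from asthmace.incremental import DominanceStatus
from asthmace.markov import HealthState, TransitionMatrix
from asthmace.sensitivity import _shift_matrix


def _frontier_icers(result):
    return [
        r.icer
        for r in sorted(result.tables["qaly"], key=lambda r: r.effect)
        if r.status is DominanceStatus.ON_FRONTIER and r.icer is not None
    ]


class TestOneWayUtility:
    def test_zero_delta_reproduces_base(self, example_config):
        base = run_base_case(example_config)
        variants = one_way_utility(example_config, delta=0.0)
        for v in variants:
            assert not v.rank_order_changed
            for row_v, row_b in zip(v.result.tables["qaly"], base.tables["qaly"]):
                assert row_v.cost == pytest.approx(row_b.cost)
                assert row_v.effect == pytest.approx(row_b.effect)

    def test_default_delta_runs_all_four_variants(self, example_config):
        variants = one_way_utility(example_config)
        assert len(variants) == 4
        for v in variants:
            assert _frontier_icers(v.result) == sorted(_frontier_icers(v.result))

    def test_interval_bounds_mode(self, example_config):
        variants = one_way_utility(example_config, use_intervals=True)
        assert len(variants) == 6

    def test_common_utility_shift_moves_qalys_through_survival(self, example_config):
        # adding eps to every state utility changes each strategy's QALYs by
        # eps x (person-time alive) / 52, so incremental QALYs only move
        # through survival differences
        eps = 0.01
        u = example_config.utilities
        base = run_base_case(example_config)
        shifted = run_base_case(
            example_config,
            utilities=(
                u.base + eps,
                u.base - u.disutility_uncontrolled + eps,
                u.base - u.disutility_exacerbation + eps,
            ),
        )
        for b, s in zip(base.strategies, shifted.strategies):
            alive_weeks = (
                b.outcomes.controlled_days
                + b.outcomes.uncontrolled_days
                + b.outcomes.exacerbation_days
            ) / 7.0
            expected = b.outcomes.total_qaly + eps * alive_weeks / 52.0
            assert s.outcomes.total_qaly == pytest.approx(expected, abs=1e-10)

    def test_purity(self, example_config):
        digest = config_digest(example_config)
        one_way_utility(example_config)
        assert config_digest(example_config) == digest


class TestPriceDiscount:
    def test_zero_fraction_is_base_case(self, example_config):
        base = run_base_case(example_config)
        same = price_discount_scenario(example_config, fraction=0.0)
        for b, s in zip(base.strategies, same.strategies):
            assert s.outcomes.total_cost == pytest.approx(b.outcomes.total_cost)

    def test_costs_monotone_in_discount(self, example_config):
        prev = None
        for fraction in (0.0, 0.25, 0.5, 0.75):
            res = price_discount_scenario(example_config, fraction=fraction)
            costs = np.array([s.outcomes.total_cost for s in res.strategies])
            if prev is not None:
                assert (costs <= prev + 1e-9).all()
            prev = costs

    def test_purity(self, example_config):
        digest = config_digest(example_config)
        price_discount_scenario(example_config)
        assert config_digest(example_config) == digest


class TestExacerbationShift:
    def test_unit_scale_is_base_case(self, example_config):
        base = run_base_case(example_config)
        same = exacerbation_shift_scenario(example_config, scale=1.0)
        for b, s in zip(base.strategies, same.strategies):
            assert s.outcomes.total_qaly == pytest.approx(b.outcomes.total_qaly)

    def test_shift_conserves_rows_and_moves_mass(self):
        P = np.array(
            [
                [0.90, 0.07, 0.029, 0.001],
                [0.30, 0.65, 0.049, 0.001],
                [0.20, 0.70, 0.098, 0.002],
                [0, 0, 0, 1.0],
            ]
        )
        shifted = _shift_matrix(TransitionMatrix(P), 1.5)
        np.testing.assert_allclose(shifted.probs.sum(axis=1), 1.0, atol=1e-12)
        E = HealthState.EXACERBATION
        np.testing.assert_allclose(shifted.probs[:3, E], 1.5 * P[:3, E], atol=1e-12)
        # compensating mass comes out of the controlled column only
        C = HealthState.CONTROLLED
        np.testing.assert_allclose(
            P[:3, C] - shifted.probs[:3, C], 0.5 * P[:3, E], atol=1e-12
        )

    def test_infeasible_shift_rejected(self):
        P = np.array(
            [
                [0.01, 0.50, 0.489, 0.001],
                [0.30, 0.65, 0.049, 0.001],
                [0.20, 0.70, 0.098, 0.002],
                [0, 0, 0, 1.0],
            ]
        )
        with pytest.raises(ValueError, match="infeasible"):
            _shift_matrix(TransitionMatrix(P), 3.0)

    def test_more_exacerbations_fewer_qalys(self, example_config):
        base = run_base_case(example_config)
        worse = exacerbation_shift_scenario(example_config, scale=1.5)
        for b, w in zip(base.strategies, worse.strategies):
            assert w.outcomes.total_qaly < b.outcomes.total_qaly
            assert w.outcomes.exacerbation_days > b.outcomes.exacerbation_days


class TestThresholdPrice:
    def test_already_cost_effective_needs_no_cut(self, example_config):
        # the reference strategy anchors the frontier: zero reduction
        res = threshold_price(example_config, "low_dose_ics")
        assert res.fraction_reduction == 0.0

    def test_root_condition_and_consistency(self, example_config):
        res = threshold_price(example_config, "ics_laba")
        assert 0.0 < res.threshold_price < res.current_price
        # re-running the analysis at the found price puts the strategy on the
        # frontier at (or below) the willingness-to-pay threshold
        variant = example_config.copy()
        variant.strategy("ics_laba").device_price = res.threshold_price
        rows = run_base_case(variant).tables["qaly"]
        row = next(r for r in rows if r.strategy == "ics_laba")
        assert row.status is DominanceStatus.ON_FRONTIER
        assert row.icer is None or row.icer <= example_config.wtp_threshold
        # and the reported ICER sits near the threshold
        assert res.icer_at_threshold == pytest.approx(
            example_config.wtp_threshold, rel=0.05
        )

    def test_unreachable_threshold_reported(self, example_config):
        # even a free inhaler cannot make the least effective strategy optimal
        with pytest.raises(ThresholdNotFoundError):
            threshold_price(example_config, "ltra", wtp=0.0)

    def test_purity(self, example_config):
        digest = config_digest(example_config)
        threshold_price(example_config, "ics_laba")
        assert config_digest(example_config) == digest


class TestStructural:
    def test_identical_parameters_identical_results(self, example_config):
        cfg = example_config.copy()
        for s in cfg.strategies:
            s.rr_control_random_effects = s.rr_control
            s.rr_exacerbation_random_effects = s.rr_exacerbation
        base = run_base_case(cfg)
        re_run = structural_scenarios(cfg, "random_effects")
        for b, r in zip(base.strategies, re_run.strategies):
            assert r.outcomes.total_qaly == pytest.approx(b.outcomes.total_qaly)
            assert r.outcomes.total_cost == pytest.approx(b.outcomes.total_cost)

    def test_random_effects_close_to_base(self, example_config):
        base = _frontier_icers(run_base_case(example_config))
        re_run = _frontier_icers(structural_scenarios(example_config, "random_effects"))
        for b, r in zip(base, re_run):
            assert r == pytest.approx(b, rel=1.0)  # same order of magnitude

    def test_medium_reference_gives_medium_unit_ratios(self, example_config):
        res = structural_scenarios(example_config, "medium_reference")
        medium = next(s for s in res.strategies if s.name == "medium_dose_ics")
        base = run_base_case(example_config)
        medium_base = next(s for s in base.strategies if s.name == "medium_dose_ics")
        # medium-dose ICS now follows the reference matrix exactly, so its
        # outcomes equal the base-case reference strategy's trace valued at
        # medium-dose prices
        ref_base = next(
            s for s in base.strategies if s.name == example_config.reference_strategy
        )
        np.testing.assert_allclose(
            medium.trace.occupancy, ref_base.trace.occupancy, atol=1e-12
        )
        assert medium.outcomes.total_qaly != pytest.approx(
            medium_base.outcomes.total_qaly, abs=1e-9
        )

    def test_dose_stratified_swaps_strategies(self, example_config):
        res = structural_scenarios(example_config, "dose_stratified_laba")
        names = {s.name for s in res.strategies}
        assert "ics_laba" not in names
        assert {"low_dose_ics_laba", "medium_dose_ics_laba", "high_dose_ics_laba"} <= names
        # every strategy still yields a complete, valid frontier
        icers = _frontier_icers(res)
        assert icers == sorted(icers)

    def test_all_scenarios_emit_valid_tables(self, example_config):
        for variant in (
            "random_effects",
            "medium_reference",
            "random_effects_medium_reference",
            "dose_stratified_laba",
        ):
            res = structural_scenarios(example_config, variant)
            icers = _frontier_icers(res)
            assert all(b > a for a, b in zip(icers, icers[1:]))
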