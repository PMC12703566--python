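"""Deterministic sensitivity analyses: one-way, scenario, threshold, structural.

All operations are pure with respect to the input configuration: they work
on copies and re-run the full incremental analysis for each variant, so
every result is a complete CEA table with a valid frontier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ModelConfig
from .errors import ConfigError, ThresholdNotFoundError
from .incremental import DominanceStatus
from .markov import HealthState, TransitionMatrix
from .model import BaseCaseResult, run_base_case
from .valuation import utilities_from_disutilities

__all__ = [
    "OwsaVariant",
    "one_way_utility",
    "price_discount_scenario",
    "exacerbation_shift_scenario",
    "threshold_price",
    "ThresholdResult",
    "structural_scenarios",
    "STRUCTURAL_VARIANTS",
]


def _rank_signature(result: BaseCaseResult, measure: str = "qaly"):
    """Cost-effectiveness ordering: strategies by effect with their statuses."""
    return tuple((row.strategy, row.status) for row in result.tables[measure])


@dataclass(frozen=True)
class OwsaVariant:
    name: str
    utilities: tuple[float, float, float]
    result: BaseCaseResult
    rank_order_changed: bool


def one_way_utility(
    config: ModelConfig,
    delta: float | None = None,
    use_intervals: bool = False,
) -> list[OwsaVariant]:
    """One-way sensitivity analysis on the state utilities.

    Varies the uncontrolled and exacerbation utility point estimates by
    ``±delta`` (default from the configuration, 0.05 in the base case), one
    at a time; with ``use_intervals`` the configured 95% interval bounds are
    used instead, for all three states. (The controlled-state utility is not
    delta-varied: the base weight sits near the top of the scale, so an
    additive bump would leave [0, 1].) Each variant re-runs the full
    incremental analysis and reports whether the cost-effectiveness rank
    ordering (strategies by effect with their dominance statuses) changed
    from the base case.
    """
    if delta is None:
        delta = config.scenarios.owsa_utility_delta
    u = config.utilities
    base_utils = utilities_from_disutilities(
        u.base, u.disutility_uncontrolled, u.disutility_exacerbation
    )
    base = run_base_case(config)
    base_rank = _rank_signature(base)

    variants: list[tuple[str, tuple[float, float, float]]] = []
    if use_intervals:
        specs = [
            ("controlled", 0, u.base_interval),
            ("uncontrolled", 1, u.disutility_uncontrolled_interval),
            ("exacerbation", 2, u.disutility_exacerbation_interval),
        ]
        for state, idx, interval in specs:
            if interval is None:
                raise ConfigError(
                    [f"config.utilities: no 95% interval configured for {state}"]
                )
            for bound, val in zip(("lower", "upper"), interval):
                utils = list(base_utils)
                # intervals for the deduction states are on the disutility scale
                utils[idx] = val if idx == 0 else u.base - val
                variants.append((f"{state}_{bound}", tuple(utils)))
    else:
        for idx, state in ((1, "uncontrolled"), (2, "exacerbation")):
            for sign, tag in ((+1.0, "plus"), (-1.0, "minus")):
                utils = list(base_utils)
                utils[idx] = base_utils[idx] + sign * delta
                variants.append((f"{state}_{tag}_{delta:g}", tuple(utils)))

    out: list[OwsaVariant] = []
    for name, utils in variants:
        if any(not 0.0 <= x <= 1.0 for x in utils):
            raise ValueError(f"variant {name}: perturbed utilities {utils} leave [0, 1]")
        result = run_base_case(config, utilities=utils)
        out.append(
            OwsaVariant(name, utils, result, _rank_signature(result) != base_rank)
        )
    return out


def price_discount_scenario(
    config: ModelConfig, fraction: float | None = None
) -> BaseCaseResult:
    """Scale branded maintenance-inhaler prices by ``(1 - fraction)`` and re-run.

    Emulates generic entry: the configured fraction (0.5 in the base
    analysis) is removed from every branded device price; non-branded items
    (e.g. reliever inhalers costed as resource items) are untouched.
    """
    if fraction is None:
        fraction = config.scenarios.price_discount_fraction
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"fraction must be in [0, 1); got {fraction}")
    variant = config.copy()
    for s in variant.strategies:
        if s.branded:
            s.device_price *= 1.0 - fraction
    return run_base_case(variant)


def _shift_matrix(matrix: TransitionMatrix, scale: float) -> TransitionMatrix:
    C, E = HealthState.CONTROLLED, HealthState.EXACERBATION
    P = np.array(matrix.probs)
    for row in (HealthState.CONTROLLED, HealthState.UNCONTROLLED, HealthState.EXACERBATION):
        added = (scale - 1.0) * P[row, E]
        P[row, E] += added
        P[row, C] -= added
        if P[row, C] < -1e-12 or P[row, E] > 1 + 1e-12:
            raise ValueError(
                f"exacerbation shift x{scale} makes row "
                f"'{matrix.probs[row]}' infeasible (controlled probability < 0)"
            )
    return TransitionMatrix(P, matrix.cycle_length_weeks)


def exacerbation_shift_scenario(
    config: ModelConfig, scale: float | None = None
) -> BaseCaseResult:
    """Scale every alive-state exacerbation transition, compensating from control.

    Multiplies each strategy's transitions into the exacerbation state by
    ``scale`` (1.5 in the base analysis, emulating a higher-severity
    population), concurrently for all treatments, and subtracts the added
    mass from the same row's transition into the controlled state so rows
    stay stochastic.
    """
    if scale is None:
        scale = config.scenarios.exacerbation_shift_scale
    if scale <= 0:
        raise ValueError(f"scale must be positive; got {scale}")
    return run_base_case(config, matrix_transform=lambda m: _shift_matrix(m, scale))


@dataclass(frozen=True)
class ThresholdResult:
    strategy: str
    current_price: float
    threshold_price: float
    fraction_reduction: float
    icer_at_threshold: float | None


def _frontier_icer(result: BaseCaseResult, strategy: str, measure: str = "qaly"):
    """The strategy's sequential ICER if on the frontier, else None/status."""
    for row in result.tables[measure]:
        if row.strategy == strategy:
            if row.status is not DominanceStatus.ON_FRONTIER:
                return None, row.status
            return row.icer, row.status
    raise KeyError(f"strategy '{strategy}' not in result")


def threshold_price(
    config: ModelConfig,
    strategy: str,
    wtp: float | None = None,
    price_tol: float = 0.005,
) -> ThresholdResult:
    """Device price at which a strategy's frontier ICER meets the threshold.

    Bisects on the strategy's inhaler price in ``(0, current price]``,
    re-screening dominance at every candidate price (the frontier can change
    shape as the price falls), until the price bracket is within
    ``price_tol`` (£0.005). If the strategy is already cost-effective at its
    current price the reduction is zero; if even a zero price cannot reach
    the threshold, :class:`ThresholdNotFoundError` is raised.
    """
    if wtp is None:
        wtp = config.wtp_threshold
    current = config.strategy(strategy).device_price
    if current <= 0:
        raise ValueError(f"strategy '{strategy}' has no positive device price")

    def cost_effective_at(price: float) -> bool:
        variant = config.copy()
        variant.strategy(strategy).device_price = price
        icer, status = _frontier_icer(run_base_case(variant), strategy)
        if status is not DominanceStatus.ON_FRONTIER:
            return False
        return icer is None or icer <= wtp

    if cost_effective_at(current):
        icer, _ = _frontier_icer(run_base_case(config), strategy)
        return ThresholdResult(strategy, current, current, 0.0, icer)
    if not cost_effective_at(0.0):
        raise ThresholdNotFoundError(
            f"strategy '{strategy}' cannot reach £{wtp:,.0f} per unit benefit "
            "at any non-negative device price"
        )
    lo, hi = 0.0, current  # cost-effective at lo, not at hi
    while hi - lo > price_tol:
        mid = 0.5 * (lo + hi)
        if cost_effective_at(mid):
            lo = mid
        else:
            hi = mid
    variant = config.copy()
    variant.strategy(strategy).device_price = lo
    icer, _ = _frontier_icer(run_base_case(variant), strategy)
    return ThresholdResult(strategy, current, lo, 1.0 - lo / current, icer)


STRUCTURAL_VARIANTS = (
    "random_effects",
    "medium_reference",
    "random_effects_medium_reference",
    "dose_stratified_laba",
)


def structural_scenarios(
    config: ModelConfig,
    variant: str,
    medium_strategy: str = "medium_dose_ics",
) -> BaseCaseResult:
    """Structural uncertainty analyses.

    * ``random_effects`` — relative effects from the random-effects network
      meta-analysis (per-strategy ``rr_*_random_effects`` config entries).
    * ``medium_reference`` — the reference matrix is taken to describe
      medium-dose ICS; every strategy's ratios are re-expressed against it.
    * ``random_effects_medium_reference`` — both of the above.
    * ``dose_stratified_laba`` — the single ICS+LABA strategy is replaced by
      individually dosed and priced ICS+LABA strategies from the
      configuration's structural block.
    """
    if variant not in STRUCTURAL_VARIANTS:
        raise ValueError(
            f"unknown structural variant '{variant}'; expected one of {STRUCTURAL_VARIANTS}"
        )
    if variant == "random_effects":
        _require_random_effects(config)
        return run_base_case(config, random_effects=True)
    if variant == "medium_reference":
        return run_base_case(config, reference_strategy=medium_strategy)
    if variant == "random_effects_medium_reference":
        _require_random_effects(config)
        return run_base_case(
            config, random_effects=True, reference_strategy=medium_strategy
        )
    # dose_stratified_laba
    if not config.dose_stratified_strategies:
        raise ConfigError(
            ["config.structural.dose_stratified_strategies: required for this variant"]
        )
    strategies = [
        s for s in config.strategies if s.name != config.dose_stratified_replaces
    ]
    strategies.extend(config.dose_stratified_strategies)
    return run_base_case(config, strategies=strategies)


def _require_random_effects(config: ModelConfig) -> None:
    missing = [
        s.name
        for s in config.strategies
        if s.rr_control_random_effects is None or s.rr_exacerbation_random_effects is None
    ]
    if missing:
        raise ConfigError(
            [f"strategies.{name}: random-effects relative effects missing" for name in missing]
        )
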