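"""Costs, utilities and outcome accrual over a cohort trace.

Resource-use profiles (counts of GP visits, emergency attendances,
admissions, prescriptions, ...) are valued with unit costs and recalibrated
to the weekly cycle. The controlled and uncontrolled profiles are annual
rates, so their weekly cost is the annual total divided by 52; the
exacerbation profile is per episode, and each cycle spent in the
exacerbation state incurs one full episode cost. Death carries zero cost
and zero utility. Utilities enter as a base weight for controlled asthma
with disutility deductions for the uncontrolled and exacerbation states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .markov import (
    ALIVE_STATES,
    N_STATES,
    WEEKS_PER_YEAR,
    CohortTrace,
    HealthState,
    half_cycle_occupancy,
)

__all__ = [
    "ResourceItem",
    "StateValuation",
    "Outcomes",
    "weekly_state_cost",
    "weekly_inhaler_cost",
    "utilities_from_disutilities",
    "accrue",
]

DAYS_PER_WEEK = 7.0
#: The model year is 52 seven-day cycles = 364 days; day-count outcomes are
#: reported on this basis for internal consistency with the weekly cycle.
DAYS_PER_HORIZON_YEAR = WEEKS_PER_YEAR * DAYS_PER_WEEK


@dataclass(frozen=True)
class ResourceItem:
    """One item of healthcare resource use with its unit cost.

    ``mean``/``sd`` are events per year for the controlled and uncontrolled
    state profiles, or events per episode for the exacerbation profile.
    """

    name: str
    mean: float
    unit_cost: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.mean < 0 or self.sd < 0 or self.unit_cost < 0:
            raise ValueError(
                f"resource item '{self.name}': counts, SDs and unit costs "
                "must be non-negative"
            )

    @property
    def annual_cost(self) -> float:
        return self.mean * self.unit_cost


def weekly_state_cost(
    items: list[ResourceItem],
    drug_weekly: float = 0.0,
    per_episode: bool = False,
) -> float:
    """Weekly cost of occupying one health state.

    For annual profiles (controlled, uncontrolled) the item costs are summed
    over the year and divided by 52. For the exacerbation profile
    (``per_episode=True``) the per-episode costs are charged in full for each
    cycle spent in the state — episodes last one weekly cycle.
    ``drug_weekly`` is added per cycle in either mode.
    """
    if drug_weekly < 0:
        raise ValueError("drug_weekly must be non-negative")
    total = sum(item.annual_cost for item in items)
    if per_episode:
        return total + drug_weekly
    return total / WEEKS_PER_YEAR + drug_weekly


def weekly_inhaler_cost(
    device_price: float,
    actuations_per_device: int | None = None,
    actuations_per_day: float | None = None,
    mode: str = "actuation",
    devices_per_year: float = 12.0,
) -> float:
    """Weekly cost of a maintenance inhaler device.

    Two costing modes:

    * ``"actuation"`` — price per actuation times the daily actuation count
      times seven: ``device_price / actuations_per_device * actuations_per_day * 7``.
    * ``"annual_devices"`` — a fixed annual prescription count spread over
      the year: ``device_price * devices_per_year / 52`` (default 12
      devices issued per year).
    """
    if device_price < 0:
        raise ValueError("device_price must be non-negative")
    if mode == "actuation":
        if not actuations_per_device or actuations_per_device <= 0:
            raise ValueError("actuations_per_device must be positive")
        if actuations_per_day is None or actuations_per_day <= 0:
            raise ValueError("actuations_per_day must be positive")
        return device_price / actuations_per_device * actuations_per_day * DAYS_PER_WEEK
    if mode == "annual_devices":
        if devices_per_year < 0:
            raise ValueError("devices_per_year must be non-negative")
        return device_price * devices_per_year / WEEKS_PER_YEAR
    raise ValueError(f"unknown inhaler costing mode '{mode}'")


def utilities_from_disutilities(
    base: float,
    disutility_uncontrolled: float,
    disutility_exacerbation: float,
) -> tuple[float, float, float]:
    """Per-state utilities (controlled, uncontrolled, exacerbation).

    The controlled state carries the base utility; the uncontrolled and
    exacerbation states deduct their disutilities from it. All three
    resulting weights must lie in [0, 1].
    """
    if not 0.0 <= base <= 1.0:
        raise ValueError(f"base utility must be in [0, 1]; got {base}")
    if disutility_uncontrolled < 0 or disutility_exacerbation < 0:
        raise ValueError("disutilities must be non-negative")
    u = (base, base - disutility_uncontrolled, base - disutility_exacerbation)
    for label, val in zip(("controlled", "uncontrolled", "exacerbation"), u):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{label} utility {val} lies outside [0, 1]")
    return u


@dataclass(frozen=True)
class StateValuation:
    """Per-state weekly cost and utility weights, death fixed at zero.

    ``check_ordering`` enforces controlled >= uncontrolled >= exacerbation
    utility; probabilistic draws may legitimately violate the ordering, so
    the sampler constructs valuations with the check disabled.
    """

    weekly_cost: np.ndarray
    utility: np.ndarray
    check_ordering: bool = True

    def __post_init__(self) -> None:
        cost = np.asarray(self.weekly_cost, dtype=float)
        util = np.asarray(self.utility, dtype=float)
        if cost.shape != (N_STATES,) or util.shape != (N_STATES,):
            raise ValueError("weekly_cost and utility must have one entry per state")
        if (cost < 0).any():
            raise ValueError("weekly costs must be non-negative")
        if (util < 0).any() or (util > 1).any():
            raise ValueError("utilities must lie in [0, 1]")
        if cost[HealthState.DEATH] != 0.0 or util[HealthState.DEATH] != 0.0:
            raise ValueError("death cost and utility must be exactly zero")
        if self.check_ordering:
            c, u, e = (util[s] for s in ALIVE_STATES)
            if not c >= u >= e:
                raise ValueError(
                    "utilities must satisfy controlled >= uncontrolled >= exacerbation"
                )
        cost = cost.copy()
        util = util.copy()
        cost.flags.writeable = False
        util.flags.writeable = False
        object.__setattr__(self, "weekly_cost", cost)
        object.__setattr__(self, "utility", util)

    @classmethod
    def build(
        cls,
        weekly_cost_controlled: float,
        weekly_cost_uncontrolled: float,
        weekly_cost_exacerbation: float,
        utilities: tuple[float, float, float],
        check_ordering: bool = True,
    ) -> "StateValuation":
        cost = np.array(
            [
                weekly_cost_controlled,
                weekly_cost_uncontrolled,
                weekly_cost_exacerbation,
                0.0,
            ]
        )
        util = np.array([*utilities, 0.0])
        return cls(cost, util, check_ordering)


@dataclass(frozen=True)
class Outcomes:
    """Accrued per-patient outcomes over the model horizon."""

    total_cost: float
    total_qaly: float
    controlled_days: float
    uncontrolled_days: float
    exacerbation_days: float
    death_days: float
    exacerbation_free_days: float
    per_state_cost_share: np.ndarray = field(repr=False)

    def effect(self, measure: str) -> float:
        """Look up an effect measure by name (for pluggable frontiers)."""
        measures = {
            "qaly": self.total_qaly,
            "controlled_days": self.controlled_days,
            "exacerbation_free_days": self.exacerbation_free_days,
        }
        if measure not in measures:
            raise KeyError(
                f"unknown effect measure '{measure}'; expected one of {sorted(measures)}"
            )
        return measures[measure]


def accrue(trace: CohortTrace, valuation: StateValuation) -> Outcomes:
    """Accrue costs, QALYs and day counts from a trace.

    Uses half-cycle-corrected effective occupancies throughout. One cycle at
    full utility contributes ``cycle_length_weeks / 52`` QALYs and seven
    days per week of cycle length to the day counts.
    """
    eff = half_cycle_occupancy(trace)  # (n_cycles, 4)
    weeks = trace.cycle_length_weeks
    person_cycles = eff.sum(axis=0)  # effective cycles per state

    per_state_cost = person_cycles * valuation.weekly_cost * weeks
    total_cost = float(per_state_cost.sum())
    total_qaly = float(
        (person_cycles * valuation.utility).sum() * weeks / WEEKS_PER_YEAR
    )
    days = person_cycles * DAYS_PER_WEEK * weeks
    return Outcomes(
        total_cost=total_cost,
        total_qaly=total_qaly,
        controlled_days=float(days[HealthState.CONTROLLED]),
        uncontrolled_days=float(days[HealthState.UNCONTROLLED]),
        exacerbation_days=float(days[HealthState.EXACERBATION]),
        death_days=float(days[HealthState.DEATH]),
        exacerbation_free_days=float(
            days[HealthState.CONTROLLED] + days[HealthState.UNCONTROLLED]
        ),
        per_state_cost_share=per_state_cost,
    )
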