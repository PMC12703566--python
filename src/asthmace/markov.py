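"""Cohort Markov engine: health states, transition matrices, traces.

The model distributes a closed cohort of children with asthma over four
mutually exclusive health states — controlled asthma on maintenance
treatment, uncontrolled asthma, asthma exacerbation, and death from asthma
exacerbation — and propagates it in weekly cycles through a per-strategy
transition-probability matrix. Death is absorbing. Comparator strategies
are expressed as a reference matrix (low-dose inhaled corticosteroid) plus
relative effects on achieving control and on exacerbating, applied
multiplicatively on the probability (risk-ratio) or odds (odds-ratio)
scale.

State order is fixed as CONTROLLED, UNCONTROLLED, EXACERBATION, DEATH and
is the index order of every matrix and occupancy vector in the package.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .errors import InfeasibleParametersError, MatrixValidationError

__all__ = [
    "HealthState",
    "STATE_NAMES",
    "ALIVE_STATES",
    "N_STATES",
    "WEEKS_PER_YEAR",
    "TransitionMatrix",
    "StrategySpec",
    "CohortTrace",
    "annual_prob_to_cycle_prob",
    "cycle_prob_to_annual_prob",
    "apply_relative_effects",
    "run_trace",
    "half_cycle_occupancy",
]

WEEKS_PER_YEAR = 52

#: Row-sum deviations below this are accepted verbatim.
ROW_SUM_ATOL = 1e-9
#: Deviations in [ROW_SUM_ATOL, ROW_SUM_RENORM_TOL) are silently renormalised
#: (forgives rounding in hand-entered published matrices); larger ones error.
ROW_SUM_RENORM_TOL = 1e-6


class HealthState(enum.IntEnum):
    """The four model states, in fixed matrix index order."""

    CONTROLLED = 0
    UNCONTROLLED = 1
    EXACERBATION = 2
    DEATH = 3


STATE_NAMES = ("controlled", "uncontrolled", "exacerbation", "death")
ALIVE_STATES = (
    HealthState.CONTROLLED,
    HealthState.UNCONTROLLED,
    HealthState.EXACERBATION,
)
N_STATES = 4


def annual_prob_to_cycle_prob(p_annual: float, cycle_length_weeks: float = 1.0) -> float:
    """Convert an annual transition probability to a per-cycle probability.

    Assumes a constant hazard over the year, so the per-cycle probability is

        p_cycle = 1 - (1 - p_annual) ** (cycle_length_weeks / 52)

    equivalently ``1 - exp(-h * t)`` with ``h = -ln(1 - p_annual)`` per year.

    Parameters
    ----------
    p_annual
        Probability of the event within one year, in ``[0, 1)``. A value of
        exactly 1 is rejected: it implies an infinite hazard.
    cycle_length_weeks
        Cycle length in weeks, in ``(0, 52]``.
    """
    if not 0.0 <= p_annual < 1.0:
        raise ValueError(f"p_annual must be in [0, 1); got {p_annual}")
    if not 0.0 < cycle_length_weeks <= WEEKS_PER_YEAR:
        raise ValueError(
            f"cycle_length_weeks must be in (0, 52]; got {cycle_length_weeks}"
        )
    return 1.0 - (1.0 - p_annual) ** (cycle_length_weeks / WEEKS_PER_YEAR)


def cycle_prob_to_annual_prob(p_cycle: float, cycle_length_weeks: float = 1.0) -> float:
    """Inverse of :func:`annual_prob_to_cycle_prob` under the same constant hazard."""
    if not 0.0 <= p_cycle < 1.0:
        raise ValueError(f"p_cycle must be in [0, 1); got {p_cycle}")
    if not 0.0 < cycle_length_weeks <= WEEKS_PER_YEAR:
        raise ValueError(
            f"cycle_length_weeks must be in (0, 52]; got {cycle_length_weeks}"
        )
    return 1.0 - (1.0 - p_cycle) ** (WEEKS_PER_YEAR / cycle_length_weeks)


def _validate_matrix(probs: np.ndarray) -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (N_STATES, N_STATES):
        raise MatrixValidationError(
            f"transition matrix must be {N_STATES}x{N_STATES}; got shape {probs.shape}"
        )
    if not np.isfinite(probs).all():
        raise MatrixValidationError("transition matrix has non-finite entries")
    # entries may overshoot [0, 1] by at most the renormalisation band
    if (probs < -ROW_SUM_RENORM_TOL).any() or (probs > 1 + ROW_SUM_RENORM_TOL).any():
        raise MatrixValidationError("transition probabilities must lie in [0, 1]")
    probs = np.clip(probs, 0.0, 1.0)
    out = probs.copy()
    for i in range(N_STATES):
        dev = abs(probs[i].sum() - 1.0)
        if dev <= ROW_SUM_ATOL:
            continue
        if dev < ROW_SUM_RENORM_TOL:
            out[i] = probs[i] / probs[i].sum()
        else:
            raise MatrixValidationError(
                f"row '{STATE_NAMES[i]}' sums to {probs[i].sum():.9f}, not 1"
            )
    death = out[HealthState.DEATH]
    expected = np.zeros(N_STATES)
    expected[HealthState.DEATH] = 1.0
    if not np.allclose(death, expected, atol=ROW_SUM_ATOL):
        raise MatrixValidationError(
            "death must be absorbing: its row must be the unit vector on death"
        )
    out[HealthState.DEATH] = expected
    out.flags.writeable = False
    return out


@dataclass(frozen=True)
class TransitionMatrix:
    """A weekly, time-homogeneous, row-stochastic 4x4 transition matrix.

    One matrix per strategy governs all cycles of the horizon. Rows must sum
    to one within 1e-9 (deviations below 1e-6 are renormalised, to forgive
    rounding in transcribed published matrices) and the death row must be the
    unit vector on death.
    """

    probs: np.ndarray
    cycle_length_weeks: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.cycle_length_weeks <= WEEKS_PER_YEAR:
            raise MatrixValidationError(
                f"cycle_length_weeks must be in (0, 52]; got {self.cycle_length_weeks}"
            )
        object.__setattr__(self, "probs", _validate_matrix(self.probs))

    def __getitem__(self, idx):
        return self.probs[idx]

    @classmethod
    def identity(cls, cycle_length_weeks: float = 1.0) -> "TransitionMatrix":
        return cls(np.eye(N_STATES), cycle_length_weeks)


@dataclass(frozen=True)
class StrategySpec:
    """A comparator strategy's relative effects versus the reference.

    ``rr_control`` scales transitions *into* the controlled state (from
    uncontrolled and from exacerbation); ``rr_exacerbation`` scales
    transitions *into* the exacerbation state (from controlled and from
    uncontrolled). ``effect_scale`` selects whether each ratio is applied as
    a risk ratio (default, multiplicative on the probability) or an odds
    ratio (multiplicative on the odds, then mapped back to a probability).
    The reference strategy has both ratios equal to 1.
    """

    name: str
    rr_control: float = 1.0
    rr_exacerbation: float = 1.0
    effect_scale: str = "risk_ratio"
    rr_control_interval: tuple[float, float] | None = None
    rr_exacerbation_interval: tuple[float, float] | None = None
    weekly_drug_cost: float = 0.0

    def __post_init__(self) -> None:
        if self.rr_control <= 0 or self.rr_exacerbation <= 0:
            raise ValueError(f"{self.name}: relative effects must be strictly positive")
        if self.effect_scale not in ("risk_ratio", "odds_ratio"):
            raise ValueError(
                f"{self.name}: effect_scale must be 'risk_ratio' or 'odds_ratio'"
            )
        for label, iv, point in (
            ("rr_control", self.rr_control_interval, self.rr_control),
            ("rr_exacerbation", self.rr_exacerbation_interval, self.rr_exacerbation),
        ):
            if iv is not None:
                lo, hi = iv
                if not lo <= point <= hi:
                    raise ValueError(
                        f"{self.name}: {label} interval ({lo}, {hi}) does not "
                        f"bracket the point estimate {point}"
                    )


def _scale_prob(p: float, ratio: float, effect_scale: str) -> float:
    """Apply a relative effect to a single destination probability."""
    if effect_scale == "odds_ratio":
        if p >= 1.0:
            return 1.0
        odds = ratio * p / (1.0 - p)
        return odds / (1.0 + odds)
    return min(p * ratio, 1.0)


def apply_relative_effects(
    reference: TransitionMatrix, strategy: StrategySpec
) -> TransitionMatrix:
    """Build a strategy's transition matrix from the reference matrix.

    Destination-specific scaling with residual reassignment: scaled entries
    are clamped to [0, 1]; the row is re-balanced by assigning the residual
    probability to the row's default state — the controlled state for the
    controlled row (staying controlled), the uncontrolled state for the
    uncontrolled and exacerbation rows. Death-transition entries are never
    rescaled. If scaling leaves a row's residual below zero the parameter
    set is infeasible and :class:`InfeasibleParametersError` is raised.
    """
    P = np.array(reference.probs, dtype=float)
    C, U, E, D = (
        HealthState.CONTROLLED,
        HealthState.UNCONTROLLED,
        HealthState.EXACERBATION,
        HealthState.DEATH,
    )
    scale = strategy.effect_scale

    # (row, scaled destination -> ratio, fixed destinations, residual state)
    plans = (
        (U, {C: strategy.rr_control, E: strategy.rr_exacerbation}, (D,), U),
        (E, {C: strategy.rr_control}, (E, D), U),
        (C, {E: strategy.rr_exacerbation}, (U, D), C),
    )
    for row, scaled, fixed, residual_state in plans:
        new_row = np.zeros(N_STATES)
        for dest, ratio in scaled.items():
            new_row[dest] = _scale_prob(P[row, dest], ratio, scale)
        for dest in fixed:
            new_row[dest] = P[row, dest]
        residual = 1.0 - new_row.sum()
        if residual < -ROW_SUM_ATOL:
            raise InfeasibleParametersError(
                f"strategy '{strategy.name}': scaled probabilities in row "
                f"'{STATE_NAMES[row]}' exceed 1 (residual {residual:.3e})"
            )
        new_row[residual_state] = max(residual, 0.0)
        P[row] = new_row
    return TransitionMatrix(P, reference.cycle_length_weeks)


@dataclass(frozen=True)
class CohortTrace:
    """Cycle-by-cycle state occupancy of a closed cohort.

    ``occupancy`` has shape ``(n_cycles + 1, 4)``; row 0 is the initial
    distribution. Every row is a probability vector and the death column is
    non-decreasing (death is absorbing).
    """

    occupancy: np.ndarray
    cycle_length_weeks: float = 1.0

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.ndim != 2 or occ.shape[1] != N_STATES or occ.shape[0] < 1:
            raise ValueError(f"occupancy must be (n_cycles + 1, 4); got {occ.shape}")
        if (occ < -1e-12).any():
            raise ValueError("occupancies must be non-negative")
        if not np.allclose(occ.sum(axis=1), 1.0, atol=ROW_SUM_ATOL):
            raise ValueError("occupancies must sum to 1 at every cycle")
        death = occ[:, HealthState.DEATH]
        if (np.diff(death) < -1e-12).any():
            raise ValueError("death occupancy must be non-decreasing")
        occ = occ.copy()
        occ.flags.writeable = False
        object.__setattr__(self, "occupancy", occ)

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1


def run_trace(
    matrix: TransitionMatrix,
    initial: np.ndarray,
    n_cycles: int = WEEKS_PER_YEAR,
) -> CohortTrace:
    """Propagate an initial occupancy vector through ``n_cycles`` weekly cycles."""
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (N_STATES,):
        raise ValueError(f"initial occupancy must have length {N_STATES}")
    if (initial < 0).any() or abs(initial.sum() - 1.0) > ROW_SUM_ATOL:
        raise ValueError("initial occupancy must be a probability vector summing to 1")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    occ = np.empty((n_cycles + 1, N_STATES))
    occ[0] = initial
    P = matrix.probs
    for t in range(n_cycles):
        occ[t + 1] = occ[t] @ P
    return CohortTrace(occ, matrix.cycle_length_weeks)


def half_cycle_occupancy(trace: CohortTrace) -> np.ndarray:
    """Effective per-cycle occupancy under the half-cycle correction.

    Transitions are treated as occurring mid-cycle, so the effective
    occupancy attributed to cycle ``t`` (t = 1..n) is the arithmetic mean of
    the occupancies at its start and end (trapezoidal state membership).
    All cost, QALY and day-count accruals use these values.

    Returns an array of shape ``(n_cycles, 4)``.
    """
    occ = trace.occupancy
    return 0.5 * (occ[:-1] + occ[1:])
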