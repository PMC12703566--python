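"""Synthetic model configurations with known statistical structure.

``generate_config`` emits complete, valid configurations — a row-stochastic
reference matrix with an absorbing death state, strategies with log-uniform
relative effects, resource profiles with non-negative means and SDs,
strictly positive unit costs, and utilities built from a base weight and
two disutilities — so every pipeline stage is testable without external
files. ``known_answer_config`` builds degenerate configurations whose
outcomes have closed forms (static cohort, geometric decay, analytic
two-strategy ICER) for engine verification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ModelConfig
from .markov import WEEKS_PER_YEAR
from .valuation import DAYS_PER_WEEK

__all__ = ["SyntheticSpec", "generate_config", "known_answer_config", "KNOWN_ANSWER_KINDS"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Ranges from which a synthetic configuration is drawn.

    Defaults emulate the magnitudes of a weekly-cycle childhood-asthma
    model: control is regained from the uncontrolled state within weeks,
    exacerbations are rare within any one week, and asthma death is very
    rare and only reached through exacerbation.
    """

    seed: int = 0
    n_strategies: int = 4
    control_prob_range: tuple[float, float] = (0.25, 0.45)
    exacerbation_prob_range: tuple[float, float] = (0.005, 0.05)
    weekly_death_prob_range: tuple[float, float] = (0.0, 0.002)
    cost_scale: float = 50.0
    utility_base: float = 0.96

    def __post_init__(self) -> None:
        for label, (lo, hi) in (
            ("control_prob_range", self.control_prob_range),
            ("exacerbation_prob_range", self.exacerbation_prob_range),
            ("weekly_death_prob_range", self.weekly_death_prob_range),
        ):
            if not 0.0 <= lo <= hi <= 1.0:
                raise ValueError(f"{label} must be an ordered interval within [0, 1]")
        if self.n_strategies < 1:
            raise ValueError("n_strategies must be >= 1")
        if self.cost_scale <= 0:
            raise ValueError("cost_scale must be positive")
        if not 0.2 < self.utility_base <= 1.0:
            raise ValueError("utility_base must be in (0.2, 1]")
        # worst-case row mass outside the stay state must leave room to stay
        worst = self.control_prob_range[1] + self.exacerbation_prob_range[1] + (
            self.weekly_death_prob_range[1]
        )
        if worst >= 1.0:
            raise ValueError("probability ranges jointly infeasible: rows cannot sum to 1")


def _uniform(rng, interval):
    lo, hi = interval
    return float(rng.uniform(lo, hi)) if hi > lo else float(lo)


def _beta_safe_sd(rng, mean: float) -> float:
    """An SD feasible for a beta moments fit (sd^2 < mean(1-mean))."""
    if mean <= 0.0 or mean >= 1.0:
        return 0.0
    return float(min(0.25 * mean, 0.5 * np.sqrt(mean * (1.0 - mean))))


def generate_config(spec: SyntheticSpec) -> ModelConfig:
    """Draw a complete model configuration; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)

    p_control = _uniform(rng, spec.control_prob_range)
    p_exac = _uniform(rng, spec.exacerbation_prob_range)
    p_death = _uniform(rng, spec.weekly_death_prob_range)
    # controlled row: mild relapse, rare exacerbation
    c_to_u = float(rng.uniform(0.02, 0.10))
    c_to_e = p_exac * float(rng.uniform(0.1, 0.5))
    # exacerbation row resolves towards uncontrolled by default
    e_to_c = p_control * float(rng.uniform(0.5, 1.0))
    e_stay = float(rng.uniform(0.02, 0.15))

    matrix = {
        "controlled": {
            "controlled": {
                "mean": 1.0 - c_to_u - c_to_e,
            },
            "uncontrolled": {"mean": c_to_u, "sd": _beta_safe_sd(rng, c_to_u)},
            "exacerbation": {"mean": c_to_e, "sd": _beta_safe_sd(rng, c_to_e)},
        },
        "uncontrolled": {
            "controlled": {"mean": p_control, "sd": _beta_safe_sd(rng, p_control)},
            "uncontrolled": {"mean": 1.0 - p_control - p_exac},
            "exacerbation": {"mean": p_exac, "sd": _beta_safe_sd(rng, p_exac)},
        },
        "exacerbation": {
            "controlled": {"mean": e_to_c, "sd": _beta_safe_sd(rng, e_to_c)},
            "uncontrolled": {"mean": 1.0 - e_to_c - e_stay - p_death},
            "exacerbation": {"mean": e_stay},
            "death": {"mean": p_death},
        },
        "death": {"death": 1.0},
    }

    def feasible(rc: float, re_: float) -> bool:
        # scaled rows must keep a non-negative residual for every strategy
        return (
            rc * p_control + re_ * p_exac <= 1.0 - 1e-9
            and rc * e_to_c + e_stay + p_death <= 1.0 - 1e-9
            and re_ * c_to_e + c_to_u <= 1.0 - 1e-9
        )

    strategies = []
    for k in range(spec.n_strategies):
        if k == 0:
            rc = re_ = 1.0
        else:
            # log-uniform on (0.2, 2]: symmetric on the ratio scale;
            # rejection-sample so every strategy's matrix stays stochastic
            for _ in range(1000):
                rc = float(np.exp(rng.uniform(np.log(0.2), np.log(2.0))))
                re_ = float(np.exp(rng.uniform(np.log(0.2), np.log(2.0))))
                if feasible(rc, re_):
                    break
            else:
                raise ValueError("could not draw feasible relative effects")
        rc_re = rc * float(rng.uniform(0.9, 1.1))
        re_re = re_ * float(rng.uniform(0.9, 1.1))
        if not feasible(rc_re, re_re):
            rc_re, re_re = rc, re_
        strategies.append(
            {
                "name": f"strategy_{k}",
                "label": f"Strategy {k}",
                "rr_control": rc,
                "rr_exacerbation": re_,
                "rr_control_random_effects": rc_re,
                "rr_exacerbation_random_effects": re_re,
                "device_price": float(rng.uniform(0.2, 1.0)) * spec.cost_scale,
                "branded": True,
            }
        )

    def profile(n_items: int, per_episode: bool) -> list[dict]:
        items = []
        for i in range(n_items):
            mean = float(rng.uniform(0.0, 2.0 if not per_episode else 0.8))
            items.append(
                {
                    "name": f"item_{i}",
                    "mean": mean,
                    "sd": mean * float(rng.uniform(0.2, 2.0)),
                    "unit_cost": float(rng.uniform(0.2, 10.0)) * spec.cost_scale,
                }
            )
        items.append(
            {
                "name": "maintenance_inhaler",
                "mean": 12.0,
                "sd": 2.0,
                "cost_source": "strategy_device",
            }
        )
        return items

    raw = {
        "name": f"synthetic-{spec.seed}",
        "description": "synthetic configuration drawn by asthmace.synthetic",
        "seed": int(spec.seed),
        "model": {"n_cycles": 52, "cycle_length_weeks": 1.0, "initial_state": "uncontrolled"},
        "reference_strategy": "strategy_0",
        "transition_matrix": matrix,
        "strategies": strategies,
        "resource_use": {
            "controlled": profile(3, False),
            "uncontrolled": profile(4, False),
            "exacerbation": profile(4, True),
        },
        "utilities": {
            "base": spec.utility_base,
            "disutility_uncontrolled": 0.10,
            "disutility_exacerbation": 0.20,
            "base_interval": [max(spec.utility_base - 0.05, 0.0), min(spec.utility_base + 0.03, 1.0)],
            "disutility_uncontrolled_interval": [0.05, 0.15],
            "disutility_exacerbation_interval": [0.15, 0.25],
        },
        "wtp": {"threshold": 20000.0, "grid": {"start": 0, "stop": 50000, "step": 1000}},
        "drug_costing": {"devices_per_year": 12.0},
        "scenarios": {},
        "psa": {"n_replicates": 1000},
    }
    return ModelConfig.from_dict(raw)


KNOWN_ANSWER_KINDS = ("static_cohort", "geometric_decay", "two_strategy_icer")

# closed-form fixture constants
_STATIC_UTILITY = 0.96
_STATIC_ITEM = {"name": "gp_visit", "mean": 0.75, "sd": 0.0, "unit_cost": 39.65}
_GEOMETRIC_P = 0.5
_GEOMETRIC_EXAC_COST = 120.0
_ICER_EXIT_A = 0.2
_ICER_EXIT_B = 0.3
_ICER_PRICE_A = 7.0
_ICER_PRICE_B = 20.0


def _base_raw(name: str, initial_state: str, matrix: dict, strategies: list[dict]) -> dict:
    empty = {"controlled": [], "uncontrolled": [], "exacerbation": []}
    return {
        "name": name,
        "seed": 0,
        "model": {"n_cycles": 52, "cycle_length_weeks": 1.0, "initial_state": initial_state},
        "reference_strategy": strategies[0]["name"],
        "transition_matrix": matrix,
        "strategies": strategies,
        "resource_use": empty,
        "utilities": {
            "base": _STATIC_UTILITY,
            "disutility_uncontrolled": 0.10,
            "disutility_exacerbation": 0.20,
        },
        "wtp": {"threshold": 20000.0},
        "drug_costing": {"devices_per_year": 12.0},
    }


def _geometric_person_cycles(p_exit: float, n_cycles: int) -> float:
    """Half-cycle-corrected person-cycles in a state left at rate ``p_exit``.

    Occupancy after t cycles is ``q^t`` with ``q = 1 - p_exit``; the
    trapezoidal accrual over n cycles is ``sum_t (q^(t-1) + q^t) / 2``,
    i.e. ``(1 + q)/2 * (1 - q^n)/(1 - q)`` (and ``n`` when ``p_exit = 0``).
    """
    q = 1.0 - p_exit
    if p_exit == 0.0:
        return float(n_cycles)
    return (1.0 + q) / 2.0 * (1.0 - q**n_cycles) / (1.0 - q)


def known_answer_config(kind: str) -> tuple[ModelConfig, dict]:
    """A degenerate configuration plus its closed-form expected outcomes.

    Returns ``(config, expected)`` where ``expected`` maps outcome names to
    values derived analytically (geometric series / direct arithmetic),
    independently of the cohort engine.
    """
    n = 52
    if kind == "static_cohort":
        # whole cohort parked in the controlled state under an identity matrix
        matrix = {
            "controlled": {"controlled": 1.0},
            "uncontrolled": {"uncontrolled": 1.0},
            "exacerbation": {"exacerbation": 1.0},
            "death": {"death": 1.0},
        }
        strategies = [
            {
                "name": "static",
                "label": "Static cohort",
                "rr_control": 1.0,
                "rr_exacerbation": 1.0,
                "device_price": 0.0,
            }
        ]
        raw = _base_raw("known-static", "controlled", matrix, strategies)
        raw["resource_use"]["controlled"] = [dict(_STATIC_ITEM)]
        weekly_cost = _STATIC_ITEM["mean"] * _STATIC_ITEM["unit_cost"] / WEEKS_PER_YEAR
        expected = {
            "strategy": "static",
            "total_cost": weekly_cost * n,
            "total_qaly": _STATIC_UTILITY * n / WEEKS_PER_YEAR,
            "controlled_days": n * DAYS_PER_WEEK,
            "exacerbation_days": 0.0,
            "exacerbation_free_days": n * DAYS_PER_WEEK,
        }
        return ModelConfig.from_dict(raw), expected

    if kind == "geometric_decay":
        # cohort starts in exacerbation and exits to death at constant rate p
        p = _GEOMETRIC_P
        matrix = {
            "controlled": {"controlled": 1.0},
            "uncontrolled": {"uncontrolled": 1.0},
            "exacerbation": {"exacerbation": 1.0 - p, "death": p},
            "death": {"death": 1.0},
        }
        strategies = [
            {
                "name": "decay",
                "label": "Geometric decay",
                "rr_control": 1.0,
                "rr_exacerbation": 1.0,
                "device_price": 0.0,
            }
        ]
        raw = _base_raw("known-geometric", "exacerbation", matrix, strategies)
        raw["resource_use"]["exacerbation"] = [
            {"name": "episode_bundle", "mean": 1.0, "sd": 0.0, "unit_cost": _GEOMETRIC_EXAC_COST}
        ]
        s = _geometric_person_cycles(p, n)
        expected = {
            "strategy": "decay",
            "person_cycles_exacerbation": s,
            "total_cost": _GEOMETRIC_EXAC_COST * s,
            "total_qaly": (_STATIC_UTILITY - 0.20) * s / WEEKS_PER_YEAR,
            "exacerbation_days": s * DAYS_PER_WEEK,
            "death_days": (n - s) * DAYS_PER_WEEK,
            "controlled_days": 0.0,
        }
        return ModelConfig.from_dict(raw), expected

    if kind == "two_strategy_icer":
        # both strategies move uncontrolled -> controlled at a constant rate;
        # strategy B exits faster (rr_control) but costs more per device.
        a, b_rr = _ICER_EXIT_A, _ICER_EXIT_B / _ICER_EXIT_A
        matrix = {
            "controlled": {"controlled": 1.0},
            "uncontrolled": {"controlled": a, "uncontrolled": 1.0 - a},
            "exacerbation": {"uncontrolled": 1.0},
            "death": {"death": 1.0},
        }
        strategies = [
            {
                "name": "cheap",
                "label": "Cheap",
                "rr_control": 1.0,
                "rr_exacerbation": 1.0,
                "device_price": _ICER_PRICE_A,
            },
            {
                "name": "effective",
                "label": "Effective",
                "rr_control": b_rr,
                "rr_exacerbation": 1.0,
                "device_price": _ICER_PRICE_B,
            },
        ]
        raw = _base_raw("known-icer", "uncontrolled", matrix, strategies)
        for state in ("controlled", "uncontrolled"):
            raw["resource_use"][state] = [
                {
                    "name": "maintenance_inhaler",
                    "mean": 12.0,
                    "sd": 0.0,
                    "cost_source": "strategy_device",
                }
            ]

        u_c, u_u = _STATIC_UTILITY, _STATIC_UTILITY - 0.10

        def analytic(exit_rate: float, price: float) -> tuple[float, float]:
            s_u = _geometric_person_cycles(exit_rate, n)
            qaly = (u_c * (n - s_u) + u_u * s_u) / WEEKS_PER_YEAR
            cost = price * 12.0 / WEEKS_PER_YEAR * n  # same drug cost in both states
            return cost, qaly

        cost_a, qaly_a = analytic(_ICER_EXIT_A, _ICER_PRICE_A)
        cost_b, qaly_b = analytic(_ICER_EXIT_B, _ICER_PRICE_B)
        expected = {
            "cost_cheap": cost_a,
            "qaly_cheap": qaly_a,
            "cost_effective": cost_b,
            "qaly_effective": qaly_b,
            "icer": (cost_b - cost_a) / (qaly_b - qaly_a),
        }
        return ModelConfig.from_dict(raw), expected

    raise ValueError(f"unknown kind '{kind}'; expected one of {KNOWN_ANSWER_KINDS}")
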