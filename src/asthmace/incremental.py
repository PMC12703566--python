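"""Incremental cost-effectiveness analysis: dominance, ICERs, NMB.

Strategies are screened for simple dominance (another option costs no more
and delivers at least as much benefit, strictly better on one axis), then
for extended dominance (a sequential ICER exceeding that of the next, more
effective, alternative). The surviving cost-effectiveness frontier has
strictly increasing costs, effects and ICERs. ICERs are always computed
from unrounded model outputs; the effect measure is pluggable (QALYs, days
of controlled asthma, exacerbation-free days).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "DominanceStatus",
    "CEATableRow",
    "dominance_screen",
    "extended_dominance",
    "icer",
    "net_monetary_benefit",
    "build_cea_table",
    "table_to_frame",
    "select_by_nmb",
    "select_by_icer_threshold",
]


class DominanceStatus(str, enum.Enum):
    ON_FRONTIER = "on_frontier"
    DOMINATED = "dominated"
    EXTENDEDLY_DOMINATED = "extendedly_dominated"


@dataclass(frozen=True)
class CEATableRow:
    """One strategy's line of the incremental analysis.

    ``icer`` is the incremental cost per effect unit versus the previous
    (next-less-effective) frontier strategy; it is ``None`` for the cheapest
    frontier strategy and for non-frontier rows. ``tied_with`` lists
    strategies with identical cost and effect (merged for frontier
    purposes).
    """

    strategy: str
    cost: float
    effect: float
    status: DominanceStatus
    icer: float | None = None
    incremental_cost: float | None = None
    incremental_effect: float | None = None
    comparator: str | None = None
    tied_with: tuple[str, ...] = ()


def icer(delta_cost: float, delta_effect: float) -> float:
    """Incremental cost-effectiveness ratio, delta-cost over delta-effect.

    A non-positive effect difference is rejected: such comparisons belong in
    dominance screening, not in an ICER.
    """
    if delta_effect <= 0:
        raise ValueError(
            f"ICER requires a positive effect difference; got {delta_effect}"
        )
    return delta_cost / delta_effect


def net_monetary_benefit(cost, effect, wtp: float):
    """Net monetary benefit ``wtp * effect - cost`` (vectorised)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * np.asarray(effect, dtype=float) - np.asarray(cost, dtype=float)


def dominance_screen(costs, effects) -> list[bool]:
    """Flag strictly dominated strategies.

    Strategy ``i`` is dominated iff some ``j`` has ``cost_j <= cost_i`` and
    ``effect_j >= effect_i`` with at least one strict inequality. Exact ties
    on both axes dominate neither way.
    """
    costs = np.asarray(costs, dtype=float)
    effects = np.asarray(effects, dtype=float)
    n = len(costs)
    if n == 0:
        raise ValueError("at least one strategy required")
    dominated = []
    for i in range(n):
        flag = False
        for j in range(n):
            if j == i:
                continue
            if (
                costs[j] <= costs[i]
                and effects[j] >= effects[i]
                and (costs[j] < costs[i] or effects[j] > effects[i])
            ):
                flag = True
                break
        dominated.append(flag)
    return dominated


def extended_dominance(costs, effects) -> list[bool]:
    """Flag extendedly dominated strategies among non-dominated candidates.

    Candidates must already have passed the strict-dominance screen (so that,
    sorted by effect, costs strictly increase apart from exact ties).
    Iteratively removes any strategy whose sequential ICER is at least that
    of the next, more effective, alternative, until sequential ICERs are
    strictly increasing. (A middle point collinear with its neighbours is
    economically redundant — a blend of the neighbours matches it exactly —
    and is removed, keeping frontier ICERs strictly increasing.) Exact
    (cost, effect) ties are collapsed to a single representative before
    screening.
    """
    costs = np.asarray(costs, dtype=float)
    effects = np.asarray(effects, dtype=float)
    n = len(costs)
    # one representative per distinct (cost, effect) point
    reps: dict[tuple[float, float], int] = {}
    for i in range(n):
        reps.setdefault((costs[i], effects[i]), i)
    alive = sorted(reps.values(), key=lambda i: (effects[i], costs[i]))
    while True:
        removed = False
        for k in range(1, len(alive) - 1):
            below, here, above = alive[k - 1], alive[k], alive[k + 1]
            icer_here = icer(costs[here] - costs[below], effects[here] - effects[below])
            icer_next = icer(costs[above] - costs[here], effects[above] - effects[here])
            if icer_here >= icer_next:
                del alive[k]
                removed = True
                break
        if not removed:
            break
    kept = {(costs[i], effects[i]) for i in alive}
    return [(costs[i], effects[i]) not in kept for i in range(n)]


def build_cea_table(entries: list[tuple[str, float, float]]) -> list[CEATableRow]:
    """Full incremental analysis of ``(name, cost, effect)`` strategies.

    Returns rows ranked by decreasing effect (ties by increasing cost) with
    dominance statuses and sequential frontier ICERs computed from the
    unrounded inputs. The result is invariant to the input order.
    """
    if not entries:
        raise ValueError("at least one strategy required")
    names = [e[0] for e in entries]
    if len(set(names)) != len(names):
        raise ValueError("strategy names must be unique")
    costs = np.array([e[1] for e in entries], dtype=float)
    effects = np.array([e[2] for e in entries], dtype=float)

    dominated = dominance_screen(costs, effects)
    statuses = [
        DominanceStatus.DOMINATED if d else DominanceStatus.ON_FRONTIER
        for d in dominated
    ]
    cand = [i for i in range(len(names)) if not dominated[i]]
    ext = extended_dominance(costs[cand], effects[cand])
    for local, i in enumerate(cand):
        if ext[local]:
            statuses[i] = DominanceStatus.EXTENDEDLY_DOMINATED

    # exact-tie bookkeeping
    ties: dict[int, tuple[str, ...]] = {}
    for i in range(len(names)):
        twins = tuple(
            names[j]
            for j in range(len(names))
            if j != i and costs[j] == costs[i] and effects[j] == effects[i]
        )
        if twins:
            ties[i] = twins

    frontier = sorted(
        (i for i, s in enumerate(statuses) if s is DominanceStatus.ON_FRONTIER),
        key=lambda i: (effects[i], costs[i], names[i]),
    )
    # keep one tie representative on the sequential ICER chain
    chain = []
    seen_points = set()
    for i in frontier:
        pt = (costs[i], effects[i])
        if pt not in seen_points:
            chain.append(i)
            seen_points.add(pt)

    rows: dict[int, CEATableRow] = {}
    for i, s in enumerate(statuses):
        rows[i] = CEATableRow(
            strategy=names[i],
            cost=float(costs[i]),
            effect=float(effects[i]),
            status=s,
            tied_with=ties.get(i, ()),
        )
    for k, i in enumerate(chain):
        if k == 0:
            continue
        prev = chain[k - 1]
        dc = float(costs[i] - costs[prev])
        de = float(effects[i] - effects[prev])
        rows[i] = replace(
            rows[i],
            icer=icer(dc, de),
            incremental_cost=dc,
            incremental_effect=de,
            comparator=names[prev],
        )
    order = sorted(range(len(names)), key=lambda i: (-effects[i], costs[i], names[i]))
    return [rows[i] for i in order]


def table_to_frame(rows: list[CEATableRow]) -> pd.DataFrame:
    """Incremental table as a DataFrame with published-table columns."""
    return pd.DataFrame(
        {
            "strategy": [r.strategy for r in rows],
            "total_cost": [r.cost for r in rows],
            "effect": [r.effect for r in rows],
            "incremental_cost": [r.incremental_cost for r in rows],
            "incremental_effect": [r.incremental_effect for r in rows],
            "icer": [r.icer for r in rows],
            "status": [r.status.value for r in rows],
        }
    )


def select_by_nmb(entries: list[tuple[str, float, float]], wtp: float) -> str:
    """Strategy with maximal net monetary benefit at ``wtp``.

    Ties broken by higher effect, then lexicographically smallest name —
    the same convention as :func:`select_by_icer_threshold`, so the two
    decision rules agree everywhere including at threshold-equal points.
    """
    vals = [
        (float(net_monetary_benefit(c, e, wtp)), e, name) for name, c, e in entries
    ]
    best_nmb = max(v[0] for v in vals)
    ties = [v for v in vals if v[0] == best_nmb]
    best_effect = max(v[1] for v in ties)
    return min(v[2] for v in ties if v[1] == best_effect)


def select_by_icer_threshold(rows: list[CEATableRow], wtp: float) -> str:
    """Frontier strategy chosen by the ICER decision rule at ``wtp``.

    Walk the frontier from least to most effective and accept each step whose
    ICER is at most ``wtp``; equivalently, the most effective frontier
    strategy whose sequential ICER does not exceed the threshold.
    """
    frontier = sorted(
        (r for r in rows if r.status is DominanceStatus.ON_FRONTIER),
        key=lambda r: (r.effect, r.cost, r.strategy),
    )
    if not frontier:
        raise ValueError("no frontier strategies")
    chosen = frontier[0]
    for row in frontier[1:]:
        if row.icer is None:  # tie with the previous point
            continue
        if row.icer <= wtp:
            chosen = row
    # report the cheapest-name representative among exact ties
    candidates = [chosen.strategy, *chosen.tied_with]
    tied_rows = [r for r in frontier if r.strategy in candidates]
    return min(r.strategy for r in tied_rows) if tied_rows else chosen.strategy
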