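"""Probabilistic sensitivity analysis and acceptability curves.

Distribution fitting follows the conventional second-order assignment for
cost-effectiveness models: gamma distributions on the disutility transform
``1 - utility`` (fixed standard deviation, 0.2 by default), lognormal
distributions on resource-use counts (drawn counts multiplied by fixed
unit costs), and beta distributions on transition probabilities. All
parameters are drawn independently; each replicate rebuilds the strategy
matrices and valuations and re-runs the deterministic cohort model, and
the joint cost/QALY cloud feeds the cost-effectiveness acceptability
curves (probability that each strategy has maximal net monetary benefit,
by willingness-to-pay threshold). Runs are fully reproducible given a seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ALIVE_STATE_NAMES, ModelConfig
from .errors import InfeasibleParametersError
from .markov import TransitionMatrix, run_trace
from .model import build_state_valuation, build_strategy_matrix
from .valuation import accrue

__all__ = [
    "DistributionSpec",
    "fit_gamma_disutility",
    "fit_lognormal_count",
    "fit_beta_probability",
    "PsaResult",
    "run_psa",
    "ceac",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistributionSpec:
    """A fitted sampling distribution for one uncertain parameter.

    ``kind`` is one of ``gamma_disutility`` (draws are ``1 - gamma``),
    ``lognormal``, ``beta`` or ``point``. ``params`` holds the fitted
    natural parameters; ``mean``/``sd`` echo the fitted moments.
    """

    kind: str
    params: tuple[float, ...]
    mean: float
    sd: float

    def sample(self, rng: np.random.Generator, size=None):
        if self.kind == "point":
            return np.full(size, self.params[0]) if size else self.params[0]
        if self.kind == "gamma_disutility":
            shape, rate, floor = self.params
            draw = 1.0 - rng.gamma(shape, 1.0 / rate, size)
            return np.maximum(draw, floor)
        if self.kind == "lognormal":
            mu, sigma = self.params
            return rng.lognormal(mu, sigma, size)
        if self.kind == "beta":
            a, b = self.params
            return rng.beta(a, b, size)
        raise ValueError(f"unknown distribution kind '{self.kind}'")


def fit_gamma_disutility(
    mean_utility: float, sd: float = 0.2, floor: float = 0.0
) -> DistributionSpec:
    """Gamma fit on the transformed ``1 - utility`` score.

    Method of moments: with ``m = 1 - mean_utility``, shape = ``(m/sd)^2``
    and rate = ``m/sd^2``, so the transformed score has mean ``m`` and the
    fixed standard deviation ``sd``. Sampled utilities are ``1 - draw``,
    truncated below at ``floor`` (large disutility draws are possible when
    ``sd`` far exceeds ``m``). ``sd = 0`` or ``mean_utility = 1`` degenerate
    to a point mass.
    """
    if not 0.0 < mean_utility <= 1.0:
        raise ValueError(f"mean_utility must be in (0, 1]; got {mean_utility}")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    m = 1.0 - mean_utility
    if sd == 0.0 or m == 0.0:
        return DistributionSpec("point", (mean_utility,), mean_utility, 0.0)
    shape = (m / sd) ** 2
    rate = m / sd**2
    return DistributionSpec("gamma_disutility", (shape, rate, floor), mean_utility, sd)


def fit_lognormal_count(mean: float, sd: float) -> DistributionSpec:
    """Lognormal fit to a resource-use count by moment matching.

    ``sigma^2 = ln(1 + (sd/mean)^2)``, ``mu = ln(mean) - sigma^2 / 2``, so
    drawn counts have expectation ``mean`` and standard deviation ``sd``.
    A zero mean or zero SD degenerates to a point mass.
    """
    if mean < 0 or sd < 0:
        raise ValueError("mean and sd must be non-negative")
    if mean == 0.0 or sd == 0.0:
        return DistributionSpec("point", (mean,), mean, 0.0)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return DistributionSpec("lognormal", (mu, float(np.sqrt(sigma2))), mean, sd)


def fit_beta_probability(
    mean: float,
    sd: float | None = None,
    interval: tuple[float, float] | None = None,
) -> DistributionSpec:
    """Beta fit to a probability from a mean and SD, or a 95% interval.

    With an SD, method of moments: ``nu = mean(1-mean)/sd^2 - 1``,
    ``alpha = mean * nu``, ``beta = (1-mean) * nu`` (requires
    ``sd^2 < mean(1-mean)``). With only an interval, ``(alpha, beta)`` are
    chosen to minimise the squared deviation of the 2.5% and 97.5% quantiles
    from the supplied bounds, keeping the mean fixed. ``sd = 0`` degenerates
    to a point mass.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean must be in (0, 1); got {mean}")
    if sd is not None:
        if sd < 0:
            raise ValueError("sd must be non-negative")
        if sd == 0.0:
            return DistributionSpec("point", (mean,), mean, 0.0)
        bound = mean * (1.0 - mean)
        if sd**2 >= bound:
            raise ValueError(
                f"infeasible beta sd {sd}: requires sd^2 < mean(1-mean) = {bound:.6g}"
            )
        nu = bound / sd**2 - 1.0
        return DistributionSpec("beta", (mean * nu, (1.0 - mean) * nu), mean, sd)
    if interval is None:
        raise ValueError("either sd or interval is required")
    lo, hi = interval
    if not lo <= mean <= hi:
        raise ValueError(f"interval ({lo}, {hi}) does not bracket the mean {mean}")

    from scipy import optimize, stats

    def residual(log_nu: float) -> float:
        nu = np.exp(log_nu)
        a, b = mean * nu, (1.0 - mean) * nu
        q = stats.beta.ppf([0.025, 0.975], a, b)
        return (q[0] - lo) ** 2 + (q[1] - hi) ** 2

    res = optimize.minimize_scalar(residual, bounds=(-5.0, 15.0), method="bounded")
    nu = float(np.exp(res.x))
    a, b = mean * nu, (1.0 - mean) * nu
    sd_fit = float(np.sqrt(mean * (1.0 - mean) / (nu + 1.0)))
    return DistributionSpec("beta", (a, b), mean, sd_fit)


# ---------------------------------------------------------------------------


def _build_specs(config: ModelConfig):
    """Distribution specs for every uncertain parameter in the configuration."""
    u = config.utilities
    psa = config.psa
    util_specs = [
        fit_gamma_disutility(u.base, psa.utility_gamma_sd, psa.utility_floor),
        fit_gamma_disutility(
            u.base - u.disutility_uncontrolled, psa.utility_gamma_sd, psa.utility_floor
        ),
        fit_gamma_disutility(
            u.base - u.disutility_exacerbation, psa.utility_gamma_sd, psa.utility_floor
        ),
    ]
    count_specs = {
        state: [
            fit_lognormal_count(item.mean, item.sd)
            for item in config.resource_use[state]
        ]
        for state in ALIVE_STATE_NAMES
    }
    matrix_specs = {}
    means, sds = config.transition_matrix.means, config.transition_matrix.sds
    for (i, j), sd in np.ndenumerate(sds):
        if sd > 0:
            matrix_specs[(i, j)] = fit_beta_probability(float(means[i, j]), float(sd))
    return util_specs, count_specs, matrix_specs


def _residual_state(row: int) -> int:
    # rows re-balance on their stay/default state: controlled stays
    # controlled; uncontrolled and exacerbation default to uncontrolled
    return 0 if row == 0 else 1


def _draw_reference_matrix(config: ModelConfig, matrix_specs, rng):
    """One draw of the reference matrix; infeasible rows raise for redraw."""
    P = np.array(config.transition_matrix.means)
    for (i, j), spec in matrix_specs.items():
        P[i, j] = spec.sample(rng)
    for i in range(3):
        # the row rebalances on its stay/default state, so that entry must
        # not carry its own distribution (the fixture leaves stay entries
        # fixed and they absorb the drawn entries' residual)
        res = _residual_state(i)
        others = sum(P[i, j] for j in range(4) if j != res)
        residual = 1.0 - others
        if residual < 0:
            raise InfeasibleParametersError(f"drawn row {i} leaves negative residual")
        P[i, res] = residual
    return P


@dataclass(frozen=True)
class PsaResult:
    """Monte-Carlo samples and summaries.

    ``samples`` has one row per (replicate, strategy) with the drawn total
    cost and QALYs; ``summary`` reports the mean and 2.5–97.5% central range
    per strategy.
    """

    samples: pd.DataFrame
    summary: pd.DataFrame
    seed: int
    n_replicates: int
    n_redraws: int

    def pivot(self, value: str) -> pd.DataFrame:
        return self.samples.pivot(index="replicate", columns="strategy", values=value)


def run_psa(
    config: ModelConfig,
    n: int | None = None,
    seed: int | None = None,
    max_redraw_fraction: float = 0.01,
) -> PsaResult:
    """Monte-Carlo propagation of joint parameter uncertainty.

    Per replicate: draw utilities, resource counts and uncertain
    reference-matrix entries independently, rebuild every strategy's matrix
    and valuation, run the deterministic model and record its cost/QALY
    pair. Replicates whose drawn matrices are infeasible are redrawn (a
    redraw rate above ``max_redraw_fraction`` triggers a warning). Identical
    seeds give identical output.
    """
    if n is None:
        n = config.psa.n_replicates
    if seed is None:
        seed = config.seed
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    util_specs, count_specs, matrix_specs = _build_specs(config)
    strategies = config.strategies
    initial = config.initial_occupancy()
    cycle = config.cycle_length_weeks

    records = []
    n_redraws = 0
    for rep in range(n):
        for attempt in range(1000):
            try:
                drawn_utils = tuple(spec.sample(rng) for spec in util_specs)
                overrides = {
                    state: {
                        item.name: specs_k.sample(rng)
                        for item, specs_k in zip(config.resource_use[state], specs)
                    }
                    for state, specs in count_specs.items()
                }
                ref = _draw_reference_matrix(config, matrix_specs, rng)
                ref_matrix = TransitionMatrix(ref, cycle)
                row = {}
                for s in strategies:
                    matrix = build_strategy_matrix(config, s, ref_matrix)
                    trace = run_trace(matrix, initial, config.n_cycles)
                    valuation = build_state_valuation(
                        config,
                        s,
                        utilities=drawn_utils,
                        count_overrides=overrides,
                        check_ordering=False,
                    )
                    out = accrue(trace, valuation)
                    row[s.name] = (out.total_cost, out.total_qaly)
                break
            except InfeasibleParametersError:
                n_redraws += 1
        else:
            raise InfeasibleParametersError(
                "could not draw a feasible parameter set after 1000 attempts"
            )
        for name, (cost, qaly) in row.items():
            records.append((rep, name, cost, qaly))

    if n_redraws > max_redraw_fraction * n:
        warnings.warn(
            f"PSA redraw rate {n_redraws}/{n} exceeds {max_redraw_fraction:.0%}",
            stacklevel=2,
        )
        logger.warning("PSA redrew %d infeasible replicates out of %d", n_redraws, n)

    samples = pd.DataFrame(records, columns=["replicate", "strategy", "cost", "qaly"])
    rows = []
    for s in strategies:
        sub = samples[samples.strategy == s.name]
        rows.append(
            {
                "strategy": s.name,
                "mean_cost": sub.cost.mean(),
                "cost_lo": sub.cost.quantile(0.025),
                "cost_hi": sub.cost.quantile(0.975),
                "mean_qaly": sub.qaly.mean(),
                "qaly_lo": sub.qaly.quantile(0.025),
                "qaly_hi": sub.qaly.quantile(0.975),
            }
        )
    summary = pd.DataFrame(rows)
    return PsaResult(samples, summary, seed, n, n_redraws)


def ceac(result: PsaResult | pd.DataFrame, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves over a threshold grid.

    For each willingness-to-pay value, each strategy's probability is the
    fraction of replicates in which its net monetary benefit is maximal;
    exact ties are split equally, so probabilities sum to one at every
    threshold.
    """
    samples = result.samples if isinstance(result, PsaResult) else result
    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("wtp grid must be non-empty")
    cost = samples.pivot(index="replicate", columns="strategy", values="cost")
    qaly = samples.pivot(index="replicate", columns="strategy", values="qaly")
    strategies = list(cost.columns)
    C = cost.to_numpy()
    Q = qaly.to_numpy()
    n = C.shape[0]
    probs = np.empty((wtp_grid.size, len(strategies)))
    for k, wtp in enumerate(wtp_grid):
        nmb = wtp * Q - C
        best = nmb.max(axis=1, keepdims=True)
        winners = nmb == best
        probs[k] = (winners / winners.sum(axis=1, keepdims=True)).sum(axis=0) / n
    out = pd.DataFrame(probs, columns=strategies)
    out.insert(0, "wtp", wtp_grid)
    return out
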