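"""Model configuration: schema, strict validation, readers and writers.

A configuration file (YAML or JSON, interchangeable) holds every clinical
parameter of the model: the reference transition matrix (with optional
per-entry standard deviations for probabilistic analysis), the comparator
strategies with their relative effects and inhaler prices, resource-use
profiles per health state, unit costs, utilities, the willingness-to-pay
threshold and grid, scenario settings and the probabilistic-analysis
settings. Validation is strict: unknown keys are rejected, clinical
parameters have no silent defaults, and every violated invariant is
reported with its configuration path.

Matrices are written row-major with state-name keys, never bare indices,
so hand-transcribed published matrices stay auditable.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError
from .markov import N_STATES, STATE_NAMES, HealthState, StrategySpec, TransitionMatrix

__all__ = [
    "ModelConfig",
    "StrategyConfig",
    "ResourceItemConfig",
    "read_config",
    "write_config",
    "config_digest",
]

_STATE_INDEX = {name: i for i, name in enumerate(STATE_NAMES)}
ALIVE_STATE_NAMES = STATE_NAMES[:3]


class _Collector:
    """Accumulates validation messages with their config paths."""

    def __init__(self) -> None:
        self.errors: list[str] = []

    def add(self, path: str, message: str) -> None:
        self.errors.append(f"{path}: {message}")

    def raise_if_any(self) -> None:
        if self.errors:
            raise ConfigError(self.errors)


def _require_keys(d: dict, path: str, required: set, optional: set, errs: _Collector):
    if not isinstance(d, dict):
        errs.add(path, f"expected a mapping, got {type(d).__name__}")
        return False
    unknown = set(d) - required - optional
    for key in sorted(unknown):
        errs.add(f"{path}.{key}", "unknown key (strict schema)")
    missing = required - set(d)
    for key in sorted(missing):
        errs.add(f"{path}.{key}", "required key missing")
    return not unknown and not missing


def _number(d, key, path, errs, lo=None, hi=None, default=None, required=True):
    if key not in d:
        if required:
            return default
        return default
    val = d[key]
    if isinstance(val, bool) or not isinstance(val, (int, float)):
        errs.add(f"{path}.{key}", f"expected a number, got {val!r}")
        return default
    val = float(val)
    if lo is not None and val < lo:
        errs.add(f"{path}.{key}", f"must be >= {lo}, got {val}")
    if hi is not None and val > hi:
        errs.add(f"{path}.{key}", f"must be <= {hi}, got {val}")
    return val


def _interval(d, key, path, errs):
    if key not in d or d[key] is None:
        return None
    iv = d[key]
    if not (isinstance(iv, (list, tuple)) and len(iv) == 2):
        errs.add(f"{path}.{key}", "interval must be a [low, high] pair")
        return None
    lo, hi = float(iv[0]), float(iv[1])
    if lo > hi:
        errs.add(f"{path}.{key}", f"interval low {lo} exceeds high {hi}")
        return None
    return (lo, hi)


@dataclass
class MatrixParam:
    """Reference transition matrix with optional per-entry uncertainty.

    ``means`` is the 4x4 matrix of weekly probabilities; ``sds`` carries the
    standard deviation of each uncertain entry (zero where the entry is
    fixed). Entries omitted in the file are structural zeros.
    """

    means: np.ndarray
    sds: np.ndarray

    def matrix(self, cycle_length_weeks: float = 1.0) -> TransitionMatrix:
        return TransitionMatrix(self.means, cycle_length_weeks)

    @classmethod
    def from_dict(cls, d: dict, path: str, errs: _Collector) -> "MatrixParam":
        means = np.zeros((N_STATES, N_STATES))
        sds = np.zeros((N_STATES, N_STATES))
        if not isinstance(d, dict):
            errs.add(path, "expected a mapping of state-name rows")
            return cls(np.eye(N_STATES), sds)
        for row_name, row in d.items():
            if row_name not in _STATE_INDEX:
                errs.add(f"{path}.{row_name}", f"unknown state (expected {STATE_NAMES})")
                continue
            i = _STATE_INDEX[row_name]
            if not isinstance(row, dict):
                errs.add(f"{path}.{row_name}", "expected a mapping of destinations")
                continue
            for col_name, entry in row.items():
                if col_name not in _STATE_INDEX:
                    errs.add(
                        f"{path}.{row_name}.{col_name}",
                        f"unknown state (expected {STATE_NAMES})",
                    )
                    continue
                j = _STATE_INDEX[col_name]
                cell_path = f"{path}.{row_name}.{col_name}"
                if isinstance(entry, dict):
                    if _require_keys(entry, cell_path, {"mean"}, {"sd"}, errs):
                        means[i, j] = _number(entry, "mean", cell_path, errs, 0.0, 1.0, 0.0)
                        sds[i, j] = _number(
                            entry, "sd", cell_path, errs, 0.0, None, 0.0, required=False
                        ) or 0.0
                elif isinstance(entry, (int, float)) and not isinstance(entry, bool):
                    means[i, j] = float(entry)
                else:
                    errs.add(cell_path, f"expected a number or {{mean, sd}}, got {entry!r}")
        for i, row_name in enumerate(STATE_NAMES):
            total = means[i].sum()
            if abs(total - 1.0) > 1e-6:
                errs.add(f"{path}.{row_name}", f"row sums to {total:.9f}, not 1")
        death = np.zeros(N_STATES)
        death[HealthState.DEATH] = 1.0
        if not np.allclose(means[HealthState.DEATH], death, atol=1e-9):
            errs.add(f"{path}.death", "death row must be the unit vector on death")
        return cls(means, sds)

    def to_dict(self) -> dict:
        out: dict = {}
        for i, row_name in enumerate(STATE_NAMES):
            row: dict = {}
            for j, col_name in enumerate(STATE_NAMES):
                if self.means[i, j] == 0.0 and self.sds[i, j] == 0.0:
                    continue
                if self.sds[i, j] > 0.0:
                    row[col_name] = {
                        "mean": float(self.means[i, j]),
                        "sd": float(self.sds[i, j]),
                    }
                else:
                    row[col_name] = float(self.means[i, j])
            out[row_name] = row
        return out


@dataclass
class StrategyConfig:
    """One comparator: relative effects vs the reference plus inhaler price."""

    name: str
    label: str
    rr_control: float
    rr_exacerbation: float
    device_price: float
    effect_scale: str = "risk_ratio"
    branded: bool = True
    rr_control_interval: tuple[float, float] | None = None
    rr_exacerbation_interval: tuple[float, float] | None = None
    rr_control_random_effects: float | None = None
    rr_exacerbation_random_effects: float | None = None

    _REQUIRED = {"name", "label", "rr_control", "rr_exacerbation", "device_price"}
    _OPTIONAL = {
        "effect_scale",
        "branded",
        "rr_control_interval",
        "rr_exacerbation_interval",
        "rr_control_random_effects",
        "rr_exacerbation_random_effects",
    }

    @classmethod
    def from_dict(cls, d: dict, path: str, errs: _Collector) -> "StrategyConfig | None":
        if not _require_keys(d, path, cls._REQUIRED, cls._OPTIONAL, errs):
            return None
        scale = d.get("effect_scale", "risk_ratio")
        if scale not in ("risk_ratio", "odds_ratio"):
            errs.add(f"{path}.effect_scale", f"must be risk_ratio or odds_ratio, got {scale!r}")
        out = cls(
            name=str(d["name"]),
            label=str(d["label"]),
            rr_control=_number(d, "rr_control", path, errs, 1e-12) or 1.0,
            rr_exacerbation=_number(d, "rr_exacerbation", path, errs, 1e-12) or 1.0,
            device_price=_number(d, "device_price", path, errs, 0.0) or 0.0,
            effect_scale=scale,
            branded=bool(d.get("branded", True)),
            rr_control_interval=_interval(d, "rr_control_interval", path, errs),
            rr_exacerbation_interval=_interval(d, "rr_exacerbation_interval", path, errs),
            rr_control_random_effects=_number(
                d, "rr_control_random_effects", path, errs, 1e-12, required=False
            ),
            rr_exacerbation_random_effects=_number(
                d, "rr_exacerbation_random_effects", path, errs, 1e-12, required=False
            ),
        )
        for label, iv, point in (
            ("rr_control_interval", out.rr_control_interval, out.rr_control),
            ("rr_exacerbation_interval", out.rr_exacerbation_interval, out.rr_exacerbation),
        ):
            if iv is not None and not iv[0] <= point <= iv[1]:
                errs.add(f"{path}.{label}", f"does not bracket the point estimate {point}")
        return out

    def to_dict(self) -> dict:
        out = {
            "name": self.name,
            "label": self.label,
            "rr_control": self.rr_control,
            "rr_exacerbation": self.rr_exacerbation,
            "device_price": self.device_price,
            "effect_scale": self.effect_scale,
            "branded": self.branded,
        }
        for key in (
            "rr_control_interval",
            "rr_exacerbation_interval",
            "rr_control_random_effects",
            "rr_exacerbation_random_effects",
        ):
            val = getattr(self, key)
            if val is not None:
                out[key] = list(val) if isinstance(val, tuple) else val
        return out

    def spec(
        self, random_effects: bool = False, rr_rescale: tuple[float, float] = (1.0, 1.0)
    ) -> StrategySpec:
        """Markov-layer strategy spec, optionally using random-effects ratios.

        ``rr_rescale`` divides both ratios (used when re-referencing the
        analysis to a different baseline strategy).
        """
        rc, re_ = self.rr_control, self.rr_exacerbation
        if random_effects:
            if self.rr_control_random_effects is None or self.rr_exacerbation_random_effects is None:
                raise ConfigError(
                    [f"strategies.{self.name}: random-effects relative effects missing"]
                )
            rc, re_ = self.rr_control_random_effects, self.rr_exacerbation_random_effects
        return StrategySpec(
            name=self.name,
            rr_control=rc / rr_rescale[0],
            rr_exacerbation=re_ / rr_rescale[1],
            effect_scale=self.effect_scale,
            rr_control_interval=self.rr_control_interval if not random_effects else None,
            rr_exacerbation_interval=(
                self.rr_exacerbation_interval if not random_effects else None
            ),
        )


@dataclass
class ResourceItemConfig:
    """A resource item in a state's profile.

    ``cost_source`` is ``"fixed"`` (unit cost given here) or
    ``"strategy_device"`` (unit cost is the strategy's inhaler price).
    """

    name: str
    mean: float
    sd: float
    unit_cost: float | None = None
    cost_source: str = "fixed"

    @classmethod
    def from_dict(cls, d: dict, path: str, errs: _Collector):
        if not _require_keys(d, path, {"name", "mean"}, {"sd", "unit_cost", "cost_source"}, errs):
            return None
        source = d.get("cost_source", "fixed")
        if source not in ("fixed", "strategy_device"):
            errs.add(f"{path}.cost_source", f"must be fixed or strategy_device, got {source!r}")
        unit_cost = _number(d, "unit_cost", path, errs, 0.0, required=False)
        if source == "fixed" and unit_cost is None:
            errs.add(f"{path}.unit_cost", "required when cost_source is fixed")
        return cls(
            name=str(d["name"]),
            mean=_number(d, "mean", path, errs, 0.0) or 0.0,
            sd=_number(d, "sd", path, errs, 0.0, required=False, default=0.0) or 0.0,
            unit_cost=unit_cost,
            cost_source=source,
        )

    def to_dict(self) -> dict:
        out = {"name": self.name, "mean": self.mean, "sd": self.sd}
        if self.unit_cost is not None:
            out["unit_cost"] = self.unit_cost
        if self.cost_source != "fixed":
            out["cost_source"] = self.cost_source
        return out


@dataclass
class UtilityConfig:
    base: float
    disutility_uncontrolled: float
    disutility_exacerbation: float
    base_interval: tuple[float, float] | None = None
    disutility_uncontrolled_interval: tuple[float, float] | None = None
    disutility_exacerbation_interval: tuple[float, float] | None = None

    @classmethod
    def from_dict(cls, d, path, errs):
        required = {"base", "disutility_uncontrolled", "disutility_exacerbation"}
        optional = {
            "base_interval",
            "disutility_uncontrolled_interval",
            "disutility_exacerbation_interval",
        }
        if not _require_keys(d, path, required, optional, errs):
            return None
        return cls(
            base=_number(d, "base", path, errs, 0.0, 1.0) or 0.0,
            disutility_uncontrolled=_number(d, "disutility_uncontrolled", path, errs, 0.0, 1.0)
            or 0.0,
            disutility_exacerbation=_number(d, "disutility_exacerbation", path, errs, 0.0, 1.0)
            or 0.0,
            base_interval=_interval(d, "base_interval", path, errs),
            disutility_uncontrolled_interval=_interval(
                d, "disutility_uncontrolled_interval", path, errs
            ),
            disutility_exacerbation_interval=_interval(
                d, "disutility_exacerbation_interval", path, errs
            ),
        )

    def to_dict(self) -> dict:
        out = {
            "base": self.base,
            "disutility_uncontrolled": self.disutility_uncontrolled,
            "disutility_exacerbation": self.disutility_exacerbation,
        }
        for key in (
            "base_interval",
            "disutility_uncontrolled_interval",
            "disutility_exacerbation_interval",
        ):
            val = getattr(self, key)
            if val is not None:
                out[key] = list(val)
        return out


@dataclass
class ScenarioSettings:
    """Deterministic sensitivity-analysis settings."""

    owsa_utility_delta: float = 0.05
    price_discount_fraction: float = 0.5
    exacerbation_shift_scale: float = 1.5

    @classmethod
    def from_dict(cls, d, path, errs):
        optional = {
            "owsa_utility_delta",
            "price_discount_fraction",
            "exacerbation_shift_scale",
        }
        _require_keys(d, path, set(), optional, errs)
        return cls(
            owsa_utility_delta=_number(
                d, "owsa_utility_delta", path, errs, 0.0, 1.0, 0.05, required=False
            ),
            price_discount_fraction=_number(
                d, "price_discount_fraction", path, errs, 0.0, 0.999999, 0.5, required=False
            ),
            exacerbation_shift_scale=_number(
                d, "exacerbation_shift_scale", path, errs, 0.0, None, 1.5, required=False
            ),
        )

    def to_dict(self) -> dict:
        return {
            "owsa_utility_delta": self.owsa_utility_delta,
            "price_discount_fraction": self.price_discount_fraction,
            "exacerbation_shift_scale": self.exacerbation_shift_scale,
        }


@dataclass
class PsaSettings:
    n_replicates: int = 10000
    utility_gamma_sd: float = 0.2
    utility_floor: float = 0.0

    @classmethod
    def from_dict(cls, d, path, errs):
        optional = {"n_replicates", "utility_gamma_sd", "utility_floor"}
        _require_keys(d, path, set(), optional, errs)
        n = d.get("n_replicates", 10000)
        if not isinstance(n, int) or isinstance(n, bool) or n < 1:
            errs.add(f"{path}.n_replicates", f"must be a positive integer, got {n!r}")
            n = 10000
        return cls(
            n_replicates=n,
            utility_gamma_sd=_number(
                d, "utility_gamma_sd", path, errs, 0.0, None, 0.2, required=False
            ),
            utility_floor=_number(
                d, "utility_floor", path, errs, 0.0, 1.0, 0.0, required=False
            ),
        )

    def to_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "utility_gamma_sd": self.utility_gamma_sd,
            "utility_floor": self.utility_floor,
        }


@dataclass
class ModelConfig:
    """Complete, validated model configuration."""

    name: str
    seed: int
    n_cycles: int
    cycle_length_weeks: float
    initial_state: str
    reference_strategy: str
    transition_matrix: MatrixParam
    strategies: list[StrategyConfig]
    resource_use: dict[str, list[ResourceItemConfig]]
    utilities: UtilityConfig
    wtp_threshold: float
    wtp_grid: list[float]
    drug_devices_per_year: float
    scenarios: ScenarioSettings = field(default_factory=ScenarioSettings)
    psa: PsaSettings = field(default_factory=PsaSettings)
    dose_stratified_strategies: list[StrategyConfig] = field(default_factory=list)
    dose_stratified_replaces: str | None = None
    description: str = ""

    def strategy(self, name: str) -> StrategyConfig:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(f"unknown strategy '{name}'")

    @property
    def strategy_names(self) -> list[str]:
        return [s.name for s in self.strategies]

    def initial_occupancy(self) -> np.ndarray:
        occ = np.zeros(N_STATES)
        occ[_STATE_INDEX[self.initial_state]] = 1.0
        return occ

    def copy(self) -> "ModelConfig":
        return copy.deepcopy(self)

    # -- construction -----------------------------------------------------

    _REQUIRED = {
        "name",
        "seed",
        "model",
        "reference_strategy",
        "transition_matrix",
        "strategies",
        "resource_use",
        "utilities",
        "wtp",
        "drug_costing",
    }
    _OPTIONAL = {"description", "scenarios", "psa", "structural"}

    @classmethod
    def from_dict(cls, raw: dict) -> "ModelConfig":
        errs = _Collector()
        _require_keys(raw, "config", cls._REQUIRED, cls._OPTIONAL, errs)
        if errs.errors:
            errs.raise_if_any()

        model = raw["model"]
        _require_keys(
            model, "config.model", {"n_cycles", "initial_state"}, {"cycle_length_weeks"}, errs
        )
        n_cycles = model.get("n_cycles", 52)
        if not isinstance(n_cycles, int) or n_cycles < 1:
            errs.add("config.model.n_cycles", f"must be a positive integer, got {n_cycles!r}")
            n_cycles = 52
        initial_state = model.get("initial_state", "uncontrolled")
        if initial_state not in STATE_NAMES:
            errs.add("config.model.initial_state", f"unknown state {initial_state!r}")
            initial_state = "uncontrolled"
        cycle_length = _number(
            model, "cycle_length_weeks", "config.model", errs, 1e-9, 52.0, 1.0, required=False
        )

        matrix = MatrixParam.from_dict(raw["transition_matrix"], "config.transition_matrix", errs)

        strategies: list[StrategyConfig] = []
        if not isinstance(raw["strategies"], list) or not raw["strategies"]:
            errs.add("config.strategies", "expected a non-empty list")
        else:
            for k, entry in enumerate(raw["strategies"]):
                s = StrategyConfig.from_dict(entry, f"config.strategies[{k}]", errs)
                if s is not None:
                    strategies.append(s)
        names = [s.name for s in strategies]
        if len(set(names)) != len(names):
            errs.add("config.strategies", "strategy names must be unique")

        reference = raw.get("reference_strategy")
        if reference not in names:
            errs.add("config.reference_strategy", f"{reference!r} is not a configured strategy")
        else:
            ref = next(s for s in strategies if s.name == reference)
            if ref.rr_control != 1.0 or ref.rr_exacerbation != 1.0:
                errs.add(
                    "config.reference_strategy",
                    f"reference strategy '{reference}' must have unit relative effects",
                )

        resource_use: dict[str, list[ResourceItemConfig]] = {}
        ru = raw["resource_use"]
        if _require_keys(ru, "config.resource_use", set(ALIVE_STATE_NAMES), set(), errs):
            for state in ALIVE_STATE_NAMES:
                items = []
                for k, entry in enumerate(ru[state]):
                    item = ResourceItemConfig.from_dict(
                        entry, f"config.resource_use.{state}[{k}]", errs
                    )
                    if item is not None:
                        items.append(item)
                resource_use[state] = items
        else:
            resource_use = {state: [] for state in ALIVE_STATE_NAMES}

        utilities = UtilityConfig.from_dict(raw["utilities"], "config.utilities", errs)
        if utilities is not None:
            base = utilities.base
            for label, du in (
                ("disutility_uncontrolled", utilities.disutility_uncontrolled),
                ("disutility_exacerbation", utilities.disutility_exacerbation),
            ):
                if du > base:
                    errs.add(f"config.utilities.{label}", "deduction exceeds the base utility")
            if utilities.disutility_exacerbation < utilities.disutility_uncontrolled:
                errs.add(
                    "config.utilities",
                    "exacerbation disutility must be >= uncontrolled disutility",
                )
        else:
            utilities = UtilityConfig(0.96, 0.10, 0.20)

        wtp = raw["wtp"]
        _require_keys(wtp, "config.wtp", {"threshold"}, {"grid"}, errs)
        threshold = _number(wtp, "threshold", "config.wtp", errs, 0.0) or 0.0
        grid_spec = wtp.get("grid", {"start": 0, "stop": 50000, "step": 1000})
        if isinstance(grid_spec, list):
            grid = [float(x) for x in grid_spec]
        else:
            _require_keys(grid_spec, "config.wtp.grid", {"start", "stop", "step"}, set(), errs)
            start = _number(grid_spec, "start", "config.wtp.grid", errs, 0.0, default=0.0)
            stop = _number(grid_spec, "stop", "config.wtp.grid", errs, 0.0, default=50000.0)
            step = _number(grid_spec, "step", "config.wtp.grid", errs, 1e-9, default=1000.0)
            grid = list(np.arange(start, stop + step / 2, step))
        if not grid:
            errs.add("config.wtp.grid", "grid must be non-empty")

        drug = raw["drug_costing"]
        _require_keys(drug, "config.drug_costing", {"devices_per_year"}, set(), errs)
        devices = _number(drug, "devices_per_year", "config.drug_costing", errs, 0.0, default=12.0)

        scenarios = ScenarioSettings.from_dict(
            raw.get("scenarios", {}), "config.scenarios", errs
        )
        psa = PsaSettings.from_dict(raw.get("psa", {}), "config.psa", errs)

        dose_strats: list[StrategyConfig] = []
        dose_replaces = None
        if "structural" in raw:
            st = raw["structural"]
            _require_keys(
                st,
                "config.structural",
                set(),
                {"dose_stratified_replaces", "dose_stratified_strategies"},
                errs,
            )
            dose_replaces = st.get("dose_stratified_replaces")
            for k, entry in enumerate(st.get("dose_stratified_strategies", [])):
                s = StrategyConfig.from_dict(
                    entry, f"config.structural.dose_stratified_strategies[{k}]", errs
                )
                if s is not None:
                    dose_strats.append(s)
            if dose_replaces is not None and dose_replaces not in names:
                errs.add(
                    "config.structural.dose_stratified_replaces",
                    f"{dose_replaces!r} is not a configured strategy",
                )

        seed = raw.get("seed")
        if not isinstance(seed, int) or isinstance(seed, bool):
            errs.add("config.seed", f"must be an integer, got {seed!r}")
            seed = 0

        errs.raise_if_any()
        return cls(
            name=str(raw["name"]),
            description=str(raw.get("description", "")),
            seed=seed,
            n_cycles=n_cycles,
            cycle_length_weeks=cycle_length,
            initial_state=initial_state,
            reference_strategy=reference,
            transition_matrix=matrix,
            strategies=strategies,
            resource_use=resource_use,
            utilities=utilities,
            wtp_threshold=threshold,
            wtp_grid=grid,
            drug_devices_per_year=devices,
            scenarios=scenarios,
            psa=psa,
            dose_stratified_strategies=dose_strats,
            dose_stratified_replaces=dose_replaces,
        )

    def to_dict(self) -> dict:
        out = {
            "name": self.name,
            "description": self.description,
            "seed": self.seed,
            "model": {
                "n_cycles": self.n_cycles,
                "cycle_length_weeks": self.cycle_length_weeks,
                "initial_state": self.initial_state,
            },
            "reference_strategy": self.reference_strategy,
            "transition_matrix": self.transition_matrix.to_dict(),
            "strategies": [s.to_dict() for s in self.strategies],
            "resource_use": {
                state: [item.to_dict() for item in items]
                for state, items in self.resource_use.items()
            },
            "utilities": self.utilities.to_dict(),
            "wtp": {"threshold": self.wtp_threshold, "grid": [float(x) for x in self.wtp_grid]},
            "drug_costing": {"devices_per_year": self.drug_devices_per_year},
            "scenarios": self.scenarios.to_dict(),
            "psa": self.psa.to_dict(),
        }
        if self.dose_stratified_strategies:
            out["structural"] = {
                "dose_stratified_replaces": self.dose_stratified_replaces,
                "dose_stratified_strategies": [
                    s.to_dict() for s in self.dose_stratified_strategies
                ],
            }
        return out


def read_config(path: str | Path) -> ModelConfig:
    """Read and validate a YAML or JSON model configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError([f"{path}: top level must be a mapping"])
    return ModelConfig.from_dict(raw)


def write_config(config: ModelConfig, path: str | Path) -> None:
    """Write a configuration back to YAML or JSON (by file extension)."""
    path = Path(path)
    data = config.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def config_digest(config: ModelConfig) -> str:
    """Content hash (sha256 hex) of the canonical configuration dump."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
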