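"""Packaged data: the example configuration and published result surfaces."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .config import ModelConfig, read_config

__all__ = [
    "example_config_path",
    "load_example_config",
    "load_published_base_case",
]


def _data_path(name: str) -> Path:
    return Path(resources.files("asthmace").joinpath("data", name))


def example_config_path() -> Path:
    """Path of the packaged example configuration.

    The example encodes the published resource-use counts, unit costs,
    inhaler prices and utilities of the paediatric-asthma step-up decision
    problem verbatim, with synthetic placeholder transition parameters (the
    published matrices are in an untranscribed supplementary appendix).
    """
    return _data_path("einstein_synthetic.yaml")


def load_example_config() -> ModelConfig:
    return read_config(example_config_path())


def load_published_base_case() -> pd.DataFrame:
    """Published base-case (cost, effect) pairs per strategy and effect block.

    Columns: ``block`` (qaly, controlled_days, exacerbation_free_days),
    ``strategy``, ``cost`` (GBP), ``effect``. These are printed, rounded
    values; they verify incremental arithmetic, not ratio-of-rounded ICERs.
    """
    return pd.read_csv(_data_path("published_base_case.csv"), comment="#")
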