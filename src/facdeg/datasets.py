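"""Bundled example datasets (plain-text fixtures shipped with the package)."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np

from facdeg.design import Factor, FactorialDesign
from facdeg.io import read_design_csv, read_factors, read_recovery_csv

__all__ = [
    "alkali_factors",
    "load_alkali_design",
    "load_recovery_panels",
    "data_path",
]


def data_path(name: str) -> Path:
    """Filesystem path of a bundled data file."""
    return Path(str(resources.files("facdeg").joinpath("data", name)))


def alkali_factors() -> list[Factor]:
    """The three stress factors of the alkali degradation study.

    NaOH normality 0.1-1.0 N, irradiation time 15-30 min, microwave
    power 420-700 W.
    """
    return read_factors(data_path("alkali_factors.yaml"))


def load_alkali_design() -> FactorialDesign:
    """The 8-run alkali degradation design with observed % degradation."""
    return read_design_csv(data_path("alkali_design.csv"), alkali_factors())


def load_recovery_panels() -> dict[float, np.ndarray]:
    """Recovery panels (3 days x 3 replicates) at 80, 100 and 120 mg."""
    return read_recovery_csv(data_path("recovery.csv"))
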