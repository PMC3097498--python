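"""Synthetic data generators matching the structure the analyses assume.

Three generators, all seed-deterministic and Gaussian by default:

* factorial responses — a factorial polynomial evaluated at the coded
  runs plus i.i.d. noise;
* recovery panels — a true level plus a per-day random effect plus
  within-day noise (the nested structure of the precision ANOVA);
* calibration standards — a straight line plus noise.

Zero-noise limits reduce each generator to its deterministic model, so
every downstream stage can be tested without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from facdeg.design import FactorialDesign
from facdeg.effects import Term, all_terms, parse_term_label, term_column

__all__ = [
    "SimulationSpec",
    "RecoverySimSpec",
    "simulate_factorial_responses",
    "simulate_recovery_panel",
    "simulate_calibration",
    "DEFAULT_CAL_SLOPE",
    "DEFAULT_CAL_INTERCEPT",
]

#: Default calibration line parameters (detector area per ug/mL, area offset).
DEFAULT_CAL_SLOPE = 601211.0
DEFAULT_CAL_INTERCEPT = 41127.0


def _normalize_terms(coefficients: Mapping[Term | str, float]) -> dict[Term, float]:
    out: dict[Term, float] = {}
    for key, val in coefficients.items():
        term = parse_term_label(key) if isinstance(key, str) else tuple(sorted(key))
        if term in out:
            raise ValueError(f"duplicate term {key!r} in true coefficients")
        out[term] = float(val)
    return out


@dataclass(frozen=True)
class SimulationSpec:
    """True factorial model plus noise level for response simulation."""

    true_coefficients: Mapping[Term | str, float]
    noise_sd: float = 0.0
    seed: int = 0
    n_designs: int = 1
    clip_at_zero: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "true_coefficients", _normalize_terms(self.true_coefficients))
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_designs < 1:
            raise ValueError("n_designs must be >= 1")


@dataclass(frozen=True)
class RecoverySimSpec:
    """Day-nested recovery generator: level + day effect + replicate noise."""

    true_level: float
    between_day_sd: float = 0.0
    within_day_sd: float = 0.0
    n_days: int = 3
    n_reps: int = 3
    seed: int = 0
    clip_at_zero: bool = False

    def __post_init__(self) -> None:
        if self.between_day_sd < 0 or self.within_day_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_days < 2 or self.n_reps < 2:
            raise ValueError("need >= 2 days and >= 2 replicates")


def simulate_factorial_responses(spec: SimulationSpec, design: FactorialDesign) -> np.ndarray:
    """Simulate responses ``y = sum(coef * term column) + N(0, noise_sd)``.

    Returns a vector of length 2^k, or an (n_designs, 2^k) matrix when
    the spec asks for replicate designs. Reproducible per seed.
    """
    universe = set(all_terms(design.k))
    coefs = dict(spec.true_coefficients)
    bad = [t for t in coefs if t not in universe]
    if bad:
        raise ValueError(f"terms outside the design's term universe: {bad}")
    mean = np.zeros(design.n_runs)
    for term, c in coefs.items():
        mean += c * term_column(design.runs, term)
    rng = np.random.default_rng(spec.seed)
    out = mean[None, :] + rng.normal(0.0, spec.noise_sd, size=(spec.n_designs, design.n_runs))
    if spec.clip_at_zero:
        out = np.clip(out, 0.0, None)
    return out[0] if spec.n_designs == 1 else out


def simulate_recovery_panel(spec: RecoverySimSpec) -> np.ndarray:
    """Simulate a days x replicates recovery matrix.

    ``value[d, r] = true_level + DayEffect[d] + eps[d, r]`` with
    DayEffect ~ N(0, between_day_sd^2) and eps ~ N(0, within_day_sd^2).
    """
    rng = np.random.default_rng(spec.seed)
    day_effects = rng.normal(0.0, spec.between_day_sd, size=spec.n_days)
    eps = rng.normal(0.0, spec.within_day_sd, size=(spec.n_days, spec.n_reps))
    out = spec.true_level + day_effects[:, None] + eps
    if spec.clip_at_zero:
        out = np.clip(out, 0.0, None)
    return out


def simulate_calibration(
    concentrations: Sequence[float],
    slope: float = DEFAULT_CAL_SLOPE,
    intercept: float = DEFAULT_CAL_INTERCEPT,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate (concentration, area) calibration pairs around a line."""
    c = np.asarray(concentrations, dtype=float)
    if c.size == 0:
        raise ValueError("concentrations must be nonempty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    areas = slope * c + intercept + rng.normal(0.0, noise_sd, size=c.shape)
    return c, areas
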