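"""Two-level full factorial designs and coded-level transforms.

A design holds k factors, each with an actual low/high level, and the
2^k run matrix in coded units where low maps to -1 and high to +1.
Coded entries are stored as exact integers so that all factorial
contrasts are computed in integer arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "MAX_FACTORS",
    "Factor",
    "FactorialDesign",
    "build_full_factorial",
    "code_value",
    "decode_value",
    "attach_responses",
    "standard_order_runs",
]

#: Upper bound on k; a 2^k design grows exponentially.
MAX_FACTORS = 10


@dataclass(frozen=True)
class Factor:
    """A controllable variable with named low/high actual levels.

    Parameters
    ----------
    name : str
        Factor identifier; must be nonempty and unique within a design.
    low, high : float
        Actual-unit settings mapped to coded -1 and +1. Requires low < high.
    units : str, optional
        Unit label used in reports (e.g. ``"N"``, ``"min"``, ``"W"``).
    """

    name: str
    low: float
    high: float
    units: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("factor name must be nonempty")
        if not (self.low < self.high):
            raise ValueError(
                f"factor {self.name!r}: low ({self.low}) must be strictly below high ({self.high})"
            )

    @property
    def midpoint(self) -> float:
        """Average of the two levels (decodes from coded 0)."""
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        """Half the difference of the levels (coded-unit scale)."""
        return 0.5 * (self.high - self.low)


def code_value(actual: float, factor: Factor) -> float:
    """Map an actual-unit setting to coded units.

    ``coded = (actual - midpoint) / half_range``; the low level codes to
    -1 and the high level to +1. Values outside [low, high] are allowed
    (they code outside [-1, +1]); callers decide whether to flag them.
    """
    return (actual - factor.midpoint) / factor.half_range


def decode_value(coded: float, factor: Factor) -> float:
    """Exact inverse of :func:`code_value`: coded units back to actual."""
    return coded * factor.half_range + factor.midpoint


def standard_order_runs(k: int) -> np.ndarray:
    """Coded run matrix of the 2^k design in standard (Yates) order.

    Column j (0-based) alternates sign in blocks of 2^j, so the first
    column alternates fastest. Entries are exact integers in {-1, +1}.
    """
    m = np.arange(2**k)
    bits = (m[:, None] >> np.arange(k)[None, :]) & 1
    return np.where(bits == 1, 1, -1).astype(np.int64)


@dataclass(frozen=True)
class FactorialDesign:
    """A 2^k coded run matrix with optionally attached responses.

    Attributes
    ----------
    factors : tuple of Factor
    runs : ndarray of int, shape (2^k, k)
        Coded levels, entries in {-1, +1}.
    responses : ndarray of float or None
        One response per run (same order as ``runs``).
    order_tag : {"standard", "user"}
    """

    factors: tuple[Factor, ...]
    runs: np.ndarray
    responses: np.ndarray | None = None
    order_tag: str = "standard"

    def __post_init__(self) -> None:
        factors = tuple(self.factors)
        object.__setattr__(self, "factors", factors)
        names = [f.name for f in factors]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate factor names: {sorted(names)}")
        runs = np.asarray(self.runs)
        k = len(factors)
        if runs.shape != (2**k, k):
            raise ValueError(f"run matrix must be {2**k} x {k}, got {runs.shape}")
        if not np.isin(runs, (-1, 1)).all():
            raise ValueError("coded run matrix entries must be -1 or +1")
        object.__setattr__(self, "runs", runs.astype(np.int64))
        if self.responses is not None:
            resp = np.asarray(self.responses, dtype=float)
            if resp.shape != (2**k,):
                raise ValueError(f"responses must have length {2**k}, got shape {resp.shape}")
            if not np.all(np.isfinite(resp)):
                raise ValueError("responses must be finite")
            object.__setattr__(self, "responses", resp)

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def n_runs(self) -> int:
        return self.runs.shape[0]

    def factor_index(self, name: str) -> int:
        for i, f in enumerate(self.factors):
            if f.name == name:
                return i
        raise KeyError(f"no factor named {name!r}")

    def actual_levels(self) -> np.ndarray:
        """Run matrix decoded to actual units, shape (2^k, k)."""
        out = np.empty(self.runs.shape, dtype=float)
        for j, f in enumerate(self.factors):
            out[:, j] = decode_value(self.runs[:, j].astype(float), f)  # type: ignore[arg-type]
        return out


def build_full_factorial(factors: Sequence[Factor]) -> FactorialDesign:
    """Construct the full 2^k design in standard (Yates) order.

    Parameters
    ----------
    factors : sequence of Factor
        Between 1 and ``MAX_FACTORS`` factors with unique names.

    Returns
    -------
    FactorialDesign
        All 2^k level combinations, no responses attached.
    """
    k = len(factors)
    if not 1 <= k <= MAX_FACTORS:
        raise ValueError(f"number of factors must be in [1, {MAX_FACTORS}], got {k}")
    return FactorialDesign(factors=tuple(factors), runs=standard_order_runs(k))


def attach_responses(design: FactorialDesign, responses: Sequence[float]) -> FactorialDesign:
    """Return a copy of ``design`` with responses bound, order preserved."""
    resp = np.asarray(responses, dtype=float)
    if resp.shape != (design.n_runs,):
        raise ValueError(f"expected {design.n_runs} responses, got shape {resp.shape}")
    if not np.all(np.isfinite(resp)):
        raise ValueError("responses must be finite")
    return replace(design, responses=resp)
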