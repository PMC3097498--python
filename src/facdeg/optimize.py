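"""Closed-form inversion of a fitted factorial model to a target response.

A two-level factorial polynomial is linear in each coordinate once the
others are fixed, so the setting of one factor that achieves a target
response has the closed form

    x_solve = (target - sum of terms without the factor)
              / (sum of coefficients of terms containing the factor,
                 evaluated at the fixed coordinates)

Every emitted solution is verified by back-substitution through the
model; the denominator above is formed from the model's own terms (an
inversion printed elsewhere with a different denominator is not an
algebraic rearrangement of the reduced model and is deliberately not
reproduced).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from facdeg.design import decode_value
from facdeg.effects import ExtrapolationWarning, FactorialModel, predict

__all__ = [
    "BACKSUB_TOL",
    "ContourSolution",
    "Recommendation",
    "NoSolutionError",
    "TargetUnreachableError",
    "solve_for_factor",
    "contour_grid",
    "recommend_conditions",
]

#: Absolute tolerance for the back-substitution consistency check.
BACKSUB_TOL = 1e-9


class NoSolutionError(ValueError):
    """The response surface is parallel to the solved factor's axis."""


class TargetUnreachableError(ValueError):
    """No solution exists inside the coded design space [-1, +1]^k."""


@dataclass(frozen=True)
class ContourSolution:
    """One point on a constant-response contour.

    ``ok`` is False for grid rows where no solution exists (degenerate
    denominator); such rows carry NaN coded/actual values and a note.
    """

    target_y: float
    fixed_coords: dict[str, float]
    solved_factor: str
    solved_coded: float
    solved_actual: float
    units: str
    in_design_space: bool
    ok: bool = True
    note: str = ""


@dataclass(frozen=True)
class Recommendation:
    """Decoded operating conditions predicted to hit a target response."""

    settings: tuple[tuple[str, float, float, str], ...]  # (name, coded, actual, units)
    predicted_y: float
    solution: ContourSolution

    def as_dict(self) -> dict:
        return {
            "predicted_response": self.predicted_y,
            "settings": [
                {"factor": n, "coded": c, "actual": a, "units": u}
                for n, c, a, u in self.settings
            ],
        }


def _assemble_point(model: FactorialModel, coords: Mapping[str, float]) -> np.ndarray:
    x = np.zeros(model.k)
    for name, v in coords.items():
        x[model.factor_index(name)] = float(v)
    return x


def _quiet_predict(model: FactorialModel, point: np.ndarray) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ExtrapolationWarning)
        return predict(model, point)


def solve_for_factor(
    model: FactorialModel,
    target_y: float,
    fixed: Mapping[str, float],
    solve_name: str,
    *,
    check_tol: float = BACKSUB_TOL,
) -> ContourSolution:
    """Solve one factor's coded setting so the model predicts ``target_y``.

    Parameters
    ----------
    model : FactorialModel
    target_y : float
        Desired predicted response.
    fixed : mapping name -> coded value
        Coordinates held fixed; factors absent from both ``fixed`` and
        ``solve_name`` sit at the design center (coded 0).
    solve_name : str
        Factor to solve for; must appear in at least one model term.

    Returns
    -------
    ContourSolution
        Verified by back-substitution to within ``check_tol``.

    Raises
    ------
    NoSolutionError
        If the effective coefficient of the solved factor is ~0 at the
        fixed coordinates (contour parallel to that axis).
    """
    solve_idx = model.factor_index(solve_name)
    if solve_name in fixed:
        raise ValueError(f"factor {solve_name!r} cannot be both fixed and solved")
    if not any(solve_idx in t for t in model.terms):
        raise NoSolutionError(f"factor {solve_name!r} does not appear in any model term")
    for name in fixed:
        model.factor_index(name)  # raises KeyError for unknown names

    x = _assemble_point(model, fixed)
    base = 0.0
    denom = 0.0
    for t, c in zip(model.terms, model.coefficients):
        if solve_idx in t:
            others = [i for i in t if i != solve_idx]
            denom += c * (np.prod(x[others]) if others else 1.0)
        else:
            base += c * (np.prod(x[list(t)]) if t else 1.0)
    if abs(denom) < 1e-12:
        raise NoSolutionError(
            f"response surface is flat along {solve_name!r} at the fixed coordinates "
            f"(effective coefficient {denom:.3g})"
        )
    solved = (float(target_y) - base) / denom

    x[solve_idx] = solved
    y_check = _quiet_predict(model, x)
    if not math.isclose(y_check, float(target_y), abs_tol=check_tol, rel_tol=0.0):
        raise AssertionError(
            f"back-substitution failed: predicted {y_check!r} vs target {target_y!r}"
        )
    factor = model.factors[solve_idx]
    coords_used = {**{n: float(v) for n, v in fixed.items()}}
    in_space = bool(abs(solved) <= 1.0 + 1e-12 and all(abs(v) <= 1.0 + 1e-12 for v in coords_used.values()))
    return ContourSolution(
        target_y=float(target_y),
        fixed_coords=coords_used,
        solved_factor=solve_name,
        solved_coded=solved,
        solved_actual=decode_value(solved, factor),
        units=factor.units,
        in_design_space=in_space,
    )


def contour_grid(
    model: FactorialModel,
    targets: Sequence[float],
    sweep_factor: str,
    sweep_values: Sequence[float],
    solve_factor: str,
    fixed: Mapping[str, float] | None = None,
) -> list[ContourSolution]:
    """Tabulate constant-response contours over a sweep grid.

    One row per (target, sweep value) pair; rows where the contour is
    parallel to the solved axis are flagged (``ok=False``), not dropped.
    """
    targets = list(targets)
    sweep_values = list(sweep_values)
    if not targets:
        raise ValueError("targets must be nonempty")
    if not sweep_values:
        raise ValueError("sweep_values must be nonempty")
    base_fixed = dict(fixed or {})
    factor = model.factors[model.factor_index(solve_factor)]
    rows: list[ContourSolution] = []
    for y in targets:
        for v in sweep_values:
            coords = {**base_fixed, sweep_factor: float(v)}
            try:
                rows.append(solve_for_factor(model, y, coords, solve_factor))
            except NoSolutionError as exc:
                rows.append(
                    ContourSolution(
                        target_y=float(y),
                        fixed_coords=coords,
                        solved_factor=solve_factor,
                        solved_coded=float("nan"),
                        solved_actual=float("nan"),
                        units=factor.units,
                        in_design_space=False,
                        ok=False,
                        note=str(exc),
                    )
                )
    return rows


def recommend_conditions(
    model: FactorialModel,
    target_y: float,
    fixed: Mapping[str, float] | None = None,
    solve: str | None = None,
    allow_extrapolation: bool = False,
) -> Recommendation:
    """Return decoded operating conditions that hit ``target_y``.

    Factors named in ``fixed`` are pinned at the given coded values; of
    the remaining factors that enter the model, the one with the largest
    absolute main-effect coefficient is solved for (override with
    ``solve``) and the rest sit at the design center. By default a
    solution with any coordinate outside [-1, +1] is refused.
    """
    fixed = dict(fixed or {})
    used = {i for t in model.terms for i in t}
    free = [model.factors[i].name for i in sorted(used) if model.factors[i].name not in fixed]
    if solve is None:
        if not free:
            raise ValueError("all model factors are fixed; nothing to solve for")

        def main_coef(name: str) -> float:
            t = (model.factor_index(name),)
            return abs(model.coefficients[model.terms.index(t)]) if t in model.terms else 0.0

        solve = max(free, key=main_coef)
    coords = dict(fixed)
    for name in free:
        if name != solve:
            coords.setdefault(name, 0.0)
    sol = solve_for_factor(model, target_y, coords, solve)
    if not sol.in_design_space and not allow_extrapolation:
        raise TargetUnreachableError(
            f"target {target_y} requires {sol.solved_factor}={sol.solved_coded:.4f} (coded), "
            "outside the design space [-1, +1]; pass allow_extrapolation=True to accept"
        )
    full = dict(coords)
    full[solve] = sol.solved_coded
    settings = tuple(
        (f.name, float(full.get(f.name, 0.0)), decode_value(float(full.get(f.name, 0.0)), f), f.units)
        for f in model.factors
    )
    point = _assemble_point(model, full)
    return Recommendation(settings=settings, predicted_y=_quiet_predict(model, point), solution=sol)
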