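"""File readers/writers for the CSV/JSON/YAML dialects the CLI speaks.

Dialects (all plain text):

* factor config — YAML or JSON list of ``{name, low, high, units}``;
* design CSV — ``run,<factor1>,...,<factork>[,response]`` with factor
  columns in actual units (or coded ±1 with ``coded=True``); rows in any
  order, permuted to standard order on load;
* model JSON — ``{"factors": [...], "terms": [...], "coefficients": [...]}``;
* recovery CSV — ``level_mg,day,replicate,amount_found_mg``;
* calibration CSV — ``concentration_ug_ml,peak_area``.

Round trips are lossless at full float precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from facdeg.design import Factor, FactorialDesign, code_value, standard_order_runs
from facdeg.effects import FactorialModel, parse_term_label, term_label
from facdeg.optimize import ContourSolution

__all__ = [
    "read_factors",
    "write_factors",
    "read_design_csv",
    "write_design_csv",
    "read_model_json",
    "write_model_json",
    "read_recovery_csv",
    "write_recovery_csv",
    "read_calibration_csv",
    "write_calibration_csv",
    "write_contour_csv",
]


class FormatError(ValueError):
    """A file does not match its documented dialect."""


def read_factors(path: str | Path) -> list[Factor]:
    """Load a factor config (YAML or JSON by extension)."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(raw, list) or not raw:
        raise FormatError(f"{path}: expected a nonempty list of factor mappings")
    factors = []
    for i, item in enumerate(raw):
        if not isinstance(item, dict) or not {"name", "low", "high"} <= set(item):
            raise FormatError(f"{path}: entry {i} must have keys name, low, high")
        factors.append(
            Factor(
                name=str(item["name"]),
                low=float(item["low"]),
                high=float(item["high"]),
                units=str(item.get("units", "")),
            )
        )
    return factors


def write_factors(factors: Sequence[Factor], path: str | Path) -> None:
    payload = [{"name": f.name, "low": f.low, "high": f.high, "units": f.units} for f in factors]
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def _numeric_column(frame: pd.DataFrame, column: str, path: Path) -> np.ndarray:
    parsed = pd.to_numeric(frame[column], errors="coerce")
    bad = parsed.index[parsed.isna() & frame[column].notna()]
    if len(bad):
        # +2: 1-based data rows under a header line
        raise FormatError(
            f"{path}: non-numeric value {frame[column][bad[0]]!r} in column "
            f"{column!r} at row {bad[0] + 2}"
        )
    if parsed.isna().any():
        row = int(parsed.index[parsed.isna()][0]) + 2
        raise FormatError(f"{path}: missing value in column {column!r} at row {row}")
    return parsed.to_numpy(dtype=float)


def read_design_csv(
    path: str | Path, factors: Sequence[Factor], coded: bool = False
) -> FactorialDesign:
    """Load a design CSV and return it permuted to standard order.

    Factor columns are matched by name; actual-unit values are coded on
    load (``coded=True`` accepts ±1 columns directly). All 2^k level
    combinations must be present exactly once.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [f.name for f in factors if f.name not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing factor column(s) {missing}; found {list(frame.columns)}")
    k = len(factors)
    n = 2**k
    if len(frame) != n:
        raise FormatError(f"{path}: expected {n} runs for k={k}, found {len(frame)}")
    coded_cols = np.empty((n, k), dtype=np.int64)
    for j, f in enumerate(factors):
        vals = _numeric_column(frame, f.name, path)
        col = vals if coded else np.array([code_value(v, f) for v in vals])
        rounded = np.rint(col)
        if not np.allclose(col, rounded, atol=1e-9) or not np.isin(rounded, (-1, 1)).all():
            kind = "coded" if coded else f"actual (levels {f.low}/{f.high})"
            raise FormatError(
                f"{path}: column {f.name!r} has values off the two {kind} levels"
            )
        coded_cols[:, j] = rounded.astype(np.int64)

    # permute user order to standard order; row index = binary code of +1 bits
    idx = ((coded_cols == 1) << np.arange(k)[None, :]).sum(axis=1)
    if sorted(idx) != list(range(n)):
        raise FormatError(f"{path}: runs do not cover every level combination exactly once")
    order = np.argsort(idx)
    responses = None
    if "response" in frame.columns:
        responses = _numeric_column(frame, "response", path)[order]
    design = FactorialDesign(
        factors=tuple(factors),
        runs=standard_order_runs(k),
        responses=responses,
        order_tag="standard",
    )
    return design


def write_design_csv(design: FactorialDesign, path: str | Path, actual: bool = True) -> None:
    """Write a design CSV (actual units by default, coded with ``actual=False``)."""
    cols: dict[str, object] = {"run": np.arange(1, design.n_runs + 1)}
    levels = design.actual_levels() if actual else design.runs
    for j, f in enumerate(design.factors):
        cols[f.name] = levels[:, j]
    if design.responses is not None:
        cols["response"] = design.responses
    pd.DataFrame(cols).to_csv(path, index=False)


def write_model_json(model: FactorialModel, path: str | Path) -> None:
    payload = {
        "factors": [
            {"name": f.name, "low": f.low, "high": f.high, "units": f.units}
            for f in model.factors
        ],
        "terms": [term_label(t) for t in model.terms],
        "coefficients": [float(c) for c in model.coefficients],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_model_json(path: str | Path) -> FactorialModel:
    raw = json.loads(Path(path).read_text())
    try:
        factors = tuple(
            Factor(name=f["name"], low=f["low"], high=f["high"], units=f.get("units", ""))
            for f in raw["factors"]
        )
        terms = tuple(parse_term_label(lbl) for lbl in raw["terms"])
        coefs = np.asarray(raw["coefficients"], dtype=float)
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: malformed model JSON ({exc})") from exc
    return FactorialModel(factors=factors, terms=terms, coefficients=coefs)


def read_recovery_csv(path: str | Path) -> dict[float, np.ndarray]:
    """Load recovery data into {spike level: days x replicates matrix}.

    Requires a balanced layout per level: every (day, replicate) cell
    present exactly once.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    required = ["level_mg", "day", "replicate", "amount_found_mg"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; found {list(frame.columns)}")
    for col in required:
        _numeric_column(frame, col, path)
    panels: dict[float, np.ndarray] = {}
    for level, grp in frame.groupby("level_mg", sort=True):
        days = sorted(grp["day"].unique())
        reps = sorted(grp["replicate"].unique())
        mat = np.full((len(days), len(reps)), np.nan)
        for _, row in grp.iterrows():
            d = days.index(row["day"])
            r = reps.index(row["replicate"])
            if not np.isnan(mat[d, r]):
                raise FormatError(
                    f"{path}: duplicate cell for level {level}, day {row['day']}, "
                    f"replicate {row['replicate']}"
                )
            mat[d, r] = row["amount_found_mg"]
        if np.isnan(mat).any():
            raise FormatError(f"{path}: level {level} is not a balanced days x replicates panel")
        panels[float(level)] = mat
    return panels


def write_recovery_csv(panels: dict[float, np.ndarray], path: str | Path) -> None:
    rows = []
    for level in sorted(panels):
        mat = np.asarray(panels[level])
        for d in range(mat.shape[0]):
            for r in range(mat.shape[1]):
                rows.append(
                    {
                        "level_mg": level,
                        "day": d + 1,
                        "replicate": r + 1,
                        "amount_found_mg": mat[d, r],
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_calibration_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    frame = pd.read_csv(path)
    for col in ("concentration_ug_ml", "peak_area"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing column {col!r}; found {list(frame.columns)}")
    return (
        _numeric_column(frame, "concentration_ug_ml", path),
        _numeric_column(frame, "peak_area", path),
    )


def write_calibration_csv(
    concentrations: np.ndarray, areas: np.ndarray, path: str | Path
) -> None:
    pd.DataFrame({"concentration_ug_ml": concentrations, "peak_area": areas}).to_csv(
        path, index=False
    )


def write_contour_csv(solutions: Sequence[ContourSolution], path: str | Path) -> None:
    rows = []
    for s in solutions:
        row = {
            "target_y": s.target_y,
            **{f"fixed_{k}": v for k, v in sorted(s.fixed_coords.items())},
            "solved_factor": s.solved_factor,
            "solved_coded": s.solved_coded,
            "solved_actual": s.solved_actual,
            "units": s.units,
            "in_design_space": s.in_design_space,
            "ok": s.ok,
            "note": s.note,
        }
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
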