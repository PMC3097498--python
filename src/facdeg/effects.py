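"""Factorial effect estimation, Yates algorithm, and significance screening.

For a saturated ±1-coded 2^k design the 2^k model terms (intercept, main
effects and all interactions) form an orthogonal basis, so each
coefficient is a simple contrast: beta_T = sum(prod(x_i, i in T) * y) / n.
The Yates pairwise algorithm produces the same contrasts in one sweep per
factor. Significance in an unreplicated design is judged against an error
mean square pooled from presumed-inert terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from facdeg.design import Factor, FactorialDesign

__all__ = [
    "Term",
    "all_terms",
    "term_label",
    "parse_term_label",
    "term_column",
    "model_matrix",
    "FactorialModel",
    "EffectScreen",
    "ExtrapolationWarning",
    "estimate_coefficients",
    "yates_algorithm",
    "screen_effects",
    "default_pool",
    "reduce_model",
    "predict",
]

#: A model term: sorted tuple of 0-based factor indices; () is the intercept.
Term = tuple[int, ...]


class ExtrapolationWarning(UserWarning):
    """Prediction requested outside the coded design cube [-1, +1]^k."""


def all_terms(k: int) -> list[Term]:
    """All 2^k terms in standard (binary-counting) order.

    For k=3: (), (0,), (1,), (0,1), (2,), (0,2), (1,2), (0,1,2) — the
    order in which the Yates algorithm emits contrasts.
    """
    return [tuple(j for j in range(k) if (m >> j) & 1) for m in range(2**k)]


def term_label(term: Term) -> str:
    """Human-readable label: ``"1"`` for the intercept, else e.g. ``"X2X3"``."""
    return "1" if not term else "".join(f"X{i + 1}" for i in term)


def parse_term_label(label: str) -> Term:
    """Inverse of :func:`term_label` (1-based X-labels to 0-based indices)."""
    if label == "1":
        return ()
    import re

    parts = re.findall(r"X(\d+)", label)
    if not parts or "".join(f"X{p}" for p in parts) != label:
        raise ValueError(f"malformed term label {label!r}")
    idx = tuple(sorted(int(p) - 1 for p in parts))
    if len(set(idx)) != len(idx) or any(i < 0 for i in idx):
        raise ValueError(f"malformed term label {label!r}")
    return idx


def term_column(runs: np.ndarray, term: Term) -> np.ndarray:
    """Elementwise product of the coded columns in ``term`` (ones for the intercept)."""
    runs = np.asarray(runs)
    if not term:
        return np.ones(runs.shape[0], dtype=runs.dtype)
    return np.prod(runs[:, list(term)], axis=1)


def model_matrix(runs: np.ndarray, terms: Sequence[Term]) -> np.ndarray:
    """Stack term columns into the n x p model matrix."""
    return np.column_stack([term_column(runs, t) for t in terms])


@dataclass(frozen=True)
class FactorialModel:
    """A (possibly reduced) factorial regression: term -> coefficient.

    Attributes
    ----------
    factors : tuple of Factor
        Full factor list of the parent design; kept for decoding even
        when terms involving some factors have been dropped.
    terms : tuple of Term
        Unique terms; the intercept ``()`` is always present.
    coefficients : ndarray of float, aligned with ``terms``.
    """

    factors: tuple[Factor, ...]
    terms: tuple[Term, ...]
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(self.factors))
        terms = tuple(tuple(t) for t in self.terms)
        if len(set(terms)) != len(terms):
            raise ValueError("term labels must be unique")
        if () not in terms:
            raise ValueError("model must contain the intercept term")
        coefs = np.asarray(self.coefficients, dtype=float)
        if coefs.shape != (len(terms),):
            raise ValueError("coefficient count must equal term count")
        object.__setattr__(self, "terms", terms)
        object.__setattr__(self, "coefficients", coefs)

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def labels(self) -> list[str]:
        return [term_label(t) for t in self.terms]

    def coefficient(self, term: Term | str) -> float:
        if isinstance(term, str):
            term = parse_term_label(term)
        return float(self.coefficients[self.terms.index(tuple(term))])

    def predict(self, coded_point: Sequence[float]) -> float:
        return predict(self, coded_point)

    def factor_index(self, name: str) -> int:
        for i, f in enumerate(self.factors):
            if f.name == name:
                return i
        raise KeyError(f"no factor named {name!r}")


def estimate_coefficients(design: FactorialDesign) -> FactorialModel:
    """Fit the saturated factorial model by orthogonal contrasts.

    Each coefficient is ``sum(term_column * y) / 2^k``; the intercept is
    the response mean. The saturated fit interpolates every observation
    exactly, which downstream code relies on.

    Raises
    ------
    ValueError
        If the design has no responses attached.
    """
    if design.responses is None:
        raise ValueError("design has no responses attached; cannot estimate coefficients")
    terms = all_terms(design.k)
    X = model_matrix(design.runs, terms)
    coefs = X.T @ design.responses / design.n_runs
    return FactorialModel(factors=design.factors, terms=tuple(terms), coefficients=coefs)


def yates_algorithm(responses_standard_order: Sequence[float]) -> np.ndarray:
    """Per-term contrast totals via the pairwise sum/difference algorithm.

    Performs k passes over a length-2^k response vector in standard order;
    each pass writes pairwise sums into the top half and pairwise
    differences (second minus first) into the bottom half. The final
    vector holds the contrast total for each term in standard term order,
    so ``contrast / 2^k`` is the coefficient, ``contrast / 2^(k-1)`` the
    effect, and ``contrast^2 / 2^k`` the term's sum of squares.
    """
    y = np.asarray(responses_standard_order, dtype=float)
    n = y.size
    if n < 2 or (n & (n - 1)) != 0:
        raise ValueError(f"response length must be a power of two >= 2, got {n}")
    k = n.bit_length() - 1
    out = y.copy()
    for _ in range(k):
        pairs = out.reshape(-1, 2)
        out = np.concatenate([pairs.sum(axis=1), pairs[:, 1] - pairs[:, 0]])
    return out


@dataclass(frozen=True)
class EffectScreen:
    """Yates-style screening table with a pooled error term.

    ``f_statistic`` entries are NaN for pooled terms (no F is formed for
    a term that contributes to the error estimate) and for every term
    when the pooled error mean square is zero (``f_defined`` False).
    """

    terms: tuple[Term, ...]
    effects: np.ndarray
    sums_of_squares: np.ndarray
    f_statistics: np.ndarray
    significant: np.ndarray
    pooled_terms: tuple[Term, ...]
    pooled_error_ms: float
    pooled_df: int
    alpha: float
    f_critical: float
    f_defined: bool

    @property
    def labels(self) -> list[str]:
        return [term_label(t) for t in self.terms]

    def to_frame(self) -> pd.DataFrame:
        pooled = [t in self.pooled_terms for t in self.terms]
        return pd.DataFrame(
            {
                "term": self.labels,
                "effect": self.effects,
                "sum_of_squares": self.sums_of_squares,
                "pooled": pooled,
                "f_statistic": self.f_statistics,
                "significant": self.significant,
            }
        )


def default_pool(design: FactorialDesign) -> list[Term]:
    """Default error pool for an unreplicated screen.

    All interaction terms (order >= 2) that are not among the top half
    (ceiling) of non-intercept terms ranked by absolute effect. With the
    bundled 2^3 alkali data this selects {X1X2, X1X3, X1X2X3}.
    """
    model = estimate_coefficients(design)
    ranked = sorted(
        (t for t in model.terms if t), key=lambda t: abs(model.coefficient(t)), reverse=True
    )
    keep = set(ranked[: (len(ranked) + 1) // 2])
    pool = [t for t in ranked if len(t) >= 2 and t not in keep]
    if not pool:
        raise ValueError(
            "default pooling found no inert interaction terms; pass an explicit pool"
        )
    return sorted(pool, key=lambda t: (len(t), t))


def _normalize_pool(pool: Iterable[Term | str]) -> list[Term]:
    out = []
    for t in pool:
        out.append(parse_term_label(t) if isinstance(t, str) else tuple(t))
    return out


def screen_effects(
    design: FactorialDesign,
    pool: Iterable[Term | str] | None = None,
    alpha: float = 0.05,
) -> EffectScreen:
    """Screen factorial effects with F tests against a pooled error term.

    Parameters
    ----------
    design : FactorialDesign
        Saturated design with responses.
    pool : iterable of terms or labels, optional
        Terms whose sums of squares form the error estimate (one df
        each). Defaults to :func:`default_pool`.
    alpha : float
        Significance level for the F criterion.

    Returns
    -------
    EffectScreen
        Per-term effect, SS, F (NaN for pooled terms) and significance
        flag; the non-intercept SS plus the pooled SS always total the
        corrected sum of squares of the responses.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    model = estimate_coefficients(design)
    n = design.n_runs
    terms = [t for t in model.terms if t]  # non-intercept
    pool_terms = default_pool(design) if pool is None else _normalize_pool(pool)
    if not pool_terms:
        raise ValueError("error pool must be nonempty for an unreplicated design")
    bad = [t for t in pool_terms if t not in terms]
    if bad:
        raise ValueError(f"pool terms not in design term universe: {[term_label(t) for t in bad]}")
    if set(pool_terms) >= set(terms):
        raise ValueError("pool exhausts all non-intercept terms; nothing left to test")

    coefs = np.array([model.coefficient(t) for t in terms])
    effects = 2.0 * coefs
    ss = n * coefs**2  # contrast^2 / n with contrast = n * beta
    pool_set = set(pool_terms)
    pooled_df = len(pool_terms)
    pooled_ms = float(sum(s for t, s in zip(terms, ss) if t in pool_set)) / pooled_df
    f_defined = pooled_ms > 0.0
    f_crit = float(stats.f.isf(alpha, 1, pooled_df))

    f_stats = np.full(len(terms), np.nan)
    signif = np.zeros(len(terms), dtype=bool)
    for i, t in enumerate(terms):
        if t in pool_set:
            continue
        if f_defined:
            f_stats[i] = ss[i] / pooled_ms
            signif[i] = f_stats[i] > f_crit
    return EffectScreen(
        terms=tuple(terms),
        effects=effects,
        sums_of_squares=ss,
        f_statistics=f_stats,
        significant=signif,
        pooled_terms=tuple(sorted(pool_set, key=lambda t: (len(t), t))),
        pooled_error_ms=pooled_ms,
        pooled_df=pooled_df,
        alpha=alpha,
        f_critical=f_crit,
        f_defined=f_defined,
    )


def reduce_model(model: FactorialModel, drop_factors: Sequence[str]) -> FactorialModel:
    """Drop every term involving any of ``drop_factors``.

    Retained coefficients are unchanged — valid because ±1-coded term
    columns are mutually orthogonal, so a least-squares refit of the
    reduced term set returns the same values.
    """
    drop_idx = {model.factor_index(name) for name in drop_factors}
    keep = [i for i, t in enumerate(model.terms) if not (set(t) & drop_idx)]
    kept_terms = [model.terms[i] for i in keep]
    used = {i for t in kept_terms for i in t}
    if drop_idx and not used and len(kept_terms) == 1:
        raise ValueError("cannot drop every factor from the model")
    return FactorialModel(
        factors=model.factors,
        terms=tuple(kept_terms),
        coefficients=model.coefficients[keep],
    )


def predict(model: FactorialModel, coded_point: Sequence[float] | Mapping[str, float]) -> float:
    """Evaluate the regression polynomial at a coded point.

    ``coded_point`` may be a length-k vector or a name->coded mapping
    (unnamed coordinates default to 0, the design center). Points outside
    the coded cube raise :class:`ExtrapolationWarning`.
    """
    if isinstance(coded_point, Mapping):
        x = np.zeros(model.k)
        for name, v in coded_point.items():
            x[model.factor_index(name)] = v
    else:
        x = np.asarray(coded_point, dtype=float)
        if x.shape != (model.k,):
            raise ValueError(f"coded point must have length {model.k}, got shape {x.shape}")
    if np.any(np.abs(x) > 1.0 + 1e-12):
        warnings.warn(
            "prediction point lies outside the coded design cube [-1, +1]",
            ExtrapolationWarning,
            stacklevel=2,
        )
    total = 0.0
    for t, c in zip(model.terms, model.coefficients):
        total += c * np.prod(x[list(t)]) if t else c
    return float(total)
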