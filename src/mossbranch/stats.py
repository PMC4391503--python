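"""Branching-pattern descriptors and genotype comparisons.

Per-gametophore descriptors
---------------------------
* branch number ``B``;
* apical inhibition zone (AIZ) size: the number of branch-free metamers
  between the apex and the most apical branch, ``L - max(positions)``;
  undefined for a branch-free shoot (excluded from dataset means);
* mean minimum inter-branch distance: for each branch, the distance in
  metamers to its nearest other branch, averaged; undefined with fewer
  than two branches.

Dataset-level descriptors
-------------------------
means +/- SD of the above, the fraction of gametophores with at least one
pair of branches on adjacent metamers, the fraction with a branch in the
most basal metamers, and per-position branch frequencies (conditioned on
gametophore length reaching the position).

Genotype comparison
-------------------
The branch-number/leaf-number relationship is compared between two
datasets with the linear model ``B = (a0 + a1 X) + (a2 + a3 X) L`` where
``X`` indicates the reference group, fitted by OLS and reduced by
backward stepwise elimination (interaction before main effects); the
groups differ if the genotype intercept ``a1`` or the interaction ``a3``
survives in the minimal model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .patterns import BranchingPattern, PatternDataset

__all__ = [
    "aiz_size",
    "mean_min_branch_distance",
    "adjacent_branch_fraction",
    "basal_branch_proportion",
    "position_distribution",
    "fit_position_polynomial",
    "fit_branch_length_model",
    "fit_branch_length_table",
    "summarize",
    "pooled_min_branch_distance",
    "SummaryStats",
    "RegressionResult",
    "PolynomialFit",
]


def aiz_size(pattern: BranchingPattern) -> int | None:
    """Apical inhibition zone size; ``None`` for a branch-free shoot."""
    if not pattern.branch_positions:
        return None
    return pattern.L - max(pattern.branch_positions)


def mean_min_branch_distance(
    pattern: BranchingPattern,
) -> float | None:
    """Mean nearest-neighbour distance between branches, in metamers.

    ``None`` ("n.d.") with fewer than two branches.
    """
    pos = np.asarray(pattern.branch_positions)
    if len(pos) < 2:
        return None
    d = np.abs(pos[:, None] - pos[None, :]).astype(float)
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


def _has_adjacent(pattern: BranchingPattern) -> bool:
    pos = pattern.branch_positions
    return any(b - a == 1 for a, b in zip(pos, pos[1:]))


def adjacent_branch_fraction(dataset: PatternDataset) -> tuple[float, int]:
    """(fraction, count) of gametophores with >= 1 adjacent branch pair."""
    dataset.require_nonempty()
    count = sum(_has_adjacent(p) for p in dataset)
    return count / len(dataset), count


def basal_branch_proportion(dataset: PatternDataset, depth: int = 5) -> float:
    """Fraction of gametophores with a branch within ``depth`` of the base."""
    dataset.require_nonempty()
    if depth <= 0:
        return 0.0
    hits = sum(
        1 for p in dataset if p.branch_positions and min(p.branch_positions) <= depth
    )
    return hits / len(dataset)


def position_distribution(dataset: PatternDataset) -> pd.DataFrame:
    """Per-position branch frequencies.

    For base-indexed position ``q``, the fraction of gametophores of
    length >= q that branch there; ``freq_apex`` gives the companion
    apex-indexed frequencies (position 1 = topmost metamer).
    """
    dataset.require_nonempty()
    max_L = int(dataset.lengths().max())
    base_hits = np.zeros(max_L)
    apex_hits = np.zeros(max_L)
    eligible = np.zeros(max_L)
    for p in dataset:
        eligible[: p.L] += 1
        for q in p.branch_positions:
            base_hits[q - 1] += 1
            apex_hits[p.L - q] += 1
    return pd.DataFrame(
        {
            "position": np.arange(1, max_L + 1),
            "n_eligible": eligible.astype(int),
            "freq_base": base_hits / eligible,
            "freq_apex": apex_hits / eligible,
        }
    )


@dataclass(frozen=True)
class PolynomialFit:
    """A least-squares polynomial through per-position frequencies."""

    degree: int
    coefficients: tuple[float, ...]  # ascending powers, unscaled domain
    positions: tuple[int, ...]
    fitted: tuple[float, ...]

    def __call__(self, x) -> np.ndarray:
        return np.polynomial.polynomial.polyval(x, self.coefficients)


def fit_position_polynomial(
    freqs: pd.DataFrame | np.ndarray, degree: int = 7
) -> PolynomialFit:
    """OLS polynomial of the stated degree over (position, frequency).

    ``freqs`` is either the frame from :func:`position_distribution` (the
    ``freq_base`` column is fitted) or an array of frequencies implicitly
    at positions 1..n.  Requires more distinct positions than the degree.
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if isinstance(freqs, pd.DataFrame):
        x = freqs["position"].to_numpy(dtype=float)
        y = freqs["freq_base"].to_numpy(dtype=float)
    else:
        y = np.asarray(freqs, dtype=float)
        x = np.arange(1, len(y) + 1, dtype=float)
    if len(np.unique(x)) <= degree:
        raise ValueError(
            f"need more than {degree} distinct positions to fit degree {degree}"
        )
    series = np.polynomial.Polynomial.fit(x, y, deg=degree)
    coefs = series.convert().coef
    fitted = np.polynomial.polynomial.polyval(x, coefs)
    return PolynomialFit(
        degree=degree,
        coefficients=tuple(float(c) for c in coefs),
        positions=tuple(int(v) for v in x),
        fitted=tuple(float(v) for v in fitted),
    )


@dataclass(frozen=True)
class RegressionResult:
    """Minimal model from the backward-stepwise genotype comparison.

    ``terms`` maps retained term names (``a0``, ``a1``, ``a2``, ``a3``) to
    (estimate, p-value); eliminated terms are absent.  ``groups_differ``
    is True iff ``a1`` or ``a3`` was retained.
    """

    terms: dict
    groups_differ: bool
    alpha: float
    n_obs: int
    elimination_order: tuple[str, ...]

    def coefficient(self, name: str) -> float:
        return self.terms[name][0]


_DESIGN_COLS = {"a0": "const", "a1": "X", "a2": "L", "a3": "XL"}


def _fit_ols(df: pd.DataFrame, terms: list[str]):
    X = df[[_DESIGN_COLS[t] for t in terms]]
    return sm.OLS(df["B"], X).fit()


def _term_pvalue(fit, col: str) -> float:
    # A perfect (zero-residual) fit yields NaN standard errors; a term with
    # a zero estimate then carries no information and is fully removable.
    p = float(fit.pvalues[col])
    if math.isnan(p):
        return 1.0 if abs(float(fit.params[col])) < 1e-8 else 0.0
    return p


def fit_branch_length_model(
    dataset_a: PatternDataset,
    dataset_b: PatternDataset,
    alpha: float = 0.05,
) -> RegressionResult:
    """Backward-stepwise OLS comparison of branch number vs leaf number.

    ``dataset_a`` is the reference group (indicator X = 1).  The full
    model ``B = a0 + a1 X + a2 L + a3 X L`` is reduced by repeatedly
    removing the removable term with the largest p-value above ``alpha``;
    the interaction ``a3`` must leave before the main effects ``a1`` and
    ``a2`` become removable, and the intercept ``a0`` is always kept.
    """
    dataset_a.require_nonempty()
    dataset_b.require_nonempty()
    rows = []
    for ds, x in ((dataset_a, 1.0), (dataset_b, 0.0)):
        for p in ds:
            rows.append((p.branch_count, p.L, x))
    df = pd.DataFrame(rows, columns=["B", "L", "X"])
    return fit_branch_length_table(df, alpha=alpha)


def fit_branch_length_table(table: pd.DataFrame, alpha: float = 0.05) -> RegressionResult:
    """Stepwise comparison on an explicit (B, L, X) table.

    Same procedure as :func:`fit_branch_length_model`; useful when the
    response is continuous (e.g. generated fixtures) rather than counts
    extracted from patterns.
    """
    df = table[["B", "L", "X"]].astype(float).copy()
    if df["L"].nunique() < 2:
        raise ValueError("degenerate design: all gametophore lengths equal")
    df["const"] = 1.0
    df["XL"] = df["X"] * df["L"]

    terms = ["a0", "a1", "a2", "a3"]
    eliminated: list[str] = []
    while True:
        fit = _fit_ols(df, terms)
        removable = [
            t for t in terms if t != "a0" and not (t in ("a1", "a2") and "a3" in terms)
        ]
        candidates = [(t, _term_pvalue(fit, _DESIGN_COLS[t])) for t in removable]
        candidates = [(t, p) for t, p in candidates if p > alpha]
        if not candidates:
            break
        worst = max(candidates, key=lambda tp: tp[1])[0]
        terms.remove(worst)
        eliminated.append(worst)
    result_terms = {
        t: (float(fit.params[_DESIGN_COLS[t]]), _term_pvalue(fit, _DESIGN_COLS[t]))
        for t in terms
    }
    return RegressionResult(
        terms=result_terms,
        groups_differ=("a1" in result_terms) or ("a3" in result_terms),
        alpha=alpha,
        n_obs=len(df),
        elimination_order=tuple(eliminated),
    )


@dataclass(frozen=True)
class SummaryStats:
    """One dataset's descriptors; n.d. quantities are ``None``."""

    label: str
    n: int
    mean_branch_number: float
    sd_branch_number: float
    mean_aiz: float | None
    sd_aiz: float | None
    n_aiz: int
    mean_min_distance: float | None
    sd_min_distance: float | None
    n_min_distance: int
    adjacent_fraction: float
    adjacent_count: int
    basal_proportion: float

    def as_row(self) -> dict:
        def nd(v):
            return "n.d." if v is None else v

        return {
            "dataset": self.label,
            "n": self.n,
            "mean_branch_number": self.mean_branch_number,
            "sd_branch_number": self.sd_branch_number,
            "mean_aiz": nd(self.mean_aiz),
            "sd_aiz": nd(self.sd_aiz),
            "mean_min_distance": nd(self.mean_min_distance),
            "sd_min_distance": nd(self.sd_min_distance),
            "adjacent_fraction": self.adjacent_fraction,
            "adjacent_count": self.adjacent_count,
            "basal_proportion": self.basal_proportion,
        }


def _mean_sd(values: list[float]) -> tuple[float | None, float | None]:
    if not values:
        return None, None
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd


def summarize(dataset: PatternDataset, basal_depth: int = 5) -> SummaryStats:
    """Assemble every per-gametophore and dataset-level descriptor."""
    dataset.require_nonempty()
    B = dataset.branch_counts()
    aiz = [aiz_size(p) for p in dataset]
    aiz = [a for a in aiz if a is not None]
    dists = [mean_min_branch_distance(p) for p in dataset]
    dists = [d for d in dists if d is not None]
    mean_aiz, sd_aiz = _mean_sd(aiz)
    mean_d, sd_d = _mean_sd(dists)
    frac, count = adjacent_branch_fraction(dataset)
    return SummaryStats(
        label=dataset.label,
        n=len(dataset),
        mean_branch_number=float(B.mean()),
        sd_branch_number=float(B.std(ddof=1)) if len(B) > 1 else 0.0,
        mean_aiz=mean_aiz,
        sd_aiz=sd_aiz,
        n_aiz=len(aiz),
        mean_min_distance=mean_d,
        sd_min_distance=sd_d,
        n_min_distance=len(dists),
        adjacent_fraction=frac,
        adjacent_count=count,
        basal_proportion=basal_branch_proportion(dataset, depth=basal_depth),
    )


def pooled_min_branch_distance(dataset: PatternDataset) -> float | None:
    """Alternative dataset-level dispersion: pool every branch's
    nearest-neighbour distance across gametophores before averaging."""
    pooled: list[float] = []
    for p in dataset:
        pos = np.asarray(p.branch_positions)
        if len(pos) < 2:
            continue
        d = np.abs(pos[:, None] - pos[None, :]).astype(float)
        np.fill_diagonal(d, np.inf)
        pooled.extend(d.min(axis=1))
    if not pooled:
        return None
    return float(np.mean(pooled))
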