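"""Synthetic branching-pattern and regression fixtures.

Stand-ins for measured pattern data with controlled statistical
structure, so the statistics layer can be tested independently of the
mechanistic simulator.  The pattern generator emulates the three features
observed on real shoots: per-shoot metamer counts in a bounded range, an
apical branch-free zone of roughly constant size, and branches in the
branching zone that are *more evenly dispersed* than a uniform-random
placement — realised with a sequential hard-core point process (uniform
proposals rejected within ``min_spacing`` of an accepted branch).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .patterns import BranchingPattern, PatternDataset

__all__ = ["SyntheticPatternSpec", "generate_patterns", "generate_regression_fixture"]

_MAX_PROPOSALS = 1000


@dataclass(frozen=True)
class SyntheticPatternSpec:
    """Controls for the synthetic pattern generator.

    ``branch_density`` is the expected number of branches per
    branching-zone metamer; ``min_spacing`` = 1 imposes no constraint
    (any two metamers are at least 1 apart).
    """

    n: int = 60
    length_range: tuple[int, int] = (20, 40)
    aiz_mu: float = 18.0
    aiz_sigma: float = 2.0
    branch_density: float = 0.15
    min_spacing: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 <= self.branch_density <= 1:
            raise ValueError("branch_density must be in [0, 1]")
        if self.min_spacing < 1:
            raise ValueError("min_spacing must be >= 1")
        if self.aiz_mu < 0 or self.aiz_sigma < 0:
            raise ValueError("aiz_mu and aiz_sigma must be >= 0")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError("length_range must satisfy 1 <= min <= max")


def _draw_aiz(spec: SyntheticPatternSpec, L: int, rng: np.random.Generator) -> int:
    if spec.aiz_sigma == 0:
        a = spec.aiz_mu
    else:
        while True:
            a = rng.normal(spec.aiz_mu, spec.aiz_sigma)
            if a >= 0:
                break
    return int(np.clip(round(a), 0, L))


def _hardcore_positions(
    zone: int, target: int, spacing: int, rng: np.random.Generator
) -> list[int]:
    """Sequential rejection sampling of positions 1..zone with a hard-core
    minimum distance.  Stops early when the proposal budget is spent."""
    accepted: list[int] = []
    while len(accepted) < target:
        placed = False
        for _ in range(_MAX_PROPOSALS):
            q = int(rng.integers(1, zone + 1))
            if all(abs(q - a) >= spacing for a in accepted):
                accepted.append(q)
                placed = True
                break
        if not placed:
            break
    return sorted(accepted)


def generate_patterns(spec: SyntheticPatternSpec) -> PatternDataset:
    """Generate a dataset of synthetic branching patterns.

    Per gametophore: length uniform in ``length_range``; an apical
    branch-free zone drawn truncated-normal and clipped to [0, L];
    branches placed in the remaining basal zone by hard-core sampling
    until the target density is met or no admissible site remains.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    lo, hi = spec.length_range
    if spec.min_spacing > max(hi - round(spec.aiz_mu) - 1, 1):
        warnings.warn(
            "min_spacing leaves room for at most one branch per gametophore",
            stacklevel=2,
        )
    patterns = []
    for _ in range(spec.n):
        L = int(rng.integers(lo, hi + 1))
        aiz = _draw_aiz(spec, L, rng)
        zone = L - aiz
        positions: list[int] = []
        if zone > 0 and spec.branch_density > 0:
            target = rng.binomial(zone, spec.branch_density)
            positions = _hardcore_positions(zone, target, spec.min_spacing, rng)
        patterns.append(BranchingPattern(L=L, branch_positions=tuple(positions)))
    return PatternDataset(
        patterns,
        label="synthetic",
        seed=spec.seed,
        metadata={
            "aiz_mu": spec.aiz_mu,
            "aiz_sigma": spec.aiz_sigma,
            "branch_density": spec.branch_density,
            "min_spacing": spec.min_spacing,
            "n": spec.n,
        },
    )


def generate_regression_fixture(
    a0: float,
    a1: float,
    a2: float,
    a3: float,
    noise_sd: float,
    n_per_group: int,
    length_range: tuple[int, int] = (20, 40),
    seed: int = 0,
    integer_counts: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """A (B, L, X) table generated from known coefficients.

    ``B = a0 + a1 X + a2 L + a3 X L + N(0, noise_sd)``; with
    ``integer_counts`` the response is rounded and floored at zero.
    Returns the table and the generating truth for recovery tests.
    """
    if n_per_group < 3:
        raise ValueError("n_per_group must be >= 3")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    lo, hi = length_range
    rows = []
    for x in (1.0, 0.0):
        L = rng.integers(lo, hi + 1, size=n_per_group).astype(float)
        B = a0 + a1 * x + a2 * L + a3 * x * L
        if noise_sd > 0:
            B = B + rng.normal(0, noise_sd, size=n_per_group)
        if integer_counts:
            B = np.maximum(np.round(B), 0.0)
        rows.append(pd.DataFrame({"B": B, "L": L, "X": x}))
    table = pd.concat(rows, ignore_index=True)
    truth = {"a0": a0, "a1": a1, "a2": a2, "a3": a3, "noise_sd": noise_sd}
    return table, truth


def table_as_datasets(table: pd.DataFrame) -> tuple[PatternDataset, PatternDataset]:
    """Convert a (B, L, X) fixture table into a pair of pattern datasets
    (X = 1 group first).  Branches are placed basally at unit spacing —
    positions carry no information for the regression, only counts do."""
    out = []
    for x, label in ((1.0, "group_ref"), (0.0, "group_alt")):
        sub = table[table["X"] == x]
        pats = []
        for _, row in sub.iterrows():
            L = int(row["L"])
            b = int(max(0, min(round(row["B"]), L)))
            pats.append(BranchingPattern(L=L, branch_positions=tuple(range(1, b + 1))))
        out.append(PatternDataset(pats, label=label))
    return out[0], out[1]
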