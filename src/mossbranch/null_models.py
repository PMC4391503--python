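"""Stochastic reference models of branching.

Two null hypotheses against which observed or simulated branching
patterns are compared:

* a purely stochastic model in which each metamer branches independently
  with probability ``p`` (branch count per shoot is Binomial(L, p));
* a competency-augmented variant in which a metamer only becomes eligible
  for its single Bernoulli trial once it is at least ``min_age``
  plastochrons old, which imposes an apical branch-free zone of at least
  ``min_age`` metamers by construction while leaving the within-zone
  dispersion Bernoulli-random.

Growth is simulated metamer-by-metamer (one metamer per plastochron) so
the competency rule can be layered on the same process.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .patterns import BranchingPattern, PatternDataset

__all__ = ["NullModelParams", "stochastic_dataset", "competency_dataset"]


@dataclass(frozen=True)
class NullModelParams:
    """Parameters of the stochastic null models.

    ``length_sampler`` is either the string ``"uniform"`` (integer lengths
    uniform over ``length_range``) or a sequence of lengths to copy, one
    per gametophore, for like-for-like comparison with a reference
    dataset.
    """

    p: float = 0.05
    min_age: int = 0
    length_range: tuple[int, int] = (20, 40)
    length_sampler: str | Sequence[int] = "uniform"

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError("p must be in [0, 1]")
        if self.min_age < 0:
            raise ValueError("min_age must be >= 0")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError("length_range must satisfy 1 <= min <= max")


def _lengths(params: NullModelParams, n: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(params.length_sampler, str):
        if params.length_sampler != "uniform":
            raise ValueError(f"unknown length sampler {params.length_sampler!r}")
        lo, hi = params.length_range
        return rng.integers(lo, hi + 1, size=n)
    lengths = np.asarray(list(params.length_sampler), dtype=int)
    if len(lengths) != n:
        raise ValueError(
            f"length_sampler provides {len(lengths)} lengths but n={n}"
        )
    return lengths


def _grow_one(
    L: int, p: float, min_age: int, rng: np.random.Generator
) -> BranchingPattern:
    # Metamer k (1-based from the base) is created at plastochron k and has
    # age L - k at the end of growth.  Each metamer is tested once, on the
    # plastochron at which its age reaches min_age; metamers that never
    # reach competency are never tested.
    positions = []
    for k in range(1, L + 1):
        if L - k >= min_age and rng.random() < p:
            positions.append(k)
    return BranchingPattern(L=L, branch_positions=tuple(positions))


def stochastic_dataset(
    params: NullModelParams, n: int, seed: int
) -> PatternDataset:
    """Purely stochastic branching: one Bernoulli(p) trial per metamer."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    lengths = _lengths(params, n, rng)
    patterns = [_grow_one(int(L), params.p, 0, rng) for L in lengths]
    return PatternDataset(
        patterns,
        label="stochastic_null",
        seed=seed,
        metadata={"p": params.p, "min_age": 0, "n": n},
    )


def competency_dataset(
    params: NullModelParams, n: int, seed: int
) -> PatternDataset:
    """Stochastic branching gated by a minimum metamer age.

    With ``min_age`` = A the A most apical metamers of every gametophore
    are branch-free, so the apparent apical inhibition zone is >= A.
    ``min_age`` = 0 reduces to :func:`stochastic_dataset`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    lengths = _lengths(params, n, rng)
    patterns = [_grow_one(int(L), params.p, params.min_age, rng) for L in lengths]
    return PatternDataset(
        patterns,
        label="competency_null",
        seed=seed,
        metadata={"p": params.p, "min_age": params.min_age, "n": n},
    )
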