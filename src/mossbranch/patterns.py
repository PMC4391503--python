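"""Core observable containers: branching patterns and datasets of them.

A :class:`BranchingPattern` is the final state of one gametophore reduced
to what is scored on real plants: the metamer count ``L`` (= leaf number)
and the 1-based, base-indexed positions of branch-bearing metamers.  A
:class:`PatternDataset` is an ordered collection of patterns with
provenance; it is the unit every statistic operates on, whatever produced
it (mechanistic simulator, stochastic null, synthetic generator, or a file
on disk).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = ["BranchingPattern", "PatternDataset"]


@dataclass(frozen=True)
class BranchingPattern:
    """One gametophore's metamer count and branch positions.

    Positions are 1-based counting from the most basal metamer.
    """

    L: int
    branch_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        pos = tuple(int(p) for p in self.branch_positions)
        if any(not (1 <= p <= self.L) for p in pos):
            raise ValueError("branch positions must lie in [1, L]")
        if len(set(pos)) != len(pos):
            raise ValueError("branch positions must be unique")
        if list(pos) != sorted(pos):
            pos = tuple(sorted(pos))
        object.__setattr__(self, "branch_positions", pos)

    @property
    def branch_count(self) -> int:
        return len(self.branch_positions)

    def is_branch(self, position: int) -> bool:
        return position in self.branch_positions

    def as_flags(self) -> np.ndarray:
        """Binary branch indicator per metamer, basal to apical."""
        flags = np.zeros(self.L, dtype=int)
        for p in self.branch_positions:
            flags[p - 1] = 1
        return flags


@dataclass
class PatternDataset:
    """An ordered collection of branching patterns with provenance."""

    patterns: list[BranchingPattern]
    label: str = "dataset"
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.patterns = list(self.patterns)

    def __len__(self) -> int:
        return len(self.patterns)

    def __iter__(self) -> Iterator[BranchingPattern]:
        return iter(self.patterns)

    def __getitem__(self, i) -> BranchingPattern:
        return self.patterns[i]

    def require_nonempty(self) -> None:
        if not self.patterns:
            raise ValueError(f"dataset {self.label!r} is empty")

    def sorted_by_length(self) -> "PatternDataset":
        """Patterns ordered by increasing size (stable)."""
        return PatternDataset(
            sorted(self.patterns, key=lambda p: p.L),
            label=self.label,
            seed=self.seed,
            metadata=dict(self.metadata),
        )

    def lengths(self) -> np.ndarray:
        return np.array([p.L for p in self.patterns], dtype=int)

    def branch_counts(self) -> np.ndarray:
        return np.array([p.branch_count for p in self.patterns], dtype=int)
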