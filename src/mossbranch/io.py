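"""Pattern-table file format and run metadata.

The on-disk format is a long CSV with header
``dataset,gametophore,metamer,is_branch``: one row per metamer, metamer
numbered 1..L from the base, ``is_branch`` in {0, 1}.  The writer emits
gametophores in ascending-length order; the reader validates contiguity
and flag values and reports parse errors with line numbers.  Round-trips
are lossless at the pattern level.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .patterns import BranchingPattern, PatternDataset

__all__ = ["read_patterns", "write_patterns", "write_metadata", "PatternFileError"]

_COLUMNS = ["dataset", "gametophore", "metamer", "is_branch"]


class PatternFileError(ValueError):
    """A malformed pattern-table file."""


def write_patterns(dataset: PatternDataset, path) -> None:
    """Write a dataset as the long-format pattern CSV (ascending length)."""
    ordered = dataset.sorted_by_length()
    rows = []
    for g, pattern in enumerate(ordered, start=1):
        flags = pattern.as_flags()
        for m in range(1, pattern.L + 1):
            rows.append((ordered.label, g, m, int(flags[m - 1])))
    df = pd.DataFrame(rows, columns=_COLUMNS)
    df.to_csv(path, index=False, lineterminator="\n")


def read_patterns(path) -> PatternDataset:
    """Read a pattern CSV, validating structure row by row."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"dataset": str})
    except Exception as exc:  # malformed CSV at the parser level
        raise PatternFileError(f"{path}: cannot parse: {exc}") from exc
    if list(df.columns) != _COLUMNS:
        raise PatternFileError(
            f"{path}: header must be {','.join(_COLUMNS)}, got {','.join(df.columns)}"
        )
    if df.empty:
        raise PatternFileError(f"{path}: no data rows")
    labels = df["dataset"].unique()
    if len(labels) > 1:
        raise PatternFileError(
            f"{path}: multiple dataset labels in one file: {list(labels)}"
        )
    # +2: one for the header, one for 1-based line numbering
    df = df.assign(_line=df.index + 2)
    patterns = []
    for g, sub in df.groupby("gametophore", sort=True):
        metamers = sub["metamer"].tolist()
        expected = list(range(1, len(metamers) + 1))
        if metamers != expected:
            bad = next(
                (line for m, e, line in zip(metamers, expected, sub["_line"]) if m != e),
                int(sub["_line"].iloc[0]),
            )
            raise PatternFileError(
                f"{path}: gametophore {g}: metamer indices are not contiguous "
                f"1..L (line {bad})"
            )
        flags = sub["is_branch"].tolist()
        for f, line in zip(flags, sub["_line"]):
            if f not in (0, 1):
                raise PatternFileError(
                    f"{path}: gametophore {g}: is_branch must be 0 or 1 "
                    f"(line {line})"
                )
        positions = tuple(m for m, f in zip(metamers, flags) if f == 1)
        patterns.append(BranchingPattern(L=len(metamers), branch_positions=positions))
    return PatternDataset(patterns, label=str(labels[0]))


def write_metadata(path, **fields) -> None:
    """Write a JSON sidecar with everything needed to reproduce a run."""
    from . import __version__

    payload = {"software_version": __version__, **fields}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
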