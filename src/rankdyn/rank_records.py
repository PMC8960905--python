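"""Data model and I/O for longitudinal ranking lists.

A :class:`RankTable` stores which element occupies each of the ``N0`` ranks of
a fixed-size ranking list at each of ``T`` observation times.  Files are read
and written in a long TSV/CSV format with columns ``time, rank, element`` and
an optional ``score`` column.  Scores, when present, must be non-increasing in
rank within each observation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RankTable",
    "ScoreTable",
    "RankTableError",
    "FormatError",
    "GapError",
    "CoverageError",
    "DegenerateSubsampleError",
    "read_rank_table",
    "write_rank_table",
    "ranks_from_scores",
    "subsample",
]


class RankTableError(ValueError):
    """Base class for ranking-table validation and parsing problems."""


class FormatError(RankTableError):
    """Malformed input: duplicate cells, non-integer ranks, missing columns."""


class GapError(RankTableError):
    """Ranks at some observation are not the contiguous block 1..N0."""


class CoverageError(RankTableError):
    """Fewer scored elements than the requested list size at some time."""


class DegenerateSubsampleError(RankTableError):
    """Subsampling would leave fewer than two observations."""


def _infer_sep(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("tsv", "csv"):
            raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
        return "\t" if dialect == "tsv" else ","
    return "," if path.suffix.lower() == ".csv" else "\t"


@dataclass
class RankTable:
    """Occupants of a fixed-size ranking list observed at T times.

    Parameters
    ----------
    occupants
        Nested sequence of shape ``(T, N0)``; ``occupants[t][R - 1]`` is the
        element id (string) at rank ``R`` at internal time ``t``.
    time_labels
        Original time labels of the observations, in order.  Internally times
        are always re-indexed to ``0..T-1``.
    scores
        Optional per-time mapping ``element id -> score``.  When present the
        occupant order must be non-increasing in score (ties allowed).
    interval_length
        Real time between consecutive observations (user-declared units).
    """

    occupants: list[list[str]]
    time_labels: tuple = None  # type: ignore[assignment]
    scores: list[dict[str, float]] | None = None
    interval_length: float = 1.0

    def __post_init__(self) -> None:
        self.occupants = [list(row) for row in self.occupants]
        if len(self.occupants) < 2:
            raise RankTableError("a RankTable needs at least T = 2 observations")
        n0 = len(self.occupants[0])
        if n0 < 1:
            raise RankTableError("list size N0 must be at least 1")
        for t, row in enumerate(self.occupants):
            if len(row) != n0:
                raise GapError(
                    f"observation {t} has {len(row)} ranks, expected N0 = {n0}"
                )
            if len(set(row)) != n0:
                seen: set[str] = set()
                for rank, el in enumerate(row, start=1):
                    if el in seen:
                        raise FormatError(
                            f"element {el!r} occupies more than one rank at time {t} "
                            f"(second occurrence at rank {rank})"
                        )
                    seen.add(el)
        if self.time_labels is None:
            self.time_labels = tuple(range(len(self.occupants)))
        else:
            self.time_labels = tuple(self.time_labels)
            if len(self.time_labels) != len(self.occupants):
                raise RankTableError("time_labels length does not match T")
        if not (self.interval_length > 0):
            raise RankTableError("interval_length must be positive")
        if self.scores is not None:
            if len(self.scores) != len(self.occupants):
                raise RankTableError("scores must provide one mapping per time")
            self.scores = [dict(m) for m in self.scores]
            for t, row in enumerate(self.occupants):
                vals = []
                for el in row:
                    if el not in self.scores[t]:
                        raise RankTableError(
                            f"missing score for listed element {el!r} at time {t}"
                        )
                    v = float(self.scores[t][el])
                    if not math.isfinite(v):
                        raise RankTableError(
                            f"non-finite score for {el!r} at time {t}"
                        )
                    vals.append(v)
                if any(a < b for a, b in zip(vals, vals[1:])):
                    raise RankTableError(
                        f"scores are not non-increasing in rank at time {t}"
                    )

    # -- basic views -----------------------------------------------------

    @property
    def n_times(self) -> int:
        """Number of observations T."""
        return len(self.occupants)

    @property
    def list_size(self) -> int:
        """Number of ranks N0 per observation."""
        return len(self.occupants[0])

    def id_set(self, t: int) -> frozenset[str]:
        """Set of element ids listed at internal time ``t``."""
        return frozenset(self.occupants[t])

    def all_ids(self) -> frozenset[str]:
        """Distinct element ids ever seen in the list."""
        out: set[str] = set()
        for row in self.occupants:
            out.update(row)
        return frozenset(out)

    def rank_of(self, t: int) -> dict[str, int]:
        """Mapping element id -> rank (1-based) at time ``t``."""
        return {el: r for r, el in enumerate(self.occupants[t], start=1)}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RankTable):
            return NotImplemented
        return (
            self.occupants == other.occupants
            and self.time_labels == other.time_labels
            and self.scores == other.scores
            and self.interval_length == other.interval_length
        )


@dataclass
class ScoreTable:
    """Raw (time, element, score) records prior to ranking.

    One score per (time, element) pair; scores must be finite reals.
    """

    records: list[tuple[object, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[object, str]] = set()
        cleaned = []
        for time, element, score in self.records:
            score = float(score)
            if not math.isfinite(score):
                raise RankTableError(
                    f"non-finite score for element {element!r} at time {time!r}"
                )
            key = (time, str(element))
            if key in seen:
                raise FormatError(
                    f"duplicate score record for element {element!r} at time {time!r}"
                )
            seen.add(key)
            cleaned.append((time, str(element), score))
        self.records = cleaned

    def times(self) -> list[object]:
        """Distinct time labels in sorted order."""
        return sorted({t for t, _, _ in self.records})

    def at(self, time: object) -> dict[str, float]:
        """Mapping element -> score at the given time label."""
        return {el: s for t, el, s in self.records if t == time}


# -- file I/O ------------------------------------------------------------


def read_rank_table(path: str | Path, dialect: str | None = None) -> RankTable:
    """Read a long-format rank table (columns ``time, rank, element[, score]``).

    Times are re-indexed to ``0..T-1`` preserving sorted order of the original
    labels, which are retained in :attr:`RankTable.time_labels`.
    """
    path = Path(path)
    sep = _infer_sep(path, dialect)
    df = pd.read_csv(path, sep=sep, dtype={"element": str})
    required = {"time", "rank", "element"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"missing required column(s): {sorted(missing)}")

    rank_f = pd.to_numeric(df["rank"], errors="coerce")
    if rank_f.isna().any() or (rank_f != rank_f.round()).any():
        bad = df.loc[rank_f.isna() | (rank_f != rank_f.round()), "rank"].iloc[0]
        raise FormatError(f"non-integer rank value {bad!r}")
    df = df.assign(rank=rank_f.astype(int))

    dup = df.duplicated(subset=["time", "rank"], keep=False)
    if dup.any():
        row = df.loc[dup].iloc[0]
        t_label = row["time"].item() if hasattr(row["time"], "item") else row["time"]
        raise FormatError(f"duplicate cell: time {t_label}, rank {int(row['rank'])}")

    labels = [
        lab.item() if hasattr(lab, "item") else lab
        for lab in sorted(df["time"].unique())
    ]
    has_scores = "score" in df.columns
    occupants: list[list[str]] = []
    scores: list[dict[str, float]] | None = [] if has_scores else None
    n0 = None
    for lab in labels:
        sub = df[df["time"] == lab].sort_values("rank")
        ranks = sub["rank"].to_numpy()
        if n0 is None:
            n0 = len(ranks)
        expected = np.arange(1, n0 + 1)
        if len(ranks) != n0 or not np.array_equal(ranks, expected):
            raise GapError(
                f"observation {lab!r} does not cover ranks 1..{n0} contiguously"
            )
        occupants.append(sub["element"].tolist())
        if has_scores:
            scores.append(  # type: ignore[union-attr]
                dict(zip(sub["element"], sub["score"].astype(float)))
            )
    return RankTable(occupants=occupants, time_labels=tuple(labels), scores=scores)


def write_rank_table(
    table: RankTable, path: str | Path, dialect: str | None = None
) -> None:
    """Write ``table`` in canonical long format (sorted by time then rank).

    Scores, when present, are written with 17 significant digits so that the
    file round-trips bit-exactly.
    """
    path = Path(path)
    sep = _infer_sep(path, dialect)
    has_scores = table.scores is not None
    lines = []
    header = ["time", "rank", "element"] + (["score"] if has_scores else [])
    lines.append(sep.join(header))
    for t in range(table.n_times):
        lab = table.time_labels[t]
        for rank, el in enumerate(table.occupants[t], start=1):
            row = [str(lab), str(rank), el]
            if has_scores:
                row.append("%.17g" % table.scores[t][el])
            lines.append(sep.join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# -- transformations -----------------------------------------------------


def ranks_from_scores(
    scores: ScoreTable,
    n0: int,
    tie_rule: str = "previous_rank_then_id",
) -> RankTable:
    """Convert score records to a rank table: rank 1 = highest score.

    Exactly ``n0`` ranks are kept per time.  Score ties are broken
    deterministically: with ``previous_rank_then_id`` an element keeps
    precedence according to its rank at the previous observation when
    available (then lexicographic id); with ``id_only`` ties go to the
    lexicographically smaller id.
    """
    if tie_rule not in ("previous_rank_then_id", "id_only"):
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    if n0 < 1:
        raise ValueError("n0 must be >= 1")
    times = scores.times()
    occupants: list[list[str]] = []
    kept_scores: list[dict[str, float]] = []
    prev_rank: dict[str, int] = {}
    for lab in times:
        at = scores.at(lab)
        if len(at) < n0:
            raise CoverageError(
                f"time {lab!r} has only {len(at)} scored elements, need {n0}"
            )
        if tie_rule == "id_only":
            key = lambda el: (-at[el], el)  # noqa: E731
        else:
            key = lambda el: (-at[el], prev_rank.get(el, math.inf), el)  # noqa: E731
        ordered = sorted(at, key=key)[:n0]
        occupants.append(ordered)
        kept_scores.append({el: at[el] for el in ordered})
        prev_rank = {el: r for r, el in enumerate(ordered, start=1)}
    return RankTable(
        occupants=occupants, time_labels=tuple(times), scores=kept_scores
    )


def subsample(table: RankTable, k: int) -> RankTable:
    """Keep observations ``0, k, 2k, ...`` so that T becomes ``ceil(T/k)``.

    The interval length is multiplied by ``k``.  Raises
    :class:`DegenerateSubsampleError` when fewer than two observations would
    remain (``k >= T``).
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    if k >= table.n_times:
        raise DegenerateSubsampleError(
            f"k = {k} leaves fewer than 2 of the T = {table.n_times} observations"
        )
    idx = list(range(0, table.n_times, k))
    return RankTable(
        occupants=[table.occupants[i] for i in idx],
        time_labels=tuple(table.time_labels[i] for i in idx),
        scores=None if table.scores is None else [table.scores[i] for i in idx],
        interval_length=table.interval_length * k,
    )
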