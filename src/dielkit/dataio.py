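"""Readers and writers for the plain-text tables the pipeline consumes.

All tabular I/O is tab-separated UTF-8 with a decimal point; gene lists are
one identifier per line.  Timepoint headers accept three label dialects:
``ZT<h>`` (hours after lights-on), bare numbers, and ``LD<h>`` (hours from
experiment start, converted to ZT by subtracting a start offset).
"""

from __future__ import annotations

import io
import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("dielkit")

__all__ = [
    "TimeCourse",
    "GeneSet",
    "IdMapping",
    "RhythmCall",
    "TimeCourseFormatError",
    "TimeCourseValidationError",
    "parse_timepoint_label",
    "read_timecourse",
    "write_timecourse",
    "read_gene_set",
    "write_gene_set",
    "read_id_mapping",
    "read_rhythm_calls",
    "write_rhythm_calls",
    "read_presence_matrix",
]


class TimeCourseFormatError(ValueError):
    """Malformed table text (ragged rows, unparsable cells)."""


class TimeCourseValidationError(ValueError):
    """Structurally valid table violating a time-course invariant."""


@dataclass(frozen=True)
class TimeCourse:
    """An expression matrix over an evenly spaced ZT sampling grid.

    Parameters
    ----------
    ids
        Unique, non-empty row identifiers (probesets, transcripts or genes).
    timepoints
        Strictly increasing ZT hours, evenly spaced by `interval`.
    values
        Expression intensities, one row per id, one column per timepoint.
    interval
        Sampling interval in hours.
    """

    ids: tuple[str, ...]
    timepoints: tuple[float, ...]
    values: np.ndarray
    interval: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "timepoints", tuple(float(t) for t in self.timepoints))
        if values.ndim != 2:
            raise TimeCourseValidationError("values must be a 2-D matrix")
        if values.shape != (len(self.ids), len(self.timepoints)):
            raise TimeCourseValidationError(
                f"shape {values.shape} does not match "
                f"{len(self.ids)} ids x {len(self.timepoints)} timepoints"
            )
        if not np.isfinite(values).all():
            raise TimeCourseValidationError("non-finite expression value")
        seen: set[str] = set()
        for i in self.ids:
            if not i:
                raise TimeCourseValidationError("empty id")
            if i in seen:
                raise TimeCourseValidationError(f"duplicate id {i!r}")
            seen.add(i)
        tp = np.asarray(self.timepoints, dtype=float)
        if len(tp) < 2:
            raise TimeCourseValidationError("need at least two timepoints")
        if (tp < 0).any():
            raise TimeCourseValidationError("negative ZT timepoint")
        diffs = np.diff(tp)
        if (diffs <= 0).any():
            raise TimeCourseValidationError(
                "timepoints must be strictly increasing"
            )
        if not np.allclose(diffs, self.interval, rtol=0, atol=1e-9):
            raise TimeCourseValidationError(
                f"timepoints are not evenly spaced by interval={self.interval}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.ids)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.ids.index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"ZT{t:g}" for t in self.timepoints]
        return pd.DataFrame(self.values, index=list(self.ids), columns=cols)


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if any(not m for m in self.members):
            raise ValueError("GeneSet members must be non-empty strings")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, item: str) -> bool:
        return item in self.members


@dataclass(frozen=True)
class IdMapping:
    """A many-to-many identifier mapping as (source, target) pairs."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        pairs = tuple((str(a), str(b)) for a, b in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        seen: set[tuple[str, str]] = set()
        for a, b in pairs:
            if not a or not b:
                raise ValueError("mapping ids must be non-empty")
            if (a, b) in seen:
                raise ValueError(f"duplicate mapping pair {(a, b)!r}")
            seen.add((a, b))

    def targets_of(self, source: str) -> list[str]:
        return [b for a, b in self.pairs if a == source]

    def as_dict(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for a, b in self.pairs:
            out.setdefault(a, []).append(b)
        return out


@dataclass(frozen=True)
class RhythmCall:
    """A per-gene rhythm detection record."""

    id: str
    method: str  # "haystack" or "jtk"
    phase: float  # ZT hours in [0, 24)
    period: float  # hours
    shape: str | None = None
    score: float | None = None  # correlation r (haystack) or S (jtk)
    p_value: float | None = None


_LABEL_RE = re.compile(r"^(ZT|LD|CT)?\s*(-?\d+(?:\.\d+)?)$", re.IGNORECASE)


def parse_timepoint_label(label: str, ld_start_offset: float = 24.0) -> float:
    """Convert a header label to ZT hours.

    ``ZT<h>``/``CT<h>`` and bare numbers are taken at face value; ``LD<h>``
    is hours from experiment start and is converted by subtracting
    `ld_start_offset` (the convention of a sampling series starting at
    lights-on of day two: LD24 -> ZT0).
    """
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise TimeCourseFormatError(f"unparsable timepoint label {label!r}")
    prefix, value = m.group(1), float(m.group(2))
    if prefix is not None and prefix.upper() == "LD":
        value -= ld_start_offset
    if value < 0:
        raise TimeCourseValidationError(f"label {label!r} maps to negative ZT")
    return value


def read_timecourse(
    source,
    interval_hint: float | None = None,
    ld_start_offset: float = 24.0,
) -> TimeCourse:
    """Parse a tab-delimited expression table into a `TimeCourse`.

    The first row is a header: an id column followed by timepoint labels.
    Row order is preserved.  Ragged rows and unparsable cells are format
    errors naming the offending row; duplicate ids and non-monotone
    timepoints are validation errors.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        try:
            text = open(source, "r", encoding="utf-8").read()
        except OSError:
            text = str(source)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise TimeCourseFormatError("empty time-course table")
    header = lines[0].rstrip("\n").split("\t")
    if len(header) < 3:
        raise TimeCourseFormatError("header must contain >=2 timepoints")
    timepoints = [parse_timepoint_label(c, ld_start_offset) for c in header[1:]]
    ncol = len(header)
    ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.rstrip("\n").split("\t")
        if len(cells) != ncol:
            raise TimeCourseFormatError(
                f"row {lineno} has {len(cells)} cells, expected {ncol}"
            )
        ids.append(cells[0].strip())
        try:
            rows.append([float(c) for c in cells[1:]])
        except ValueError as exc:
            raise TimeCourseFormatError(f"row {lineno}: {exc}") from exc
    if interval_hint is not None:
        interval = float(interval_hint)
    else:
        if len(timepoints) < 2:
            raise TimeCourseFormatError("cannot infer interval from one timepoint")
        interval = timepoints[1] - timepoints[0]
    return TimeCourse(tuple(ids), tuple(timepoints), np.asarray(rows), interval)


def write_timecourse(tc: TimeCourse, destination) -> None:
    """Write a time course as a tab-delimited table (ZT-labelled header)."""
    buf = io.StringIO()
    buf.write("id\t" + "\t".join(f"ZT{t:g}" for t in tc.timepoints) + "\n")
    for gene_id, row in zip(tc.ids, tc.values):
        buf.write(gene_id + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    _write_text(destination, buf.getvalue())


def read_gene_set(source, name: str = "geneset") -> GeneSet:
    """Read a one-id-per-line gene list; blanks and duplicates are dropped
    (the duplicate count is logged)."""
    text = source.read() if hasattr(source, "read") else _maybe_file_text(source)
    members: set[str] = set()
    n_dup = 0
    for line in text.splitlines():
        ident = line.strip()
        if not ident:
            continue
        if ident in members:
            n_dup += 1
        members.add(ident)
    if n_dup:
        logger.info("read_gene_set(%s): dropped %d duplicate ids", name, n_dup)
    return GeneSet(name, frozenset(members))


def write_gene_set(gs: GeneSet, destination) -> None:
    _write_text(destination, "\n".join(sorted(gs.members)) + "\n")


def read_id_mapping(source) -> IdMapping:
    """Read a two-column TSV of (source id, target id) pairs; duplicated
    pairs are dropped, header rows starting with '#' ignored."""
    text = source.read() if hasattr(source, "read") else _maybe_file_text(source)
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cells = line.rstrip("\n").split("\t")
        if len(cells) < 2:
            raise TimeCourseFormatError(f"mapping row {lineno}: need 2 columns")
        pair = (cells[0].strip(), cells[1].strip())
        if pair in seen:
            continue
        seen.add(pair)
        pairs.append(pair)
    return IdMapping(tuple(pairs))


_CALL_COLUMNS = ["id", "method", "phase", "period", "shape", "score", "p_value"]


def write_rhythm_calls(calls: Sequence[RhythmCall], destination) -> None:
    """Write detection records as TSV, stably ordered by (id, method)."""
    rows = sorted(calls, key=lambda c: (c.id, c.method))
    buf = io.StringIO()
    buf.write("\t".join(_CALL_COLUMNS) + "\n")
    for c in rows:
        buf.write(
            "\t".join(
                [
                    c.id,
                    c.method,
                    f"{c.phase:g}",
                    f"{c.period:g}",
                    "" if c.shape is None else c.shape,
                    "" if c.score is None else repr(float(c.score)),
                    "" if c.p_value is None else repr(float(c.p_value)),
                ]
            )
            + "\n"
        )
    _write_text(destination, buf.getvalue())


def read_rhythm_calls(source) -> list[RhythmCall]:
    text = source.read() if hasattr(source, "read") else _maybe_file_text(source)
    lines = text.splitlines()
    if not lines or lines[0].split("\t") != _CALL_COLUMNS:
        raise TimeCourseFormatError("rhythm-call table missing expected header")
    out: list[RhythmCall] = []
    for line in lines[1:]:
        if not line.strip():
            continue
        cells = line.split("\t")
        out.append(
            RhythmCall(
                id=cells[0],
                method=cells[1],
                phase=float(cells[2]),
                period=float(cells[3]),
                shape=cells[4] or None,
                score=float(cells[5]) if cells[5] else None,
                p_value=float(cells[6]) if cells[6] else None,
            )
        )
    return out


def read_presence_matrix(source) -> pd.DataFrame:
    """Read a gene x dataset binary membership TSV into a 0/1 DataFrame."""
    if hasattr(source, "read"):
        df = pd.read_csv(source, sep="\t", index_col=0)
    else:
        df = pd.read_csv(io.StringIO(_maybe_file_text(source)), sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise TimeCourseValidationError("duplicate gene ids in presence matrix")
    if not df.isin([0, 1]).all().all():
        raise TimeCourseValidationError("presence matrix must be binary")
    if (df.sum(axis=1) == 0).any():
        raise TimeCourseValidationError("gene present in no dataset")
    return df.astype(int)


def _maybe_file_text(source) -> str:
    try:
        return open(source, "r", encoding="utf-8").read()
    except (OSError, TypeError):
        return str(source)


def _write_text(destination, text: str) -> None:
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        with open(destination, "w", encoding="utf-8") as fh:
            fh.write(text)
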