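"""Genomic intervals, BED I/O, and indexed peak sets.

All coordinates are 0-based, half-open ([start, end)), the native convention
of both BED and chain files.  Conversion to other conventions happens only at
I/O boundaries, never internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO, Union

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "read_bed",
    "write_bed",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A located, optionally stranded region on a named sequence.

    Parameters
    ----------
    seq_name : str
        Sequence (chromosome/contig) identifier.
    start, end : int
        0-based half-open coordinates; ``0 <= start < end`` is enforced.
    strand : str
        One of ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    seq_name: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not isinstance(self.start, int) or not isinstance(self.end, int):
            raise TypeError("start and end must be integers")
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.seq_name}:{self.start}-{self.end}: "
                "requires 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 base on the same sequence."""
        return (
            self.seq_name == other.seq_name
            and self.start < other.end
            and other.start < self.end
        )

    def expanded(self, flank: int, seq_size: int | None = None) -> "GenomicInterval":
        """Symmetric extension by ``flank`` bases, clipped at 0 and seq_size."""
        start = max(0, self.start - flank)
        end = self.end + flank
        if seq_size is not None:
            end = min(end, seq_size)
        return GenomicInterval(self.seq_name, start, end, self.strand)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.seq_name}:{self.start}-{self.end}({self.strand})"


def _open_maybe(source: Union[str, Path, TextIO], mode: str = "r"):
    if isinstance(source, (str, Path)):
        return open(source, mode), True
    return source, False


def read_bed(source: Union[str, Path, TextIO]) -> list[GenomicInterval]:
    """Read BED3/BED6 records; the strand column is honored when present."""
    handle, close = _open_maybe(source)
    out: list[GenomicInterval] = []
    try:
        for line_no, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"BED line {line_no}: fewer than 3 columns")
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            out.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            )
    finally:
        if close:
            handle.close()
    return out


def write_bed(
    intervals: Iterable[GenomicInterval],
    dest: Union[str, Path, TextIO],
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    """Write BED3 (or BED6 when names/scores are given)."""
    handle, close = _open_maybe(dest, "w")
    try:
        for i, iv in enumerate(intervals):
            cols = [iv.seq_name, str(iv.start), str(iv.end)]
            if names is not None or scores is not None:
                cols.append(names[i] if names is not None else f"region_{i}")
                cols.append(str(scores[i]) if scores is not None else "0")
                cols.append(iv.strand if iv.strand != "." else "+")
            handle.write("\t".join(cols) + "\n")
    finally:
        if close:
            handle.close()


class PeakSet:
    """A named, indexed collection of intervals (peaks from one assay).

    Overlap queries run against per-sequence interval trees and agree with a
    linear scan by construction of :mod:`intervaltree`.
    """

    def __init__(self, intervals: Iterable[GenomicInterval], name: str = "") -> None:
        self.name = name
        self.intervals: tuple[GenomicInterval, ...] = tuple(
            sorted(intervals, key=lambda iv: (iv.seq_name, iv.start, iv.end))
        )
        self._trees: dict[str, IntervalTree] = {}
        for iv in self.intervals:
            self._trees.setdefault(iv.seq_name, IntervalTree()).addi(
                iv.start, iv.end, iv
            )

    @classmethod
    def from_bed(cls, path: Union[str, Path, TextIO], name: str = "") -> "PeakSet":
        name = name or (Path(path).stem if isinstance(path, (str, Path)) else "")
        return cls(read_bed(path), name=name)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def overlaps(self, region: GenomicInterval) -> bool:
        """True iff ``region`` shares >= 1 base with any peak."""
        tree = self._trees.get(region.seq_name)
        return bool(tree is not None and tree.overlap(region.start, region.end))

    def overlapping(self, region: GenomicInterval) -> list[GenomicInterval]:
        tree = self._trees.get(region.seq_name)
        if tree is None:
            return []
        return sorted(
            (hit.data for hit in tree.overlap(region.start, region.end)),
            key=lambda iv: (iv.start, iv.end),
        )
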