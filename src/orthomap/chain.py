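"""UCSC chain parsing, validation, indexing and multi-mapping lift-over.

A chain record describes one chained pairwise alignment as a header line
followed by gapless block lines.  In over.chain nomenclature the header's
first ("t") side is the genome coordinates are lifted FROM; to avoid clashing
with the query/target vocabulary of cross-species mapping, that side is
called ``source`` here and the genome being lifted TO is called ``dest``.

The source strand is always forward.  Destination coordinates of
reverse-strand chains are stored raw (reverse-oriented, as in the file) and
flipped to forward orientation at lift time; raw reverse coordinates never
escape this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, TextIO, Union

from intervaltree import IntervalTree

from .intervals import GenomicInterval

__all__ = [
    "AlignmentBlock",
    "ChainSide",
    "Chain",
    "ChainIndex",
    "ChainFormatError",
    "parse_chain_file",
    "write_chain_file",
    "build_index",
    "lift_interval",
    "invert_chain",
]


class ChainFormatError(ValueError):
    """Raised for malformed or arithmetically inconsistent chain records."""


@dataclass(frozen=True)
class AlignmentBlock:
    """One gapless aligned block: ``size`` bases, then a gap of ``dt`` bases
    on the source side and ``dq`` bases on the destination side."""

    size: int
    dt: int = 0
    dq: int = 0

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ChainFormatError(f"block size must be positive, got {self.size}")
        if self.dt < 0 or self.dq < 0:
            raise ChainFormatError("block gaps must be non-negative")


@dataclass(frozen=True)
class ChainSide:
    seq_name: str
    seq_size: int
    strand: str
    start: int
    end: int


@dataclass(frozen=True)
class Chain:
    """A validated chain record (header plus ordered blocks)."""

    score: float
    source: ChainSide
    dest: ChainSide
    chain_id: int
    blocks: tuple[AlignmentBlock, ...]

    def __post_init__(self) -> None:
        if self.source.strand != "+":
            raise ChainFormatError(
                f"chain {self.chain_id}: source strand must be '+', "
                f"got {self.source.strand!r}"
            )
        if not self.blocks:
            raise ChainFormatError(f"chain {self.chain_id}: no blocks")
        last = self.blocks[-1]
        if last.dt != 0 or last.dq != 0:
            raise ChainFormatError(
                f"chain {self.chain_id}: last block must have zero gaps"
            )
        src_span = sum(b.size + b.dt for b in self.blocks)
        dst_span = sum(b.size + b.dq for b in self.blocks)
        if src_span != self.source.end - self.source.start:
            raise ChainFormatError(
                f"chain {self.chain_id}: source block sum {src_span} != "
                f"header span {self.source.end - self.source.start}"
            )
        if dst_span != self.dest.end - self.dest.start:
            raise ChainFormatError(
                f"chain {self.chain_id}: dest block sum {dst_span} != "
                f"header span {self.dest.end - self.dest.start}"
            )


def parse_chain_file(source: Union[str, Path, TextIO]) -> list[Chain]:
    """Parse a UCSC chain file into validated :class:`Chain` records.

    Records are a 13-field ``chain`` header followed by block lines of
    ``size [dt dq]``; blank lines separate records.  Raises
    :class:`ChainFormatError` with the offending line number on malformed
    headers, non-integer fields, or block sums inconsistent with the header.
    """
    if isinstance(source, (str, Path)):
        with open(source) as handle:
            return parse_chain_file(handle)

    chains: list[Chain] = []
    header: list[str] | None = None
    header_line = 0
    blocks: list[tuple[int, int, int]] = []

    def finish(line_no: int) -> None:
        nonlocal header, blocks
        if header is None:
            return
        if not blocks:
            raise ChainFormatError(f"line {header_line}: chain record has no blocks")
        try:
            score = float(header[1])
            s_name, s_size, s_strand = header[2], int(header[3]), header[4]
            s_start, s_end = int(header[5]), int(header[6])
            d_name, d_size, d_strand = header[7], int(header[8]), header[9]
            d_start, d_end = int(header[10]), int(header[11])
            chain_id = int(header[12])
        except ValueError as exc:
            raise ChainFormatError(f"line {header_line}: non-numeric field: {exc}")
        parsed = tuple(AlignmentBlock(*b) for b in blocks)
        chains.append(
            Chain(
                score=score,
                source=ChainSide(s_name, s_size, s_strand, s_start, s_end),
                dest=ChainSide(d_name, d_size, d_strand, d_start, d_end),
                chain_id=chain_id,
                blocks=parsed,
            )
        )
        header, blocks = None, []

    line_no = 0
    for line_no, raw in enumerate(source, 1):
        line = raw.strip()
        if not line:
            finish(line_no)
            continue
        if line.startswith("chain"):
            finish(line_no)
            fields = line.split()
            if len(fields) != 13:
                raise ChainFormatError(
                    f"line {line_no}: chain header has {len(fields)} fields, "
                    "expected 13"
                )
            header, header_line = fields, line_no
            continue
        if header is None:
            raise ChainFormatError(f"line {line_no}: block line outside a record")
        parts = line.split()
        if len(parts) not in (1, 3):
            raise ChainFormatError(
                f"line {line_no}: block line must have 1 or 3 fields"
            )
        try:
            nums = [int(p) for p in parts]
        except ValueError:
            raise ChainFormatError(f"line {line_no}: non-integer block field")
        if len(nums) == 1:
            nums += [0, 0]
        blocks.append((nums[0], nums[1], nums[2]))
    finish(line_no + 1)
    return chains


def write_chain_file(
    chains: Iterable[Chain], dest: Union[str, Path, TextIO]
) -> None:
    """Write chains in UCSC format (bit-exact field order, blank-line
    separated records, gap fields omitted on the final block line)."""
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as handle:
            write_chain_file(chains, handle)
        return
    for chain in chains:
        score = int(chain.score) if chain.score == int(chain.score) else chain.score
        s, d = chain.source, chain.dest
        dest.write(
            f"chain {score} {s.seq_name} {s.seq_size} {s.strand} "
            f"{s.start} {s.end} {d.seq_name} {d.seq_size} {d.strand} "
            f"{d.start} {d.end} {chain.chain_id}\n"
        )
        for block in chain.blocks[:-1]:
            dest.write(f"{block.size} {block.dt} {block.dq}\n")
        dest.write(f"{chain.blocks[-1].size}\n\n")


class ChainIndex:
    """Per-sequence interval index over chain source spans."""

    def __init__(self, chains: Iterable[Chain]) -> None:
        self.chains: tuple[Chain, ...] = tuple(chains)
        self._trees: dict[str, IntervalTree] = {}
        for chain in self.chains:
            self._trees.setdefault(chain.source.seq_name, IntervalTree()).addi(
                chain.source.start, chain.source.end, chain
            )

    def query(self, seq_name: str, start: int, end: int) -> list[Chain]:
        """All chains whose source span overlaps [start, end) on seq_name,
        in (source start, chain id) order."""
        tree = self._trees.get(seq_name)
        if tree is None:
            return []
        hits = [hit.data for hit in tree.overlap(start, end)]
        return sorted(hits, key=lambda c: (c.source.start, c.chain_id))

    def source_sizes(self) -> dict[str, int]:
        """Source-genome sequence sizes recorded in the chain headers."""
        return {c.source.seq_name: c.source.seq_size for c in self.chains}


def build_index(chains: Iterable[Chain]) -> ChainIndex:
    return ChainIndex(chains)


def _lift_through_chain(
    q: GenomicInterval, chain: Chain
) -> list[GenomicInterval]:
    """Maximal gapless destination segments for the bases of ``q`` that fall
    inside this chain's alignment blocks, flipped to forward orientation."""
    raw: list[tuple[int, int]] = []
    s = chain.source.start
    d = chain.dest.start
    for block in chain.blocks:
        lo = max(q.start, s)
        hi = min(q.end, s + block.size)
        if lo < hi:
            raw.append((d + (lo - s), d + (hi - s)))
        s += block.size + block.dt
        d += block.size + block.dq
        if s >= q.end:
            break
    if not raw:
        return []
    if chain.dest.strand == "-":
        size = chain.dest.seq_size
        raw = [(size - e, size - b) for b, e in raw]
        raw.reverse()
    # merge abutting segments into maximal gapless runs
    merged: list[list[int]] = [list(raw[0])]
    for b, e in raw[1:]:
        if b == merged[-1][1]:
            merged[-1][1] = e
        else:
            merged.append([b, e])
    strand = chain.dest.strand
    return [
        GenomicInterval(chain.dest.seq_name, b, e, strand) for b, e in merged
    ]


def lift_interval(
    q: GenomicInterval,
    index: ChainIndex,
    min_mapped_fraction: float = 0.0,
) -> list[tuple[int, list[GenomicInterval]]]:
    """Lift ``q`` through every overlapping chain.

    Returns ``[(chain_id, segments), ...]`` where ``segments`` are the
    disjoint, sorted, forward-orientation destination intervals covering the
    bases of ``q`` inside alignment blocks.  Chains mapping fewer than
    ``min_mapped_fraction * width(q)`` bases are dropped.  Multi-chain
    results are all retained: multi-mapping is resolved downstream by
    similarity scoring, not here.  An unknown sequence name yields ``[]``.
    """
    if not 0.0 <= min_mapped_fraction <= 1.0:
        raise ValueError("min_mapped_fraction must be in [0, 1]")
    out: list[tuple[int, list[GenomicInterval]]] = []
    for chain in index.query(q.seq_name, q.start, q.end):
        segments = _lift_through_chain(q, chain)
        if not segments:
            continue
        mapped = sum(seg.width for seg in segments)
        if mapped < min_mapped_fraction * q.width:
            continue
        out.append((chain.chain_id, segments))
    return out


def invert_chain(chain: Chain) -> Chain:
    """Swap the source and destination sides of a forward/forward chain.

    Only forward-destination chains can be inverted directly (the inverted
    source must be forward-stranded); used for round-trip checks on
    one-to-one chain sets.
    """
    if chain.dest.strand != "+":
        raise ValueError("can only invert a forward-destination chain")
    blocks = tuple(
        AlignmentBlock(b.size, b.dq, b.dt) for b in chain.blocks
    )
    return Chain(
        score=chain.score,
        source=chain.dest,
        dest=chain.source,
        chain_id=chain.chain_id,
        blocks=blocks,
    )
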