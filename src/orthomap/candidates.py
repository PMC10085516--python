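"""Adaptive candidate generation: two-step mapping, gap merging, tiling.

The mapping of a query region proceeds in two steps.  Step one lifts the
query directly through the chains; if that yields nothing, the query is
extended symmetrically by a local window and the extended interval is lifted
instead.  Small gaps (< 10 bp by default) between the resulting orthologous
segments are merged, and each merged region is tiled with evenly spaced
candidate target windows whose width equals the query's width.  Every
candidate is retained — multi-mapping is resolved later by similarity
scoring, never by a one-to-one constraint here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .chain import ChainIndex, lift_interval
from .intervals import GenomicInterval

__all__ = [
    "OrthologousRegion",
    "CandidateTarget",
    "DEFAULT_WINDOW",
    "DEFAULT_GAP_THRESHOLD",
    "DEFAULT_RESOLUTION",
    "merge_small_gaps",
    "adaptive_map",
    "tile_candidates",
    "generate_candidates",
]

#: Local extension window in bases; ~2 kb is the cross-validated optimum.
DEFAULT_WINDOW = 2000
#: Gaps strictly below this many bases between orthologous segments are merged.
DEFAULT_GAP_THRESHOLD = 10
#: Spacing of candidate tile starts along a merged orthologous region.
DEFAULT_RESOLUTION = 50


@dataclass(frozen=True)
class OrthologousRegion:
    """A merged lifted segment group on the target genome.

    ``chain_ids`` records every chain contributing to the merged region;
    ``origin`` is ``'direct'`` when the query lifted without extension and
    ``'extended'`` when the windowed rescue produced it.
    """

    region: GenomicInterval
    chain_ids: tuple[int, ...]
    origin: str


@dataclass(frozen=True)
class CandidateTarget:
    """One candidate target window for a query, scored downstream."""

    query: GenomicInterval
    target: GenomicInterval
    chain_ids: tuple[int, ...] = ()
    origin: str = "direct"
    epi_similarity: float | None = None
    seq_similarity: float | None = None
    probability: float | None = None

    def with_scores(
        self, epi: float, seq: float, probability: float
    ) -> "CandidateTarget":
        return replace(
            self, epi_similarity=epi, seq_similarity=seq, probability=probability
        )


def merge_small_gaps(
    segments: list[GenomicInterval], gap_threshold: int
) -> list[GenomicInterval]:
    """Union consecutive same-sequence segments separated by < gap_threshold.

    Merging is transitive; the output is sorted and disjoint with all
    remaining same-sequence separations >= gap_threshold.  Input must be
    sorted by (sequence, start).
    """
    if segments != sorted(segments, key=lambda s: (s.seq_name, s.start, s.end)):
        raise ValueError("merge_small_gaps requires sorted input segments")
    merged: list[GenomicInterval] = []
    for seg in segments:
        if (
            merged
            and seg.seq_name == merged[-1].seq_name
            and seg.start - merged[-1].end < gap_threshold
        ):
            prev = merged[-1]
            merged[-1] = GenomicInterval(
                prev.seq_name, prev.start, max(prev.end, seg.end), prev.strand
            )
        else:
            merged.append(seg)
    return merged


def _merge_with_provenance(
    tagged: list[tuple[GenomicInterval, int]], gap_threshold: int, origin: str
) -> list[OrthologousRegion]:
    """Merge (segment, chain_id) pairs across chains, pooling provenance."""
    tagged = sorted(tagged, key=lambda t: (t[0].seq_name, t[0].start, t[0].end))
    out: list[OrthologousRegion] = []
    for seg, cid in tagged:
        if (
            out
            and seg.seq_name == out[-1].region.seq_name
            and seg.start - out[-1].region.end < gap_threshold
        ):
            prev = out[-1]
            ids = prev.chain_ids if cid in prev.chain_ids else prev.chain_ids + (cid,)
            out[-1] = OrthologousRegion(
                GenomicInterval(
                    prev.region.seq_name,
                    prev.region.start,
                    max(prev.region.end, seg.end),
                    prev.region.strand,
                ),
                ids,
                origin,
            )
        else:
            out.append(OrthologousRegion(seg, (cid,), origin))
    return out


def adaptive_map(
    q: GenomicInterval,
    index: ChainIndex,
    window: int = DEFAULT_WINDOW,
    gap_threshold: int = DEFAULT_GAP_THRESHOLD,
    min_mapped_fraction: float = 0.0,
    seq_sizes: dict[str, int] | None = None,
) -> list[OrthologousRegion]:
    """Two-step mapping of one query region.

    Direct lift first; a partially mapping query counts as a direct success.
    Only when the direct lift is empty is the query extended by ``window``
    bases on both sides (clipped at 0 and at the sequence length when known)
    and lifted again.  Merged segments are returned; the list may be empty
    (the query has no orthologous region at this window).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    direct = lift_interval(q, index, min_mapped_fraction)
    if direct:
        tagged = [(seg, cid) for cid, segs in direct for seg in segs]
        return _merge_with_provenance(tagged, gap_threshold, "direct")
    if window == 0:
        return []
    sizes = seq_sizes if seq_sizes is not None else index.source_sizes()
    extended = q.expanded(window, sizes.get(q.seq_name))
    lifted = lift_interval(extended, index, 0.0)
    tagged = [(seg, cid) for cid, segs in lifted for seg in segs]
    return _merge_with_provenance(tagged, gap_threshold, "extended")


def tile_candidates(
    region: GenomicInterval,
    query_width: int,
    resolution: int = DEFAULT_RESOLUTION,
    seq_size: int | None = None,
) -> list[GenomicInterval]:
    """Evenly spaced candidate windows of ``query_width`` over a region.

    A region no wider than the query yields exactly one tile centered on it
    (so every orthologous region contributes at least one candidate).  Wider
    regions get start-anchored tiles every ``resolution`` bases plus a final
    flush tile ending at the region's end.  Tiles are clipped to sequence
    bounds: a centered tile is shifted inside, grid tiles falling outside are
    dropped.
    """
    if query_width < 1:
        raise ValueError("query_width must be >= 1")
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    strand = region.strand
    if region.width <= query_width:
        start = region.start + (region.width - query_width) // 2
        start = max(0, start)
        if seq_size is not None and start + query_width > seq_size:
            start = seq_size - query_width
            if start < 0:
                return []
        return [GenomicInterval(region.seq_name, start, start + query_width, strand)]
    last_start = region.end - query_width
    starts = list(range(region.start, last_start + 1, resolution))
    if starts[-1] != last_start:
        starts.append(last_start)  # flush tile ending at region.end
    tiles = []
    for s in starts:
        if s < 0 or (seq_size is not None and s + query_width > seq_size):
            continue
        tiles.append(GenomicInterval(region.seq_name, s, s + query_width, strand))
    return sorted(set(tiles), key=lambda t: (t.seq_name, t.start))


def generate_candidates(
    q: GenomicInterval,
    index: ChainIndex,
    window: int = DEFAULT_WINDOW,
    gap_threshold: int = DEFAULT_GAP_THRESHOLD,
    resolution: int = DEFAULT_RESOLUTION,
    min_mapped_fraction: float = 0.0,
    seq_sizes: dict[str, int] | None = None,
    dest_seq_sizes: dict[str, int] | None = None,
) -> list[CandidateTarget]:
    """Adaptive mapping, gap merging and tiling composed for one query.

    Returns unscored candidates; empty iff the adaptive mapping found no
    orthologous region.  ``dest_seq_sizes`` bounds tile placement on the
    target genome (defaults to the sizes recorded in the chain headers).
    """
    regions = adaptive_map(
        q, index, window, gap_threshold, min_mapped_fraction, seq_sizes
    )
    if dest_seq_sizes is None:
        dest_seq_sizes = {
            c.dest.seq_name: c.dest.seq_size for c in index.chains
        }
    out: list[CandidateTarget] = []
    seen: set[tuple[str, int, int]] = set()
    for reg in regions:
        size = dest_seq_sizes.get(reg.region.seq_name)
        for tile in tile_candidates(reg.region, q.width, resolution, size):
            key = (tile.seq_name, tile.start, tile.end)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                CandidateTarget(
                    query=q, target=tile, chain_ids=reg.chain_ids, origin=reg.origin
                )
            )
    return out
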