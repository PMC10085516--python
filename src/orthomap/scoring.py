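"""Similarity scoring and candidate selection.

Each candidate target T_i of a query Q receives an epigenomic similarity
E_i = sim(e_Q, e_Ti) and a sequence-grammar similarity S_i = sim(s_Q, s_Ti),
where sim is the weighted cosine of binary vectors:

    sim(u, v) = sum_i w_i u_i v_i / (sqrt(sum_i w_i u_i) * sqrt(sum_i w_i v_i))

with equal weights by default.  The two similarities feed a logistic score

    P(T_i orthologous to Q) = sigma(beta0 + beta1 * E_i + beta2 * S_i)

with default coefficients (-3, 4, 5); selection keeps candidates above a
probability threshold (0.4 by default), ranked descending, optionally capped
at top k.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .candidates import CandidateTarget
from .features import (
    MatchedFeatureConfig,
    MotifScanner,
    epigenomic_vector,
    fetch_sequence,
)
from .intervals import GenomicInterval

__all__ = [
    "LogisticParams",
    "SelectionPolicy",
    "DEFAULT_PARAMS",
    "DEFAULT_POLICY",
    "weighted_cosine",
    "weighted_jaccard",
    "logistic_score",
    "score_candidates",
    "select_targets",
]


@dataclass(frozen=True)
class LogisticParams:
    """Coefficients (intercept, epigenomic slope, grammar slope)."""

    beta0: float = -3.0
    beta1: float = 4.0
    beta2: float = 5.0

    def __post_init__(self) -> None:
        for value in (self.beta0, self.beta1, self.beta2):
            if not np.isfinite(value):
                raise ValueError("logistic coefficients must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2])


@dataclass(frozen=True)
class SelectionPolicy:
    """Probability threshold and/or top-k cap; threshold applies first."""

    threshold: float = 0.4
    k: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")
        if self.k is not None and self.k < 1:
            raise ValueError("k must be a positive count or None")


DEFAULT_PARAMS = LogisticParams()
DEFAULT_POLICY = SelectionPolicy()


def _check_pair(u: np.ndarray, v: np.ndarray, w: np.ndarray | None):
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("vectors must be 1-D with matching dimensions")
    if w is None:
        w = np.ones_like(u)
    else:
        w = np.asarray(w, dtype=float)
        if w.shape != u.shape:
            raise ValueError("weight dimension mismatch")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
    return u, v, w


def weighted_cosine(
    u: Sequence[int], v: Sequence[int], w: Sequence[float] | None = None
) -> float:
    """Weighted cosine similarity of two binary vectors, in [0, 1].

    A vector with empty weighted support scores 0 against anything: an
    unannotated region carries no evidence of conservation.
    """
    u, v, w = _check_pair(u, v, w)
    num = float(np.sum(w * u * v))
    denom_u = float(np.sum(w * u))
    denom_v = float(np.sum(w * v))
    if denom_u <= 0.0 or denom_v <= 0.0:
        return 0.0
    return num / float(np.sqrt(denom_u * denom_v))


def weighted_jaccard(
    u: Sequence[int], v: Sequence[int], w: Sequence[float] | None = None
) -> float:
    """Weighted Jaccard of binary vectors (experimental alternative; cosine
    is the default as it is the more stable of the two for binary features)."""
    u, v, w = _check_pair(u, v, w)
    inter = float(np.sum(w * u * v))
    union = float(np.sum(w * np.maximum(u, v)))
    if union <= 0.0:
        return 0.0
    return inter / union


_SIMILARITIES = {"cosine": weighted_cosine, "jaccard": weighted_jaccard}


def logistic_score(
    E: float, S: float, params: LogisticParams = DEFAULT_PARAMS
) -> float:
    """sigma(beta0 + beta1*E + beta2*S); strictly increasing in each
    similarity when its slope is positive."""
    return float(expit(params.beta0 + params.beta1 * E + params.beta2 * S))


def _grammar_bits_batched(
    tiles: Sequence[GenomicInterval],
    genome: Mapping[str, object],
    scanner: MotifScanner,
    flank: int,
) -> list[np.ndarray]:
    """Grammar bits for many tiles, scanning each covering span only once.

    Tiles are clustered per sequence; each cluster's span is scanned for hit
    start positions, and a tile's bit is set iff some hit lies entirely
    within the tile extended by the flank.  Equivalent to scanning every
    tile independently, but linear in covered bases instead of tile count
    times tile width.
    """
    motif_lengths = [pwm.length for pwm in scanner.motifs]
    bits = [np.zeros(len(scanner.motifs), dtype=np.uint8) for _ in tiles]
    order = sorted(
        range(len(tiles)), key=lambda i: (tiles[i].seq_name, tiles[i].start)
    )
    cluster: list[int] = []

    def flush() -> None:
        if not cluster:
            return
        seq_name = tiles[cluster[0]].seq_name
        lo = min(tiles[i].start for i in cluster) - flank
        hi = max(tiles[i].end for i in cluster) + flank
        seq, clipped_lo = fetch_sequence(genome, seq_name, lo, hi)
        hit_lists = scanner.hit_starts(seq)
        for m, (starts, length) in enumerate(zip(hit_lists, motif_lengths)):
            if not starts.size:
                continue
            abs_starts = starts + clipped_lo
            abs_ends = abs_starts + length
            for i in cluster:
                a = np.searchsorted(abs_starts, tiles[i].start - flank, "left")
                b = np.searchsorted(abs_starts, tiles[i].end + flank, "left")
                if np.any(abs_ends[a:b] <= tiles[i].end + flank):
                    bits[i][m] = 1
        cluster.clear()

    span_gap = 10_000  # start a new scan cluster past this separation
    for i in order:
        if cluster and (
            tiles[i].seq_name != tiles[cluster[-1]].seq_name
            or tiles[i].start - tiles[cluster[-1]].end > span_gap
        ):
            flush()
        cluster.append(i)
    flush()
    return bits


def score_candidates(
    cands: Sequence[CandidateTarget],
    config: MatchedFeatureConfig,
    query_genome: Mapping[str, object],
    target_genome: Mapping[str, object],
    params: LogisticParams = DEFAULT_PARAMS,
    scanner: MotifScanner | None = None,
    similarity: str = "cosine",
) -> list[CandidateTarget]:
    """Attach E, S and the logistic probability to each candidate.

    All candidates must share one query region; its feature vectors are
    computed once from the query-genome side of each pair, candidate vectors
    from the target-genome side.  Input order is preserved.
    """
    if not cands:
        return []
    queries = {c.query for c in cands}
    if len(queries) != 1:
        raise ValueError("score_candidates expects candidates of one query")
    query = cands[0].query
    sim = _SIMILARITIES[similarity]
    if scanner is None:
        scanner = config.scanner()

    e_query = epigenomic_vector(query, config.query_peak_sets())
    s_query = _grammar_bits_batched([query], query_genome, scanner, config.flank)[0]

    target_sets = config.target_peak_sets()
    tiles = [c.target for c in cands]
    s_tiles = _grammar_bits_batched(tiles, target_genome, scanner, config.flank)
    weights = config.epi_weights

    scored = []
    for cand, s_tile in zip(cands, s_tiles):
        e_tile = epigenomic_vector(cand.target, target_sets)
        E = sim(e_query, e_tile, weights)
        S = sim(s_query, s_tile, None)
        scored.append(cand.with_scores(E, S, logistic_score(E, S, params)))
    return scored


def select_targets(
    scored: Sequence[CandidateTarget],
    policy: SelectionPolicy = DEFAULT_POLICY,
) -> list[CandidateTarget]:
    """Threshold, rank descending by probability, keep at most k.

    Ties break by (sequence name, start) ascending so results are
    deterministic across runs.
    """
    kept = [
        c
        for c in scored
        if c.probability is not None and c.probability >= policy.threshold
    ]
    kept.sort(key=lambda c: (-c.probability, c.target.seq_name, c.target.start))
    if policy.k is not None:
        kept = kept[: policy.k]
    return kept
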