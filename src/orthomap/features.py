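"""Binary feature spaces: epigenomic peak overlap and sequence grammar.

Two binary vectors describe each region.  The epigenomic vector has one bit
per matched cross-species dataset pair; bit *d* is 1 iff the region overlaps
at least one peak of pair *d*'s peak set on the region's own genome.  The
sequence-grammar vector has one bit per PWM motif; bit *m* is 1 iff the
region (optionally extended by a flank) contains a motif hit whose log-odds
score reaches the p-value-derived threshold on either strand.

Binarization trades quantitative signal for robustness and speed; both
vectors feed the weighted cosine similarity downstream.

Motif scoring uses log2-odds against a background base composition, with a
pseudocount applied to count matrices.  Scores are discretized on a fixed
grid (0.01 log2-odds units by default); the p-value threshold is computed by
exact dynamic programming over the per-position score distribution on the
same grid, so threshold and scan arithmetic are identical and the
discretization error never exceeds half a grid unit per position.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

import numpy as np
import yaml

from .intervals import GenomicInterval, PeakSet

__all__ = [
    "PWM",
    "FeaturePair",
    "MatchedFeatureConfig",
    "MotifScanner",
    "parse_jaspar",
    "write_jaspar",
    "pvalue_score_threshold",
    "epigenomic_vector",
    "sequence_grammar_vector",
    "fetch_sequence",
]

DEFAULT_P_CUTOFF = 5e-5
DEFAULT_PSEUDOCOUNT = 0.8
DEFAULT_GRID = 0.01
UNIFORM_BACKGROUND = np.full(4, 0.25)

_BASE_ORDER = "ACGT"
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(_BASE_ORDER):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.int8)


@dataclass(frozen=True)
class PWM:
    """A position weight matrix (counts or probabilities, 4 x L, ACGT rows)."""

    motif_id: str
    matrix: np.ndarray
    name: str = ""
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", matrix)
        if matrix.ndim != 2 or matrix.shape[0] != 4 or matrix.shape[1] < 1:
            raise ValueError(f"PWM {self.motif_id}: matrix must be 4 x L with L >= 1")
        if np.any(matrix < 0):
            raise ValueError(f"PWM {self.motif_id}: negative matrix entries")
        if np.any(matrix.sum(axis=0) <= 0):
            raise ValueError(f"PWM {self.motif_id}: degenerate all-zero column")
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "background", bg)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0) or np.any(bg <= 0):
            raise ValueError(f"PWM {self.motif_id}: invalid background")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
        """log2-odds matrix; pseudocount is spread by background composition."""
        probs = self.matrix + pseudocount * self.background[:, None]
        probs = probs / probs.sum(axis=0, keepdims=True)
        return np.log2(probs / self.background[:, None])

    def int_scores(
        self,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        grid: float = DEFAULT_GRID,
    ) -> np.ndarray:
        """5 x L integer score matrix on the grid; row 4 (N/ambiguous) is 0."""
        lo = np.rint(self.log_odds(pseudocount) / grid).astype(np.int64)
        out = np.zeros((5, self.length), dtype=np.int64)
        out[:4] = lo
        return out


_JASPAR_ROW = re.compile(r"^\s*([ACGTacgt])\s*\[?\s*([-0-9.eE+\s]*?)\s*\]?\s*$")


def parse_jaspar(source: Union[str, Path, TextIO]) -> list[PWM]:
    """Parse JASPAR-style PFM text: '>ID name' plus 4 A/C/G/T rows.

    Both the bracketed ('A [ 1 2 3 ]') and bare-number row styles are
    accepted; rows may appear in any order but all four bases must occur.
    """
    if isinstance(source, (str, Path)):
        with open(source) as handle:
            return parse_jaspar(handle)
    motifs: list[PWM] = []
    header: tuple[str, str] | None = None
    rows: dict[str, list[float]] = {}

    def finish() -> None:
        nonlocal header, rows
        if header is None:
            return
        if set(rows) != set("ACGT"):
            raise ValueError(f"motif {header[0]}: missing base rows")
        matrix = np.array([rows[b] for b in _BASE_ORDER])
        motifs.append(PWM(motif_id=header[0], matrix=matrix, name=header[1]))
        header, rows = None, {}

    for line in source:
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith(">"):
            finish()
            parts = line[1:].split(None, 1)
            header = (parts[0], parts[1].strip() if len(parts) > 1 else "")
            continue
        match = _JASPAR_ROW.match(line)
        if match is None or header is None:
            raise ValueError(f"unparseable PFM line: {line!r}")
        rows[match.group(1).upper()] = [float(x) for x in match.group(2).split()]
    finish()
    return motifs


def write_jaspar(motifs: Iterable[PWM], dest: Union[str, Path, TextIO]) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as handle:
            write_jaspar(motifs, handle)
        return
    for pwm in motifs:
        dest.write(f">{pwm.motif_id} {pwm.name}\n".rstrip() + "\n")
        for i, base in enumerate(_BASE_ORDER):
            values = " ".join(f"{v:g}" for v in pwm.matrix[i])
            dest.write(f"{base} [ {values} ]\n")


def _score_distribution(
    int_matrix: np.ndarray, background: np.ndarray
) -> tuple[int, np.ndarray]:
    """Exact distribution of the total integer score under the background.

    Returns (minimum attainable score, probability array) where entry i is
    P(score == minimum + i).  Dynamic programming column by column.
    """
    base_min = 0
    dist = np.ones(1)
    for j in range(int_matrix.shape[1]):
        col = int_matrix[:4, j]
        lo, hi = int(col.min()), int(col.max())
        new = np.zeros(dist.size + hi - lo)
        for b in range(4):
            off = int(col[b]) - lo
            new[off : off + dist.size] += background[b] * dist
        dist = new
        base_min += lo
    return base_min, dist


def pvalue_score_threshold(
    pwm: PWM,
    p: float,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    grid: float = DEFAULT_GRID,
) -> float:
    """Score threshold with tail probability at most ``p`` under background.

    Computed exactly on the discretized score distribution: the threshold is
    the smallest grid score *s* with ``P(score > s) <= p``, clamped below at
    the minimum attainable score (so ``p = 1`` returns the minimum).  A hit
    is a window scoring >= the threshold.  Returned in log2-odds units.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError("p must be in (0, 1]")
    base_min, dist = _score_distribution(
        pwm.int_scores(pseudocount, grid), pwm.background
    )
    # suffix[i] = P(score >= base_min + i); strict tail of s is suffix[i+1]
    suffix = np.cumsum(dist[::-1])[::-1]
    strict_tail = np.append(suffix[1:], 0.0)
    idx = int(np.argmax(strict_tail <= p + 1e-12))
    return (base_min + idx) * grid


class MotifScanner:
    """Batch scanner: per-motif integer matrices and p-value thresholds.

    Precomputes forward and reverse-complement integer score matrices and
    the integer threshold for each motif once, then reports hit start
    offsets (forward-strand coordinates, either strand) in any sequence.
    """

    def __init__(
        self,
        motifs: Sequence[PWM],
        p_cutoff: float = DEFAULT_P_CUTOFF,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        grid: float = DEFAULT_GRID,
    ) -> None:
        self.motifs = tuple(motifs)
        self.p_cutoff = p_cutoff
        self.grid = grid
        self._fwd: list[np.ndarray] = []
        self._rev: list[np.ndarray] = []
        self._thresholds: list[int] = []
        for pwm in self.motifs:
            mat = pwm.int_scores(pseudocount, grid)
            self._fwd.append(mat)
            self._rev.append(mat[_COMPLEMENT][:, ::-1].copy())
            thr = pvalue_score_threshold(pwm, p_cutoff, pseudocount, grid)
            self._thresholds.append(int(round(thr / grid)))

    @staticmethod
    def encode(seq: str) -> np.ndarray:
        return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]

    @staticmethod
    def _window_scores(codes: np.ndarray, matrix: np.ndarray) -> np.ndarray:
        length = matrix.shape[1]
        n = codes.size - length + 1
        if n <= 0:
            return np.empty(0, dtype=np.int64)
        scores = np.zeros(n, dtype=np.int64)
        for j in range(length):
            scores += matrix[codes[j : j + n], j]
        return scores

    def hit_starts(self, seq: str) -> list[np.ndarray]:
        """Per motif: sorted unique start offsets of hits on either strand."""
        codes = self.encode(seq)
        out: list[np.ndarray] = []
        for fwd, rev, thr in zip(self._fwd, self._rev, self._thresholds):
            hits_f = np.nonzero(self._window_scores(codes, fwd) >= thr)[0]
            hits_r = np.nonzero(self._window_scores(codes, rev) >= thr)[0]
            out.append(np.union1d(hits_f, hits_r))
        return out

    def bits(self, seq: str) -> np.ndarray:
        """0/1 vector: motif present anywhere in ``seq`` on either strand."""
        return np.array(
            [1 if starts.size else 0 for starts in self.hit_starts(seq)],
            dtype=np.uint8,
        )


def fetch_sequence(
    genome: Mapping[str, object], seq_name: str, start: int, end: int
) -> tuple[str, int]:
    """Slice [start, end) from a genome (dict of strings or pyfaidx.Fasta),
    clipping at the sequence bounds.  Returns (sequence, clipped start)."""
    if seq_name not in genome:
        raise KeyError(f"sequence {seq_name!r} not in genome")
    record = genome[seq_name]
    size = len(record)
    lo, hi = max(0, start), min(end, size)
    if lo >= hi:
        return "", lo
    return str(record[lo:hi]).upper(), lo


def epigenomic_vector(
    r: GenomicInterval, peak_sets: Sequence[PeakSet]
) -> np.ndarray:
    """Binary overlap vector: bit d = 1 iff r shares >= 1 base with any peak
    of peak set d.  Unknown sequence names simply yield 0 bits."""
    return np.array(
        [1 if ps.overlaps(r) else 0 for ps in peak_sets], dtype=np.uint8
    )


def sequence_grammar_vector(
    r: GenomicInterval,
    genome: Mapping[str, object],
    motifs: Sequence[PWM] | None = None,
    flank: int = 0,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    scanner: MotifScanner | None = None,
) -> np.ndarray:
    """Binary motif-presence vector over ``r`` extended by ``flank`` bases.

    Both strands are scanned; ambiguous bases contribute log-odds 0.  Pass a
    prebuilt :class:`MotifScanner` to amortize threshold computation.
    """
    if scanner is None:
        if motifs is None:
            raise ValueError("provide either motifs or a scanner")
        scanner = MotifScanner(motifs, p_cutoff)
    seq, _ = fetch_sequence(genome, r.seq_name, r.start - flank, r.end + flank)
    return scanner.bits(seq)


@dataclass
class FeaturePair:
    """One matched cross-species dataset pair: the query-genome member, the
    target-genome member, a label, and a non-negative similarity weight."""

    query_peaks: PeakSet
    target_peaks: PeakSet
    label: str = ""
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError(f"pair {self.label!r}: weight must be >= 0")


@dataclass
class MatchedFeatureConfig:
    """The ordered matched dataset pairs plus the motif library.

    Pair order defines the epigenomic coordinate system: index d refers to
    the PAIR, so a query's vector (built from query-genome members) and a
    candidate's vector (built from target-genome members) are comparable
    coordinate-wise.  Equal weights are the default.
    """

    pairs: list[FeaturePair]
    motifs: list[PWM]
    flank: int = 0
    p_cutoff: float = DEFAULT_P_CUTOFF
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    @property
    def epi_dim(self) -> int:
        return len(self.pairs)

    @property
    def seq_dim(self) -> int:
        return len(self.motifs)

    @property
    def epi_weights(self) -> np.ndarray:
        return np.array([p.weight for p in self.pairs], dtype=float)

    def query_peak_sets(self) -> list[PeakSet]:
        return [p.query_peaks for p in self.pairs]

    def target_peak_sets(self) -> list[PeakSet]:
        return [p.target_peaks for p in self.pairs]

    def scanner(self) -> MotifScanner:
        return MotifScanner(self.motifs, self.p_cutoff, self.pseudocount)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "MatchedFeatureConfig":
        """Load a config file listing matched pairs, weights and the motif
        library; relative paths resolve against the config file's directory."""
        path = Path(path)
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        base = path.parent

        def resolve(p: str) -> Path:
            candidate = Path(p)
            return candidate if candidate.is_absolute() else base / candidate

        pairs = [
            FeaturePair(
                query_peaks=PeakSet.from_bed(resolve(entry["query"])),
                target_peaks=PeakSet.from_bed(resolve(entry["target"])),
                label=str(entry.get("label", f"pair_{i}")),
                weight=float(entry.get("weight", 1.0)),
            )
            for i, entry in enumerate(raw.get("pairs", []))
        ]
        motifs = parse_jaspar(resolve(raw["motifs"])) if raw.get("motifs") else []
        return cls(
            pairs=pairs,
            motifs=motifs,
            flank=int(raw.get("flank", 0)),
            p_cutoff=float(raw.get("p_cutoff", DEFAULT_P_CUTOFF)),
            pseudocount=float(raw.get("pseudocount", DEFAULT_PSEUDOCOUNT)),
        )
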