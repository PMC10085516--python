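"""Self-contained paired-genome fixtures with planted orthologous elements.

The generator emulates the statistical structure the adaptive mapping
method assumes, without any real-genome download:

* two genomes related by a consistent chain file (gapless blocks separated
  by small indels plus larger alignment breaks);
* planted orthologous elements whose target-genome copies are reachable
  through the chain;
* query intervals displaced from their elements by a Gaussian offset
  (emulating assay-coordinate noise); queries displaced beyond the element
  fall inside an alignment break and are recoverable only by windowed
  extension, with the required window growing with the displacement;
* conserved "confuser" elements a few kb away (emulating nearby paralogous
  regulatory elements) that pollute over-wide extension windows with
  feature-rich decoy candidates;
* optional decoy duplication chains that make every query multi-map, with
  conserved peak/motif evidence present only at the true target;
* matched peak-set pairs with tunable per-pair activity and cross-genome
  conservation, background noise peaks, and a motif library planted into
  conserved elements.

One global seed drives independent per-component generators (layout,
genome, peaks, motifs, decoys) so components can be regenerated in
isolation; the same seed always yields a byte-identical bundle.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .chain import AlignmentBlock, Chain, ChainSide, write_chain_file
from .features import PWM, write_jaspar
from .intervals import GenomicInterval, PeakSet, write_bed

__all__ = ["FixtureSpec", "FixtureBundle", "generate", "adversarial_multimap"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the paired-genome fixture; defaults are the study conditions
    every test and the acceptance checks run under."""

    seed: int = 0
    n_sequences: int = 2
    sequence_length: int = 500_000
    n_elements: int = 100
    element_width: int = 200
    #: sd (bases) of the Gaussian query/element offset; 0 plants queries
    #: exactly on their elements.
    displacement_sd: float = 500.0
    #: aligned slack between an element and the alignment break holding its
    #: displaced query; tiles landing here are feature-rich but miss the
    #: true target, penalizing barely-sufficient windows.
    alignment_slack: int = 25
    #: per-base rate of small (1..small_gap_max bp) alignment indels.
    small_gap_rate: float = 2e-4
    small_gap_max: int = 9
    #: duplicated decoy chains per element (multi-mapping pressure).
    n_decoys: int = 0
    decoy_copy_features: bool = False
    #: conserved decoy elements per query and their distance range (bases).
    #: Confusers are genuine regulatory elements of the target landscape
    #: (they carry peaks and enter the gold standard) but their tissue
    #: activity profile is largely independent of the query's element.
    n_confusers: int = 4
    confuser_distance: tuple[int, int] = (1400, 6000)
    confuser_activity: float = 0.4
    n_feature_pairs: int = 6
    #: chance an element is active in a given dataset pair.
    pair_activity: float = 0.8
    #: chance an active element's mark is conserved to the target genome.
    peak_conservation: float = 0.9
    #: half-width padding of planted peaks around their element.
    peak_pad: int = 300
    n_background_peaks: int = 250
    background_peak_width: int = 200
    #: chance a planted element carries a motif instance.
    motif_rate: float = 0.8
    n_motifs: int = 8
    motif_length: int = 10
    mutation_rate: float = 0.01

    def validate(self) -> None:
        for name in (
            "pair_activity",
            "peak_conservation",
            "motif_rate",
            "mutation_rate",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")
        for name in (
            "n_sequences",
            "sequence_length",
            "n_elements",
            "element_width",
            "n_feature_pairs",
            "n_motifs",
            "motif_length",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.displacement_sd < 0 or self.small_gap_rate < 0:
            raise ValueError("rates must be >= 0")
        per_seq = -(-self.n_elements // self.n_sequences)
        spacing = self.sequence_length // (per_seq + 1)
        required = int(self.element_width + 8 * self.displacement_sd + 1000)
        if spacing < required:
            raise ValueError(
                f"{self.n_elements} elements do not fit: per-element spacing "
                f"{spacing} < required {required} bases"
            )


@dataclass
class FixtureBundle:
    """Everything a mapping run needs, in memory, plus a writer."""

    spec: FixtureSpec
    query_genome: dict[str, str]
    target_genome: dict[str, str]
    chains: list[Chain]
    queries: list[GenomicInterval]
    query_names: list[str]
    feature_pairs: list  # list[FeaturePair]; typed loosely to avoid cycle
    motifs: list[PWM]
    gold: PeakSet
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> dict:
        """Write FASTA/chain/BED/PFM/TSV files plus a manifest; byte-stable
        for a fixed spec."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_fasta(self.query_genome, outdir / "query_genome.fa")
        _write_fasta(self.target_genome, outdir / "target_genome.fa")
        write_chain_file(self.chains, outdir / "alignment.chain")
        write_bed(
            self.queries,
            outdir / "queries.bed",
            names=self.query_names,
            scores=[0] * len(self.queries),
        )
        pair_entries = []
        for i, pair in enumerate(self.feature_pairs):
            qp, tp = f"pair_{i}_query.bed", f"pair_{i}_target.bed"
            write_bed(pair.query_peaks, outdir / qp)
            write_bed(pair.target_peaks, outdir / tp)
            pair_entries.append(
                {"label": pair.label, "query": qp, "target": tp, "weight": pair.weight}
            )
        write_jaspar(self.motifs, outdir / "motifs.jaspar")
        write_bed(self.gold, outdir / "gold.bed")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        config = {
            "pairs": pair_entries,
            "motifs": "motifs.jaspar",
            "flank": 0,
            "p_cutoff": 5e-5,
        }
        import yaml

        (outdir / "features.yaml").write_text(
            yaml.safe_dump(config, sort_keys=True)
        )
        spec_dict = asdict(self.spec)
        spec_dict["confuser_distance"] = list(self.spec.confuser_distance)
        manifest = {
            "spec": spec_dict,
            "n_queries": len(self.queries),
            "n_chains": len(self.chains),
            "files": sorted({p.name for p in outdir.iterdir()} | {"manifest.json"}),
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        return manifest


def _write_fasta(genome: dict[str, str], path: Path, width: int = 60) -> None:
    with open(path, "w") as handle:
        for name in genome:
            handle.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def _random_motifs(rng: np.random.Generator, spec: FixtureSpec) -> list[PWM]:
    """PFMs with a dominant base per column (>= 1 bit of information), so
    planted consensus instances clear the default scan threshold."""
    motifs = []
    for m in range(spec.n_motifs):
        dominant = rng.integers(0, 4, size=spec.motif_length)
        matrix = np.full((4, spec.motif_length), 5.0)
        matrix[dominant, np.arange(spec.motif_length)] = 85.0
        motifs.append(PWM(motif_id=f"SYN{m:03d}", matrix=matrix, name=f"synthetic_{m}"))
    return motifs


def _consensus(pwm: PWM) -> np.ndarray:
    return np.argmax(pwm.matrix, axis=0)


class _Occupancy:
    """Interval bookkeeping to keep planted structures from colliding."""

    def __init__(self) -> None:
        self.spans: list[tuple[int, int]] = []

    def clashes(self, start: int, end: int, margin: int = 20) -> bool:
        return any(s < end + margin and start - margin < e for s, e in self.spans)

    def add(self, start: int, end: int) -> None:
        self.spans.append((start, end))


def generate(spec: FixtureSpec) -> FixtureBundle:
    """Build the full fixture bundle deterministically from the spec."""
    spec.validate()
    from .features import FeaturePair  # deferred: features imports intervals only

    root = np.random.SeedSequence(spec.seed)
    rng_layout, rng_genome, rng_peaks, rng_motif, rng_decoy = (
        np.random.default_rng(s) for s in root.spawn(5)
    )
    motifs = _random_motifs(rng_motif, spec)

    per_seq = [
        spec.n_elements // spec.n_sequences
        + (1 if i < spec.n_elements % spec.n_sequences else 0)
        for i in range(spec.n_sequences)
    ]

    query_genome: dict[str, str] = {}
    target_genome: dict[str, str] = {}
    chains: list[Chain] = []
    elements: list[dict] = []  # one record per planted element
    confuser_records: list[dict] = []
    w_e = spec.element_width
    slack = spec.alignment_slack

    for si in range(spec.n_sequences):
        q_name, t_name = f"chrQ{si + 1}", f"chrT{si + 1}"
        L = spec.sequence_length
        n_el = per_seq[si]
        spacing = L // (n_el + 1)
        occupied = _Occupancy()

        seq_elements = []
        for k in range(n_el):
            center = (k + 1) * spacing + int(
                rng_layout.integers(-spacing // 8, spacing // 8 + 1)
            )
            e_start = int(np.clip(center, 5000, L - 5000 - w_e))
            element = (e_start, e_start + w_e)
            delta = (
                int(round(rng_layout.normal(0.0, spec.displacement_sd)))
                if spec.displacement_sd > 0
                else 0
            )
            query = (element[0] + delta, element[1] + delta)
            gap = None
            if delta > w_e:
                gap = (element[1] + slack, query[1] + (delta - w_e))
            elif delta < -w_e:
                gap = (query[0] - (-delta - w_e), element[0] - slack)
            if gap is not None and gap[0] >= gap[1]:
                gap = None
            lo = min(element[0], query[0]) - slack
            hi = max(element[1], query[1]) + slack
            if gap is not None:
                lo, hi = min(lo, gap[0]), max(hi, gap[1])
            occupied.add(lo, hi)
            seq_elements.append(
                {
                    "eid": f"e{si}_{k}",
                    "q_seq": q_name,
                    "t_seq": t_name,
                    "element": element,
                    "query": query,
                    "delta": delta,
                    "gap": gap,
                }
            )

        # conserved decoy elements near each query
        seq_confusers = []
        for rec in seq_elements:
            for _ in range(spec.n_confusers):
                dist = int(
                    rng_layout.integers(
                        spec.confuser_distance[0], spec.confuser_distance[1] + 1
                    )
                )
                if rng_layout.random() < 0.5:
                    c_start = rec["query"][0] - dist - w_e
                else:
                    c_start = rec["query"][1] + dist
                if c_start < 1000 or c_start + w_e > L - 1000:
                    continue
                if occupied.clashes(c_start, c_start + w_e, margin=50):
                    continue
                occupied.add(c_start, c_start + w_e)
                seq_confusers.append(
                    {"q_seq": q_name, "t_seq": t_name, "element": (c_start, c_start + w_e)}
                )

        # small alignment indels away from planted structure
        small_gaps = []
        n_small = int(rng_layout.poisson(spec.small_gap_rate * L))
        for _ in range(n_small):
            pos = int(rng_layout.integers(500, L - 500))
            size = int(rng_layout.integers(1, spec.small_gap_max + 1))
            if occupied.clashes(pos, pos + size, margin=40):
                continue
            occupied.add(pos, pos + size)
            kind = "dt" if rng_layout.random() < 0.5 else "dq"
            small_gaps.append((pos, size, kind))

        # assemble ordered (source position, dt, dq) events
        events: list[tuple[int, int, int]] = []
        for rec in seq_elements:
            if rec["gap"] is not None:
                events.append((rec["gap"][0], rec["gap"][1] - rec["gap"][0], 0))
        for pos, size, kind in small_gaps:
            events.append((pos, size, 0) if kind == "dt" else (pos, 0, size))
        events.sort()
        pruned: list[tuple[int, int, int]] = []
        cursor = 1
        for pos, dt, dq in events:
            if pos < cursor or pos + dt > L - 1:
                continue
            pruned.append((pos, dt, dq))
            cursor = pos + dt + 1

        # source sequence with planted motif instances
        src = rng_genome.integers(0, 4, size=L, dtype=np.int8)
        planted: list[tuple[dict, PWM | None]] = []
        for rec in seq_elements + seq_confusers:
            pwm = None
            if rng_genome.random() < spec.motif_rate:
                pwm = motifs[int(rng_genome.integers(0, len(motifs)))]
                start = rec["element"][0] + (w_e - pwm.length) // 2
                src[start : start + pwm.length] = _consensus(pwm)
            rec["motif"] = pwm.motif_id if pwm is not None else ""
            planted.append((rec, pwm))

        # walk events: build target sequence, chain blocks, image map
        blocks: list[AlignmentBlock] = []
        block_map: list[tuple[int, int, int]] = []  # (src_start, src_end, tgt_start)
        parts: list[np.ndarray] = []
        c = 0
        tgt_len = 0
        for pos, dt, dq in pruned + [(L, 0, 0)]:
            size = pos - c
            piece = src[c:pos].copy()
            flips = rng_genome.random(size) < spec.mutation_rate
            if flips.any():
                piece[flips] = (
                    piece[flips] + rng_genome.integers(1, 4, size=int(flips.sum()))
                ) % 4
            parts.append(piece)
            block_map.append((c, pos, tgt_len))
            tgt_len += size
            if pos == L:
                blocks.append(AlignmentBlock(size, 0, 0))
                break
            blocks.append(AlignmentBlock(size, dt, dq))
            if dq:
                parts.append(rng_genome.integers(0, 4, size=dq, dtype=np.int8))
                tgt_len += dq
            c = pos + dt

        tgt = np.concatenate(parts)
        assert tgt.size == tgt_len

        starts = np.array([b[0] for b in block_map])
        ends = np.array([b[1] for b in block_map])
        t_starts = np.array([b[2] for b in block_map])

        def image(x: int) -> int:
            i = int(np.searchsorted(ends, x, side="right"))
            i = min(i, len(block_map) - 1)
            if not starts[i] <= x < ends[i]:
                raise ValueError(f"source position {x} not aligned")
            return int(t_starts[i] + (x - starts[i]))

        for rec in seq_elements + seq_confusers:
            e0, e1 = rec["element"]
            rec["t_element"] = (image(e0), image(e0) + w_e)
        elements.extend(seq_elements)
        confuser_records.extend(seq_confusers)

        query_genome[q_name] = "".join(_BASES[src])
        target_genome[t_name] = "".join(_BASES[tgt])
        chains.append(
            Chain(
                score=float(sum(b.size for b in blocks)),
                source=ChainSide(q_name, L, "+", 0, L),
                dest=ChainSide(t_name, tgt_len, "+", 0, tgt_len),
                chain_id=si + 1,
                blocks=tuple(blocks),
            )
        )

    # decoy duplication chains (multi-mapping) on the target genome
    next_id = spec.n_sequences + 1
    protected: dict[str, _Occupancy] = {}
    for rec in elements + confuser_records:
        protected.setdefault(rec["t_seq"], _Occupancy()).add(*rec["t_element"])
    decoy_edits: list[tuple[str, int, str]] = []
    for rec in elements:
        rec["decoys"] = []
        for _ in range(spec.n_decoys):
            span_lo = min(rec["element"][0], rec["query"][0]) - 50
            span_hi = max(rec["element"][1], rec["query"][1]) + 50
            span_w = span_hi - span_lo
            t_seq = f"chrT{int(rng_decoy.integers(0, spec.n_sequences)) + 1}"
            t_len = len(target_genome[t_seq])
            occ = protected.setdefault(t_seq, _Occupancy())
            placed = None
            for _attempt in range(100):
                pos = int(rng_decoy.integers(1000, t_len - span_w - 1000))
                if not occ.clashes(pos, pos + span_w, margin=500):
                    placed = pos
                    break
            if placed is None:
                continue
            occ.add(placed, placed + span_w)
            chains.append(
                Chain(
                    score=float(span_w),
                    source=ChainSide(rec["q_seq"], spec.sequence_length, "+", span_lo, span_hi),
                    dest=ChainSide(t_seq, t_len, "+", placed, placed + span_w),
                    chain_id=next_id,
                    blocks=(AlignmentBlock(span_w, 0, 0),),
                )
            )
            decoy_elem = (
                placed + (rec["element"][0] - span_lo),
                placed + (rec["element"][0] - span_lo) + w_e,
            )
            rec["decoys"].append({"t_seq": t_seq, "t_element": decoy_elem, "chain_id": next_id})
            next_id += 1
            if spec.decoy_copy_features:
                e0, e1 = rec["t_element"]
                source_piece = target_genome[rec["t_seq"]][e0:e1]
                decoy_edits.append((t_seq, decoy_elem[0], source_piece))

    if decoy_edits:
        editable = {name: bytearray(seq.encode()) for name, seq in target_genome.items()}
        for t_seq, pos, piece in decoy_edits:
            editable[t_seq][pos : pos + len(piece)] = piece.encode()
        target_genome = {name: buf.decode() for name, buf in editable.items()}

    # matched peak-set pairs
    pad = spec.peak_pad
    activity_p = np.array(
        [spec.pair_activity] * len(elements)
        + [spec.confuser_activity] * len(confuser_records)
    )
    activity = (
        rng_peaks.random((len(elements) + len(confuser_records), spec.n_feature_pairs))
        < activity_p[:, None]
    )
    conserved = rng_peaks.random(activity.shape) < spec.peak_conservation
    feature_pairs = []
    all_records = elements + confuser_records
    for d in range(spec.n_feature_pairs):
        q_peaks: list[GenomicInterval] = []
        t_peaks: list[GenomicInterval] = []
        for r_idx, rec in enumerate(all_records):
            if not activity[r_idx, d]:
                continue
            if "query" in rec:
                q_lo = min(rec["element"][0], rec["query"][0]) - pad
                q_hi = max(rec["element"][1], rec["query"][1]) + pad
            else:
                q_lo, q_hi = rec["element"][0] - pad, rec["element"][1] + pad
            q_peaks.append(GenomicInterval(rec["q_seq"], max(0, q_lo), q_hi))
            if conserved[r_idx, d]:
                t0, t1 = rec["t_element"]
                t_peaks.append(
                    GenomicInterval(rec["t_seq"], max(0, t0 - pad), t1 + pad)
                )
                if spec.decoy_copy_features and rec.get("decoys"):
                    for decoy in rec["decoys"]:
                        d0, d1 = decoy["t_element"]
                        t_peaks.append(
                            GenomicInterval(decoy["t_seq"], max(0, d0 - pad), d1 + pad)
                        )
        for genome, peaks in ((query_genome, q_peaks), (target_genome, t_peaks)):
            names = sorted(genome)
            for _ in range(spec.n_background_peaks):
                name = names[int(rng_peaks.integers(0, len(names)))]
                size = len(genome[name])
                pos = int(rng_peaks.integers(0, size - spec.background_peak_width))
                peaks.append(
                    GenomicInterval(name, pos, pos + spec.background_peak_width)
                )
        feature_pairs.append(
            FeaturePair(
                query_peaks=PeakSet(q_peaks, name=f"pair_{d}_query"),
                target_peaks=PeakSet(t_peaks, name=f"pair_{d}_target"),
                label=f"pair_{d}",
            )
        )

    queries = [
        GenomicInterval(rec["q_seq"], rec["query"][0], rec["query"][1])
        for rec in elements
    ]
    # the gold standard is the target-genome peak landscape of the assay:
    # planted element images AND confuser elements (real peaks that are not
    # any query's counterpart) both belong to it
    gold = PeakSet(
        [
            GenomicInterval(rec["t_seq"], rec["t_element"][0], rec["t_element"][1])
            for rec in elements + confuser_records
        ],
        name="gold",
    )
    truth = pd.DataFrame(
        [
            {
                "element_id": rec["eid"],
                "query_seq": rec["q_seq"],
                "query_start": rec["query"][0],
                "query_end": rec["query"][1],
                "target_seq": rec["t_seq"],
                "target_start": rec["t_element"][0],
                "target_end": rec["t_element"][1],
                "displacement": rec["delta"],
                "motif": rec["motif"],
                "n_decoys": len(rec.get("decoys", [])),
            }
            for rec in elements
        ]
    )
    return FixtureBundle(
        spec=spec,
        query_genome=query_genome,
        target_genome=target_genome,
        chains=chains,
        queries=queries,
        query_names=[rec["eid"] for rec in elements],
        feature_pairs=feature_pairs,
        motifs=motifs,
        gold=gold,
        truth=truth,
    )


def adversarial_multimap(spec: FixtureSpec) -> FixtureBundle:
    """Multi-mapping stress fixture: queries sit exactly on their elements
    (so every query maps directly through >= 2 chains) and each element owns
    at least one duplicated decoy chain whose target carries no conserved
    evidence unless ``decoy_copy_features`` is set."""
    if spec.n_decoys < 1:
        raise ValueError("adversarial_multimap requires n_decoys >= 1")
    return generate(replace(spec, displacement_sd=0.0))
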