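"""Binary feature spaces: peak overlap bits and PWM motif scanning."""

import io
import itertools

import numpy as np
import pytest

from orthomap.features import (
    PWM,
    MotifScanner,
    epigenomic_vector,
    parse_jaspar,
    pvalue_score_threshold,
    sequence_grammar_vector,
    write_jaspar,
)
from orthomap.intervals import GenomicInterval, PeakSet

from conftest import scan_brute_force

GRID = 0.01


def random_pwm(rng: np.random.Generator, length: int, motif_id="M0") -> PWM:
    counts = rng.integers(1, 60, size=(4, length)).astype(float)
    return PWM(motif_id=motif_id, matrix=counts)


def enumerated_distribution(pwm: PWM) -> dict[int, float]:
    """Exact integer-score distribution by enumerating all 4^L sequences."""
    ints = pwm.int_scores()
    dist: dict[int, float] = {}
    for word in itertools.product(range(4), repeat=pwm.length):
        score = int(sum(ints[b, j] for j, b in enumerate(word)))
        prob = float(np.prod([pwm.background[b] for b in word]))
        dist[score] = dist.get(score, 0.0) + prob
    return dist


def threshold_oracle(pwm: PWM, p: float) -> float:
    """Smallest grid score with strict tail <= p, clamped at the minimum
    attainable score; computed from the enumerated distribution."""
    dist = enumerated_distribution(pwm)
    scores = sorted(dist)
    total = sum(dist.values())
    for s in range(scores[0], scores[-1] + 2):
        strict_tail = sum(v for k, v in dist.items() if k > s)
        if strict_tail <= p + 1e-12:
            return max(s, scores[0]) * GRID
    raise AssertionError("unreachable")


class TestEpigenomicVector:
    def setup_method(self):
        peak = lambda a, b: PeakSet([GenomicInterval("chr1", a, b)])
        self.sets = [peak(100, 200), peak(500, 600), peak(150, 260), peak(900, 950)]

    def test_overlap_pattern(self):
        r = GenomicInterval("chr1", 180, 220)
        assert epigenomic_vector(r, self.sets).tolist() == [1, 0, 1, 0]

    def test_empty_sets_and_unknown_sequence(self):
        empty = [PeakSet([]), PeakSet([])]
        assert epigenomic_vector(GenomicInterval("chr1", 0, 10), empty).tolist() == [0, 0]
        r = GenomicInterval("chrX", 100, 200)
        assert epigenomic_vector(r, self.sets).tolist() == [0, 0, 0, 0]

    def test_half_open_boundary(self):
        # one shared base flips the bit; abutting does not
        assert epigenomic_vector(GenomicInterval("chr1", 199, 300), self.sets)[0] == 1
        assert epigenomic_vector(GenomicInterval("chr1", 200, 300), self.sets)[0] == 0

    def test_monotone_under_added_peaks(self):
        r = GenomicInterval("chr1", 400, 450)
        before = epigenomic_vector(r, self.sets)
        grown = [
            PeakSet(list(ps.intervals) + [GenomicInterval("chr1", 440, 460)])
            for ps in self.sets
        ]
        after = epigenomic_vector(r, grown)
        assert np.all(after >= before)


class TestJasparIO:
    TEXT = """>MA0001.1 DEMO
A [ 10 0 3 ]
C [ 0 20 3 ]
G [ 5 0 3 ]
T [ 0 0 11 ]
>MA0002.1 BARE
A 1 2
C 3 4
G 5 6
T 7 8
"""

    def test_parse_both_row_styles(self):
        motifs = parse_jaspar(io.StringIO(self.TEXT))
        assert [m.motif_id for m in motifs] == ["MA0001.1", "MA0002.1"]
        assert motifs[0].matrix[3, 2] == 11
        assert motifs[1].length == 2

    def test_round_trip(self):
        motifs = parse_jaspar(io.StringIO(self.TEXT))
        buf = io.StringIO()
        write_jaspar(motifs, buf)
        again = parse_jaspar(io.StringIO(buf.getvalue()))
        for a, b in zip(motifs, again):
            assert a.motif_id == b.motif_id
            assert np.allclose(a.matrix, b.matrix)

    def test_degenerate_column_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            PWM(motif_id="bad", matrix=np.array([[0, 1], [0, 1], [0, 1], [0, 1]]))


class TestScoreThreshold:
    def test_matches_exhaustive_enumeration(self):
        """DP threshold equals brute-force enumeration for short motifs."""
        rng = np.random.default_rng(17)
        for trial in range(20):
            length = int(rng.integers(2, 8))
            pwm = random_pwm(rng, length, motif_id=f"M{trial}")
            p = float(rng.choice([5e-5, 1e-3, 0.01, 0.2, 0.7]))
            assert pvalue_score_threshold(pwm, p) == pytest.approx(
                threshold_oracle(pwm, p), abs=1e-9
            )

    def test_p_one_gives_minimum_attainable_score(self):
        rng = np.random.default_rng(2)
        pwm = random_pwm(rng, 5)
        ints = pwm.int_scores()
        min_score = int(ints[:4].min(axis=0).sum())
        assert pvalue_score_threshold(pwm, 1.0) == pytest.approx(min_score * GRID)

    def test_uniform_pwm_threshold_zero_at_half(self):
        uniform = PWM(motif_id="U", matrix=np.full((4, 6), 25.0))
        assert pvalue_score_threshold(uniform, 0.5) == 0.0

    def test_less_stringent_p_never_raises_threshold(self):
        rng = np.random.default_rng(8)
        pwm = random_pwm(rng, 7)
        ps = [1e-5, 1e-4, 1e-3, 1e-2, 0.1, 0.5, 1.0]
        thresholds = [pvalue_score_threshold(pwm, p) for p in ps]
        assert thresholds == sorted(thresholds, reverse=True)


class TestGrammarVector:
    def planted_genome(self, pwm: PWM, rng, where=500, length=2000):
        consensus = "".join("ACGT"[b] for b in np.argmax(pwm.matrix, axis=0))
        seq = "".join(rng.choice(list("ACGT"), size=length))
        seq = seq[:where] + consensus + seq[where + len(consensus):]
        return {"chr1": seq}, consensus

    def test_planted_hit_found_and_absent_elsewhere(self):
        rng = np.random.default_rng(3)
        pwm = PWM(
            motif_id="STRONG",
            matrix=np.where(np.eye(4)[:, [0, 1, 2, 3, 0, 1, 2, 3, 0, 1]] > 0, 85.0, 5.0),
        )
        genome, _ = self.planted_genome(pwm, rng)
        hit_region = GenomicInterval("chr1", 450, 650)
        far_region = GenomicInterval("chr1", 1000, 1200)
        assert sequence_grammar_vector(hit_region, genome, [pwm])[0] == 1
        assert sequence_grammar_vector(far_region, genome, [pwm])[0] == 0

    def test_reverse_complement_hit_detected(self):
        rng = np.random.default_rng(4)
        pwm = PWM(
            motif_id="RC",
            matrix=np.where(np.eye(4)[:, [0, 0, 1, 3, 2, 1, 0, 2, 3, 3]] > 0, 85.0, 5.0),
        )
        genome, consensus = self.planted_genome(pwm, rng)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[c] for c in reversed(consensus))
        seq = genome["chr1"]
        genome_rc = {"chr1": seq[:500] + rc + seq[500 + len(rc):]}
        region = GenomicInterval("chr1", 450, 650)
        assert sequence_grammar_vector(region, genome_rc, [pwm])[0] == 1

    def test_matches_naive_all_offset_scanner(self):
        """Random sequence, 20 random motifs: bits equal the brute-force
        all-offsets, both-strands scan at the same threshold."""
        rng = np.random.default_rng(19)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        genome = {"chr1": seq}
        motifs = [random_pwm(rng, int(rng.integers(4, 9)), f"M{i}") for i in range(20)]
        scanner = MotifScanner(motifs, p_cutoff=1e-3)
        region = GenomicInterval("chr1", 0, 1000)
        got = sequence_grammar_vector(region, genome, scanner=scanner)
        for m, pwm in enumerate(motifs):
            threshold = pvalue_score_threshold(pwm, 1e-3)
            # oracle scores on the same discretized matrix
            ints = pwm.int_scores().astype(float) * GRID
            expected = scan_brute_force(seq, ints[:4], threshold)
            assert bool(got[m]) == expected

    def test_invariant_under_reverse_complementing_genome(self):
        rng = np.random.default_rng(23)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[c] for c in reversed(seq))
        motifs = [random_pwm(rng, 6, f"M{i}") for i in range(10)]
        scanner = MotifScanner(motifs, p_cutoff=5e-3)
        region = GenomicInterval("chr1", 0, 400)
        fwd = sequence_grammar_vector(region, {"chr1": seq}, scanner=scanner)
        rev = sequence_grammar_vector(region, {"chr1": rc}, scanner=scanner)
        assert np.array_equal(fwd, rev)

    def test_raising_p_cutoff_never_clears_bits(self):
        rng = np.random.default_rng(29)
        seq = "".join(rng.choice(list("ACGT"), size=600))
        motifs = [random_pwm(rng, 7, f"M{i}") for i in range(8)]
        region = GenomicInterval("chr1", 0, 600)
        previous = None
        for p in (1e-5, 1e-3, 1e-1):
            bits = sequence_grammar_vector(region, {"chr1": seq}, motifs, p_cutoff=p)
            if previous is not None:
                assert np.all(bits >= previous)
            previous = bits

    def test_ambiguous_bases_score_as_background(self):
        pwm = PWM(
            motif_id="N",
            matrix=np.where(np.eye(4)[:, [0, 1, 2, 3]] > 0, 85.0, 5.0),
        )
        region = GenomicInterval("chr1", 0, 20)
        bits = sequence_grammar_vector(region, {"chr1": "N" * 20}, [pwm])
        assert bits[0] == 0

    def test_missing_sequence_raises(self):
        with pytest.raises(KeyError):
            sequence_grammar_vector(
                GenomicInterval("chrX", 0, 10), {"chr1": "ACGT"}, []
            )
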