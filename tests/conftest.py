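"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library's own code paths: chain
lifting is checked base by base, tiling by direct enumeration, AUROC by the
all-pairs Mann-Whitney sum, and motif thresholds by exhaustive enumeration.
"""

from __future__ import annotations

import numpy as np
import pytest

from orthomap.chain import AlignmentBlock, Chain, ChainSide
from orthomap.intervals import GenomicInterval


# ---------------------------------------------------------------------------
# brute-force per-base chain mapping


def per_base_map(q: GenomicInterval, chain: Chain) -> list[tuple[int, int]]:
    """Map every base of ``q`` individually through block arithmetic and
    return the maximal runs of consecutive destination positions (forward
    orientation), sorted."""
    positions = []
    for x in range(q.start, q.end):
        s = chain.source.start
        d = chain.dest.start
        for block in chain.blocks:
            if s <= x < s + block.size:
                raw = d + (x - s)
                if chain.dest.strand == "-":
                    positions.append(chain.dest.seq_size - raw - 1)
                else:
                    positions.append(raw)
                break
            s += block.size + block.dt
            d += block.size + block.dq
    positions.sort()
    runs: list[list[int]] = []
    for p in positions:
        if runs and p == runs[-1][1]:
            runs[-1][1] = p + 1
        else:
            runs.append([p, p + 1])
    return [(a, b) for a, b in runs]


def random_chain(
    rng: np.random.Generator,
    chain_id: int,
    src_name: str = "chrS",
    dst_name: str = "chrD",
    reverse: bool = False,
    seq_size: int = 100_000,
) -> Chain:
    """A structurally valid random chain with 1-8 blocks and random gaps."""
    n_blocks = int(rng.integers(1, 9))
    sizes = rng.integers(5, 200, size=n_blocks)
    dts = rng.integers(0, 120, size=n_blocks)
    dqs = rng.integers(0, 120, size=n_blocks)
    dts[-1] = dqs[-1] = 0
    src_span = int((sizes + dts).sum())
    dst_span = int((sizes + dqs).sum())
    src_start = int(rng.integers(0, seq_size - src_span))
    dst_start = int(rng.integers(0, seq_size - dst_span))
    blocks = tuple(
        AlignmentBlock(int(s), int(t), int(q)) for s, t, q in zip(sizes, dts, dqs)
    )
    return Chain(
        score=1000.0,
        source=ChainSide(src_name, seq_size, "+", src_start, src_start + src_span),
        dest=ChainSide(
            dst_name, seq_size, "-" if reverse else "+", dst_start, dst_start + dst_span
        ),
        chain_id=chain_id,
        blocks=blocks,
    )


def identity_chain(
    seq_size: int = 1000,
    src_name: str = "chrS",
    dst_name: str = "chrD",
    chain_id: int = 1,
) -> Chain:
    return Chain(
        score=float(seq_size),
        source=ChainSide(src_name, seq_size, "+", 0, seq_size),
        dest=ChainSide(dst_name, seq_size, "+", 0, seq_size),
        chain_id=chain_id,
        blocks=(AlignmentBlock(seq_size, 0, 0),),
    )


# ---------------------------------------------------------------------------
# other brute-force oracles


def auroc_brute_force(scores, labels) -> float:
    """Mann-Whitney over every positive x negative pair, ties counted 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def scan_brute_force(seq: str, log_odds: np.ndarray, threshold: float) -> bool:
    """Naive both-strand scan: any window reaching the threshold?"""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = log_odds.shape[1]

    def score(s: str) -> float:
        return sum(
            log_odds[idx[c], j] if c in idx else 0.0 for j, c in enumerate(s)
        )

    rc = "".join(comp.get(c, "N") for c in reversed(seq))
    for offset in range(len(seq) - L + 1):
        if score(seq[offset : offset + L]) >= threshold - 1e-9:
            return True
        if score(rc[offset : offset + L]) >= threshold - 1e-9:
            return True
    return False


# ---------------------------------------------------------------------------
# session fixtures (generated once; several modules test against them)


@pytest.fixture(scope="session")
def small_bundle():
    """A compact displaced-query fixture used across feature/scoring tests."""
    from orthomap.simulate import FixtureSpec, generate

    return generate(
        FixtureSpec(seed=7, n_elements=30, sequence_length=200_000, n_sequences=2)
    )


@pytest.fixture(scope="session")
def multimap_bundle():
    """Adversarial duplication fixture: each query maps through two chains."""
    from orthomap.simulate import FixtureSpec, adversarial_multimap

    return adversarial_multimap(
        FixtureSpec(seed=11, n_elements=40, sequence_length=250_000, n_decoys=1)
    )
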