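"""Stratified permutation enrichment of mapped regions in annotations.

The observed statistic is the number of regions overlapping an annotation
peak set.  The null resamples region identities from a background universe,
drawing without replacement within user-supplied strata (chromosome,
binned conservation score, width quantile, ...) so each draw matches the
regions' stratum composition exactly.  Enrichment is reported as a z-score
against the null mean and standard deviation plus an add-one empirical
p-value, which is therefore never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np

from .intervals import GenomicInterval, PeakSet

__all__ = ["EnrichmentResult", "stratified_permutation_test", "DEFAULT_PERMUTATIONS"]

DEFAULT_PERMUTATIONS = 10_000


@dataclass(frozen=True)
class EnrichmentResult:
    observed: int
    null_mean: float
    null_sd: float
    z: float
    empirical_p: float
    n_permutations: int
    degenerate_null: bool = False

    def to_json_dict(self) -> dict:
        return {
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": None if self.degenerate_null else self.z,
            "empirical_p": self.empirical_p,
            "n_permutations": self.n_permutations,
            "degenerate_null": self.degenerate_null,
        }


def stratified_permutation_test(
    regions: Sequence[GenomicInterval],
    annotation: PeakSet,
    universe: Sequence[GenomicInterval],
    strata: Sequence[Hashable],
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
) -> EnrichmentResult:
    """Permutation test of region-annotation overlap with stratum matching.

    ``strata`` labels each universe element; regions must be a subset of the
    universe (matched by coordinates) and inherit their elements' labels.
    Each of ``n_permutations`` draws samples, per stratum, as many universe
    elements as the regions hold in that stratum, without replacement, and
    counts overlaps.  Overlap is binary per region, not per base.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if len(strata) != len(universe):
        raise ValueError("strata must label every universe element")
    key = lambda iv: (iv.seq_name, iv.start, iv.end)
    membership = {key(iv): i for i, iv in enumerate(universe)}
    try:
        region_idx = [membership[key(r)] for r in regions]
    except KeyError as exc:
        raise ValueError(f"region {exc} is not in the universe")

    raw_labels = list(strata)
    overlap = np.array(
        [1 if annotation.overlaps(iv) else 0 for iv in universe], dtype=np.int64
    )
    observed = int(overlap[region_idx].sum())

    # per-stratum universe indices and region counts
    strata_values: dict[Hashable, np.ndarray] = {}
    for i, lab in enumerate(raw_labels):
        strata_values.setdefault(lab, []).append(i)  # type: ignore[arg-type]
    need: dict[Hashable, int] = {}
    for i in region_idx:
        need[raw_labels[i]] = need.get(raw_labels[i], 0) + 1
    for lab, count in need.items():
        pool = strata_values[lab]
        if count > len(pool):
            raise ValueError(
                f"stratum {lab!r}: {count} regions exceed {len(pool)} "
                "universe elements"
            )

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations, dtype=np.int64)
    pools = {lab: np.asarray(idx) for lab, idx in strata_values.items()}
    for b in range(n_permutations):
        total = 0
        for lab, count in need.items():
            draw = rng.choice(pools[lab], size=count, replace=False)
            total += int(overlap[draw].sum())
        null[b] = total

    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=0))
    degenerate = null_sd == 0.0
    z = float("nan") if degenerate else (observed - null_mean) / null_sd
    empirical_p = (1 + int(np.sum(null >= observed))) / (n_permutations + 1)
    return EnrichmentResult(
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z=z,
        empirical_p=empirical_p,
        n_permutations=n_permutations,
        degenerate_null=degenerate,
    )
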