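# Methods

## Coordinate model and the chain engine

All intervals are 0-based, half-open, the native convention of BED and chain
files; nothing else is used internally.  A chain record is a header plus
gapless blocks with two inter-block gap fields (source-side and
destination-side).  Because the chain format's own "target/query" field
names point in the opposite direction from the mapping vocabulary (the
format's *t* side is the genome being lifted FROM), the parser names the
sides `source` and `dest` and never exposes the format's names beyond I/O.

The source strand must be `+` (as in UCSC over.chain files).  Reverse
destination strands are kept raw at parse time and flipped to forward
orientation during lifting (`forward_start = seq_size − raw_end`); raw
reverse coordinates never leave the chain module.  Lifting walks the blocks
once per overlapping chain, emits the destination images of the query bases
that fall inside blocks, and merges abutting images into maximal gapless
segments, so the output equals the per-base map of the query.  Every
overlapping chain contributes a result: multi-mapping is intentional and is
resolved by scoring, never by a reciprocal-best rule.  A
`min_mapped_fraction` filter exists for parity experiments with other
lift-over tools but defaults to 0 (keep every partial mapping): the workflow
relies on candidate scoring, not a match-fraction cut-off, to discard poor
mappings.

## Candidate generation

Direct lift first; a *partial* direct success counts as success (the
extension step is only for queries that map nowhere).  The extension is
symmetric, clipped at zero and at the sequence length when known.  Merging
unions segments whose separation is strictly below the gap threshold
(default 10 bases), transitively, and pools chain provenance when segments
from different chains land within the threshold on the same sequence.
Tiling is start-anchored with a flush tile ending at the region's end
(whether the reference tiling is start-anchored or centered is not
documented anywhere we could find; start-anchored is simpler and the flush
tile guarantees end coverage).  A region narrower than the query yields one
centered tile, so an orthologous region always produces at least one
candidate.  Defaults: window 2000 bases (the cross-validated optimum on the
data regime this method targets), gap threshold 10, resolution 50 (the
candidate spacing is not documented either; 50 bases balances candidate
density against runtime and is exposed as a flag).

## Feature spaces

Epigenomic bits use the ≥ 1-shared-base overlap rule with no minimum
fraction — binarization is deliberate, trading quantitative signal for
robustness and speed.  Pair order defines the coordinate system: bit *d* of
a query vector comes from the query-genome member of pair *d* and bit *d* of
a candidate vector from the target-genome member, which is what makes the
two vectors comparable coordinate-wise.

Motif scoring is log2-odds against the background composition (uniform by
default), with a pseudocount of 0.8 spread by background added to count
matrices.  Scores are discretized on a 0.01 log2-odds grid and *all*
arithmetic — the threshold DP and the scanning itself — runs on the integer
grid, so the discretization error is bounded by half a grid unit per motif
position and threshold and scan can never disagree with each other.  The
p-value threshold is computed by exact dynamic programming over the
per-position score distribution: the threshold is the smallest grid score
*s* with P(score > s) ≤ p, clamped below at the minimum attainable score,
and a hit is a window scoring ≥ *s*.  (The clamp makes p = 1 return the
minimum attainable score, and a completely uninformative matrix thresholds
at 0 for p = 0.5.)  Ambiguous bases contribute zero log-odds.  Both strands
are scanned by also scanning the reverse-complemented matrix, which keeps
hit coordinates on the forward strand.  The scan cutoff defaults to
p = 5·10⁻⁵ and the flank around a region to 0; both are configuration, not
constants, because the exact "vicinity" and cutoff of the reference
scanning setup are not printed anywhere.

Batch scanning: when many tiles cover one merged region, the region is
scanned once per motif and each tile's bit is derived from the hit
positions, which is algebraically identical to scanning every tile but
linear in covered bases rather than in tiles × tile width.

## Scoring and selection

The weighted cosine of binary vectors is Σwᵢuᵢvᵢ / √(Σwᵢuᵢ · Σwᵢvᵢ); a
vector with empty weighted support scores 0 against anything (an
unannotated region carries no evidence of conservation — returning NaN
would poison downstream ranking).  Cosine is the default similarity;
weighted Jaccard is available behind a flag for stability comparisons only.
The logistic score is σ(β₀ + β₁E + β₂S) with defaults (−3, 4, 5), the
coefficients the training module estimates on this data regime.  Selection
applies the probability threshold first (default 0.4) and then the top-k
cap; ties break by (sequence, start) ascending so output is deterministic.

## Training

Candidates are labeled positive by ≥ 1-base overlap with the gold-standard
target-genome peak set — the whole peak landscape of the assay, not a
per-query truth assignment; a candidate landing on *any* real peak is a
positive even if a weakly similar one.  The logistic fit is IRLS (Newton on
the penalized binomial log-likelihood) with an optional ridge penalty on
the slopes only; default ridge 1e-6 exists purely to keep toy, separable
data fittable, and complete separation at ridge 0 raises an error that says
so.  Convergence: max coefficient change < 1e-8 or 100 iterations.

AUROC is the Mann–Whitney probability with ties counted half; AUPR is the
step integral of precision over recall at every distinct threshold (both
delegated to scikit-learn, which implements exactly these definitions, and
cross-checked in the tests against brute-force oracles).  The window grid
defaults to 0–4800 by 400 (13 windows); a flush 5000 endpoint is available
via `window_grid(flush=True)`.  The selected window maximizes AUROC with
AUPR as tie-breaker — the two were optimized jointly in the source analysis
without a stated rule, so a deterministic one is fixed here.  Windows that
produce no candidates or single-class labels are recorded with missing
metrics rather than failing.

Cross-validation is leave-one-dataset-out with tissue exclusion: the
held-out dataset supplies queries and gold labels, every dataset sharing
its tissue is removed from the fold's feature pairs, and the final
coefficients are the arithmetic mean over folds (the per-fold coefficient
optima vary much more than the window optimum does, which is why averaging
rather than re-selection is used).  Folds whose labels collapse to one
class are skipped with a warning.

## Enrichment

The statistic is the count of regions overlapping the annotation (binary
per region, not per base).  The null resamples region identities within
user-supplied strata of a background universe, without replacement, so each
draw matches the regions' stratum composition exactly.  Strata are generic
labels — chromosome, binned conservation score, width quantile — supplied
by the user rather than computed from any particular track.  Results are
z = (observed − null mean)/null sd and the add-one empirical p-value
(1 + #{null ≥ observed})/(B + 1), which can never be zero; a zero-variance
null is flagged rather than silently dividing.  Default B = 10,000.

## The synthetic fixture generator

The generator emulates the statistical structure the method assumes:

* Two genomes tied by a *consistent* chain: the target sequence is built by
  walking the chain events (copy aligned blocks with ~1% substitutions,
  skip source-side gaps, insert random sequence at destination-side gaps),
  so chain arithmetic, sequences and truth coordinates can never disagree.
* Planted orthologous elements (default 100 across 2 × 0.5 Mb sequences,
  200 bp wide).  Each query is the element's interval displaced by a
  Gaussian offset (default sd 500 bp), emulating assay-coordinate noise.
  Displacements beyond the element width put the query inside an alignment
  break sized with the displacement, so direct lift-over fails and the
  required rescue window grows with |displacement| — the fixture's analogue
  of queries recoverable only by extension.  A short aligned slack (25 bp)
  separates each element from its break; with this geometry a window of 0
  maps only near-exact queries, and each of those yields a single tile that
  overlaps its true element, so the window-0 labels are single-class and
  the grid search correctly records that window as unusable.
* Confuser elements: conserved regulatory elements 1.4–6 kb from each query
  (4 per query by default) that carry peaks in both genomes — and therefore
  belong to the gold-standard peak landscape — but whose tissue-activity
  profile is largely independent of the query's element (activity 0.4
  versus 0.8).  Over-wide extension windows sweep these up as genuine but
  weakly matching positives, which is what makes discrimination degrade
  beyond the displacement scale and gives the window grid an interior
  optimum, as observed on real epigenomes.
* Matched peak pairs (default 6): an active element's query-side mark is
  always present, its target-side mark with the conservation probability
  (default 0.9); 250 background peaks per pair per genome supply realistic
  false-overlap density.
* Motifs: 8 generated PFMs with ≥ 1 bit/column information, planted as
  consensus into 80% of elements (both genomes, via the aligned copy), so
  planted instances clear the default scan threshold; mutations can destroy
  a planted instance at the realistic rate.
* Decoy duplication chains (`adversarial_multimap`): each query also maps
  through one extra single-block chain to a random target locus carrying no
  conserved evidence (or a full copy of it, for tie-rule tests).  That
  fixture sets displacement to zero so the multi-mapping axis is isolated
  from the rescue axis.

One global seed drives independent per-component generators, so identical
seeds give byte-identical bundles.

**What the fixtures do not emulate:** realistic indel/evolutionary models,
GC or repeat structure, quantitative peak signal, inter-dataset correlation
beyond the planted activity patterns, and genome-scale data volumes.
Passing tests therefore demonstrate the correctness and the qualitative
behavior of the machinery (rescue, prioritization, window selection,
calibration) — not performance figures transferable to real genomes.

## Problem sizes

Test and acceptance runs use 2 × 0.5 Mb genome pairs with 100 planted
elements (smaller for unit tests), 5 seeds for the window-grid property,
500 repeats at 299 permutations for the null calibration, and n = 5000 for
coefficient recovery — sizes chosen so the full suite completes in about
two minutes while leaving the statistical assertions well-powered.

## Known limitations

* Binary features only; quantitative signal support would require a
  different similarity.
* The chain engine does not read net/axt formats and never splits or merges
  chains at parse time.
* Probabilities are prioritization scores, not calibrated posterior
  probabilities; calibrating them against external gold standards is the
  training module's job on real data.
* The enrichment module accepts arbitrary precomputed strata; it does not
  compute conservation-score strata from tracks itself.
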