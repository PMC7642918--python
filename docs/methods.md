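# Methods

This note documents the models and procedures implemented in `chromqc`,
the parameters that matter, the numerical choices behind them, and what
the synthetic benchmark does and does not demonstrate.

## Coordinates and conventions

All intervals are 0-based half-open internally. File readers and writers
convert at the boundary: TRF `.dat` rows, NLR prediction TSVs and GFF3 are
1-based inclusive on disk; BED and the internal truth files are 0-based
half-open. Gaps of unknown size are rendered and accounted as exactly
100 bp; known-size gaps keep their literal length. A gap-truth annotation,
when available, decides which rule applies to each N-run; without one, a
run of exactly 100 Ns is taken as unknown-size (the inverse of the
rendering convention, which is the best available heuristic and is wrong
only for genuine 100 bp known gaps).

## Genome size from k-mer histograms

The estimator is the classical coverage argument: every base of a genome
sequenced at coverage *c* contributes ≈ *c* k-mer instances, so the total
instance count divided by the per-copy coverage is the genome length,

  G = (Σ_{f=f_min}^{f_max} f · count(f)) / peak,  default f ∈ [1, 10 000].

Summing f·count (instances) rather than count (distinct k-mers) is the
only reading under which division by coverage yields a length; the
frequency window caps the contribution of extreme-copy repeats.

Peak finding excludes the sequencing-error region by locating the first
local minimum of the densified histogram when it opens on a descending
slope, then taking the argmax beyond it. A histogram that only decreases
has no coverage peak and is an error. A secondary peak is reported when
the argmax within [1.8, 2.2] × primary is a local maximum; that window
operationalises "roughly double", the signature of two-copy repeats.

The simulator draws per-bin counts as Poisson around a three-component
expectation: a Poisson-shaped unique component, a geometric error
component on frequencies 1–5 (ratio 0.2), and a Poisson-shaped two-copy
component at twice the coverage. Two deliberate choices:

* the unique component's shape parameter is `coverage_peak + 0.5`, whose
  integer mode is exactly `coverage_peak`. A Poisson with integer mean λ
  has tied modes at λ−1 and λ, which would make the simulated histogram's
  argmax a coin flip under sampling noise; the half-unit offset makes the
  requested peak the unique mode. The component is rescaled so its
  instances sum to exactly size × peak, keeping the estimator unbiased.
* default contamination weights are `error_weight = 0.01` and
  `repeat2x_weight = 0.005` (fractions of unique k-mer instances), a
  low-contamination regime typical of deep short-read data after quality
  trimming. These components are *included* in the AUC, so the estimate
  runs ~1.5% above truth at the defaults — the same bias the estimator has
  on real histograms — and stays inside the 2% band the tests assert.

Desk-scale problem sizes: the benchmark histogram simulates a 50 Mb
genome at peak 101. At that depth the mode's count (~2 × 10⁶) stands ~5
standard deviations clear of its neighbours, so peak identity is stable
across seeds; much smaller simulated genomes genuinely flip the argmax
between adjacent bins, which is a property of the data, not the finder.

`count_kmers` (canonical-strand, N-aware) is provided for desk-scale
sequences; disk-backed counting of real read sets is out of scope.

## Tandem-array detection

The detector is a Hamming-distance block scanner, not a reimplementation
of Tandem Repeats Finder's alignment scoring; a TRF `.dat` reader is
provided for users who prefer TRF output. For each unit length
u = 1…500 (`max_unit` mirrors the usual maxperiod setting):

1. **Scan.** Compare the sequence to itself at lag u; windows of u
   consecutive comparisons give adjacent-block Hamming distances, and
   maximal runs with distance ≤ `max_divergence`·u (default 0.2) are
   candidates. A point mutation perturbs ~2u consecutive windows, so runs
   separated by ≤ 2u are re-merged.
2. **Refine.** A provisional majority consensus picks the best tiling
   phase (scored over the candidate interval only); the block grid is then
   extended one unit beyond the candidate, per-block distances computed,
   and the longest run of within-budget blocks kept, bridging up to 4
   divergent blocks provided the run's mean distance stays within budget.
   Edge blocks diverging beyond 2 × median + 1 are trimmed (they are
   usually flanking sequence admitted by the lenient budget).
3. **Polish.** Boundaries are adjusted at base resolution by a
   maximal-scoring-subarray pass (+1 match, −(1−d)/d mismatch with
   d = `max_divergence`), so the reported interval extends exactly as far
   as ≥ (1−d) identity continues. A planted exact repeat is recovered at
   its planted coordinates with purity 1.0 unless a flank base happens to
   continue the repeat pattern — indistinguishable from array sequence by
   any detector.
4. **Resolve harmonics.** A period-u array is also periodic at 2u, 3u, …;
   among overlapping reports whose span is within 5% of the cluster
   maximum, the smallest unit wins, then purity, then position.
5. **Fold to the primitive unit.** An array of two alternating 7-mers is
   *exactly* periodic only at 14 bp and is detected most robustly there,
   but the repeat unit as the field reports it is 7 bp. When a consensus
   is internally periodic at a proper divisor (cyclic self-match ≥ 1−d),
   the array is retiled at that divisor.

`min_copies` defaults to 3 and `min_span` to 20 bp; without a span floor,
every ≥3 bp homopolymer in megabase-scale sequence is technically a
tandem array and the output drowns in them. N breaks arrays.

Consensus monomers (`build_monomer_consensus`) are per-column majorities
over the interval tiled from its start, ties broken alphabetically, with
the result rotated to best match the first block (anchoring the monomer to
the array's own phase). Majority vote recovers a planted monomer exactly
whenever the per-column error rate is far from 1/2 — comfortably so at
≤ 5% per-base mutation with ≥ 10 copies. Purity is the fraction of bases
in full blocks matching the tiled consensus.

## Classification and per-scaffold QC

Telomeric: unit length 7 and either within `end_window` (default 10 kb)
of a scaffold terminus or consensus within one substitution of a canonical
heptamer under rotation — interior canonical arrays stay telomeric
precisely so the QC stage can flag them. Centromeric: unit length within
±10% of the centromeric monomer (default 181 bp) or of its dimer, span
≥ 5 kb. Everything else is unclassified; the three classes partition every
array list.

`n_telomeres` counts telomere-bearing *ends* (0, 1 or 2), not arrays.
Status is a total function of (n_telomeres, has_centromere): two ends →
T2T; one end with a centromere → near_complete; one end without → arm;
no end telomeres → fragment. Centromeric arrays within 100 kb merge into
clusters; ≥ 2 clusters separated by > 1 Mb flag `multiple_centromeres`,
and a telomeric array with its midpoint outside both end windows flags
`interior_telomere`. When both co-occur, the proposed split is the gap
nearest the interior telomere that lies between the clusters — long-range
scaffolding joins sequence at gaps, so an erroneous join is undone at one
— falling back to the telomere midpoint if no such gap exists; separated
clusters alone split midway between them. The distance thresholds are
configurable because they scale with genome size; the synthetic tests use
5 kb / 20 kb on 30–60 kb chromosomes.

Splitting preserves total length, names the pieces `<seqid>_L` / `_R`,
and lifts each annotation exactly once to the side holding its larger
share (clipped at the cut; ties left). Nx statistics (N50, N90) are the
largest length L such that scaffolds ≥ L hold ≥ x% of the total — computed
by the cumulative-sum walk and cross-checked in tests against an
exhaustive-threshold oracle.

## Consensus error rate

A site is an error iff reference support is 0 *and* alternative support is
≥ 3 — both conditions, exactly at the ≥ 3 boundary. Each error site
contributes the reference bases it affects (minimum 1, so an insertion
counts one base); counting max(ref, alt) instead is available via
`indel_mode="max"` since the convention for indels is genuinely ambiguous.
The summary identities `quality + errors_per_10kb/100 = 100` hold to
floating precision by construction. Alignment and variant calling are out
of scope; the module reads site-level TSVs or a tolerant VCF subset
(RO/AO in INFO or FORMAT, multi-allelic support collapsed by maximum).

## Consensus NLR sets

Containment intersection requires the annotated gene's full span inside
the predicted NLR interval on the same scaffold, strand ignored (the
opposite direction is available via `containment="nlr-in-gene"`). When
several predictions contain one gene the representative is chosen by
largest overlap, then longer prediction, then leftmost, then id — a total
order, so results are reproducible; deduplication changes which prediction
represents a gene, never the set of genes represented (tested against a
quadratic all-pairs oracle). One prediction may represent several genes
and then counts once in the class partition. The missing-data filter
excludes aligned sequences with strictly more than the threshold (default
50%) of `- . X x ?` characters (plus N for nucleotide alignments — N is a
residue in protein data). The motif scanner is an ungapped wildcard match
(lowercase `x` = any residue) with an optional mismatch budget.

## The synthetic benchmark

`benchmark_preset` builds twelve scaffolds whose lengths are the published
chromosome lengths of a well-studied 8 Gb conifer assembly divided by
1,600 (≈ 5 Mb total): seven carry alternating-heptamer telomeric arrays
(120 copies, 1% per-base substitution) on both ends, four plus the
centromere-less arm scaffold on one end, and eleven carry an interior
181 bp-monomer centromeric array (55 copies, 2% substitution) — mutation
levels chosen as plausible within-genome repeat divergence, exposed as
parameters since real centromeric divergence varies by species. Gap counts
are the published counts divided by 1,000, all unknown-size.
`fused_preset` concatenates two telomere-capped, centromere-bearing
chromosomes around an unknown-size gap, the signature mis-join. The
mutation model is substitution-only; indels default to off.

Every planted feature is recorded once in a `TruthSet` (arrays, gaps,
junctions), and recovery tests read truth only from there. Identical
seeds give byte-identical FASTA/TSV outputs.

What passing these tests shows: the detector, classifier, QC logic and
estimators recover planted structure under substitution-type divergence at
realistic rates, and the bookkeeping (gap rule, class partitions, Nx,
split arithmetic) is exact. What it does not show: behaviour under
indel-rich divergence, higher-order repeat structure within centromeric
arrays, segmental duplications, heterozygosity, or the fragmented-array
landscape of real pericentromeric regions — real assemblies are messier
than any of these fixtures.

## Known limitations

* The tandem detector assumes substitution-dominated divergence; an indel
  inside an array shifts the register and will split the array at that
  point rather than absorb it.
* Unit lengths are reported exactly; a true 181 bp monomer detected at
  180 or 182 due to register drift would classify correctly (±10% band)
  but shift the unit-length histogram by one bin.
* The unknown-gap heuristic without truth mislabels genuine 100 bp
  known-size gaps.
* `count_kmers` holds its counts in memory and is not meant for read sets.
* Windowed densities apportion interval features by overlap; point tracks
  are counted in the window containing their start coordinate.
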