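"""Synthetic assemblies, histograms, and fixtures with planted ground truth.

Every downstream stage of the package is testable at desk scale against the
outputs of this module: chromosome-like scaffolds carrying end-proximal
alternating-heptamer telomeric arrays and large interior ~181 bp-monomer
centromeric arrays, N-gap runs, deliberately fused (mis-assembled)
scaffolds, Poisson-mixture k-mer histograms, variant-site support tables,
and NLR/gene interval fixtures with controlled containment. All coordinates
are 0-based half-open internally; GFF3 and prediction-table writers convert
to 1-based inclusive.

Generators are deterministic under a fixed integer seed, and every planted
feature is recorded exactly once in a :class:`TruthSet` so that recovery
tests never peek at generator internals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from ._seqio import write_fasta
from .exceptions import ValidationError
from .kmers import KmerHistogram

__all__ = [
    "UNKNOWN_GAP_LENGTH",
    "RepeatUnitSpec",
    "GapSpec",
    "ScaffoldSpec",
    "TruthArray",
    "TruthGap",
    "TruthJunction",
    "TruthSet",
    "Assembly",
    "RepeatArray",
    "make_repeat_array",
    "build_assembly",
    "SimulatedHistogram",
    "simulate_kmer_histogram",
    "simulate_variant_sites",
    "write_variant_sites",
    "NlrFixture",
    "simulate_nlr_fixture",
    "write_nlr_tsv",
    "write_genes_gff3",
    "benchmark_preset",
    "fused_preset",
    "NLR_CLASS_MIX",
]

UNKNOWN_GAP_LENGTH = 100  # rendered length of an unknown-size gap

_DNA = "ACGT"
_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_CODE[_b] = _i

#: Completeness-class mix of NLR-Annotator predictions used as the fixture
#: default: (complete, complete_pseudo, partial, partial_pseudo).
NLR_CLASS_MIX = (442 / 984, 332 / 984, 88 / 984, 122 / 984)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Repeat arrays
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatUnitSpec:
    """A tandem-repeat unit to plant: monomer, copy count, mutation rate.

    When ``alternate_monomer`` is set, copies strictly alternate between the
    two units (monomer first) before mutation — the construction used for
    telomeric arrays in which TTTAGGG alternates with TTGAGGG. Mutation is
    substitution-only: each base is independently replaced, with the stated
    probability, by a uniform choice among the three other bases.
    """

    monomer: str
    copies: int
    alternate_monomer: str | None = None
    per_base_mutation_rate: float = 0.0

    def __post_init__(self):
        if not self.monomer or not (1 <= len(self.monomer) <= 500):
            raise ValidationError("monomer must be a non-empty DNA string of 1-500 bp")
        for unit in (self.monomer, self.alternate_monomer or self.monomer):
            if set(unit) - set(_DNA):
                raise ValidationError(f"monomer alphabet must be ACGT, got {unit!r}")
        if self.alternate_monomer is not None and len(self.alternate_monomer) != len(self.monomer):
            raise ValidationError("alternate_monomer must have the same length as monomer")
        if self.copies < 1:
            raise ValidationError("copies must be >= 1")
        if not (0.0 <= self.per_base_mutation_rate <= 1.0):
            raise ValidationError("per_base_mutation_rate must be in [0, 1]")

    @property
    def array_length(self) -> int:
        return self.copies * len(self.monomer)


class RepeatArray(NamedTuple):
    """A rendered repeat array and its per-copy truth (pre-mutation units)."""

    sequence: str
    units: tuple[str, ...]


def _mutate_codes(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return codes
    mask = rng.random(len(codes)) < rate
    n = int(mask.sum())
    if n:
        codes = codes.copy()
        codes[mask] = (codes[mask] + rng.integers(1, 4, size=n)) % 4
    return codes


def make_repeat_array(spec: RepeatUnitSpec, seed) -> RepeatArray:
    """Render a repeat array: alternating concatenation, then point mutation."""
    rng = _rng(seed)
    if spec.alternate_monomer is None:
        units = (spec.monomer,) * spec.copies
    else:
        units = tuple(
            spec.monomer if i % 2 == 0 else spec.alternate_monomer for i in range(spec.copies)
        )
    codes = _BASE_TO_CODE[np.frombuffer("".join(units).encode("ascii"), dtype=np.uint8)]
    codes = _mutate_codes(codes, spec.per_base_mutation_rate, rng)
    return RepeatArray(sequence=_CODE_TO_BASE[codes].tobytes().decode("ascii"), units=units)


# ---------------------------------------------------------------------------
# Scaffolds and assemblies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GapSpec:
    """A planted gap. Unknown-size gaps are rendered as exactly 100 Ns."""

    position: int
    length: int = UNKNOWN_GAP_LENGTH
    known_size: bool = False

    @property
    def rendered_length(self) -> int:
        return self.length if self.known_size else UNKNOWN_GAP_LENGTH


@dataclass(frozen=True)
class ScaffoldSpec:
    """Blueprint for one synthetic scaffold.

    Either a plain scaffold (``length`` plus optional planted features) or a
    mis-assembly construction: ``fusion_of`` concatenates two component
    scaffolds around an interstitial unknown-size gap, emulating an
    erroneous long-range join.
    """

    name: str
    length: int | None = None
    telomere_5p: RepeatUnitSpec | None = None
    telomere_3p: RepeatUnitSpec | None = None
    centromere: tuple[RepeatUnitSpec, float] | None = None
    gaps: tuple[GapSpec, ...] = ()
    fusion_of: tuple["ScaffoldSpec", "ScaffoldSpec"] | None = None

    def __post_init__(self):
        if self.fusion_of is None:
            if self.length is None or self.length < 1:
                raise ValidationError(f"scaffold {self.name}: length must be positive")
            if self.centromere is not None:
                _, frac = self.centromere
                if not (0.0 < frac < 1.0):
                    raise ValidationError("centromere position fraction must be in (0, 1)")
        elif len(self.fusion_of) != 2:
            raise ValidationError("fusion_of must name exactly two component scaffolds")


@dataclass(frozen=True)
class TruthArray:
    seqid: str
    start: int
    end: int
    array_class: str  # telomeric | centromeric
    monomer: str


@dataclass(frozen=True)
class TruthGap:
    seqid: str
    start: int
    end: int
    known_size: bool


@dataclass(frozen=True)
class TruthJunction:
    seqid: str
    position: int
    left: str
    right: str
    left_length: int
    right_length: int


@dataclass
class TruthSet:
    """Planted ground truth for one synthetic assembly."""

    arrays: list[TruthArray] = field(default_factory=list)
    gaps: list[TruthGap] = field(default_factory=list)
    junctions: list[TruthJunction] = field(default_factory=list)

    def for_seqid(self, seqid: str) -> "TruthSet":
        return TruthSet(
            arrays=[a for a in self.arrays if a.seqid == seqid],
            gaps=[g for g in self.gaps if g.seqid == seqid],
            junctions=[j for j in self.junctions if j.seqid == seqid],
        )

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "truth_arrays.bed", "w") as handle:
            for a in self.arrays:
                handle.write(f"{a.seqid}\t{a.start}\t{a.end}\t{a.array_class}\t{a.monomer}\n")
        with open(outdir / "truth_gaps.bed", "w") as handle:
            for g in self.gaps:
                kind = "known" if g.known_size else "unknown"
                handle.write(f"{g.seqid}\t{g.start}\t{g.end}\t{kind}\n")
        with open(outdir / "truth_junctions.tsv", "w") as handle:
            handle.write("seqid\tposition\tleft\tright\tleft_length\tright_length\n")
            for j in self.junctions:
                handle.write(
                    f"{j.seqid}\t{j.position}\t{j.left}\t{j.right}"
                    f"\t{j.left_length}\t{j.right_length}\n"
                )


def load_truth(outdir) -> TruthSet:
    """Read a :class:`TruthSet` written by :meth:`TruthSet.write`."""
    outdir = Path(outdir)
    truth = TruthSet()
    arrays_path = outdir / "truth_arrays.bed"
    if arrays_path.exists():
        for line in arrays_path.read_text().splitlines():
            seqid, start, end, cls, monomer = line.split("\t")
            truth.arrays.append(TruthArray(seqid, int(start), int(end), cls, monomer))
    gaps_path = outdir / "truth_gaps.bed"
    if gaps_path.exists():
        for line in gaps_path.read_text().splitlines():
            seqid, start, end, kind = line.split("\t")
            truth.gaps.append(TruthGap(seqid, int(start), int(end), kind == "known"))
    junctions_path = outdir / "truth_junctions.tsv"
    if junctions_path.exists():
        lines = junctions_path.read_text().splitlines()[1:]
        for line in lines:
            seqid, pos, left, right, ll, rl = line.split("\t")
            truth.junctions.append(TruthJunction(seqid, int(pos), left, right, int(ll), int(rl)))
    return truth


@dataclass
class Assembly:
    """In-memory synthetic assembly: sequences plus planted truth."""

    sequences: dict[str, str]
    truth: TruthSet

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


def _render_scaffold(
    spec: ScaffoldSpec, seqid: str, rng: np.random.Generator
) -> tuple[str, TruthSet]:
    """Render one (possibly fused) scaffold and its truth records."""
    truth = TruthSet()
    if spec.fusion_of is not None:
        left_spec, right_spec = spec.fusion_of
        left_seq, left_truth = _render_scaffold(left_spec, seqid, rng)
        right_seq, right_truth = _render_scaffold(right_spec, seqid, rng)
        junction = len(left_seq)
        offset = junction + UNKNOWN_GAP_LENGTH
        truth.arrays = left_truth.arrays + [
            dataclasses.replace(a, start=a.start + offset, end=a.end + offset)
            for a in right_truth.arrays
        ]
        truth.gaps = (
            left_truth.gaps
            + [TruthGap(seqid, junction, junction + UNKNOWN_GAP_LENGTH, False)]
            + [
                dataclasses.replace(g, start=g.start + offset, end=g.end + offset)
                for g in right_truth.gaps
            ]
        )
        truth.junctions = [
            TruthJunction(
                seqid=seqid,
                position=junction,
                left=left_spec.name,
                right=right_spec.name,
                left_length=len(left_seq),
                right_length=len(right_seq),
            )
        ]
        seq = left_seq + "N" * UNKNOWN_GAP_LENGTH + right_seq
        return seq, truth

    length = spec.length
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)

    planted: list[tuple[int, int]] = []

    def place(start: int, end: int, what: str):
        if start < 0 or end > length:
            raise ValidationError(f"scaffold {spec.name}: {what} [{start}, {end}) exceeds length")
        for s, e in planted:
            if start < e and s < end:
                raise ValidationError(
                    f"scaffold {spec.name}: {what} [{start}, {end}) overlaps a planted feature"
                )
        planted.append((start, end))

    if spec.telomere_5p is not None:
        arr = make_repeat_array(spec.telomere_5p, rng)
        place(0, len(arr.sequence), "5' telomere")
        codes[: len(arr.sequence)] = _BASE_TO_CODE[
            np.frombuffer(arr.sequence.encode(), dtype=np.uint8)
        ]
        truth.arrays.append(
            TruthArray(seqid, 0, len(arr.sequence), "telomeric", spec.telomere_5p.monomer)
        )
    if spec.centromere is not None:
        cen_spec, frac = spec.centromere
        arr = make_repeat_array(cen_spec, rng)
        alen = len(arr.sequence)
        start = int(frac * length) - alen // 2
        start = max(0, min(start, length - alen))
        place(start, start + alen, "centromere")
        codes[start : start + alen] = _BASE_TO_CODE[
            np.frombuffer(arr.sequence.encode(), dtype=np.uint8)
        ]
        truth.arrays.append(
            TruthArray(seqid, start, start + alen, "centromeric", cen_spec.monomer)
        )
    if spec.telomere_3p is not None:
        arr = make_repeat_array(spec.telomere_3p, rng)
        alen = len(arr.sequence)
        place(length - alen, length, "3' telomere")
        codes[length - alen :] = _BASE_TO_CODE[
            np.frombuffer(arr.sequence.encode(), dtype=np.uint8)
        ]
        truth.arrays.append(
            TruthArray(seqid, length - alen, length, "telomeric", spec.telomere_3p.monomer)
        )

    seq = _CODE_TO_BASE[codes].tobytes().decode("ascii")
    chars = list(seq)
    for gap in spec.gaps:
        rlen = gap.rendered_length
        place(gap.position, gap.position + rlen, "gap")
        chars[gap.position : gap.position + rlen] = "N" * rlen
        truth.gaps.append(TruthGap(seqid, gap.position, gap.position + rlen, gap.known_size))
    truth.gaps.sort(key=lambda g: g.start)
    return "".join(chars), truth


def build_assembly(specs: list[ScaffoldSpec], seed: int, outdir=None) -> Assembly:
    """Render an assembly from scaffold blueprints; optionally write it out.

    Deterministic under a fixed seed: identical specs and seed produce
    byte-identical FASTA and truth files. When ``outdir`` is given, writes
    ``assembly.fasta`` (80-column wrap), ``truth_arrays.bed``,
    ``truth_gaps.bed`` and ``truth_junctions.tsv``.
    """
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValidationError("scaffold names must be unique")
    rng = _rng(seed)
    sequences: dict[str, str] = {}
    truth = TruthSet()
    for spec in specs:
        seq, sub = _render_scaffold(spec, spec.name, rng)
        sequences[spec.name] = seq
        truth.arrays.extend(sub.arrays)
        truth.gaps.extend(sub.gaps)
        truth.junctions.extend(sub.junctions)
    assembly = Assembly(sequences=sequences, truth=truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(sequences, outdir / "assembly.fasta", wrap=80)
        truth.write(outdir)
    return assembly


# ---------------------------------------------------------------------------
# k-mer histogram simulation
# ---------------------------------------------------------------------------

class SimulatedHistogram(NamedTuple):
    histogram: KmerHistogram
    true_size: int
    true_peak: int


def simulate_kmer_histogram(
    true_genome_size: int,
    coverage_peak: float,
    error_weight: float = 0.01,
    repeat2x_weight: float = 0.005,
    max_freq: int = 10_000,
    seed: int = 0,
    k: int = 31,
) -> SimulatedHistogram:
    """Simulate a k-mer frequency histogram as a three-component mixture.

    Components (expected counts, then Poisson-sampled per bin):

    * unique sequence — Poisson-shaped in frequency with mode exactly at
      ``coverage_peak`` (shape parameter ``coverage_peak + 0.5``, whose
      integer mode is ``coverage_peak``), scaled so that its k-mer instances
      sum to ``true_genome_size * coverage_peak``;
    * sequencing errors — geometric decay over frequencies 1-5 carrying
      ``error_weight`` of the unique instances;
    * two-copy repeats — the same Poisson shape centred at twice the
      coverage, carrying ``repeat2x_weight`` of the unique instances.

    The default weights keep the contaminating components at ~1.5% of total
    instances, a regime in which the AUC/peak estimator read directly off
    the histogram stays within 2% of the true size.
    """
    if coverage_peak <= 0:
        raise ValidationError("coverage_peak must be positive")
    if max_freq < coverage_peak:
        raise ValidationError("max_freq must be at least coverage_peak")
    for name, w in (("error_weight", error_weight), ("repeat2x_weight", repeat2x_weight)):
        if not (0.0 <= w <= 1.0):
            raise ValidationError(f"{name} must be in [0, 1]")
    rng = _rng(seed)
    freqs = np.arange(1, max_freq + 1)
    instances = float(true_genome_size) * float(coverage_peak)

    lam = coverage_peak + 0.5
    expected = instances / lam * stats.poisson.pmf(freqs, lam)

    if error_weight > 0:
        q = 0.2
        shape = q ** (freqs[:5] - 1)
        err_scale = error_weight * instances / float(np.sum(freqs[:5] * shape))
        expected[:5] += err_scale * shape

    if repeat2x_weight > 0:
        lam2 = 2.0 * coverage_peak + 0.5
        expected += repeat2x_weight * instances / lam2 * stats.poisson.pmf(freqs, lam2)

    counts = rng.poisson(expected)
    bins = {int(f): int(c) for f, c in zip(freqs, counts) if c > 0}
    return SimulatedHistogram(
        histogram=KmerHistogram(bins=bins, k=k),
        true_size=int(true_genome_size),
        true_peak=int(round(coverage_peak)),
    )


# ---------------------------------------------------------------------------
# Variant-site fixtures
# ---------------------------------------------------------------------------

def simulate_variant_sites(
    n_sites: int,
    fraction_error: float,
    mean_depth: float = 30.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate per-site read-support counts with known error labels.

    True consensus-error sites have zero reads supporting the reference and
    at least three supporting one alternative allele. Non-error sites
    violate at least one of the two conditions: most keep reference support
    (ordinary heterozygous-looking or noisy sites), the rest have zero
    reference support but fewer than three alternative reads.

    Returns the site table and a boolean truth vector aligned to its rows.
    """
    if not (0.0 <= fraction_error <= 1.0):
        raise ValidationError("fraction_error must be in [0, 1]")
    if n_sites < 0:
        raise ValidationError("n_sites must be non-negative")
    rng = _rng(seed)
    n_err = int(round(fraction_error * n_sites))
    is_error = np.zeros(n_sites, dtype=bool)
    is_error[rng.permutation(n_sites)[:n_err]] = True

    bases = np.array(list(_DNA))
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4

    ref_support = np.zeros(n_sites, dtype=np.int64)
    alt_support = np.zeros(n_sites, dtype=np.int64)
    lam = max(mean_depth - 3.0, 0.0)
    n_true = int(is_error.sum())
    alt_support[is_error] = 3 + rng.poisson(lam, size=n_true)

    idx_clean = np.flatnonzero(~is_error)
    low_alt = rng.random(idx_clean.size) < 0.2
    # zero reference support but < 3 alternative reads
    alt_support[idx_clean[low_alt]] = rng.integers(0, 3, size=int(low_alt.sum()))
    # reference-supported sites (alt support unconstrained)
    keep = idx_clean[~low_alt]
    ref_support[keep] = 1 + rng.poisson(mean_depth, size=keep.size)
    alt_support[keep] = rng.poisson(2.0, size=keep.size)

    df = pd.DataFrame(
        {
            "seqid": "chrS",
            "pos": np.arange(100, 100 + 10 * n_sites, 10, dtype=np.int64),
            "ref_allele": bases[ref_idx],
            "alt_allele": bases[alt_idx],
            "ref_support": ref_support,
            "alt_support": alt_support,
        }
    )
    return df, is_error


def write_variant_sites(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# NLR / gene fixtures
# ---------------------------------------------------------------------------

_NLR_CLASSES = ("complete", "complete_pseudo", "partial", "partial_pseudo")


class NlrFixture(NamedTuple):
    nlrs: pd.DataFrame  # id, seqid, start, end, strand, completeness (0-based half-open)
    genes: pd.DataFrame  # id, seqid, start, end, strand
    truth_pairs: list[tuple[str, str]]  # (nlr_id, gene_id) expected consensus pairs


def _largest_remainder(proportions, total: int) -> list[int]:
    """Deterministic integer apportionment of ``total`` by proportions."""
    raw = [p * total for p in proportions]
    counts = [int(np.floor(r)) for r in raw]
    short = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:short]:
        counts[i] += 1
    return counts


def simulate_nlr_fixture(
    n_nlr: int,
    n_genes: int,
    containment_fraction: float | None = None,
    class_mix: tuple[float, float, float, float] = NLR_CLASS_MIX,
    n_chromosomes: int = 11,
    seed: int = 0,
    contained_class_counts: dict[str, int] | None = None,
) -> NlrFixture:
    """NLR predictions and gene annotations with controlled containment.

    NLR loci are laid on disjoint 30 kb slots across ``n_chromosomes``
    chromosomes; completeness classes are apportioned deterministically from
    ``class_mix`` (largest-remainder) and shuffled. A controlled subset of
    genes is placed strictly inside a distinct NLR interval (those are the
    expected consensus pairs); every other gene straddles an NLR boundary or
    sits in free space, so it is fully contained in no NLR.

    The contained subset is sized either by ``containment_fraction`` of
    ``n_genes`` or, for fixtures that must hit exact per-class tallies, by
    ``contained_class_counts`` mapping completeness class to the number of
    contained NLRs of that class.
    """
    if abs(sum(class_mix) - 1.0) > 1e-9:
        raise ValidationError("class_mix proportions must sum to 1")
    if containment_fraction is None and contained_class_counts is None:
        raise ValidationError("give containment_fraction or contained_class_counts")
    rng = _rng(seed)

    class_counts = _largest_remainder(class_mix, n_nlr)
    classes = np.repeat(np.array(_NLR_CLASSES, dtype=object), class_counts)
    classes = classes[rng.permutation(n_nlr)]

    slot = 30_000
    chroms = [f"chr{i + 1}" for i in range(n_chromosomes)]
    nlr_rows = []
    for i in range(n_nlr):
        seqid = chroms[i % n_chromosomes]
        slot_start = (i // n_chromosomes) * slot
        start = slot_start + 5_000 + int(rng.integers(0, 2_000))
        length = int(rng.integers(3_000, 8_001))
        nlr_rows.append(
            {
                "id": f"nlr{i + 1:04d}",
                "seqid": seqid,
                "start": start,
                "end": start + length,
                "strand": "+" if rng.random() < 0.5 else "-",
                "completeness": classes[i],
            }
        )
    nlrs = pd.DataFrame(nlr_rows)

    if contained_class_counts is not None:
        unknown = set(contained_class_counts) - set(_NLR_CLASSES)
        if unknown:
            raise ValidationError(f"unknown completeness classes: {sorted(unknown)}")
        chosen: list[int] = []
        for cls, want in contained_class_counts.items():
            pool = np.flatnonzero(classes == cls)
            if want > pool.size:
                raise ValidationError(
                    f"cannot contain {want} NLRs of class {cls}; only {pool.size} available"
                )
            chosen.extend(rng.choice(pool, size=want, replace=False).tolist())
        chosen = sorted(chosen)
        n_contained = len(chosen)
        if n_contained > n_genes:
            raise ValidationError("contained_class_counts exceed n_genes")
    else:
        n_contained = int(round(containment_fraction * n_genes))
        if n_contained > n_nlr:
            raise ValidationError("cannot contain more genes than there are NLRs")
        chosen = sorted(rng.choice(n_nlr, size=n_contained, replace=False).tolist())

    gene_rows = []
    truth_pairs: list[tuple[str, str]] = []
    gene_no = 0
    for i in chosen:
        row = nlrs.iloc[i]
        pad = max(1, (row.end - row.start) // 4)
        gene_no += 1
        gid = f"gene{gene_no:04d}"
        gene_rows.append(
            {
                "id": gid,
                "seqid": row.seqid,
                "start": int(row.start + pad),
                "end": int(row.end - pad),
                "strand": row.strand,
            }
        )
        truth_pairs.append((row.id, gid))

    free = [i for i in range(n_nlr) if i not in set(chosen)]
    next_free_slot = (n_nlr + n_chromosomes - 1) // n_chromosomes
    for j in range(n_genes - n_contained):
        gene_no += 1
        gid = f"gene{gene_no:04d}"
        if j < len(free):
            # partial overlap: straddle the NLR's left boundary
            row = nlrs.iloc[free[j]]
            gene_rows.append(
                {
                    "id": gid,
                    "seqid": row.seqid,
                    "start": int(row.start - 1_000),
                    "end": int(row.start + 1_000),
                    "strand": "+",
                }
            )
        else:
            # free space beyond all NLR slots
            k = j - len(free)
            seqid = chroms[k % n_chromosomes]
            slot_start = (next_free_slot + k // n_chromosomes) * slot
            gene_rows.append(
                {
                    "id": gid,
                    "seqid": seqid,
                    "start": slot_start + 5_000,
                    "end": slot_start + 7_000,
                    "strand": "+",
                }
            )
    genes = pd.DataFrame(
        gene_rows, columns=["id", "seqid", "start", "end", "strand"]
    )
    return NlrFixture(nlrs=nlrs, genes=genes, truth_pairs=truth_pairs)


def write_nlr_tsv(nlrs: pd.DataFrame, path) -> None:
    """Write NLR predictions as TSV with 1-based inclusive coordinates."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out = nlrs.copy()
    out["start"] = out["start"] + 1
    out.to_csv(path, sep="\t", index=False,
               columns=["id", "seqid", "start", "end", "strand", "completeness"])


def write_genes_gff3(genes: pd.DataFrame, path, source: str = "chromqc_sim") -> None:
    """Write gene models as GFF3 ``gene`` features (1-based inclusive)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for _, row in genes.iterrows():
            handle.write(
                f"{row.seqid}\t{source}\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.id}\n"
            )


# ---------------------------------------------------------------------------
# Assembly presets
# ---------------------------------------------------------------------------

#: (name, full-scale length bp, has centromere, telomere count, gap count)
#: layout of the twelve largest scaffolds of a chromosome-scale conifer
#: assembly: eleven chromosomes (seven telomere-to-telomere, four with one
#: telomere) plus one large centromere-less chromosome-arm scaffold.
_BENCHMARK_LAYOUT = (
    ("chr1", 986_618_365, True, 1, 4_415),
    ("chr2", 873_713_311, True, 2, 3_812),
    ("chr3", 843_110_718, True, 1, 3_788),
    ("chr4", 722_823_090, True, 2, 3_028),
    ("chr5", 690_549_816, True, 2, 2_902),
    ("chr6", 676_903_824, True, 1, 3_005),
    ("chr7", 659_235_867, True, 2, 2_790),
    ("chr8", 649_867_199, True, 2, 2_953),
    ("chr9", 641_211_466, True, 1, 2_707),
    ("chr10", 632_191_860, True, 2, 2_642),
    ("chr11", 443_565_592, True, 2, 1_885),
    ("scf12", 171_454_409, False, 1, 731),
)

CENTROMERE_MONOMER_181 = (
    "AAAAATTGGAGTTCGCGTGACACAGATGCAACGTAGCCTTAAAATCAGGTCTTCGCCGAACTCGACATT"
    "AAATCGATGGAAATTCAACATTCACGAAAACTGATAGAAAATAAAGGTTCTTAATAGTCATCTACAACA"
    "CAATCTAAATCAAAGTTCTCCAAACATGGTTGATTATGGGTGA"
)[:181]


def _random_monomer(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_DNA), size=length))


def _telomere_spec(copies: int, rate: float) -> RepeatUnitSpec:
    return RepeatUnitSpec(
        monomer="TTTAGGG",
        alternate_monomer="TTGAGGG",
        copies=copies,
        per_base_mutation_rate=rate,
    )


def _place_gaps(
    n_gaps: int,
    length: int,
    keepout: list[tuple[int, int]],
    rng: np.random.Generator,
) -> tuple[GapSpec, ...]:
    """Place unknown-size gaps uniformly, avoiding planted features."""
    gaps: list[GapSpec] = []
    placed: list[tuple[int, int]] = list(keepout)
    attempts = 0
    while len(gaps) < n_gaps and attempts < 1000 * max(n_gaps, 1):
        attempts += 1
        pos = int(rng.integers(0, max(1, length - UNKNOWN_GAP_LENGTH)))
        iv = (pos - 50, pos + UNKNOWN_GAP_LENGTH + 50)
        if any(iv[0] < e and s < iv[1] for s, e in placed):
            continue
        placed.append((pos, pos + UNKNOWN_GAP_LENGTH))
        gaps.append(GapSpec(position=pos, known_size=False))
    if len(gaps) < n_gaps:
        raise ValidationError("could not place all gaps without overlap")
    return tuple(sorted(gaps, key=lambda g: g.position))


def benchmark_preset(
    seed: int = 0,
    scale: int = 1_600,
    telomere_copies: int = 120,
    telomere_rate: float = 0.01,
    centromere_copies: int = 55,
    centromere_rate: float = 0.02,
    gap_scale: int = 1_000,
) -> list[ScaffoldSpec]:
    """Blueprints for a 12-scaffold assembly mirroring the published layout.

    Scaffold lengths are the published chromosome lengths divided by
    ``scale`` (default ~5 Mb total); seven scaffolds carry telomeric arrays
    on both ends, four (plus the arm scaffold) on one end, and eleven carry
    an interior centromeric array of the 181 bp monomer. Gap counts are the
    published counts divided by ``gap_scale``, all of unknown size.
    Telomeres are alternating-heptamer arrays at 1% per-base mutation;
    centromeres use the 181 bp monomer at 2%.
    """
    rng = _rng(seed)
    specs = []
    for name, full_length, has_cen, n_tel, n_gaps in _BENCHMARK_LAYOUT:
        length = full_length // scale
        tel5 = _telomere_spec(telomere_copies, telomere_rate)
        tel3 = _telomere_spec(telomere_copies, telomere_rate) if n_tel == 2 else None
        keepout: list[tuple[int, int]] = [(0, tel5.array_length + 200)]
        if tel3 is not None:
            keepout.append((length - tel3.array_length - 200, length))
        centromere = None
        if has_cen:
            cen_spec = RepeatUnitSpec(
                monomer=CENTROMERE_MONOMER_181,
                copies=centromere_copies,
                per_base_mutation_rate=centromere_rate,
            )
            frac = 0.35 + 0.3 * float(rng.random())
            cen_len = cen_spec.array_length
            cen_start = int(frac * length) - cen_len // 2
            keepout.append((cen_start - 200, cen_start + cen_len + 200))
            centromere = (cen_spec, frac)
        n_scaled_gaps = max(1, round(n_gaps / gap_scale))
        gaps = _place_gaps(n_scaled_gaps, length, keepout, rng)
        specs.append(
            ScaffoldSpec(
                name=name,
                length=length,
                telomere_5p=tel5,
                telomere_3p=tel3,
                centromere=centromere,
                gaps=gaps,
            )
        )
    return specs


def fused_preset(
    seed: int = 0,
    component_length: int = 60_000,
    telomere_copies: int = 60,
    telomere_rate: float = 0.01,
    centromere_copies: int = 40,
    centromere_rate: float = 0.02,
    name: str = "fused1",
) -> ScaffoldSpec:
    """Blueprint for one mis-assembled scaffold: two fused T2T chromosomes.

    Each component is telomere-capped at both ends with an interior
    centromere, so the fusion carries two interior telomeric regions and two
    centromeric clusters around an interstitial unknown-size gap — the
    signature that triggers mis-assembly detection and splitting.
    """
    rng = _rng(seed)

    def component(idx: int) -> ScaffoldSpec:
        cen = RepeatUnitSpec(
            monomer=_random_monomer(181, rng),
            copies=centromere_copies,
            per_base_mutation_rate=centromere_rate,
        )
        return ScaffoldSpec(
            name=f"{name}_part{idx}",
            length=component_length,
            telomere_5p=_telomere_spec(telomere_copies, telomere_rate),
            telomere_3p=_telomere_spec(telomere_copies, telomere_rate),
            centromere=(cen, 0.45 + 0.1 * float(rng.random())),
        )

    return ScaffoldSpec(name=name, fusion_of=(component(1), component(2)))
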