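"""Genome-size estimation from k-mer frequency histograms.

A k-mer frequency histogram maps multiplicity ``f`` (how many times a k-mer
occurs in the read set) to the number of distinct k-mers with that
multiplicity. For a haploid genome sequenced at coverage ``c``, k-mers from
unique sequence pile up around ``f = c`` while sequencing errors create a
spike at ``f = 1``; two-copy repeats form a smaller secondary peak near
``2c``. The genome size follows from the total number of k-mer instances
(the area under the curve, AUC = sum of f * count(f)) divided by the
coverage peak:

    size = AUC / peak

which is the standard coverage-based estimator. The AUC is taken over a
frequency window (default 1..10,000) so that extreme high-copy repeats do
not dominate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._seqio import as_sequences
from .exceptions import NoCoveragePeakError, ParseError, ValidationError

__all__ = [
    "KmerHistogram",
    "PeakReport",
    "GenomeSizeEstimate",
    "read_kmer_histogram",
    "write_kmer_histogram",
    "count_kmers",
    "find_coverage_peaks",
    "estimate_genome_size",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class KmerHistogram:
    """Sparse k-mer frequency histogram: multiplicity -> distinct k-mer count."""

    bins: dict[int, int]
    k: int | None = None

    def __post_init__(self):
        for f, c in self.bins.items():
            if f < 1:
                raise ValidationError(f"k-mer frequency must be >= 1, got {f}")
            if c < 0:
                raise ValidationError(f"count must be non-negative, got {c} at frequency {f}")

    def auc(self, f_min: int = 1, f_max: int = 10_000) -> int:
        """Total k-mer instances with multiplicity in [f_min, f_max]."""
        return int(sum(f * c for f, c in self.bins.items() if f_min <= f <= f_max))

    def dense(self) -> tuple[np.ndarray, np.ndarray]:
        """Densified (frequencies, counts) spanning min..max observed frequency."""
        if not self.bins:
            raise ValidationError("empty histogram")
        lo, hi = min(self.bins), max(self.bins)
        freqs = np.arange(lo, hi + 1)
        counts = np.zeros(hi - lo + 1, dtype=np.int64)
        for f, c in self.bins.items():
            counts[f - lo] = c
        return freqs, counts


@dataclass
class PeakReport:
    """Primary (coverage) peak and, when present, the ~2x repeat peak."""

    primary_peak: int
    secondary_peak: int | None = None
    secondary_ratio: float | None = None


@dataclass
class GenomeSizeEstimate:
    """AUC-based genome size: ``size_bp = auc / peak`` over [f_min, f_max]."""

    auc: int
    peak: int
    size_bp: float = field(init=False)
    f_min: int = 1
    f_max: int = 10_000

    def __post_init__(self):
        if self.peak < 1:
            raise ValidationError("coverage peak must be >= 1")
        if self.f_min > self.f_max:
            raise ValidationError("f_min must not exceed f_max")
        self.size_bp = self.auc / self.peak


def read_kmer_histogram(path, k: int | None = None) -> KmerHistogram:
    """Read a two-column ``frequency count`` histogram (jellyfish-histo style).

    Whitespace-delimited; ``#`` comment lines are skipped; duplicate
    frequencies are rejected.
    """
    bins: dict[int, int] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ParseError(
                    f"expected two fields 'frequency count', got {len(fields)}",
                    path=path, line=lineno,
                )
            try:
                f, c = int(fields[0]), int(fields[1])
            except ValueError:
                raise ParseError(f"non-integer field in {fields!r}", path=path, line=lineno)
            if f in bins:
                raise ParseError(f"duplicate frequency {f}", path=path, line=lineno)
            bins[f] = c
    if not bins:
        raise ParseError("empty histogram file", path=path)
    return KmerHistogram(bins=bins, k=k)


def write_kmer_histogram(hist: KmerHistogram, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as handle:
        for f in sorted(hist.bins):
            handle.write(f"{f} {hist.bins[f]}\n")


def _canonical(kmer: str) -> str:
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc


def count_kmers(sequences, k: int) -> KmerHistogram:
    """Count canonical k-mers in the given sequences and histogram them.

    k-mers overlapping any non-ACGT character (e.g. N) are skipped. Each
    k-mer is counted on its canonical strand: the lexicographic minimum of
    the k-mer and its reverse complement. Intended for desk-scale sequences;
    disk-backed counting of real read sets is out of scope.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    seqs = as_sequences(sequences)
    counts: dict[str, int] = {}
    valid = frozenset("ACGT")
    for seq in seqs.values():
        n = len(seq)
        # next invalid character at or after each position, to skip k-mers spanning it
        next_bad = np.empty(n, dtype=np.int64)
        last = n + k
        for i in range(n - 1, -1, -1):
            if seq[i] not in valid:
                last = i
            next_bad[i] = last
        for i in range(n - k + 1):
            if next_bad[i] < i + k:
                continue
            kmer = _canonical(seq[i : i + k])
            counts[kmer] = counts.get(kmer, 0) + 1
    bins: dict[int, int] = {}
    for mult in counts.values():
        bins[mult] = bins.get(mult, 0) + 1
    return KmerHistogram(bins=bins, k=k)


def find_coverage_peaks(hist: KmerHistogram) -> PeakReport:
    """Locate the coverage peak, excluding the low-frequency error region.

    The error spike at f = 1 decays monotonically; the primary peak is the
    argmax of counts over frequencies strictly greater than the first local
    minimum of the histogram (the trough between the error slope and the
    coverage peak). If the histogram does not start on a descending error
    slope the whole range is searched. A secondary peak is reported when the
    argmax within the window [1.8, 2.2] x primary is a local maximum.

    Raises :class:`NoCoveragePeakError` for a monotonically decreasing
    histogram with no interior peak.
    """
    freqs, counts = hist.dense()
    n = len(counts)
    if n == 1:
        return PeakReport(primary_peak=int(freqs[0]))

    start = 0  # first index eligible as the primary peak
    if counts[0] > counts[1]:
        # descending error slope: find the first local minimum
        minimum = None
        for i in range(1, n - 1):
            if counts[i - 1] > counts[i] and counts[i] <= counts[i + 1]:
                minimum = i
                break
        if minimum is None:
            raise NoCoveragePeakError(
                "histogram decreases monotonically; no coverage peak beyond the error region"
            )
        start = minimum + 1

    region = counts[start:]
    primary_idx = start + int(np.argmax(region))
    primary = int(freqs[primary_idx])
    if counts[primary_idx] == 0:
        raise NoCoveragePeakError("no non-zero counts beyond the error region")

    secondary = None
    ratio = None
    lo = int(np.ceil(1.8 * primary))
    hi = int(np.floor(2.2 * primary))
    window = (freqs >= lo) & (freqs <= hi)
    if window.any():
        w_counts = np.where(window, counts, -1)
        idx = int(np.argmax(w_counts))
        if counts[idx] > 0:
            left = counts[idx - 1] if idx > 0 else 0
            right = counts[idx + 1] if idx < n - 1 else 0
            if counts[idx] >= left and counts[idx] >= right:
                secondary = int(freqs[idx])
                ratio = secondary / primary
    return PeakReport(primary_peak=primary, secondary_peak=secondary, secondary_ratio=ratio)


def estimate_genome_size(
    hist: KmerHistogram, peak: int, f_min: int = 1, f_max: int = 10_000
) -> GenomeSizeEstimate:
    """Estimate genome size as AUC / peak over the frequency window.

    AUC is the total number of k-mer instances, ``sum(f * count(f))`` for
    ``f_min <= f <= f_max``; dividing by the coverage peak converts
    instances to base pairs of (haploid) genome.
    """
    if peak < 1:
        raise ValidationError("peak must be a frequency >= 1")
    auc = hist.auc(f_min=f_min, f_max=f_max)
    return GenomeSizeEstimate(auc=auc, peak=peak, f_min=f_min, f_max=f_max)
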