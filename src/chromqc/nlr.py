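"""Consensus NLR gene set: containment intersection, partitioning, filtering.

NLR (nucleotide-binding leucine-rich-repeat) locus predictors scan genomic
sequence for NLR motifs without using gene models, so their output mixes
real genes, pseudogenes, and fragments. Cross-referencing predictions with
an independent gene annotation separates the likely functional arsenal: a
prediction and an annotated gene form a consensus pair when the gene
interval is fully contained within the predicted NLR interval on the same
scaffold (strand ignored). When several predictions contain one gene, a
single representative is kept deterministically. Consensus sets are
partitioned by the predictor's completeness classes (complete /
complete_pseudo / partial / partial_pseudo — "pseudo-" marking a predicted
in-domain stop codon).

Also here: the missing-data filter for NB-ARC domain alignments (sequences
with more than 50% gaps/ambiguity are excluded from phylogenetic work) and
an ungapped wildcard motif scan used to detect the RPW8-like RNL motif
CFLDLGxFP in predicted proteins.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from intervaltree import IntervalTree

from .exceptions import ParseError, ValidationError

__all__ = [
    "COMPLETENESS_CLASSES",
    "RPW8_MOTIF",
    "NlrPrediction",
    "GeneModel",
    "ConsensusNlrSet",
    "AlignmentFilterResult",
    "normalize_completeness",
    "read_nlr_predictions",
    "read_gene_models",
    "consensus_intersect",
    "class_tally",
    "partition_by_completeness",
    "filter_alignment_by_missing",
    "scan_motif",
]

COMPLETENESS_CLASSES = ("complete", "complete_pseudo", "partial", "partial_pseudo")
RPW8_MOTIF = "CFLDLGxFP"


@dataclass(frozen=True)
class NlrPrediction:
    id: str
    seqid: str
    start: int  # 0-based half-open
    end: int
    strand: str
    completeness: str

    def __post_init__(self):
        if self.completeness not in COMPLETENESS_CLASSES:
            raise ValidationError(
                f"completeness must be one of {COMPLETENESS_CLASSES}, got {self.completeness!r}"
            )
        if self.end <= self.start:
            raise ValidationError(f"empty interval for NLR {self.id}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    id: str
    seqid: str
    start: int
    end: int
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ConsensusNlrSet:
    """Consensus pairs plus class counts and per-scaffold tallies.

    Class counts are over distinct NLR predictions: an NLR containing
    several genes appears in several pairs but contributes once.
    """

    pairs: list[tuple[NlrPrediction, GeneModel]]
    class_counts: dict[str, int] = field(init=False)
    per_seqid: dict[str, int] = field(init=False)

    def __post_init__(self):
        seen: dict[str, str] = {}
        for nlr, _ in self.pairs:
            seen[nlr.id] = nlr.completeness
        counts = Counter(seen.values())
        self.class_counts = {cls: counts.get(cls, 0) for cls in COMPLETENESS_CLASSES}
        self.per_seqid = dict(Counter(gene.seqid for _, gene in self.pairs))

    @property
    def n_consensus(self) -> int:
        return sum(self.class_counts.values())


@dataclass
class AlignmentFilterResult:
    kept: list[str]
    excluded: list[str]
    missing_fraction: dict[str, float]


def normalize_completeness(raw: str) -> str:
    """Map predictor output spellings ('complete pseudo-') to canonical classes."""
    cleaned = raw.strip().lower().rstrip("-").replace("-", "_").replace(" ", "_")
    if cleaned in COMPLETENESS_CLASSES:
        return cleaned
    raise ParseError(
        f"unknown completeness class {raw!r}; valid classes: {', '.join(COMPLETENESS_CLASSES)}"
    )


def read_nlr_predictions(path) -> list[NlrPrediction]:
    """Read NLR predictions from TSV: id, seqid, start, end, strand, class.

    Input coordinates are 1-based inclusive (the usual tabular convention)
    and converted to 0-based half-open. An optional header row is skipped.
    """
    predictions = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise ParseError(
                    f"expected 6 columns (id seqid start end strand class), got {len(fields)}",
                    path=path, line=lineno,
                )
            if lineno == 1 and not fields[2].isdigit():
                continue  # header
            try:
                start, end = int(fields[2]), int(fields[3])
            except ValueError:
                raise ParseError("non-integer coordinates", path=path, line=lineno)
            try:
                completeness = normalize_completeness(fields[5])
            except ParseError as exc:
                raise ParseError(str(exc), path=path, line=lineno)
            predictions.append(
                NlrPrediction(
                    id=fields[0],
                    seqid=fields[1],
                    start=start - 1,
                    end=end,
                    strand=fields[4],
                    completeness=completeness,
                )
            )
    return predictions


def read_gene_models(path, feature_type: str = "gene") -> list[GeneModel]:
    """Read ``gene`` features from a GFF3 file (1-based inclusive -> half-open)."""
    genes = []
    counter = 0
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"GFF3 record needs 9 columns, got {len(fields)}",
                                 path=path, line=lineno)
            if fields[2] != feature_type:
                continue
            attrs = dict(
                item.split("=", 1) for item in fields[8].split(";") if "=" in item
            )
            counter += 1
            gid = attrs.get("ID") or attrs.get("Name") or f"{feature_type}{counter}"
            genes.append(
                GeneModel(
                    id=gid,
                    seqid=fields[0],
                    start=int(fields[3]) - 1,
                    end=int(fields[4]),
                    strand=fields[6],
                )
            )
    return genes


def consensus_intersect(
    nlrs: list[NlrPrediction],
    genes: list[GeneModel],
    containment: str = "gene-in-nlr",
) -> ConsensusNlrSet:
    """Pair predictions and genes by 100% containment on the same scaffold.

    A pair forms when the gene interval is fully contained within the NLR
    interval (``containment='nlr-in-gene'`` flips the direction); strand is
    ignored. When several NLRs contain one gene, the representative is the
    one with the largest overlap, then the longer NLR, then the leftmost
    start, then the smaller id — a deterministic total order. One NLR may
    represent several genes (it contributes once to class counts).
    """
    if containment not in ("gene-in-nlr", "nlr-in-gene"):
        raise ValidationError("containment must be 'gene-in-nlr' or 'nlr-in-gene'")

    trees: dict[str, IntervalTree] = {}
    for nlr in nlrs:
        trees.setdefault(nlr.seqid, IntervalTree()).addi(nlr.start, nlr.end, nlr)

    pairs: list[tuple[NlrPrediction, GeneModel]] = []
    for gene in genes:
        tree = trees.get(gene.seqid)
        if tree is None:
            continue
        candidates = []
        for iv in tree.overlap(gene.start, gene.end):
            nlr = iv.data
            if containment == "gene-in-nlr":
                contained = nlr.start <= gene.start and gene.end <= nlr.end
            else:
                contained = gene.start <= nlr.start and nlr.end <= gene.end
            if contained:
                overlap = min(nlr.end, gene.end) - max(nlr.start, gene.start)
                candidates.append((overlap, nlr))
        if not candidates:
            continue
        best = min(
            candidates,
            key=lambda c: (-c[0], -c[1].length, c[1].start, c[1].id),
        )[1]
        pairs.append((best, gene))
    pairs.sort(key=lambda p: (p[1].seqid, p[1].start, p[1].id))
    return ConsensusNlrSet(pairs=pairs)


def class_tally(predictions: list[NlrPrediction]) -> dict[str, int]:
    """Completeness-class counts over a raw prediction list."""
    counts = Counter(p.completeness for p in predictions)
    return {cls: counts.get(cls, 0) for cls in COMPLETENESS_CLASSES}


def partition_by_completeness(
    consensus: ConsensusNlrSet,
) -> tuple[dict[str, int], pd.DataFrame]:
    """Class counts plus a per-scaffold tally sorted by count descending."""
    per_seqid = pd.DataFrame(
        sorted(consensus.per_seqid.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["seqid", "n_consensus_nlr"],
    )
    return dict(consensus.class_counts), per_seqid


def _as_named_sequences(source) -> list[tuple[str, str]]:
    if isinstance(source, (str, Path)):
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(source), "fasta")]
    out = []
    for item in source:
        if hasattr(item, "id") and hasattr(item, "seq"):
            out.append((item.id, str(item.seq)))
        else:
            name, seq = item
            out.append((name, str(seq)))
    return out


def filter_alignment_by_missing(
    alignment,
    threshold: float = 0.5,
    nucleotide: bool = False,
) -> AlignmentFilterResult:
    """Exclude aligned sequences with more than ``threshold`` missing data.

    Missing characters are gaps and ambiguity codes: ``- . X x ?`` (plus
    ``N``/``n`` for nucleotide alignments; N is a valid residue in protein
    alignments). The inequality is strict: a sequence at exactly the
    threshold is kept. Ragged alignments are rejected.
    """
    records = _as_named_sequences(alignment)
    if not records:
        return AlignmentFilterResult(kept=[], excluded=[], missing_fraction={})
    length = len(records[0][1])
    missing_chars = set("-.Xx?")
    if nucleotide:
        missing_chars |= {"N", "n"}
    kept, excluded, fractions = [], [], {}
    for name, seq in records:
        if len(seq) != length:
            raise ValidationError(
                f"ragged alignment: {name} has length {len(seq)}, expected {length}"
            )
        frac = sum(1 for ch in seq if ch in missing_chars) / length
        fractions[name] = frac
        (excluded if frac > threshold else kept).append(name)
    return AlignmentFilterResult(kept=kept, excluded=excluded, missing_fraction=fractions)


def scan_motif(
    proteins,
    pattern: str = RPW8_MOTIF,
    max_mismatches: int = 0,
) -> list[tuple[str, int]]:
    """Find ungapped occurrences of a wildcard motif in protein sequences.

    Lowercase ``x`` in the pattern matches any residue; other positions
    must match exactly, up to ``max_mismatches`` substitutions. Offsets are
    0-based. Returns (sequence id, offset) for every hit.
    """
    if not pattern:
        raise ValidationError("motif pattern must be non-empty")
    records = _as_named_sequences(proteins)
    fixed = [(i, ch) for i, ch in enumerate(pattern) if ch != "x"]
    plen = len(pattern)
    hits = []
    for name, seq in records:
        seq = seq.upper()
        for offset in range(len(seq) - plen + 1):
            mismatches = 0
            for i, ch in fixed:
                if seq[offset + i] != ch:
                    mismatches += 1
                    if mismatches > max_mismatches:
                        break
            if mismatches <= max_mismatches:
                hits.append((name, offset))
    return hits
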