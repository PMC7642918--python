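"""Assembly consensus error rate from per-site read-support counts.

A consensus position is called an error when the aligned short reads give
it no support at all and at least three reads agree on one alternative
allele — a deliberately conservative two-condition rule that separates
genuine consensus mistakes from ordinary alignment noise and residual
heterozygosity. The summary divides the error bases by the total assembly
bases:

    errors_per_10kb       = 10,000 * error_bases / total_bases
    consensus_quality_pct = 100 * (1 - error_bases / total_bases)

so a rate of 0.3 errors per 10,000 bases is a consensus quality of 99.997%.

Read alignment and variant calling themselves are out of scope: the module
consumes site-level support counts, either as a simple TSV or from a
VCF-like file carrying RO (reference observations) and AO (alternative
observations) fields.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

from .exceptions import ParseError, ValidationError

__all__ = [
    "VariantSite",
    "ErrorRateSummary",
    "read_variant_sites",
    "classify_error_sites",
    "summarize_error_rate",
]

MIN_ALT_SUPPORT = 3


@dataclass(frozen=True)
class VariantSite:
    """Per-site support counts; ``is_error`` is derived by classification."""

    seqid: str
    pos: int
    ref_allele: str
    alt_allele: str
    ref_support: int
    alt_support: int
    is_error: bool | None = None

    def __post_init__(self):
        if self.ref_support < 0 or self.alt_support < 0:
            raise ValidationError("support counts must be non-negative")


@dataclass
class ErrorRateSummary:
    error_bases: int
    total_bases: int
    errors_per_10kb: float = field(init=False)
    consensus_quality_pct: float = field(init=False)

    def __post_init__(self):
        if self.total_bases <= 0:
            raise ValidationError("total_bases must be positive")
        if self.error_bases > self.total_bases:
            raise ValidationError("error_bases cannot exceed total_bases")
        rate = self.error_bases / self.total_bases
        self.errors_per_10kb = 10_000 * rate
        self.consensus_quality_pct = 100 * (1 - rate)


def _max_support(text: str, path, lineno: int) -> int:
    """Parse an integer or comma-separated list (multi-allelic: take the max)."""
    try:
        values = [int(v) for v in text.split(",")]
    except ValueError:
        raise ParseError(f"non-integer support value {text!r}", path=path, line=lineno)
    if any(v < 0 for v in values):
        raise ParseError(f"negative support value in {text!r}", path=path, line=lineno)
    return max(values)


def _read_tsv(path) -> list[VariantSite]:
    sites: list[VariantSite] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise ParseError(
                    f"expected 6 columns (seqid pos ref alt ref_support alt_support), "
                    f"got {len(fields)}",
                    path=path, line=lineno,
                )
            if lineno == 1 and not fields[1].lstrip("-").isdigit():
                continue  # header row
            try:
                pos = int(fields[1])
            except ValueError:
                raise ParseError(f"non-integer position {fields[1]!r}", path=path, line=lineno)
            sites.append(
                VariantSite(
                    seqid=fields[0],
                    pos=pos,
                    ref_allele=fields[2],
                    alt_allele=fields[3],
                    ref_support=_max_support(fields[4], path, lineno),
                    alt_support=_max_support(fields[5], path, lineno),
                )
            )
    return sites


def _read_vcf(path) -> list[VariantSite]:
    """Tolerant VCF-subset reader: RO/AO taken from INFO or FORMAT/first sample."""
    sites: list[VariantSite] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ParseError(
                    f"VCF record needs >= 8 columns, got {len(fields)}", path=path, line=lineno
                )
            info = dict(
                item.split("=", 1) if "=" in item else (item, "")
                for item in fields[7].split(";")
                if item
            )
            ro = info.get("RO")
            ao = info.get("AO")
            if (ro is None or ao is None) and len(fields) >= 10:
                keys = fields[8].split(":")
                values = fields[9].split(":")
                sample = dict(zip(keys, values))
                ro = ro if ro is not None else sample.get("RO")
                ao = ao if ao is not None else sample.get("AO")
            if ro is None or ao is None:
                raise ParseError(
                    "no RO/AO support fields in INFO or FORMAT", path=path, line=lineno
                )
            alts = fields[4].split(",")
            sites.append(
                VariantSite(
                    seqid=fields[0],
                    pos=int(fields[1]) - 1,
                    ref_allele=fields[3],
                    alt_allele=alts[0],
                    ref_support=_max_support(ro, path, lineno),
                    alt_support=_max_support(ao, path, lineno),
                )
            )
    return sites


def read_variant_sites(path) -> list[VariantSite]:
    """Read per-site support counts from TSV or a minimal VCF.

    The TSV dialect has columns (seqid, pos, ref, alt, ref_support,
    alt_support), with an optional header. VCF is recognised by extension
    or a ``##fileformat=VCF`` first line; positions there are converted
    from 1-based to the internal 0-based convention. Multi-allelic support
    lists collapse to their maximum.
    """
    path = Path(path)
    is_vcf = path.suffix == ".vcf"
    if not is_vcf:
        with open(path) as handle:
            first = handle.readline()
        is_vcf = first.startswith("##fileformat=VCF")
    return _read_vcf(path) if is_vcf else _read_tsv(path)


def classify_error_sites(sites: list[VariantSite]) -> list[VariantSite]:
    """Apply the two-condition rule: no reference support AND >= 3 alt reads."""
    return [
        dataclasses.replace(
            s, is_error=(s.ref_support == 0 and s.alt_support >= MIN_ALT_SUPPORT)
        )
        for s in sites
    ]


def _error_bases(site: VariantSite, indel_mode: str) -> int:
    if indel_mode == "ref":
        return max(len(site.ref_allele), 1)
    if indel_mode == "max":
        return max(len(site.ref_allele), len(site.alt_allele), 1)
    raise ValidationError(f"indel_mode must be 'ref' or 'max', got {indel_mode!r}")


def summarize_error_rate(
    sites: list[VariantSite], total_bases: int, indel_mode: str = "ref"
) -> ErrorRateSummary:
    """Total error bases over total assembly bases, as rate and quality.

    Sites are classified on the fly if not already. Each error site
    contributes the reference bases it affects (minimum 1, so a pure
    insertion still counts one base); ``indel_mode='max'`` counts the longer
    of the two alleles instead.
    """
    if total_bases <= 0:
        raise ValidationError("total_bases must be positive")
    classified = [
        s if s.is_error is not None else classify_error_sites([s])[0] for s in sites
    ]
    error_bases = sum(_error_bases(s, indel_mode) for s in classified if s.is_error)
    return ErrorRateSummary(error_bases=error_bases, total_bases=total_bases)
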