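"""Small FASTA helpers used by several modules.

Sequences are handled as plain uppercase Python strings keyed by record id;
Biopython does the actual parsing and formatting.
"""

from __future__ import annotations

import os
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` dict (uppercased)."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(records: dict[str, str], path, wrap: int = 80) -> None:
    """Write ``{id: sequence}`` to FASTA, wrapped at ``wrap`` columns."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=wrap)
        writer.write_file(
            SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
        )


def as_sequences(sequences) -> dict[str, str]:
    """Coerce a path, mapping, or iterable of sequences to ``{id: seq}``.

    A string or Path naming an existing file is read as FASTA; a bare string
    is treated as a single anonymous sequence.
    """
    if isinstance(sequences, (str, Path)):
        if os.path.exists(sequences):
            return read_fasta(sequences)
        return {"seq": str(sequences).upper()}
    if isinstance(sequences, dict):
        return {k: v.upper() for k, v in sequences.items()}
    return {f"seq{i}": s.upper() for i, s in enumerate(sequences)}
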