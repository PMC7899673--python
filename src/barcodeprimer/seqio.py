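"""FASTA reading/writing and alignment-aware validation.

Parsing is delegated to Bio.SeqIO; this layer adds the checks the workflow
needs (unique ids, IUPAC-only residues, equal column counts for alignments)
and reports offending line numbers.  External coordinates are 1-based
inclusive throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .iupac import InvalidSequenceError, validate_sequence

__all__ = [
    "SequenceRecord",
    "AlignmentBlock",
    "FastaError",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "degap",
]


class FastaError(ValueError):
    """Malformed or invalid FASTA input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One named nucleotide sequence (IUPAC codes, optionally gapped)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise FastaError("record id must be non-empty")
        if not self.sequence:
            raise FastaError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentBlock:
    """A multiple sequence alignment: >=2 equal-length gapped records."""

    records: tuple[SequenceRecord, ...]
    length: int = field(init=False)

    def __post_init__(self):
        if len(self.records) < 2:
            raise FastaError("an alignment needs at least 2 records")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            bad = next(r for r in self.records if len(r) != len(self.records[0]))
            raise FastaError(
                f"ragged alignment: record {bad.id!r} has length {len(bad)}, "
                f"expected {len(self.records[0])}"
            )
        object.__setattr__(self, "length", len(self.records[0]))

    @property
    def n_rows(self) -> int:
        return len(self.records)

    def column(self, col: int) -> list[str]:
        """Residues of 1-based column ``col``, top to bottom."""
        if not 1 <= col <= self.length:
            raise IndexError(f"column {col} outside 1..{self.length}")
        return [r.sequence[col - 1] for r in self.records]


def _header_line_numbers(path: Path) -> dict[str, list[int]]:
    """Map record id -> line numbers of its '>' headers (for messages)."""
    out: dict[str, list[int]] = {}
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                rid = line[1:].split(None, 1)[0].strip() if len(line) > 1 else ""
                out.setdefault(rid, []).append(lineno)
    return out


def read_fasta(path: str | Path, *, allow_gaps: bool = False) -> list[SequenceRecord]:
    """Parse a FASTA file into validated records, case-folded to upper.

    Duplicate ids, empty records and non-IUPAC characters are rejected with
    the line number of the offending record's header.  CRLF and LF files
    parse identically; '-' is legal only with ``allow_gaps``.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    lines = _header_line_numbers(path)
    for rec in SeqIO.parse(str(path), "fasta"):
        n_seen = seen.get(rec.id, 0)
        occurrences = lines.get(rec.id, [])
        lineno = occurrences[n_seen] if n_seen < len(occurrences) else "?"
        where = f"line {lineno}"
        if not rec.id:
            raise FastaError(f"record without an id ({path}, {where})")
        if n_seen:
            raise FastaError(f"duplicate record id {rec.id!r} ({path}, {where})")
        seen[rec.id] = n_seen + 1
        raw = str(rec.seq)
        if not raw:
            raise FastaError(f"record {rec.id!r} is empty ({path}, {where})")
        try:
            seq = validate_sequence(raw, allow_gaps=allow_gaps, context=f"record {rec.id!r}")
        except InvalidSequenceError as exc:
            raise FastaError(f"{exc} ({path}, {where})") from exc
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, sequence=seq, description=desc))
    if not records:
        raise FastaError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, *, width: int = 70) -> None:
    """Write records as wrapped FASTA; round-trips with read_fasta."""
    bio = [
        _BioRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_alignment(path: str | Path) -> AlignmentBlock:
    """Read a FASTA alignment (equal-length, gap-tolerant, >=2 records)."""
    return AlignmentBlock(tuple(read_fasta(path, allow_gaps=True)))


def degap(record: SequenceRecord) -> tuple[SequenceRecord, list[int]]:
    """Strip gaps, returning the ungapped record and a residue->column map.

    ``colmap[i]`` is the 1-based alignment column of ungapped residue i+1, so
    positions found on the ungapped template can be re-expressed in the
    alignment frame.
    """
    seq_chars: list[str] = []
    colmap: list[int] = []
    for col, ch in enumerate(record.sequence, start=1):
        if ch != "-":
            seq_chars.append(ch)
            colmap.append(col)
    if not seq_chars:
        raise FastaError(f"record {record.id!r} is all gaps")
    return (
        SequenceRecord(id=record.id, sequence="".join(seq_chars), description=record.description),
        colmap,
    )
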