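"""Sequence records, alphabets, and FASTA input/output.

Sequences are plain upper-case strings over a declared alphabet (DNA or
protein).  Two control characters below every printable symbol are reserved
as index sentinels and may never appear in residues.  Reversal here is plain
character reversal — the backward-extension machinery works on reversed
strings — and is deliberately *not* reverse complementation.
"""
from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError

#: Sentinel characters reserved by the generalized index; smaller than every
#: printable symbol, with SENTINEL_1 < SENTINEL_2.
SENTINEL_1 = "\x01"
SENTINEL_2 = "\x02"

_DNA_SYMBOLS = "ACGTN"
_DNA_CORE = "ACGT"
_PROTEIN_CORE = "ACDEFGHIKLMNPQRSTVWY"
_PROTEIN_SYMBOLS = _PROTEIN_CORE + "XBZUO"

#: Suffix toggled on a record name by :func:`reverse_residues`.
REVERSAL_MARKER = "_rev"


@dataclass(frozen=True)
class Alphabet:
    """An ordered residue alphabet.

    Parameters
    ----------
    symbols
        Every symbol a residue string may contain (ambiguity codes included;
        they match only themselves).
    kind
        ``"dna"``, ``"protein"``, or ``"auto"`` (resolved at read time).
    core
        The unambiguous symbols used by the synthetic-sequence generators.
    """

    symbols: str
    kind: str
    core: str

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValidationError("alphabet symbols must be distinct")
        for s in self.symbols:
            if s in (SENTINEL_1, SENTINEL_2) or not s.isprintable():
                raise ValidationError(
                    "alphabet symbols must be printable and must not include "
                    "the reserved sentinel characters"
                )

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols


DNA = Alphabet(_DNA_SYMBOLS, "dna", _DNA_CORE)
PROTEIN = Alphabet(_PROTEIN_SYMBOLS, "protein", _PROTEIN_CORE)
#: Placeholder resolved against file content by :func:`read_fasta`.
AUTO = Alphabet(_PROTEIN_SYMBOLS, "auto", _PROTEIN_CORE)


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence.

    ``name`` is the FASTA header token up to the first whitespace and must be
    unique within any loaded set (names key distance matrices and PHYLIP
    rows).  ``residues`` is non-empty and upper-case.
    """

    name: str
    residues: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("sequence name must be non-empty")
        if not self.residues:
            raise ValidationError(f"sequence {self.name!r} has no residues")

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


def infer_alphabet(residues: Iterable[str]) -> Alphabet:
    """Infer DNA vs protein from content: anything outside {A,C,G,T,N} is protein."""
    dna = set(_DNA_SYMBOLS)
    for chunk in residues:
        if not set(chunk) <= dna:
            return PROTEIN
    return DNA


def validate_record(record: SequenceRecord, alphabet: Alphabet) -> None:
    """Raise :class:`ValidationError` naming record and 1-based position of the
    first residue outside *alphabet*."""
    allowed = set(alphabet.symbols)
    for pos, ch in enumerate(record.residues, start=1):
        if ch not in allowed:
            raise ValidationError(
                f"record {record.name!r}: residue {ch!r} at position {pos} "
                f"is not in the {alphabet.kind} alphabet"
            )


def read_fasta(path: str | Path, alphabet: Alphabet = AUTO) -> list[SequenceRecord]:
    """Read a multi-FASTA file into validated records.

    Wrapped lines are joined, CR/LF tolerated, residues upper-cased, and the
    record name is the header token up to the first whitespace.  An empty file
    (zero records) is a :class:`FormatError`; residues outside *alphabet* or
    duplicate names are :class:`ValidationError`.
    """
    path = Path(path)
    with open(path, "r", newline=None) as handle:
        raw = list(SeqIO.parse(handle, "fasta"))
    if not raw:
        raise FormatError(f"{path}: no FASTA records found")
    records = [SequenceRecord(r.id, str(r.seq).upper()) for r in raw]
    if alphabet.kind == "auto":
        alphabet = infer_alphabet(r.residues for r in records)
    seen: set[str] = set()
    for rec in records:
        if rec.name in seen:
            raise ValidationError(f"{path}: duplicate sequence name {rec.name!r}")
        seen.add(rec.name)
        validate_record(rec, alphabet)
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as wrapped multi-FASTA; read_fasta(write_fasta(x)) == x."""
    bio = [SeqRecord(Seq(r.residues), id=r.name, description="") for r in records]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(bio)


def reverse_residues(record: SequenceRecord) -> SequenceRecord:
    """Character-wise reversal (no complementation).

    The name gets a reversal marker toggled, so the operation is an involution
    on whole records.
    """
    if record.name.endswith(REVERSAL_MARKER):
        name = record.name[: -len(REVERSAL_MARKER)]
    else:
        name = record.name + REVERSAL_MARKER
    return SequenceRecord(name, record.residues[::-1])
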