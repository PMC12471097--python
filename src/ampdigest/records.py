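"""Peptide sequence records, validation, FASTA I/O and the reference dataset.

The reference dataset is a fixed panel of 57 plant antimicrobial
oligopeptides with reported anticancer activity, identified by their
Antimicrobial Peptide Database accessions (``AP…``).  It ships with the
package as a TSV asset and is content-hashed so that any accidental edit
is caught by the test suite.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass
from importlib import resources
from typing import IO, Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical one-letter amino-acid codes.  Ambiguity codes
#: (B, J, O, U, X, Z) are rejected outright: the source sequences contain
#: none, and guessing a residue would silently corrupt every downstream
#: descriptor.
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

_FASTA_WRAP = 60


class SequenceError(ValueError):
    """A sequence failed validation (empty or non-canonical residue)."""


@dataclass(frozen=True)
class PeptideRecord:
    """One source oligopeptide.

    Attributes
    ----------
    apd_id:
        Accession string, e.g. ``"AP00236"``.  Unique within a dataset.
    name:
        Peptide name (free text; may be empty).
    source:
        Organism / material of origin (free text; may be empty).
    sequence:
        Uppercase sequence over the 20 canonical residues.
    """

    apd_id: str
    name: str
    source: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_sequence(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


def validate_sequence(raw: str) -> str:
    """Normalize *raw* to an uppercase canonical sequence or raise.

    Whitespace is stripped; the result must be non-empty and contain only
    the 20 standard residues.  Error messages report 1-based positions.
    """
    seq = raw.strip().upper()
    if not seq:
        raise SequenceError("empty sequence")
    for i, ch in enumerate(seq):
        if ch not in CANONICAL_RESIDUES:
            raise SequenceError(
                f"non-canonical residue {ch!r} at position {i + 1}"
            )
    return seq


def _record_from_seqrecord(rec: SeqRecord) -> PeptideRecord:
    # Header dialect ">apd_id|name|source"; missing parts tolerated.
    parts = [p.strip() for p in rec.description.split("|")]
    parts += [""] * (3 - len(parts))
    apd_id, name, source = parts[0], parts[1], parts[2]
    if not apd_id:
        raise SequenceError("FASTA record with empty identifier")
    if len(rec.seq) == 0:
        raise SequenceError(f"record {apd_id!r} has no sequence")
    return PeptideRecord(apd_id, name, source, str(rec.seq))


def parse_fasta(stream: IO[str] | str) -> list[PeptideRecord]:
    """Read peptide records from FASTA (path or open text handle).

    Headers follow ``>apd_id|name|source``; a plain ``>apd_id`` is accepted
    with empty name/source.  Sequences may be single-line or wrapped.
    Raises :class:`SequenceError` on an empty file, a record without
    sequence, or any non-canonical residue.
    """
    records = [_record_from_seqrecord(r) for r in SeqIO.parse(stream, "fasta")]
    if not records:
        raise SequenceError("no FASTA records found")
    seen: set[str] = set()
    for r in records:
        if r.apd_id in seen:
            raise SequenceError(f"duplicate accession {r.apd_id!r}")
        seen.add(r.apd_id)
    return records


def write_fasta(records: Iterable[PeptideRecord], stream: IO[str] | None = None) -> str:
    """Write records as FASTA (60-column wrap); returns the text.

    Round-trips with :func:`parse_fasta` for any valid record list.
    """
    out = stream if stream is not None else io.StringIO()
    seqrecords = []
    for r in records:
        header = r.apd_id
        if r.name or r.source:
            header = f"{r.apd_id}|{r.name}|{r.source}"
        seqrecords.append(SeqRecord(Seq(r.sequence), id=header, description=""))
    writer = SeqIO.FastaIO.FastaWriter(out, wrap=_FASTA_WRAP)
    writer.write_file(seqrecords)
    return out.getvalue() if stream is None else ""


def _reference_text() -> str:
    return (
        resources.files("ampdigest.data")
        .joinpath("reference_peptides.tsv")
        .read_text(encoding="utf-8")
    )


def load_reference_dataset() -> list[PeptideRecord]:
    """Return the built-in 57-record oligopeptide panel, in table order."""
    records = []
    lines = _reference_text().splitlines()
    for line in lines[1:]:  # skip header
        if not line.strip():
            continue
        _, apd_id, name, source, sequence = line.split("\t")
        records.append(PeptideRecord(apd_id, name, source, sequence))
    return records


def reference_checksum() -> str:
    """SHA-256 over the canonical ``id:sequence`` serialization of the panel."""
    payload = "\n".join(
        f"{r.apd_id}:{r.sequence}" for r in load_reference_dataset()
    )
    return hashlib.sha256(payload.encode("ascii")).hexdigest()
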