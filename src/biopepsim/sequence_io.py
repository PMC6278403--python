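"""Protein sequence records and FASTA input/output.

Coordinate conventions used throughout the package: internal coordinates are
0-based half-open; everything surfaced in reports is 1-based inclusive.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from ._util import AMINO_ACIDS, AMBIGUOUS_CODES

logger = logging.getLogger(__name__)

PathOrStream = Union[str, Path, IO[str]]


class FastaParseError(ValueError):
    """Malformed FASTA text (bad header / stray data)."""


class SequenceValidationError(ValueError):
    """A sequence contains characters outside the canonical alphabet."""

    def __init__(self, record_id: str, position: int, character: str):
        self.record_id = record_id
        self.position = position  # 1-based
        self.character = character
        super().__init__(
            f"invalid residue {character!r} at position {position} "
            f"in record {record_id!r}"
        )


@dataclass(frozen=True)
class ProteinRecord:
    """A named, validated amino-acid sequence.

    ``sequence`` is uppercase over the 20 canonical one-letter codes
    (permissive mode additionally tolerates B, Z, X, U, O, which never
    match reference peptides or cleavage rules).
    """

    id: str
    sequence: str
    description: str = ""
    permissive: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        if self.sequence != self.sequence.upper():
            logger.warning("record %r: lowercase residues upcased", self.id)
            object.__setattr__(self, "sequence", self.sequence.upper())
        allowed = AMINO_ACIDS | AMBIGUOUS_CODES if self.permissive else AMINO_ACIDS
        for i, ch in enumerate(self.sequence):
            if ch not in allowed:
                raise SequenceValidationError(self.id, i + 1, ch)

    @property
    def n_residues(self) -> int:
        """Residue count N of the chain."""
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    def subsequence(self, start: int, end: int) -> str:
        """Residues at 1-based inclusive positions ``start..end``."""
        if not (1 <= start <= end <= len(self.sequence)):
            raise IndexError(f"positions {start}..{end} outside 1..{len(self.sequence)}")
        return self.sequence[start - 1 : end]


def _open_maybe(path_or_stream: PathOrStream, mode: str):
    if isinstance(path_or_stream, (str, Path)):
        return open(path_or_stream, mode), True
    return path_or_stream, False


def read_fasta(path_or_stream: PathOrStream, permissive: bool = False) -> list[ProteinRecord]:
    """Read zero or more protein records from FASTA text.

    The header is split at the first whitespace into id and description.
    Raises :class:`FastaParseError` on malformed headers and
    :class:`SequenceValidationError` on disallowed residues.
    """
    handle, close = _open_maybe(path_or_stream, "r")
    try:
        text = handle.read()
    finally:
        if close:
            handle.close()

    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        bad_line = text.splitlines()[0]
        raise FastaParseError(f"FASTA must start with '>': first line {bad_line!r}")

    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if not rec.id:
            raise FastaParseError("empty FASTA header (line '>')")
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        records.append(
            ProteinRecord(id=rec.id, sequence=str(rec.seq), description=desc,
                          permissive=permissive)
        )
    return records


def bundled_vitellogenin_like() -> ProteinRecord:
    """The bundled 615-residue vitellogenin-like fixture protein.

    A deterministic synthetic stand-in with the residue count (N = 615) of
    the study protein it emulates; used by the end-to-end regression tests
    and the example pipeline.
    """
    from importlib.resources import files

    data = files("biopepsim.data").joinpath("vitellogenin_like.fasta")
    with data.open("r") as handle:
        (record,) = read_fasta(handle)
    return record


def write_fasta(records: Iterable[ProteinRecord], path_or_stream: PathOrStream,
                line_width: int = 60) -> None:
    """Write records as wrapped FASTA; read_fasta round-trips ids and sequences."""
    handle, close = _open_maybe(path_or_stream, "w")
    try:
        writer = FastaWriter(handle, wrap=line_width)
        writer.write_file(
            SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
            for r in records
        )
    finally:
        if close:
            handle.close()
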