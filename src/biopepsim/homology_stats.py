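"""Identities / positives / gaps statistics on a given pairwise alignment.

The module consumes an existing alignment (two equal-length gapped strings);
producing the alignment is out of scope.  Percentages are rounded half away
from zero to the nearest integer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Union

from Bio.Align import substitution_matrices

from ._util import AMINO_ACIDS, round_half_away

GAP = "-"


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two equal-length aligned strings over the residue alphabet plus '-'."""

    aligned_x: str
    aligned_y: str

    def __post_init__(self) -> None:
        if len(self.aligned_x) != len(self.aligned_y):
            raise ValueError(
                f"aligned rows differ in length: {len(self.aligned_x)} vs "
                f"{len(self.aligned_y)}"
            )
        if not self.aligned_x:
            raise ValueError("alignment is empty")
        alphabet = AMINO_ACIDS | {GAP}
        for name, row in (("x", self.aligned_x), ("y", self.aligned_y)):
            for i, ch in enumerate(row):
                if ch not in alphabet:
                    raise ValueError(
                        f"invalid character {ch!r} at column {i + 1} of row {name}"
                    )
        for i, (a, b) in enumerate(zip(self.aligned_x, self.aligned_y)):
            if a == GAP and b == GAP:
                raise ValueError(f"column {i + 1} is gapped in both rows")

    def __len__(self) -> int:
        return len(self.aligned_x)


@dataclass(frozen=True)
class AlignmentStats:
    """Column counts over an alignment of length L, plus integer percentages."""

    length: int
    identities: int
    positives: int
    gaps: int

    @property
    def identity_pct(self) -> int:
        return int(round_half_away(100 * self.identities / self.length))

    @property
    def positives_pct(self) -> int:
        return int(round_half_away(100 * self.positives / self.length))

    @property
    def gaps_pct(self) -> int:
        return int(round_half_away(100 * self.gaps / self.length))


def alignment_stats(alignment: PairwiseAlignment,
                    matrix: str = "BLOSUM62") -> AlignmentStats:
    """Count identity, positive and gap columns of a pairwise alignment.

    A column is an identity when both residues are equal and ungapped, a
    positive when its substitution score is > 0 (identities included), and
    a gap when either row holds '-'.
    """
    scores = substitution_matrices.load(matrix)
    identities = positives = gaps = 0
    for a, b in zip(alignment.aligned_x, alignment.aligned_y):
        if a == GAP or b == GAP:
            gaps += 1
            continue
        if a == b:
            identities += 1
        if scores[a, b] > 0:
            positives += 1
    return AlignmentStats(
        length=len(alignment),
        identities=identities,
        positives=positives,
        gaps=gaps,
    )


def read_aligned_fasta(path_or_stream: Union[str, Path, IO[str]]) -> PairwiseAlignment:
    """Read a 2-record aligned FASTA into a PairwiseAlignment."""
    text = (Path(path_or_stream).read_text()
            if isinstance(path_or_stream, (str, Path)) else path_or_stream.read())
    rows: list[str] = []
    current: list[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            if current:
                rows.append("".join(current))
                current = []
        elif line.strip():
            current.append(line.strip())
    if current:
        rows.append("".join(current))
    if len(rows) != 2:
        raise ValueError(f"aligned FASTA must contain exactly 2 records, got {len(rows)}")
    return PairwiseAlignment(aligned_x=rows[0].upper(), aligned_y=rows[1].upper())
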