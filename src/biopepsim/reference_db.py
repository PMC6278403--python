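"""Reference sets of bioactive peptides and the activity vocabulary.

A :class:`ReferenceSet` is the local, explicit stand-in for an online
bioactive-peptide database: reproducibility is anchored to the concrete
table that was loaded, recorded in ``version_tag``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Union

from ._util import AMINO_ACIDS

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("sequence", "activity", "ref_id", "source")

# Canonical activity labels and case-insensitive aliases.  The vocabulary is
# open: unknown labels are kept verbatim (after whitespace normalization).
_ALIASES = {
    "dpp-iv inhibitor": "DPP-IV inhibitor",
    "dpp iv inhibitor": "DPP-IV inhibitor",
    "dppiv inhibitor": "DPP-IV inhibitor",
    "dpp-iv inhibitory": "DPP-IV inhibitor",
    "dipeptidyl peptidase-iv inhibitor": "DPP-IV inhibitor",
    "dipeptidyl peptidase iv inhibitor": "DPP-IV inhibitor",
    "ace inhibitor": "ACE inhibitor",
    "ace-i inhibitor": "ACE inhibitor",
    "ace inhibitory": "ACE inhibitor",
    "ace-i inhibitory": "ACE inhibitor",
    "angiotensin-i converting enzyme inhibitor": "ACE inhibitor",
    "antioxidative": "antioxidative",
    "antioxidant": "antioxidative",
    "antihypertensive": "antihypertensive",
    "hypotensive": "hypotensive",
}


class SchemaError(ValueError):
    """Reference table is missing a required column."""


def normalize_activity(label: str) -> str:
    """Map an activity spelling to its canonical form."""
    cleaned = " ".join(label.split())
    if not cleaned:
        raise ValueError("activity label must be non-empty")
    return _ALIASES.get(cleaned.lower(), cleaned)


@dataclass(frozen=True)
class BioactivePeptide:
    """A reference peptide fragment with one activity label."""

    sequence: str
    activity: str
    ref_id: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        for i, ch in enumerate(self.sequence):
            if ch not in AMINO_ACIDS:
                raise ValueError(
                    f"invalid residue {ch!r} at position {i + 1} in "
                    f"reference peptide {self.sequence!r}"
                )
        object.__setattr__(self, "activity", normalize_activity(self.activity))


@dataclass
class ReferenceSet:
    """A collection of reference peptides plus provenance."""

    entries: list[BioactivePeptide]
    version_tag: str = ""
    _by_activity: dict[str, list[BioactivePeptide]] = field(
        init=False, repr=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        unique: list[BioactivePeptide] = []
        for entry in self.entries:
            key = (entry.sequence, entry.activity)
            if key in seen:
                logger.warning("duplicate reference entry %s collapsed", key)
                continue
            seen.add(key)
            unique.append(entry)
        self.entries = unique
        for entry in unique:
            self._by_activity.setdefault(entry.activity, []).append(entry)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def activities(self) -> list[str]:
        """Canonical activity labels present, sorted."""
        return sorted(self._by_activity)

    def by_activity(self, activity: str) -> list[BioactivePeptide]:
        return list(self._by_activity.get(normalize_activity(activity), []))

    @property
    def peptide_sequences(self) -> set[str]:
        return {e.sequence for e in self.entries}


def load_reference_table(
    path: Union[str, Path, IO[str]], format: str = "tsv", version_tag: str | None = None
) -> ReferenceSet:
    """Load a delimited reference table (columns sequence/activity/ref_id/source).

    Duplicate (sequence, activity) rows are collapsed with a logged warning.
    """
    delim = {"tsv": "\t", "csv": ","}.get(format)
    if delim is None:
        raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'csv')")
    if isinstance(path, (str, Path)):
        handle = open(path, newline="")
        close = True
        tag = version_tag if version_tag is not None else str(path)
    else:
        handle, close = path, False
        tag = version_tag or "<stream>"
    try:
        reader = csv.DictReader(handle, delimiter=delim)
        header = reader.fieldnames or []
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"reference table missing column(s): {', '.join(missing)}")
        entries = []
        for lineno, row in enumerate(reader, start=2):
            try:
                entries.append(
                    BioactivePeptide(
                        sequence=(row["sequence"] or "").strip(),
                        activity=(row["activity"] or "").strip(),
                        ref_id=(row["ref_id"] or "").strip(),
                        source=(row["source"] or "").strip(),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"row {lineno}: {exc}") from exc
    finally:
        if close:
            handle.close()
    return ReferenceSet(entries=entries, version_tag=tag)


def save_reference_table(
    refset: ReferenceSet, path: Union[str, Path, IO[str]], format: str = "tsv"
) -> None:
    delim = {"tsv": "\t", "csv": ","}[format]
    handle, close = (open(path, "w", newline=""), True) if isinstance(path, (str, Path)) else (path, False)
    try:
        writer = csv.writer(handle, delimiter=delim, lineterminator="\n")
        writer.writerow(REQUIRED_COLUMNS)
        for e in refset.entries:
            writer.writerow([e.sequence, e.activity, e.ref_id, e.source])
    finally:
        if close:
            handle.close()


def builtin_fixture_set() -> ReferenceSet:
    """The curated reference fixture shipped with the package.

    A small literature-derived set of short peptides (mostly di/tripeptides)
    across DPP-IV-inhibitory, ACE-inhibitory, antioxidative and other
    activities.  It documents its own labels; it is not a snapshot of any
    online database.
    """
    from importlib.resources import files

    data = files("biopepsim.data").joinpath("reference_peptides.tsv")
    with data.open("r") as handle:
        return load_reference_table(handle, format="tsv",
                                    version_tag="biopepsim-builtin-fixture-v1")


def entries_from_pairs(pairs: Iterable[tuple[str, str]]) -> ReferenceSet:
    """Convenience: build a ReferenceSet from (sequence, activity) pairs."""
    return ReferenceSet(
        entries=[BioactivePeptide(sequence=s, activity=a) for s, a in pairs],
        version_tag="<inline>",
    )
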