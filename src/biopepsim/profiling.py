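"""Occurrence profiling of reference peptides within intact proteins.

Every occurrence position counts, with multiplicity and overlap, and a
peptide carrying k activity labels contributes one occurrence to each of
the k activities at every position.  The frequency-of-occurrence statistic
is A = a/N, with a the per-activity occurrence count and N the residue
count of the protein chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._util import round_half_away
from .reference_db import BioactivePeptide, ReferenceSet, normalize_activity
from .sequence_io import ProteinRecord


@dataclass(frozen=True)
class Occurrence:
    """One match of a reference peptide, at 1-based inclusive positions."""

    peptide: BioactivePeptide
    start: int
    end: int


@dataclass
class ActivityProfile:
    """Per-activity occurrence lists, counts a, and statistic A for one protein."""

    protein_id: str
    n_residues: int
    occurrences: dict[str, list[Occurrence]] = field(default_factory=dict)

    def count(self, activity: str) -> int:
        return len(self.occurrences.get(normalize_activity(activity), []))

    def frequency(self, activity: str) -> float:
        """A = a/N, full precision."""
        return frequency_of_occurrence(self.count(activity), self.n_residues)

    @property
    def activities(self) -> list[str]:
        return sorted(self.occurrences)


def frequency_of_occurrence(a: int, n: int) -> float:
    """The statistic A = a/N.

    Rounding to 3 decimals (half away from zero) is a presentation concern;
    see :func:`format_frequency`.
    """
    if n < 1:
        raise ValueError(f"N must be >= 1, got {n}")
    if a < 0:
        raise ValueError(f"a must be >= 0, got {a}")
    return a / n


def format_frequency(value: float) -> str:
    """Render A to 3 decimals, halves away from zero."""
    return f"{round_half_away(value, 3):.3f}"


def find_occurrences(protein: ProteinRecord, refset: ReferenceSet) -> ActivityProfile:
    """Locate every occurrence of every reference peptide in ``protein``.

    Overlapping matches and repeated matches of the same peptide all count;
    activities present in the reference set but absent from the protein are
    reported with empty occurrence lists (count 0).
    """
    if len(refset) == 0:
        raise ValueError("reference set is empty")
    profile = ActivityProfile(protein_id=protein.id, n_residues=protein.n_residues)
    for activity in refset.activities:
        profile.occurrences[activity] = []
    seq = protein.sequence
    for entry in refset:
        hits = profile.occurrences[entry.activity]
        start = seq.find(entry.sequence)
        while start != -1:
            hits.append(Occurrence(peptide=entry, start=start + 1,
                                   end=start + len(entry.sequence)))
            start = seq.find(entry.sequence, start + 1)
    for hits in profile.occurrences.values():
        hits.sort(key=lambda o: (o.start, o.end, o.peptide.sequence))
    return profile


OTHER_COLUMN = "other activities"


def profile_report(
    profiles: list[ActivityProfile],
    top_activities: list[str] | None = None,
) -> pd.DataFrame:
    """Tabulate profiles: one row per protein, one column per requested activity.

    Each activity cell is rendered "a (A)" with A to 3 decimals; remaining
    activities are pooled into an aggregate count column.
    """
    if not profiles:
        raise ValueError("at least one profile is required")
    known = sorted({act for p in profiles for act in p.activities})
    if top_activities is None:
        requested = known
    else:
        requested = [normalize_activity(a) for a in top_activities]
        unknown = [a for a in requested if a not in known]
        if unknown:
            raise ValueError(
                f"unknown activity label(s) {unknown}; known labels: {known}"
            )
    rows = []
    for p in profiles:
        row: dict[str, object] = {"protein": p.protein_id, "N": p.n_residues}
        for act in requested:
            row[act] = f"{p.count(act)} ({format_frequency(p.frequency(act))})"
        row[OTHER_COLUMN] = sum(
            p.count(act) for act in p.activities if act not in requested
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=["protein", "N", *requested, OTHER_COLUMN])
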