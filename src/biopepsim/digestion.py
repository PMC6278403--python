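"""In silico proteolysis: declarative cleavage rules, digestion, fragment matching.

A cleavage rule is a set of clauses over the four-residue window
P2-P1-P1'-P2' around a peptide bond (the bond is cut between P1 and P1'),
plus exception clauses of the same shape that veto a match.  Window
positions beyond the sequence termini satisfy unconstrained positions and
fail constrained ones.  Combined digestion by up to three proteases is
simultaneous: the union of all cut sites.

The bundled rulebook encodes a documented, PeptideCutter-style
simplification of each enzyme's specificity restricted to the P2..P2'
window; it is a reproducible local convention, not a reconstruction of any
web tool's internal rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence, Union

import yaml

from ._util import AMINO_ACIDS
from .reference_db import BioactivePeptide, ReferenceSet, normalize_activity
from .sequence_io import ProteinRecord

MAX_ENZYMES = 3

WINDOW_POSITIONS = ("p2", "p1", "p1prime", "p2prime")
# Offsets of window positions relative to bond index i (1-based bond between
# residues i and i+1), as 0-based sequence indices.
_OFFSETS = {"p2": -2, "p1": -1, "p1prime": 0, "p2prime": 1}


@dataclass(frozen=True)
class SiteClause:
    """Allowed residue sets per window position; absent position = any residue."""

    p2: frozenset[str] | None = None
    p1: frozenset[str] | None = None
    p1prime: frozenset[str] | None = None
    p2prime: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for pos in WINDOW_POSITIONS:
            residues = getattr(self, pos)
            if residues is None:
                continue
            if not residues:
                raise ValueError(f"clause position {pos} has an empty residue set")
            bad = set(residues) - AMINO_ACIDS
            if bad:
                raise ValueError(f"clause position {pos} has invalid residues {sorted(bad)}")

    def matches(self, sequence: str, bond: int) -> bool:
        """True iff the window around 1-based bond index satisfies the clause."""
        for pos in WINDOW_POSITIONS:
            allowed = getattr(self, pos)
            if allowed is None:
                continue
            idx = bond + _OFFSETS[pos]
            if idx < 0 or idx >= len(sequence):
                return False  # constrained position beyond a terminus
            if sequence[idx] not in allowed:
                return False
        return True

    @classmethod
    def from_dict(cls, spec: dict) -> "SiteClause":
        unknown = set(spec) - set(WINDOW_POSITIONS)
        if unknown:
            raise ValueError(f"unknown clause position(s) {sorted(unknown)}")
        kwargs = {}
        for pos in WINDOW_POSITIONS:
            if pos in spec:
                residues = spec[pos]
                if isinstance(residues, str):
                    residues = list(residues)
                kwargs[pos] = frozenset(residues)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            pos: sorted(getattr(self, pos))
            for pos in WINDOW_POSITIONS
            if getattr(self, pos) is not None
        }


@dataclass(frozen=True)
class CleavageRule:
    """Site clauses (any may fire) and exception clauses (any vetoes)."""

    clauses: tuple[SiteClause, ...]
    exceptions: tuple[SiteClause, ...] = ()

    def __post_init__(self) -> None:
        if not self.clauses:
            raise ValueError("a cleavage rule needs at least one clause")

    def cuts_at(self, sequence: str, bond: int) -> bool:
        if not any(c.matches(sequence, bond) for c in self.clauses):
            return False
        return not any(e.matches(sequence, bond) for e in self.exceptions)


@dataclass(frozen=True)
class Protease:
    """A named enzyme with a cleavage rule; ec_number may be '-' if unassigned."""

    name: str
    rule: CleavageRule
    ec_number: str = "-"


@dataclass(frozen=True)
class Fragment:
    """A contiguous sub-peptide of a parent protein, 1-based inclusive coords.

    ``missed`` is the number of internal cleavage sites left uncut (0 for
    fragments of the covering digest; >0 flags a non-covering partial).
    """

    parent_id: str
    start: int
    end: int
    sequence: str
    missed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad fragment coordinates {self.start}..{self.end}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("fragment sequence length disagrees with coordinates")


@dataclass
class DigestResult:
    """Fragments released by a (co-)digestion, with bioactive matches."""

    protein_id: str
    protease_names: tuple[str, ...]
    fragments: list[Fragment]                       # covering digest, in order
    partial_fragments: list[Fragment] = field(default_factory=list)
    matches: dict[str, list[tuple[Fragment, BioactivePeptide]]] = field(default_factory=dict)

    def match_count(self, activity: str) -> int:
        return len(self.matches.get(normalize_activity(activity), []))

    @property
    def all_fragments(self) -> list[Fragment]:
        return self.fragments + self.partial_fragments


def cut_sites(protein: ProteinRecord, protease: Protease) -> list[int]:
    """1-based bond indices cut by the protease (bond i joins residues i, i+1)."""
    seq = protein.sequence
    return [bond for bond in range(1, len(seq)) if protease.rule.cuts_at(seq, bond)]


def digest(
    protein: ProteinRecord,
    proteases: Sequence[Protease],
    missed_cleavages: int = 0,
) -> DigestResult:
    """Simultaneously co-digest with 1..3 proteases (union of all cut sites).

    With ``missed_cleavages = m > 0``, every union of up to m+1 consecutive
    covering segments is additionally emitted as a partial fragment.
    """
    if not 1 <= len(proteases) <= MAX_ENZYMES:
        raise ValueError(
            f"number of proteases must be 1..{MAX_ENZYMES}, got {len(proteases)}"
        )
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    sites: set[int] = set()
    for protease in proteases:
        sites.update(cut_sites(protein, protease))
    boundaries = sorted(sites)
    seq = protein.sequence
    starts = [1, *[b + 1 for b in boundaries]]
    ends = [*boundaries, len(seq)]
    fragments = [
        Fragment(parent_id=protein.id, start=s, end=e, sequence=seq[s - 1 : e])
        for s, e in zip(starts, ends)
    ]
    partials: list[Fragment] = []
    n_seg = len(fragments)
    for span in range(2, missed_cleavages + 2):
        for i in range(n_seg - span + 1):
            s, e = fragments[i].start, fragments[i + span - 1].end
            partials.append(
                Fragment(parent_id=protein.id, start=s, end=e,
                         sequence=seq[s - 1 : e], missed=span - 1)
            )
    return DigestResult(
        protein_id=protein.id,
        protease_names=tuple(p.name for p in proteases),
        fragments=fragments,
        partial_fragments=partials,
    )


def search_active_fragments(result: DigestResult, refset: ReferenceSet) -> DigestResult:
    """Match released fragments against the reference set (whole-fragment, exact).

    A fragment equal to a peptide carrying k activity labels counts once per
    activity.  Matches are populated in place and the result returned.
    """
    if len(refset) == 0:
        raise ValueError("reference set is empty")
    by_sequence: dict[str, list[BioactivePeptide]] = {}
    for entry in refset:
        by_sequence.setdefault(entry.sequence, []).append(entry)
    matches: dict[str, list[tuple[Fragment, BioactivePeptide]]] = {
        activity: [] for activity in refset.activities
    }
    for fragment in result.all_fragments:
        for entry in by_sequence.get(fragment.sequence, ()):
            matches[entry.activity].append((fragment, entry))
    result.matches = matches
    return result


def rank_proteases(
    protein: ProteinRecord,
    rulebook: Sequence[Protease],
    refset: ReferenceSet,
    activity: str,
    combinations: Sequence[Sequence[str]] = (),
    missed_cleavages: int = 0,
) -> list[dict]:
    """Per-protease released-peptide counts, sorted by the requested activity.

    Rows are dicts with the enzyme name(s) and per-activity counts; sorting
    is descending by the requested activity with ties broken by name.
    Enzymes releasing nothing appear as zero rows (rendered "ND" by the
    reporting layer).
    """
    if not rulebook:
        raise ValueError("rulebook is empty")
    activity = normalize_activity(activity)
    if activity not in refset.activities:
        raise ValueError(
            f"unknown activity {activity!r}; known: {refset.activities}"
        )
    by_name = {p.name: p for p in rulebook}
    selections: list[tuple[str, list[Protease]]] = [(p.name, [p]) for p in rulebook]
    for combo in combinations:
        enzymes = [by_name[name] for name in combo]
        selections.append((" + ".join(combo), enzymes))
    rows = []
    for label, enzymes in selections:
        result = search_active_fragments(
            digest(protein, enzymes, missed_cleavages=missed_cleavages), refset
        )
        row: dict[str, object] = {"protease": label}
        for act in refset.activities:
            row[act] = result.match_count(act)
        rows.append(row)
    rows.sort(key=lambda r: (-int(r[activity]), str(r["protease"])))
    return rows


# ---------------------------------------------------------------------------
# Rulebook I/O

def _parse_rule(spec: dict) -> Protease:
    for key in ("name", "clauses"):
        if key not in spec:
            raise ValueError(f"rulebook entry missing {key!r}: {spec}")
    clauses = tuple(SiteClause.from_dict(c) for c in spec["clauses"])
    exceptions = tuple(SiteClause.from_dict(c) for c in spec.get("exceptions", ()))
    return Protease(
        name=spec["name"],
        ec_number=str(spec.get("ec", "-")),
        rule=CleavageRule(clauses=clauses, exceptions=exceptions),
    )


def load_rulebook(path: Union[str, Path, IO[str]]) -> list[Protease]:
    """Load proteases from a YAML rulebook (list of name/ec/clauses/exceptions)."""
    if isinstance(path, (str, Path)):
        with open(path) as handle:
            raw = yaml.safe_load(handle)
    else:
        raw = yaml.safe_load(path)
    if not isinstance(raw, list):
        raise ValueError("rulebook must be a YAML list of enzyme entries")
    proteases = [_parse_rule(entry) for entry in raw]
    names = [p.name for p in proteases]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate protease name(s) in rulebook: {sorted(dupes)}")
    return proteases


def builtin_rulebook() -> list[Protease]:
    """The cleavage rulebook shipped with the package."""
    from importlib.resources import files

    data = files("biopepsim.data").joinpath("cleavage_rules.yaml")
    with data.open("r") as handle:
        return load_rulebook(handle)


def get_protease(name: str, rulebook: Iterable[Protease] | None = None) -> Protease:
    """Look up a protease by (case-insensitive) name."""
    book = list(rulebook) if rulebook is not None else builtin_rulebook()
    for protease in book:
        if protease.name.lower() == name.lower():
            return protease
    known = ", ".join(sorted(p.name for p in book))
    raise KeyError(f"unknown protease {name!r}; known: {known}")
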