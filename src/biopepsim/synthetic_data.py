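"""Seeded synthetic fixtures with known ground truth.

Every generator derives its randomness from a named stream keyed on the
user seed, so adding a generator never perturbs the output of another and
identical (parameters, seed) pairs replay exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._util import AMINO_ACIDS
from .digestion import Protease, cut_sites
from .reference_db import BioactivePeptide
from .sequence_io import ProteinRecord

ALPHABET = sorted(AMINO_ACIDS)

#: Approximate residue frequencies of vertebrate proteins (normalised).
VERTEBRATE_COMPOSITION: Mapping[str, float] = {
    "A": 0.077, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047,
    "G": 0.074, "H": 0.029, "I": 0.038, "K": 0.072, "L": 0.079,
    "M": 0.018, "N": 0.044, "P": 0.050, "Q": 0.037, "R": 0.042,
    "S": 0.084, "T": 0.062, "V": 0.068, "W": 0.013, "Y": 0.033,
}

def _rng(stream: str, seed: int) -> np.random.Generator:
    """Independent named stream for one generator family."""
    stream_ids = {"protein": 1, "motifs": 2, "cleavage": 3}
    return np.random.default_rng([stream_ids[stream], seed])


class PlacementError(RuntimeError):
    """Motif planting could not satisfy its constraints within bounded retries."""


class ConstructionError(RuntimeError):
    """A cleavage fixture could not be constructed for the given rule/alphabet."""


@dataclass
class SyntheticTruth:
    """A generated protein plus the exact ground truth used to build it."""

    protein: ProteinRecord
    planted_occurrences: list[tuple[str, int, int, str]] = field(default_factory=list)
    planted_cut_sites: dict[str, list[int]] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "protein_id": self.protein.id,
                "sequence": self.protein.sequence,
                "planted_occurrences": self.planted_occurrences,
                "planted_cut_sites": self.planted_cut_sites,
                "params": self.params,
            },
            indent=2,
            sort_keys=True,
        )

    def verify(self) -> None:
        """Check every planted occurrence / site against the sequence itself."""
        for motif, start, end, _activity in self.planted_occurrences:
            if self.protein.subsequence(start, end) != motif:
                raise AssertionError(
                    f"planted occurrence {motif!r} at {start}..{end} does not "
                    "match the generated sequence"
                )
        for name, bonds in self.planted_cut_sites.items():
            for bond in bonds:
                if not 1 <= bond < len(self.protein):
                    raise AssertionError(f"{name}: bond {bond} out of range")


def _normalise_composition(composition) -> tuple[list[str], np.ndarray]:
    if composition == "uniform":
        return ALPHABET, np.full(len(ALPHABET), 1 / len(ALPHABET))
    if composition == "vertebrate":
        composition = VERTEBRATE_COMPOSITION
    letters = sorted(composition)
    if set(letters) - AMINO_ACIDS:
        raise ValueError("composition contains non-canonical residues")
    probs = np.array([composition[ch] for ch in letters], dtype=float)
    if (probs < 0).any():
        raise ValueError("composition frequencies must be non-negative")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"composition frequencies sum to {probs.sum()!r}, not 1")
    return letters, probs


def generate_protein(length: int, composition="uniform", seed: int = 0,
                     record_id: str = "synth") -> ProteinRecord:
    """Random protein with residues drawn i.i.d. from ``composition``.

    ``composition`` is "uniform", "vertebrate", or a residue->frequency
    mapping summing to 1 (within 1e-9).  Deterministic for a fixed seed.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    letters, probs = _normalise_composition(composition)
    rng = _rng("protein", seed)
    seq = "".join(rng.choice(letters, size=length, p=probs))
    return ProteinRecord(id=record_id, sequence=seq,
                         description=f"synthetic length={length} seed={seed}")


def plant_motifs(
    protein: ProteinRecord,
    motifs: Sequence[BioactivePeptide],
    copies_per_motif: int,
    seed: int = 0,
    non_overlapping: bool = True,
    motif_free_background: bool = False,
    max_retries: int = 200,
) -> SyntheticTruth:
    """Overwrite residues of ``protein`` with motif copies at random positions.

    Returns the exact truth positions.  With ``motif_free_background`` the
    non-planted residues are resampled (bounded retries) until no motif
    occurs outside the planted positions, so profiling counts are exact.
    """
    total = sum(len(m.sequence) for m in motifs) * copies_per_motif
    if total > len(protein):
        raise PlacementError(
            f"total planted length {total} exceeds protein length {len(protein)}"
        )
    rng = _rng("motifs", seed)
    if copies_per_motif == 0:
        return SyntheticTruth(
            protein=protein, planted_occurrences=[],
            params={"copies_per_motif": 0, "seed": seed},
        )
    motif_letters = sorted({ch for m in motifs for ch in m.sequence})
    background_letters = [ch for ch in ALPHABET if ch not in motif_letters] \
        if motif_free_background else ALPHABET

    for _attempt in range(max_retries):
        if motif_free_background:
            base = list(rng.choice(background_letters, size=len(protein)))
        else:
            base = list(protein.sequence)
        placements: list[tuple[str, int, int, str]] = []
        occupied: set[int] = set()
        ok = True
        for motif in motifs:
            for _copy in range(copies_per_motif):
                placed = False
                for _try in range(max_retries):
                    start0 = int(rng.integers(0, len(protein) - len(motif.sequence) + 1))
                    span = range(start0, start0 + len(motif.sequence))
                    if non_overlapping and occupied.intersection(span):
                        continue
                    for offset, ch in zip(span, motif.sequence):
                        base[offset] = ch
                    occupied.update(span)
                    placements.append(
                        (motif.sequence, start0 + 1, start0 + len(motif.sequence),
                         motif.activity)
                    )
                    placed = True
                    break
                if not placed:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        sequence = "".join(base)
        if motif_free_background:
            expected = {
                m.sequence: sum(1 for p in placements if p[0] == m.sequence)
                for m in motifs
            }
            actual = {
                s: _count_overlapping(sequence, s) for s in expected
            }
            if expected != actual:
                continue  # accidental background occurrence; resample
        truth = SyntheticTruth(
            protein=ProteinRecord(id=protein.id, sequence=sequence,
                                  description=protein.description),
            planted_occurrences=sorted(placements, key=lambda p: p[1]),
            params={"copies_per_motif": copies_per_motif, "seed": seed,
                    "non_overlapping": non_overlapping,
                    "motif_free_background": motif_free_background},
        )
        truth.verify()
        return truth
    raise PlacementError(
        f"could not place {copies_per_motif} copies of {len(motifs)} motif(s) "
        f"after {max_retries} retries"
    )


def _count_overlapping(sequence: str, motif: str) -> int:
    count = 0
    start = sequence.find(motif)
    while start != -1:
        count += 1
        start = sequence.find(motif, start + 1)
    return count


def generate_cleavage_fixture(
    protease: Protease,
    n_sites: int,
    spacer_alphabet: Sequence[str] = ("A", "G", "S", "T", "V"),
    seed: int = 0,
    max_retries: int = 500,
) -> SyntheticTruth:
    """A sequence of inert spacers and site windows with exactly known cut sites.

    Spacer residues must not satisfy any P1/P1' clause constraint of the
    rule; the construction is verified against :func:`cut_sites` and
    resampled until the planted bonds are exactly the bonds cut.
    """
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    spacers = sorted(set(spacer_alphabet))
    if set(spacers) - AMINO_ACIDS:
        raise ValueError("spacer alphabet contains non-canonical residues")
    for clause in protease.rule.clauses:
        for pos in ("p1", "p1prime"):
            allowed = getattr(clause, pos)
            if allowed is not None and set(spacers) & set(allowed):
                raise ConstructionError(
                    f"spacer alphabet {spacers} overlaps {pos} residues of a "
                    f"clause of {protease.name!r}"
                )
    site_window = _find_site_window(protease, spacers)
    rng = _rng("cleavage", seed)

    for _attempt in range(max_retries):
        parts: list[str] = []
        planted: list[int] = []
        pos = 0
        for i in range(n_sites + 1):
            spacer_len = int(rng.integers(3, 9))
            spacer = "".join(rng.choice(spacers, size=spacer_len))
            parts.append(spacer)
            pos += spacer_len
            if i < n_sites:
                parts.append(site_window)
                # the window is p2 p1 | p1' p2'; the bond follows its 2nd residue
                planted.append(pos + 2)
                pos += len(site_window)
        sequence = "".join(parts)
        protein = ProteinRecord(id=f"cleavage-{protease.name}", sequence=sequence,
                                description=f"planted sites for {protease.name}")
        if cut_sites(protein, protease) == planted:
            truth = SyntheticTruth(
                protein=protein,
                planted_cut_sites={protease.name: planted},
                params={"n_sites": n_sites, "seed": seed,
                        "spacer_alphabet": spacers, "protease": protease.name},
            )
            truth.verify()
            return truth
    raise ConstructionError(
        f"could not build a fixture with exactly {n_sites} site(s) for "
        f"{protease.name!r} after {max_retries} attempts"
    )


def _find_site_window(protease: Protease, spacers: Sequence[str]) -> str:
    """A P2-P1-P1'-P2' 4-mer cut only at its middle bond when embedded in spacers.

    Candidates are verified inside homogeneous spacer context so the window
    introduces no cuts at its internal or junction bonds.
    """
    from itertools import product

    rule = protease.rule

    def clean_in_context(window: str) -> bool:
        for spacer in spacers:
            probe = ProteinRecord(id="probe", sequence=spacer * 4 + window + spacer * 4)
            if cut_sites(probe, protease) != [6]:
                return False
        return True

    for clause in rule.clauses:
        candidates = []
        for pos in ("p2", "p1", "p1prime", "p2prime"):
            allowed = getattr(clause, pos)
            candidates.append(sorted(allowed) if allowed is not None else ALPHABET)
        for combo in product(*candidates):
            window = "".join(combo)
            if rule.cuts_at(window, 2) and clean_in_context(window):
                return window
    raise ConstructionError(
        f"no satisfiable site window exists for {protease.name!r} with "
        f"spacer alphabet {sorted(spacers)}"
    )
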