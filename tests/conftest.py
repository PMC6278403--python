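import random

import pytest

from biopepsim.reference_db import BioactivePeptide, ReferenceSet
from biopepsim.sequence_io import ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: random.Random, length: int, record_id: str = "rand") -> ProteinRecord:
    return ProteinRecord(id=record_id,
                         sequence="".join(rng.choice(AA) for _ in range(length)))


def random_refset(rng: random.Random, n_entries: int, max_len: int = 4) -> ReferenceSet:
    activities = ["DPP-IV inhibitor", "ACE inhibitor", "antioxidative", "other:misc"]
    entries = []
    seen = set()
    while len(entries) < n_entries:
        length = rng.randint(1, max_len)
        seq = "".join(rng.choice(AA) for _ in range(length))
        act = rng.choice(activities)
        if (seq, act) in seen:
            continue
        seen.add((seq, act))
        entries.append(BioactivePeptide(sequence=seq, activity=act))
    return ReferenceSet(entries=entries, version_tag="random")


@pytest.fixture
def rng() -> random.Random:
    return random.Random(1234)


@pytest.fixture
def tiny_refset() -> ReferenceSet:
    return ReferenceSet(
        entries=[
            BioactivePeptide(sequence="GP", activity="ACE inhibitor"),
            BioactivePeptide(sequence="AA", activity="DPP-IV inhibitor"),
            BioactivePeptide(sequence="KF", activity="DPP-IV inhibitor"),
            BioactivePeptide(sequence="KF", activity="antihypertensive"),
        ],
        version_tag="tiny",
    )
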