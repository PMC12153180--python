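import random

import numpy as np
import pytest

from divmine import simbench as sb
from divmine.records import SequenceRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AA20) for _ in range(length))


def mutate(rng: random.Random, seq: str, fraction: float) -> str:
    """Substitute a given fraction of positions (never to the same residue)."""
    positions = rng.sample(range(len(seq)), int(round(fraction * len(seq))))
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([a for a in AA20 if a != out[p]])
    return "".join(out)


@pytest.fixture
def rng():
    return random.Random(20240917)


@pytest.fixture(scope="session")
def scaled_benchmark():
    """One scaled benchmark run (16 leaves, factors 1/2/4/8, 2 replicates,
    fixed seed) shared by the tests that assert on its outcome."""
    scores, frame = sb.run_scaled_benchmark(master_seed=1, backend="blast")
    return frame


def make_records(seqs, source="environmental", prefix="s"):
    return [
        SequenceRecord(id=f"{prefix}{i}", residues=s, source=source)
        for i, s in enumerate(seqs, start=1)
    ]
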