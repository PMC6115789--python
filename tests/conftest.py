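from __future__ import annotations

import numpy as np
import pytest

from mirtarp.energy import load_energy_model
from mirtarp.sequence_io import MiRNARecord, NucSequence


@pytest.fixture(scope="session")
def model():
    return load_energy_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240101)


def random_rna(rng, length: int, alphabet: str = "ACGU") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def make_mirna(seq: str, mid: str = "mir-x", origin: str = "host") -> MiRNARecord:
    return MiRNARecord(id=mid, origin=origin, seq=NucSequence(id=mid, residues=seq))


def make_target(seq: str, tid: str = "t-x") -> NucSequence:
    return NucSequence(id=tid, residues=seq)
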