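"""Shared fixtures and the independent brute-force scanning oracle."""

import numpy as np
import pytest

from myrfscan import ConsensusModel

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "N": {"A", "C", "G", "T"},
}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def naive_scan(sequence: str, pattern: str = "CTGGYAC", budget: int = 2):
    """All-windows, both-strand enumeration, written independently of the package.

    Returns a set of (start, strand, mismatch-position tuple).
    """
    sequence = sequence.upper()
    k = len(pattern)
    out = set()
    for start in range(len(sequence) - k + 1):
        window = sequence[start:start + k]
        for strand, view in (("+", window), ("-", naive_revcomp(window))):
            mm = tuple(
                p + 1 for p in range(k) if view[p] not in IUPAC_SETS[pattern[p]]
            )
            if len(mm) <= budget:
                out.add((start, strand, mm))
    return out


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def model() -> ConsensusModel:
    return ConsensusModel()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
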