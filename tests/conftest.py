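"""Shared fixtures: the worked single-reference example, the four-sequence
graph example, and helpers for random mutated populations."""

from __future__ import annotations

import numpy as np
import pytest

from mrfact import RME, Factorization, ReferenceSet

# Worked single-reference example: one reference and two sequences, where
# the second is the first with one extra leading character.
REF1 = "AAGCTCGGGAGGTGGCCAGGCGGCAGGAAGGCGCACCC"
S1 = "TAGGAGCTCGGGAGGGCCAGGCGGCAGGAAGGCGCACCC"
S2 = "ATAGGAGCTCGGGAGGGCCAGGCGGCAGGAAGGCGCACCC"

F1_RMES = [RME(0, 4, 1, "A"), RME(0, 7, 4, "C"), RME(0, 4, 8, "G"),
           RME(0, 15, 22, "C")]
F2_RMES = [RME(0, 0, 1, "T"), RME(0, 24, 4, "G"), RME(0, 3, 9, "G"),
           RME(0, 15, 22, "C")]

# Four factorizations against two references, used as the graph-shape
# fixture only (the raw sequences behind them are not available, so they
# are never unfolded).
GRAPH_FACTS = [
    [RME(1, 0, 8, "C"), RME(0, 10, 13, "T"), RME(0, 24, 11, "G"), RME(1, 32, 4, "A")],
    [RME(1, 0, 8, "C"), RME(0, 10, 13, "T"), RME(0, 24, 8, "A"), RME(0, 23, 3, "C"),
     RME(0, 12, 3, "G")],
    [RME(0, 26, 3, "C"), RME(0, 4, 5, "C"), RME(0, 10, 13, "T"), RME(0, 24, 11, "A"),
     RME(0, 33, 3, "A")],
    [RME(0, 0, 23, "T"), RME(0, 24, 11, "G"), RME(1, 32, 4, "A")],
]


@pytest.fixture
def single_ref() -> ReferenceSet:
    return ReferenceSet([("ref1", REF1)])


@pytest.fixture
def graph_factorizations() -> list[Factorization]:
    return [Factorization(f"s{i + 1}", list(rmes))
            for i, rmes in enumerate(GRAPH_FACTS)]


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def mutate_snps(rng: np.random.Generator, s: str, p: float) -> str:
    """Substitute each base with probability p (to a different base)."""
    arr = np.frombuffer(s.encode(), dtype=np.uint8).copy()
    lut = {65: "CGT", 67: "AGT", 71: "ACT", 84: "ACG"}
    out = list(s)
    for i in np.flatnonzero(rng.random(len(s)) < p):
        out[i] = lut[arr[i]][rng.integers(0, 3)]
    return "".join(out)


@pytest.fixture
def small_population():
    """Five references and five sequences, ~1 kb, SNP-mutated from one base."""
    rng = np.random.default_rng(42)
    base = random_dna(rng, 1000)
    refs = [(f"ref{i}", mutate_snps(rng, base, 0.01)) for i in range(5)]
    seqs = [(f"seq{i}", mutate_snps(rng, base, 0.01)) for i in range(5)]
    return refs, seqs
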