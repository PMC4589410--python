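"""Greedy optimal factorization and the prediction-driven database driver.

The core parse is the classic greedy longest-match rule: traverse the input
left to right and, at every step, replace the longest prefix found anywhere
in the references by one RME ``(id, pos, |pre|, next char)``.  When the
remaining suffix is matched entirely, the final RME is shortened by one so
its own last character serves as the mismatch literal.  Under uniform RME
cost this greedy parse is minimal (no factorization of the same sequence
against the same references uses fewer RMEs); :func:`minimal_parse_oracle`
provides an independent dynamic-programming check of that claim at test
scale.

:func:`factorize_db` adds the factorization-history machinery: a predictor
may propose the next RME, skipping the index lookup, and with the
graph-based predictors (succ/posi/graph) the RME graph is threaded across
sequences, each finished factorization contributing its non-terminal RMEs
within a bounded window.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Iterable, Sequence

import numpy as np

from .graph import RMEGraph
from .index import multi_ref_longest_match
from .model import (FSD, RME, Factorization, ManifestEntry, ReferenceSet,
                    sha1_of, validate_sequence)
from .predict import make_predictor

_PREDICTORS = ("base", "loma", "succ", "posi", "graph")
_GRAPH_PREDICTORS = ("succ", "posi", "graph")


@dataclass
class FactorizerConfig:
    """Configuration of one factorization run, named INDEX_MATCHFINDING_EXTENSION.

    ``index_kind``: "esa" (exact suffix array) or "kmer" (seed and extend;
    forfeits the optimality guarantee of the graph predictors).
    ``predictor``: "base" (always look up), "loma", "succ", "posi", or
    "graph" (unfiltered graph scan).  ``extension``: "none", "left" or
    "right".  Defaults ``k = l_min = 16``, ``delta_max = 10`` and a history
    window of 10 sequences follow the published parameter study.
    """

    index_kind: str = "esa"
    predictor: str = "base"
    extension: str = "none"
    k: int = 16
    delta_max: int = 10
    l_min: int = 16
    window: int = 10

    def __post_init__(self) -> None:
        if self.index_kind not in ("esa", "kmer"):
            raise ValueError(f"unknown index kind: {self.index_kind!r}")
        if self.predictor not in _PREDICTORS:
            raise ValueError(f"unknown predictor: {self.predictor!r}")
        if self.extension not in ("none", "left", "right"):
            raise ValueError(f"unknown extension mode: {self.extension!r}")

    @property
    def label(self) -> str:
        ext = {"none": "N", "left": "L", "right": "R"}[self.extension]
        return f"{self.index_kind.upper()}_{self.predictor.upper()}_{ext}"


def _greedy_rmes(s: str, refs: ReferenceSet, predict=None) -> tuple[list[RME], int]:
    """One sequence's RME list; returns (rmes, number of predicted RMEs)."""
    n = len(s)
    sb = s.encode("ascii")
    sarr = np.frombuffer(sb, dtype=np.uint8)
    rmes: list[RME] = []
    pos = 0
    prme: RME | None = None  # first RME of a sequence always uses a lookup
    predicted = 0
    while pos < n:
        if predict is not None and prme is not None:
            cand = predict(s, sarr, pos, prme)
            if cand is not None:
                rmes.append(cand)
                pos += cand.length + 1
                prme = cand
                predicted += 1
                continue
        rid, rpos, l = multi_ref_longest_match(refs, sb, pos)
        if pos + l < n:
            rme = RME(rid, rpos, l, s[pos + l])
            pos += l + 1
        else:  # remaining suffix matched entirely: shorten by one
            rme = RME(rid, rpos, l - 1, s[pos + l - 1])
            pos += l
        rmes.append(rme)
        prme = rme
    return rmes, predicted


def factorize_optimal(s: str, refs: ReferenceSet | Iterable[tuple[str, str]],
                      name: str = "seq") -> Factorization:
    """Greedy longest-match parse of one sequence (minimal RME count)."""
    if not isinstance(refs, ReferenceSet):
        refs = ReferenceSet(refs)
    validate_sequence(s, name)
    rmes, _ = _greedy_rmes(s, refs)
    return Factorization(name, rmes)


def _raw_manifest(refs: ReferenceSet) -> list[ManifestEntry]:
    return [ManifestEntry("raw", i, name, len(seq), sha1_of(seq))
            for i, (name, seq) in enumerate(refs)]


def factorize_db(S: Sequence[tuple[str, str]],
                 refs: ReferenceSet | Iterable[tuple[str, str]],
                 cfg: FactorizerConfig | None = None,
                 initial_graph: RMEGraph | None = None) -> FSD:
    """Factorize a whole sequence database with the configured predictor.

    With a graph predictor, every finished factorization (minus its final
    RME) feeds the RME graph before the next sequence starts; the window is
    enforced on every addition.  ``initial_graph`` lets callers seed the
    history (used by reference extension, where the factorized references
    contribute first).
    """
    cfg = cfg or FactorizerConfig()
    if not isinstance(refs, ReferenceSet):
        refs = ReferenceSet(refs, cfg.index_kind, cfg.k)
    S = list(S)
    for name, s in S:
        validate_sequence(s, f"sequence {name!r}")

    graph: RMEGraph | None = None
    if cfg.predictor in _GRAPH_PREDICTORS:
        graph = initial_graph if initial_graph is not None else RMEGraph(cfg.window)
    predict = make_predictor(cfg.predictor, refs, graph, cfg.delta_max, cfg.l_min)

    facts: list[Factorization] = []
    lookups_per_seq: list[int] = []
    predicted_per_seq: list[int] = []
    for name, s in S:
        before = refs.lookups
        rmes, predicted = _greedy_rmes(s, refs, predict)
        f = Factorization(name, rmes)
        facts.append(f)
        lookups_per_seq.append(refs.lookups - before)
        predicted_per_seq.append(predicted)
        if graph is not None:
            graph.add(f)

    total_rmes = sum(len(f) for f in facts)
    stats = {
        "lookups_per_sequence": lookups_per_seq,
        "predicted_per_sequence": predicted_per_seq,
        "rmes_per_sequence": [len(f) for f in facts],
        "lookups": sum(lookups_per_seq),
        "predicted": sum(predicted_per_seq),
        "lookup_avoided_fraction": (sum(predicted_per_seq) / total_rmes
                                    if total_rmes else 0.0),
        "indexes_built": refs.indexes_built,
    }
    return FSD(_raw_manifest(refs), [], facts, params=asdict(cfg), stats=stats)


def minimal_parse_oracle(s: str, ref_seqs: Sequence[str]) -> int:
    """Minimum possible RME count for ``s``, by dynamic programming.

    Brute force and independent of the greedy path: ``maxmatch(i)``, the
    longest match of ``s[i:]`` starting anywhere in any reference, is
    computed by direct character comparison (no index), and a DP over
    positions takes every transition ``i -> i + l + 1`` (one RME covering a
    match of length ``l <= maxmatch(i)`` plus its mismatch character) at
    cost 1.  Intended for short test instances (|s| of a few hundred).
    """
    n = len(s)
    if n == 0:
        return 0
    sarr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    maxmatch = np.zeros(n, dtype=np.int64)
    for ref in ref_seqs:
        rarr = np.frombuffer(ref.encode("ascii"), dtype=np.uint8)
        m = len(rarr)
        nxt = np.zeros(m + 1, dtype=np.int64)
        for i in range(n - 1, -1, -1):
            cur = np.zeros(m + 1, dtype=np.int64)
            cur[:m] = np.where(rarr == sarr[i], nxt[1:] + 1, 0)
            best = int(cur.max())
            if best > maxmatch[i]:
                maxmatch[i] = best
            nxt = cur
    big = n + 1
    dp = np.full(n + 1, big, dtype=np.int64)
    dp[n] = 0
    for i in range(n - 1, -1, -1):
        hi = min(int(maxmatch[i]), n - 1 - i)  # l, with i + l + 1 <= n
        dp[i] = 1 + int(dp[i + 1:i + hi + 2].min())
    return int(dp[0])
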