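"""Prediction heuristics that avoid index lookups during factorization.

All predictors answer the same question: given the previously emitted RME
``prme`` and the not-yet-factorized suffix of the current sequence, can the
next RME be proposed without querying a reference index?  A proposed
candidate is only used when it *matches* the suffix (the predicate of
:func:`mrfact.model.rme_matches`), so every prediction is sound and the
factorization always unfolds back to its input.

* LOMA (local matching): scan a +-delta window around the end of the
  previous match in the same reference and keep the best direct-comparison
  match of length >= ``l_min``.  Fast, but not optimality-preserving.
* Graph scan / SUCC / POSI: propose nodes of the RME graph.  Graph nodes
  are maximal matches, so any matching node is itself a longest match and
  optimality is preserved (with an exact index as fallback).  SUCC restricts
  candidates to graph successors of ``prme``; POSI to successors of any node
  whose match ended at the same reference position as ``prme``'s.

Following the published scan semantics, candidate loops do not stop at the
first match: the last matching candidate under the graph's deterministic
(insertion) order wins.  All matching nodes are maximal, so the choice does
not affect factorization size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .index import _lcp
from .model import RME, ReferenceSet, rme_matches
from .graph import RMEGraph


@dataclass
class Prediction:
    """Outcome of one predict call; ``candidate`` is None when no RME could
    be proposed (the caller then falls back to an index lookup)."""

    candidate: RME | None
    lookup_avoided: bool


def _matches(rme: RME, s: str, pos: int, refs: ReferenceSet) -> bool:
    return rme_matches(rme, s, refs, start=pos)


def predict_loma(s: str, pos: int, prme: RME | None, refs: ReferenceSet,
                 delta_max: int = 10, l_min: int = 16,
                 _sarr: np.ndarray | None = None) -> Prediction:
    """Local matching around the previous match end (same reference only).

    Positions ``prme.start + prme.length + 1 + delta`` for delta in
    ``[-delta_max, +delta_max]`` are tried; the ``+1`` treats the previous
    mismatch character as a SNP aligned to the reference.  Ties on length go
    to the later delta (scan order with >=).  Candidates shorter than
    ``l_min`` are discarded.
    """
    if prme is None or not (0 <= prme.ref_id < len(refs)):
        return Prediction(None, False)
    ref_arr = refs.array(prme.ref_id)
    L = len(ref_arr)
    if _sarr is None:
        _sarr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    remaining = len(s) - pos
    best: RME | None = None
    best_l = 0
    center = prme.start + prme.length + 1
    for delta in range(-delta_max, delta_max + 1):
        p = center + delta
        if p < 0 or p >= L:
            continue
        l = _lcp(ref_arr, p, _sarr, pos)
        if l >= remaining:
            l = remaining - 1  # keep one character as the literal mismatch
        if l >= l_min and l >= best_l:
            best = RME(prme.ref_id, p, l, s[pos + l])
            best_l = l
    return Prediction(best, best is not None)


def predict_graph_all(s: str, pos: int, prme: RME | None, refs: ReferenceSet,
                      graph: RMEGraph) -> Prediction:
    """Unfiltered scan over every node of the RME graph."""
    cand: RME | None = None
    for rme in graph.nodes():
        if _matches(rme, s, pos, refs):
            cand = rme
    return Prediction(cand, cand is not None)


def predict_succ(s: str, pos: int, prme: RME | None, refs: ReferenceSet,
                 graph: RMEGraph) -> Prediction:
    """Candidates are the graph successors of ``prme``."""
    if prme is None:
        return Prediction(None, False)
    cand: RME | None = None
    for rme in graph.successors_of(prme):
        if _matches(rme, s, pos, refs):
            cand = rme
    return Prediction(cand, cand is not None)


def predict_posi(s: str, pos: int, prme: RME | None, refs: ReferenceSet,
                 graph: RMEGraph) -> Prediction:
    """Candidates are all nodes following *some* node whose match ended at
    the same reference position as ``prme``'s (a superset of SUCC)."""
    if prme is None:
        return Prediction(None, False)
    cand: RME | None = None
    for rme in graph.successors_by_end_pos(prme.ref_id, prme.ref_end):
        if _matches(rme, s, pos, refs):
            cand = rme
    return Prediction(cand, cand is not None)


def make_predictor(predictor: str, refs: ReferenceSet, graph: RMEGraph | None,
                   delta_max: int = 10, l_min: int = 16):
    """Internal driver protocol: ``fn(s, sarr, pos, prme) -> RME | None``.

    Returns None for the "base" predictor (always use the index).
    """
    if predictor == "base":
        return None
    if predictor == "loma":
        def fn(s, sarr, pos, prme):
            return predict_loma(s, pos, prme, refs, delta_max, l_min,
                                _sarr=sarr).candidate
        return fn
    if graph is None:
        raise ValueError(f"predictor {predictor!r} requires an RME graph")
    if predictor == "graph":
        def fn(s, sarr, pos, prme):
            return predict_graph_all(s, pos, prme, refs, graph).candidate
        return fn
    if predictor == "succ":
        def fn(s, sarr, pos, prme):
            return predict_succ(s, pos, prme, refs, graph).candidate
        return fn
    if predictor == "posi":
        def fn(s, sarr, pos, prme):
            return predict_posi(s, pos, prme, refs, graph).candidate
        return fn
    raise ValueError(f"unknown predictor: {predictor!r}")
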