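"""The RME graph: factorization history as a successor structure.

Nodes are the RMEs of previously computed factorizations, *excluding the
last RME of each factorization*: final RMEs are produced by the shortened
end-of-sequence rule and do not necessarily describe maximal matches, and
only maximal matches may be replayed without losing optimality.  A directed
edge connects two RMEs that occurred consecutively; each edge carries one
occurrence label ``(i, pos)`` per occurrence, where ``i`` identifies the
contributing factorization and ``pos`` is the unfolded offset of the
successor RME within it.

Two secondary indexes drive the predictors: successors by node identity
(SUCC) and successors keyed by where the predecessor's match ended in the
reference (POSI) -- the key is ``(ref_id, start + length + 1)``, counting
the mismatch character as one aligned position.

A bounded window keeps only the most recent ``window`` contributing
factorizations; eviction removes exactly their occurrence labels plus any
node or edge left without an occurrence.
"""

from __future__ import annotations

from collections import OrderedDict
from typing import Iterable

from .model import RME, Factorization


class RMEGraph:
    def __init__(self, window: int | None = 10):
        if window is not None and window < 0:
            raise ValueError("window must be >= 0 or None")
        self.window = window
        self._node_count: dict[RME, int] = {}
        self._edges: dict[tuple[RME, RME], list[tuple[int, int]]] = {}
        self._succ: dict[RME, list[RME]] = {}
        self._end_pos: dict[tuple[int, int], list[RME]] = {}
        self._end_pos_count: dict[tuple[tuple[int, int], RME], int] = {}
        # factorization index -> (node occurrences, edge occurrences)
        self._contrib: OrderedDict[int, tuple[list[RME], list[tuple[RME, RME]]]] = OrderedDict()
        self._auto = 0

    # -- construction ------------------------------------------------------

    def add(self, f: Factorization | Iterable[RME], index: int | None = None) -> "RMEGraph":
        """Add one factorization's non-terminal RMEs and consecutive pairs."""
        rmes = list(f.rmes) if isinstance(f, Factorization) else list(f)
        if not rmes:
            raise ValueError("factorization must contain at least one RME")
        if index is None:
            index = self._auto
        if index in self._contrib:
            raise ValueError(f"factorization index {index} already contributed")
        self._auto = max(self._auto, index + 1)

        nodes = rmes[:-1]  # never store the last RME
        for node in nodes:
            self._node_count[node] = self._node_count.get(node, 0) + 1
        edge_recs: list[tuple[RME, RME]] = []
        pos = rmes[0].length + 1  # offset of rmes[1]
        for j in range(len(rmes) - 2):  # successor must not be terminal
            a, b = rmes[j], rmes[j + 1]
            labels = self._edges.get((a, b))
            if labels is None:
                self._edges[(a, b)] = labels = []
                self._succ.setdefault(a, []).append(b)
                key = (a.ref_id, a.ref_end)
                ck = (key, b)
                if self._end_pos_count.get(ck, 0) == 0:
                    self._end_pos.setdefault(key, []).append(b)
                self._end_pos_count[ck] = self._end_pos_count.get(ck, 0) + 1
            labels.append((index, pos))
            edge_recs.append((a, b))
            pos += rmes[j + 1].length + 1
        self._contrib[index] = (nodes, edge_recs)
        if self.window is not None:
            while len(self._contrib) > self.window:
                self._evict_oldest()
        return self

    def _evict_oldest(self) -> None:
        index, (nodes, edge_recs) = self._contrib.popitem(last=False)
        for a, b in dict.fromkeys(edge_recs):
            labels = [lab for lab in self._edges[(a, b)] if lab[0] != index]
            if labels:
                self._edges[(a, b)] = labels
                continue
            del self._edges[(a, b)]
            succ = self._succ[a]
            succ.remove(b)
            if not succ:
                del self._succ[a]
            key = (a.ref_id, a.ref_end)
            ck = (key, b)
            self._end_pos_count[ck] -= 1
            if self._end_pos_count[ck] == 0:
                del self._end_pos_count[ck]
                ends = self._end_pos[key]
                ends.remove(b)
                if not ends:
                    del self._end_pos[key]
        for node in nodes:
            self._node_count[node] -= 1
            if self._node_count[node] == 0:
                del self._node_count[node]

    def evict(self, keep: int) -> "RMEGraph":
        """Keep only the labels of the most recent ``keep`` factorizations."""
        if keep < 0:
            raise ValueError("keep must be >= 0")
        while len(self._contrib) > keep:
            self._evict_oldest()
        return self

    # -- queries -----------------------------------------------------------

    def nodes(self) -> list[RME]:
        return list(self._node_count)

    def __contains__(self, rme: RME) -> bool:
        return rme in self._node_count

    def edges(self) -> dict[tuple[RME, RME], list[tuple[int, int]]]:
        return {pair: list(labels) for pair, labels in self._edges.items()}

    def edge_occurrences(self, a: RME, b: RME) -> list[tuple[int, int]]:
        return list(self._edges.get((a, b), []))

    def successors_of(self, prme: RME) -> list[RME]:
        """All nodes with an edge from ``prme``, in insertion order."""
        return list(self._succ.get(prme, []))

    def successors_by_end_pos(self, ref_id: int, end_pos: int) -> list[RME]:
        """All nodes whose (some) predecessor's match ended at ``end_pos``
        in reference ``ref_id`` -- a superset of ``successors_of`` for any
        node with that end key."""
        return list(self._end_pos.get((ref_id, end_pos), []))

    @property
    def n_contributing(self) -> int:
        return len(self._contrib)

    @property
    def next_index(self) -> int:
        return self._auto

    @property
    def n_nodes(self) -> int:
        return len(self._node_count)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    @property
    def n_occurrences(self) -> int:
        return sum(len(labels) for labels in self._edges.values())


def graph_add(graph: RMEGraph, f: Factorization, i: int | None = None) -> RMEGraph:
    return graph.add(f, i)


def graph_evict(graph: RMEGraph, keep: int) -> RMEGraph:
    return graph.evict(keep)
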