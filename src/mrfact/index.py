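"""Reference indexing and longest-prefix-match search.

Two index backends answer the same question -- *what is the longest prefix
of a query that occurs anywhere in the reference, and where?* -- with
different guarantees:

* :class:`SuffixIndex` ("esa" role): a plain suffix array searched by binary
  search; exact, the returned length is the true maximum.
* :class:`KmerIndex` ("kmer" role): a k-mer occurrence map; every seed hit
  is verified and extended by direct comparison, so matches shorter than
  ``k`` are invisible and the result length is either 0 or ``>= k``.

Ties on match length are broken towards the smallest reference position;
:func:`multi_ref_longest_match` breaks ties across references towards the
smallest reference id first.
"""

from __future__ import annotations

import numpy as np

from .model import ReferenceSet


def _as_bytes(q) -> bytes:
    if isinstance(q, bytes):
        return q
    if isinstance(q, str):
        return q.encode("ascii")
    raise TypeError(f"query must be str or bytes, got {type(q)!r}")


def _lcp(a: np.ndarray, i: int, b: np.ndarray, j: int) -> int:
    """Length of the longest common prefix of a[i:] and b[j:]."""
    m = min(len(a) - i, len(b) - j)
    if m <= 0:
        return 0
    neq = a[i:i + m] != b[j:j + m]
    k = int(np.argmax(neq))
    return k if neq[k] else m


def build_suffix_array(arr: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling, O(n log^2 n) with numpy sorts."""
    n = len(arr)
    rank = arr.astype(np.int64)
    sa = np.argsort(rank, kind="stable")
    k = 1
    while k < n:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[:n - k] = rank[k:]
        sa = np.lexsort((key2, rank))
        changed = (rank[sa[1:]] != rank[sa[:-1]]) | (key2[sa[1:]] != key2[sa[:-1]])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[sa] = np.concatenate(([0], np.cumsum(changed)))
        rank = new_rank
        if rank[sa[-1]] == n - 1:
            break
        k *= 2
    return sa


class SuffixIndex:
    """Suffix-array index over one reference; exact longest-prefix search."""

    kind = "esa"

    def __init__(self, ref: str, ref_id: int = 0):
        if not ref:
            raise ValueError("cannot index an empty reference")
        self.ref_id = ref_id
        self.seq = ref
        self._bytes = ref.encode("ascii")
        self._arr = np.frombuffer(self._bytes, dtype=np.uint8)
        self._sa = build_suffix_array(self._arr)

    def longest_prefix_match(self, q, start: int = 0) -> tuple[int, int]:
        """``(pos, len)`` of the longest prefix of ``q[start:]`` occurring in
        the reference; ``(0, 0)`` when even the first character is absent.
        Among equally long matches the smallest position wins."""
        qb = _as_bytes(q)
        if start >= len(qb):
            raise ValueError("empty query")
        qa = np.frombuffer(qb, dtype=np.uint8)
        rb, sa = self._bytes, self._sa
        n = len(sa)
        qsuf = qb[start:]
        lo, hi = 0, n
        while lo < hi:
            mid = (lo + hi) // 2
            if rb[sa[mid]:] < qsuf:
                lo = mid + 1
            else:
                hi = mid
        best = 0
        for cand in (lo - 1, lo):
            if 0 <= cand < n:
                best = max(best, _lcp(self._arr, int(sa[cand]), qa, start))
        if best == 0:
            return (0, 0)
        pre = qsuf[:best]
        lo2, hi2 = 0, n
        while lo2 < hi2:
            mid = (lo2 + hi2) // 2
            if rb[sa[mid]:sa[mid] + best] < pre:
                lo2 = mid + 1
            else:
                hi2 = mid
        lo3, hi3 = lo2, n
        while lo3 < hi3:
            mid = (lo3 + hi3) // 2
            if rb[sa[mid]:sa[mid] + best] <= pre:
                lo3 = mid + 1
            else:
                hi3 = mid
        pos = int(sa[lo2:lo3].min())
        return (pos, best)


class KmerIndex:
    """k-mer seed index: every k-mer maps to its sorted occurrence list.

    A query shorter than ``k``, or one whose leading k-mer is absent, yields
    ``(0, 0)``; otherwise every occurrence of the seed is extended by direct
    comparison and the longest extension wins (ties: smallest position).
    """

    kind = "kmer"

    def __init__(self, ref: str, ref_id: int = 0, k: int = 16):
        if not ref:
            raise ValueError("cannot index an empty reference")
        if k < 1:
            raise ValueError("k must be >= 1")
        self.ref_id = ref_id
        self.seq = ref
        self.k = k
        self._bytes = ref.encode("ascii")
        self._arr = np.frombuffer(self._bytes, dtype=np.uint8)
        occ: dict[bytes, list[int]] = {}
        rb = self._bytes
        for p in range(len(rb) - k + 1):  # empty when k > |ref|
            occ.setdefault(rb[p:p + k], []).append(p)
        self._occ = occ

    def longest_prefix_match(self, q, start: int = 0) -> tuple[int, int]:
        qb = _as_bytes(q)
        if start >= len(qb):
            raise ValueError("empty query")
        k = self.k
        if len(qb) - start < k:
            return (0, 0)
        occs = self._occ.get(qb[start:start + k])
        if not occs:
            return (0, 0)
        qa = np.frombuffer(qb, dtype=np.uint8)
        best_pos, best_len = 0, 0
        for p in occs:  # ascending, so strict '>' keeps the smallest position
            l = k + _lcp(self._arr, p + k, qa, start + k)
            if l > best_len:
                best_pos, best_len = p, l
        return (best_pos, best_len)


def build_suffix_index(ref: str, ref_id: int = 0) -> SuffixIndex:
    return SuffixIndex(ref, ref_id)


def build_kmer_index(ref: str, ref_id: int = 0, k: int = 16) -> KmerIndex:
    return KmerIndex(ref, ref_id, k)


def longest_prefix_match(index, q, start: int = 0) -> tuple[int, int]:
    """Dispatch to the index's search; see the class docstrings for the
    exactness contract of each backend."""
    return index.longest_prefix_match(q, start)


def multi_ref_longest_match(refs: ReferenceSet, q, start: int = 0) -> tuple[int, int, int]:
    """``(id, pos, len)`` of the longest match across all references.

    Ties on length are broken by the smallest reference id, then the
    smallest position.  Counts as one index lookup in the telemetry.
    """
    if len(refs) == 0:
        raise ValueError("empty reference set")
    refs.lookups += 1
    best = (0, 0, 0)
    for i in range(len(refs)):
        pos, l = refs.index_for(i).longest_prefix_match(q, start)
        if l > best[2]:
            best = (i, pos, l)
    return best
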