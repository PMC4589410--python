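"""Core domain model for multi-reference referential factorization.

A *referential match entry* (RME) encodes a run of characters as a pointer
into a reference sequence plus a single literal mismatch character.  A
sequence is stored as an ordered list of RMEs (a :class:`Factorization`)
whose *unfolding* -- substituting every RME by the referenced substring
followed by its mismatch character -- reproduces the sequence exactly.  A
:class:`FSD` (factorized sequence database) bundles many factorizations that
share one reference manifest.

Conventions used throughout the package:

* the alphabet is the uppercase DNA alphabet ``{A, C, G, T, N}``;
* all positions are 0-based and match intervals ``[start, start+length)``
  are half-open;
* reference identifiers are integers: ids ``0..m-1`` address the raw
  references of a :class:`ReferenceSet` in input order, ids ``>= m`` address
  factorized references carried by an :class:`FSD` (id ``- m`` indexes its
  factorized-reference section).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

import numpy as np

ALPHABET = "ACGTN"
_ALPHABET_SET = frozenset(ALPHABET)


class AlphabetError(ValueError):
    """A sequence contains a character outside {A, C, G, T, N}."""


class ResolutionError(LookupError):
    """An RME reference id cannot be resolved against the available references."""


class RME(NamedTuple):
    """Referential match entry ``(id, s, l, m)``.

    ``ref_id`` names the referenced sequence, ``start`` the 0-based match
    start within its unfolded form, ``length`` the match length (``>= 0``)
    and ``mismatch`` the single literal character appended after the match.
    The size of an RME is ``length + 1``, always at least one character.
    """

    ref_id: int
    start: int
    length: int
    mismatch: str

    @property
    def size(self) -> int:
        return self.length + 1

    @property
    def ref_end(self) -> int:
        """End position in the reference with the mismatch counted as one
        aligned character (the position a SNP-like mismatch would occupy)."""
        return self.start + self.length + 1


def rme_size(rme: RME) -> int:
    """Size of an RME in unfolded characters: ``l + 1``."""
    return rme.length + 1


@dataclass
class Factorization:
    """An ordered list of RMEs that unfolds to one sequence."""

    seq_name: str
    rmes: list[RME]

    def __len__(self) -> int:
        return len(self.rmes)

    def __iter__(self) -> Iterator[RME]:
        return iter(self.rmes)

    @property
    def rme_count(self) -> int:
        return len(self.rmes)

    @property
    def unfolded_length(self) -> int:
        return sum(r.length + 1 for r in self.rmes)

    def offsets(self) -> list[int]:
        return offsets(self)


def offsets(f: Factorization) -> list[int]:
    """Unfolded start offset of every RME: ``offset(f, rme_i) = sum_{j<i} size(rme_j)``."""
    out = []
    acc = 0
    for rme in f.rmes:
        out.append(acc)
        acc += rme.length + 1
    return out


def validate_sequence(seq: str, name: str = "sequence") -> None:
    if not seq:
        raise ValueError(f"{name} is empty")
    if not _ALPHABET_SET.issuperset(seq):
        bad = sorted(set(seq) - _ALPHABET_SET)
        raise AlphabetError(f"{name} contains characters outside {{A,C,G,T,N}}: {bad}")


def sha1_of(seq: str) -> str:
    return hashlib.sha1(seq.encode("ascii")).hexdigest()


class ReferenceSet:
    """Ordered collection of raw references with per-reference search indexes.

    Indexes (suffix-array or k-mer, selected by ``index_kind``) are built
    lazily on first use; ``indexes_built`` and ``lookups`` are telemetry
    counters used to verify the memory contract of reference extension and
    the lookup savings of the prediction heuristics.
    """

    def __init__(self, references: Iterable[tuple[str, str]],
                 index_kind: str = "esa", k: int = 16):
        refs = [(str(name), seq) for name, seq in references]
        if not refs:
            raise ValueError("at least one reference is required")
        seen: set[str] = set()
        for name, seq in refs:
            if name in seen:
                raise ValueError(f"duplicate reference name: {name!r}")
            seen.add(name)
            validate_sequence(seq, f"reference {name!r}")
        if index_kind not in ("esa", "kmer"):
            raise ValueError(f"unknown index kind: {index_kind!r}")
        self._refs = refs
        self.index_kind = index_kind
        self.k = k
        self._indexes: dict[int, object] = {}
        self._arrays: dict[int, np.ndarray] = {}
        self.lookups = 0
        self.indexes_built = 0

    @classmethod
    def from_sequences(cls, seqs: Iterable[str], **kwargs) -> "ReferenceSet":
        return cls([(f"ref{i}", s) for i, s in enumerate(seqs)], **kwargs)

    def __len__(self) -> int:
        return len(self._refs)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self._refs)

    def items(self) -> list[tuple[str, str]]:
        return list(self._refs)

    def name(self, i: int) -> str:
        return self._refs[i][0]

    def sequence(self, i: int) -> str:
        return self._refs[i][1]

    def array(self, i: int) -> np.ndarray:
        """Reference as a uint8 numpy view (cached), for fast comparisons."""
        arr = self._arrays.get(i)
        if arr is None:
            arr = np.frombuffer(self._refs[i][1].encode("ascii"), dtype=np.uint8)
            self._arrays[i] = arr
        return arr

    def index_for(self, i: int):
        idx = self._indexes.get(i)
        if idx is None:
            from .index import build_kmer_index, build_suffix_index

            name, seq = self._refs[i]
            if self.index_kind == "esa":
                idx = build_suffix_index(seq, i)
            else:
                idx = build_kmer_index(seq, i, self.k)
            self._indexes[i] = idx
            self.indexes_built += 1
        return idx

    def subset(self, n: int) -> "ReferenceSet":
        """First ``n`` references, sharing this set's index cache."""
        sub = ReferenceSet(self._refs[:n], self.index_kind, self.k)
        sub._indexes = self._indexes
        sub._arrays = self._arrays
        return sub


@dataclass
class ManifestEntry:
    """One reference descriptor of an FSD manifest."""

    kind: str  # "raw" | "factorized"
    ref_id: int
    name: str
    length: int
    sha1: str


@dataclass
class FSD:
    """Factorized sequence database: reference manifest plus factorizations.

    ``size`` counts RMEs across the sequence factorizations (the measure
    optimized by the greedy parser, under uniform per-RME storage); the
    unfolded character total is exposed separately as :attr:`unfolded_length`.
    """

    manifest: list[ManifestEntry]
    factorized_refs: list[Factorization]
    factorizations: list[Factorization]
    params: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict, compare=False, repr=False)
    _ref_cache: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        kinds = [e.kind for e in self.manifest]
        if "factorized" in kinds and "raw" in kinds:
            if kinds.index("factorized") < len(kinds) - 1 - kinds[::-1].index("raw"):
                raise ValueError("raw manifest entries must precede factorized ones")
        for i, e in enumerate(self.manifest):
            if e.ref_id != i:
                raise ValueError("manifest ids must be dense from 0")

    @property
    def n_raw(self) -> int:
        return sum(1 for e in self.manifest if e.kind == "raw")

    @property
    def size(self) -> int:
        """Total RME count across all sequence factorizations."""
        return sum(len(f) for f in self.factorizations)

    @property
    def unfolded_length(self) -> int:
        return sum(f.unfolded_length for f in self.factorizations)

    def unfolded_reference(self, idx: int, refs: ReferenceSet) -> str:
        """Unfold factorized reference ``idx`` (cached)."""
        s = self._ref_cache.get(idx)
        if s is None:
            s = unfold(self.factorized_refs[idx], refs)
            self._ref_cache[idx] = s
        return s


def _resolve(ref_id: int, refs: ReferenceSet, fsd: FSD | None) -> str:
    """Unfolded sequence addressed by ``ref_id`` (raw or factorized)."""
    m = len(refs)
    if 0 <= ref_id < m:
        return refs.sequence(ref_id)
    if fsd is not None and 0 <= ref_id - m < len(fsd.factorized_refs):
        # factorized references contain only raw ids, so recursion depth <= 1
        return fsd.unfolded_reference(ref_id - m, refs)
    raise ResolutionError(f"reference id {ref_id} cannot be resolved")


def unfold(f: Factorization, refs: ReferenceSet, fsd: FSD | None = None) -> str:
    """Unfold a factorization: concatenate ``id(s, l) . m`` for every RME."""
    parts: list[str] = []
    for rme in f.rmes:
        base = _resolve(rme.ref_id, refs, fsd)
        if rme.start < 0 or rme.length < 0 or rme.start + rme.length > len(base):
            raise ValueError(
                f"RME {rme} exceeds referenced sequence of length {len(base)}")
        parts.append(base[rme.start:rme.start + rme.length])
        parts.append(rme.mismatch)
    return "".join(parts)


def rme_matches(rme: RME, s: str, refs: ReferenceSet,
                fsd: FSD | None = None, start: int = 0) -> bool:
    """True iff ``s(start, l+1) = id(s, l) . m`` (the matching predicate

    that decides whether an RME from the factorization history can stand in
    for the next index lookup)."""
    base = _resolve(rme.ref_id, refs, fsd)
    l = rme.length
    if rme.start < 0 or rme.start + l > len(base):
        raise ValueError(f"RME {rme} exceeds referenced sequence")
    if start + l + 1 > len(s):
        return False
    return (s[start + l] == rme.mismatch
            and s[start:start + l] == base[rme.start:rme.start + l])
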