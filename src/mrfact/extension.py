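"""Reference extension: multi-reference factorization with one index.

Indexing every reference is the dominant memory cost of multi-reference
factorization.  Reference extension sidesteps it: everything -- the
remaining references and all input sequences -- is first factorized against
the single base reference ``ref_1``, and factorizations are then *rewritten*
against the factorized references.  Identical subsequences tend to be
encoded by identical RMEs, so shared RMEs act as anchors between a
factorized sequence and a factorized reference.

* Right-extension treats RMEs as symbols: a run of consecutively identical
  RMEs shared with a factorized reference is replaced by a single RME into
  that reference's unfolded form, provided the run covers at least two RMEs.
* Left-extension additionally extends character-wise to the left of an
  anchor, comparing the two unfolded sequences; the matched span may start
  mid-RME on the reference side, while on the sequence side whole RMEs are
  replaced.  This uncovers identities that right-extension misses when the
  same subsequence was entered through different factorization contexts.

Both rewrites preserve unfolding exactly and never increase the RME count.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .factorize import FactorizerConfig, factorize_db
from .graph import RMEGraph
from .model import (FSD, RME, Factorization, ManifestEntry, ReferenceSet,
                    offsets, sha1_of, unfold)

_GRAPH_PREDICTORS = ("succ", "posi", "graph")


@dataclass
class ExtensionPlan:
    """Factorized references against the single base reference, plus an
    occurrence index mapping every RME of ``fsd_ref`` to the places where it
    occurs: ``(factorized-ref index, RME ordinal, unfolded char offset)``."""

    base: ReferenceSet
    fsd_ref: list[Factorization]
    unfolded: list[str]
    occ_index: dict[RME, list[tuple[int, int, int]]]
    _arrays: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def n_factorized(self) -> int:
        return len(self.fsd_ref)

    def array(self, r: int) -> np.ndarray:
        arr = self._arrays.get(r)
        if arr is None:
            arr = np.frombuffer(self.unfolded[r].encode("ascii"), dtype=np.uint8)
            self._arrays[r] = arr
        return arr


def build_plan(refs: ReferenceSet | Iterable[tuple[str, str]],
               cfg: FactorizerConfig | None = None) -> ExtensionPlan:
    """Factorize references 2..m against ref_1 and index their RMEs.

    With a single reference the plan is empty and extension degenerates to
    a no-op.  Anchors include the terminal RME of each factorized reference:
    left-extension needs them (the shared RME may be the last one), and for
    right-extension a terminal anchor can never start a run of two.
    """
    cfg = cfg or FactorizerConfig()
    items = refs.items() if isinstance(refs, ReferenceSet) else list(refs)
    if not items:
        raise ValueError("at least one reference is required")
    base = ReferenceSet(items[:1], cfg.index_kind, cfg.k)
    rest = items[1:]
    if rest:
        inner = replace(cfg, extension="none")
        fsd = factorize_db(rest, base, inner)
        fsd_ref = fsd.factorizations
    else:
        fsd_ref = []
    unfolded = [unfold(f, base) for f in fsd_ref]
    occ: dict[RME, list[tuple[int, int, int]]] = {}
    for r, f in enumerate(fsd_ref):
        for j, (rme, off) in enumerate(zip(f.rmes, offsets(f))):
            occ.setdefault(rme, []).append((r, j, off))
    return ExtensionPlan(base, fsd_ref, unfolded, occ)


def right_extend(f: Factorization, plan: ExtensionPlan) -> Factorization:
    """Replace runs of RMEs shared with a factorized reference, left to right.

    At each RME the longest run of consecutively identical RMEs shared with
    any factorized reference is sought (ties: smallest factorized-ref id,
    then smallest offset); a run covering >= 2 RMEs becomes one RME into
    the unfolded factorized reference.
    """
    src = f.rmes
    n = len(src)
    out: list[RME] = []
    i = 0
    while i < n:
        rme = src[i]
        best_t, best_r, best_off = 1, -1, -1
        for r, j, off in plan.occ_index.get(rme, ()):
            fr = plan.fsd_ref[r].rmes
            t = 0
            while i + t < n and j + t < len(fr) and src[i + t] == fr[j + t]:
                t += 1
            if t > best_t:  # first occurrence wins ties (smallest r, then off)
                best_t, best_r, best_off = t, r, off
        if best_t >= 2:
            run = src[i:i + best_t]
            clen = sum(x.length + 1 for x in run)
            out.append(RME(1 + best_r, best_off, clen - 1, run[-1].mismatch))
            i += best_t
        else:
            out.append(rme)
            i += 1
    return Factorization(f.seq_name, out)


def left_extend(f: Factorization, plan: ExtensionPlan) -> Factorization:
    """Extend character-wise leftward from shared anchors, right to left.

    For every occurrence of the current RME in a factorized reference, the
    two unfolded sequences are compared leftward from the anchor; the span
    is snapped to whole-RME boundaries on the sequence side (the reference
    side may start mid-RME) and the longest span wins (ties: smallest
    factorized-ref id, then smallest reference start).  A span covering
    >= 2 RMEs is replaced by one RME into the unfolded reference.

    The scan runs right to left so that leftward extension can reach over
    RMEs not yet rewritten; an anchor whose shared run would extend
    rightward is always discovered at the run's rightmost RME first.
    """
    src = f.rmes
    if not src:
        return Factorization(f.seq_name, [])
    offs = offsets(f)
    uf = unfold(f, plan.base)
    uf_arr = np.frombuffer(uf.encode("ascii"), dtype=np.uint8)
    out_rev: list[RME] = []
    hi = len(src) - 1
    while hi >= 0:
        rme = src[hi]
        off_f = offs[hi]
        end_f = off_f + rme.length + 1
        best = None  # (span_len, r, ref_start, i0)
        for r, j, off_ref in plan.occ_index.get(rme, ()):
            ref_arr = plan.array(r)
            # character-wise leftward extension of the unfolded sequences
            w = min(off_ref, off_f)
            if w:
                a = ref_arr[off_ref - w:off_ref][::-1]
                b = uf_arr[off_f - w:off_f][::-1]
                neq = a != b
                k = int(np.argmax(neq))
                L = k if neq[k] else w
            else:
                L = 0
            i0 = bisect_left(offs, off_f - L, 0, hi + 1)
            if i0 > hi - 1:
                continue  # span must cover at least two RMEs of f
            span_len = end_f - offs[i0]
            ref_start = off_ref - (off_f - offs[i0])
            key = (span_len, -r, -ref_start)
            if best is None or key > (best[0], -best[1], -best[2]):
                best = (span_len, r, ref_start, i0)
        if best is not None:
            span_len, r, ref_start, i0 = best
            out_rev.append(RME(1 + r, ref_start, span_len - 1, rme.mismatch))
            hi = i0 - 1
        else:
            out_rev.append(rme)
            hi -= 1
    out_rev.reverse()
    return Factorization(f.seq_name, out_rev)


def factorize_with_extension(S: Sequence[tuple[str, str]],
                             refs: ReferenceSet | Iterable[tuple[str, str]],
                             cfg: FactorizerConfig | None = None) -> FSD:
    """Full extension pipeline: factorize everything against ref_1, then
    rewrite each sequence factorization by left- or right-extension.

    Only the base reference is ever indexed.  With the graph predictors the
    RME graph is seeded from the factorized references before the input
    sequences are processed.  ``extension == "none"`` falls back to plain
    multi-reference factorization.
    """
    cfg = cfg or FactorizerConfig()
    if cfg.extension == "none":
        return factorize_db(S, refs, cfg)
    items = refs.items() if isinstance(refs, ReferenceSet) else list(refs)
    plan = build_plan(items, cfg)
    inner = replace(cfg, extension="none")

    initial_graph = None
    if cfg.predictor in _GRAPH_PREDICTORS:
        initial_graph = RMEGraph(cfg.window)
        for fref in plan.fsd_ref:
            initial_graph.add(fref)
    fsd_s = factorize_db(S, plan.base, inner, initial_graph=initial_graph)

    extend = left_extend if cfg.extension == "left" else right_extend
    extended = [extend(f, plan) for f in fsd_s.factorizations]

    manifest = [ManifestEntry("raw", 0, plan.base.name(0),
                              len(plan.base.sequence(0)),
                              sha1_of(plan.base.sequence(0)))]
    for r, (fref, uf) in enumerate(zip(plan.fsd_ref, plan.unfolded)):
        manifest.append(ManifestEntry("factorized", 1 + r, fref.seq_name,
                                      len(uf), sha1_of(uf)))
    stats = dict(fsd_s.stats)
    stats["indexes_built"] = plan.base.indexes_built
    stats["rmes_per_sequence"] = [len(f) for f in extended]
    stats["rmes_before_extension"] = [len(f) for f in fsd_s.factorizations]
    from dataclasses import asdict
    return FSD(manifest, plan.fsd_ref, extended, params=asdict(cfg), stats=stats)
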