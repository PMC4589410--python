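# Methods

## The model: referential match entries and minimal parses

A referential match entry (RME) `(id, s, l, m)` encodes `l + 1` characters:
the substring `id(s, l)` of a reference plus one literal character `m`.
A factorization of a sequence is an ordered RME list whose unfolding equals
the sequence; a factorized sequence database (FSD) is a set of such
factorizations sharing one reference manifest. We measure FSD size in
**number of RMEs** — under the assumption that every RME occupies the same
storage, which is how the entries are serialized here. The unfolded
character total (`Σ (l+1)`) is exposed separately; minimizing the RME count
is the optimization target throughout.

The greedy parser (`factorize_optimal`) repeatedly takes the longest prefix
of the remaining input that occurs in any reference and emits
`(id, pos, |pre|, next char)`, consuming `|pre| + 1` characters. Two
boundary conventions make the algorithm total:

- if the entire remaining suffix is matched (`s = pre`), the final RME is
  shortened by one and the suffix's last character becomes the mismatch
  literal, so nothing is consumed twice;
- if no prefix occurs anywhere (not even one character), a zero-length RME
  `(ref_0, 0, 0, first char)` is emitted — dissimilar data degenerates to
  one RME per character.

Greedy longest-match parsing with a per-RME cost of 1 is minimal; the test
suite verifies this against an independent dynamic program
(`minimal_parse_oracle`) that computes `maxmatch(i)` by brute-force
character comparison and takes every transition `i → i + l + 1`,
`l ≤ maxmatch(i)`, at cost 1. The oracle shares no code with the parser
and is intended for inputs of a few hundred characters.

## Index backends

Both backends answer *longest prefix of the query occurring anywhere in
one reference*:

- **esa** — a plain suffix array (numpy prefix-doubling construction,
  O(n log² n); the contract is search exactness, not construction speed).
  The query suffix is located by binary search; the result length is the
  larger LCP with the two neighbouring suffixes, and the smallest position
  within the matching suffix-array interval breaks ties.
- **kmer** — a hash from every k-mer to its sorted occurrence positions.
  The leading k-mer of the query seeds the search and *every* occurrence
  is extended by direct comparison (k = 16 by default, at which k-mer
  occurrence lists in genomic data are short). Matches shorter than k are
  invisible: the result length is 0 or ≥ k, and when ≥ k it equals the
  exact result. Queries shorter than k, and references shorter than k,
  return no match.

Across references, ties on length are broken by the smallest reference id,
then the smallest position. These tie-breaks are not forced by the
algorithm — any longest match preserves minimality — but fixing them makes
every output byte-reproducible, and they reproduce the worked example's
printed positions.

## Prediction: skipping index lookups

`factorize_db` threads a `predict` hook through the parse: a predicted
candidate RME is used *only if it matches the remaining suffix*
(`s(pos, l+1) = id(s, l) ∘ m`), so predictions can never corrupt a
factorization, only save lookups. The previous emitted RME `prme` is
updated after every step (predicted or looked up) and reset at each
sequence start, so the first RME of every sequence always pays one lookup.

- **loma** (local matching): search only reference `prme.id` at positions
  `prme.s + prme.l + 1 + δ` for `δ ∈ [−δ_max, +δ_max]` (δ_max = 10). The
  `+1` aligns the previous mismatch to the reference as if it were a SNP.
  The best direct-comparison match is used if it reaches `l_min` (= 16,
  suppressing spurious short matches); ties go to the later δ in scan
  order. Fast, but a local match may pre-empt a longer one elsewhere —
  optimality is lost.
- **RME graph predictors**: the graph stores the non-terminal RMEs of
  recent factorizations as nodes and consecutive pairs as edges labelled
  with `(factorization, offset)` occurrences. Terminal RMEs are excluded
  because the end-of-sequence convention shortens them — they need not be
  maximal matches, and replaying a non-maximal match would break
  minimality. Any *matching* graph node is automatically a longest match
  (if a longer match existed, the node's own factorization would have used
  it), so graph prediction preserves optimality when the fallback index is
  exact. Three candidate-selection policies are provided: scan all nodes
  (`graph`), successors of `prme` (`succ`), and — keyed by where `prme`'s
  match ended in the reference rather than by `prme`'s identity — `posi`,
  whose candidate set is a superset of `succ`'s. Candidate loops keep the
  last match under the graph's deterministic insertion order; since all
  matching candidates are maximal, the choice cannot change counts, and
  with an exact index the emitted tuples are bit-identical to the base
  configuration (the test suite asserts tuple equality, not just counts).

The graph window keeps the most recent 10 contributing factorizations
(returns diminish beyond that; configurable). Eviction is incremental and
exact: removing a factorization removes exactly its occurrence labels and
any node or edge left unreferenced, which the tests check against a batch
rebuild.

With a k-mer index, `succ`/`posi` still run and still round trip, but the
fallback is inexact, so the optimality guarantee is forfeited — the
configuration is permitted and documented rather than rejected.

## Reference extension

Indexing m references costs m times the memory; extension keeps only one.
All remaining references and all inputs are factorized against `ref_1`
(the first reference in input order; reference-selection heuristics are
out of scope), and each input factorization is then rewritten against the
factorized references:

- **right-extension** treats RMEs as opaque symbols: a run of ≥ 2
  consecutive RMEs identical to a run in a factorized reference is
  replaced by one RME into that reference's unfolded form. The occurrence
  index maps every RME of the factorized references to its positions;
  anchors at terminal RMEs are indexed too (they can never start a run of
  two, so they are harmless here and required below).
- **left-extension** extends character-wise *leftward* from a shared
  anchor, comparing the two unfolded sequences; the matched span may start
  mid-RME on the reference side, while on the sequence side whole RMEs are
  replaced (a span must still cover ≥ 2 of them). The scan runs right to
  left so leftward extension reaches over not-yet-rewritten RMEs;
  rightward whole-RME extension is subsumed, because any run extending
  right from an anchor ends at an RME that itself occurs in the factorized
  reference and is met first. The replacement RME is
  `(id, span start, span length − 1, last char)` — the same
  shorten-by-one convention as the parser's final RME — and the longest
  span wins, ties to the smallest factorized-reference id then smallest
  offset.

Both rewrites preserve unfolding exactly and never increase the RME count;
on the worked example left-extension halves the second sequence's
factorization while right-extension cannot touch it. Extension ids live
above the raw ids: with one raw reference, factorized reference r is id
`1 + r`, and unfolding resolves them through the FSD's
factorized-reference section (recursion depth 1, since factorized
references contain only raw ids).

## File format and hygiene

The FSD file is text, one RME per tab-separated line, with `#REF` manifest
lines carrying the unfolded length and SHA-1 of every reference — raw and
factorized — so unfolding against the wrong reference FASTA fails with a
checksum error (CLI exit code 3) instead of emitting garbage. Sequences
are uppercase `{A,C,G,T,N}`; lowercase input is folded, anything else is a
hard error unless `--sanitize` maps it to N.

## Synthetic populations

The generator draws one uniform base sequence and derives every reference
and every input as an independent mutant (star phylogeny): substitutions
at rate `p_snp` (always to a different base), indel events at rate
`p_indel` with geometric lengths (mean 3). Three presets span the
similarity regimes the method targets: `human-like`
(`p_snp = 10⁻³, p_indel = 10⁻⁴` — population-scale human chromosomes are
SNP-dominated at roughly one variant per kilobase), `at-like`
(`5·10⁻³ / 5·10⁻⁴`), and `yeast-like` (`2·10⁻² / 2·10⁻³`, approaching the
few-percent divergence of yeast genome collections). The star phylogeny is
a deliberate simplification: real populations share variants
(haplotype structure), carry structural variants and N-runs, and human
chromosomes are orders of magnitude longer. Passing tests therefore
demonstrate algorithmic correctness and the *direction* of the
multi-reference effect, not real-data compression magnitudes.

Benchmark scale: the property checks run at desk scale — minimality on
1,000 random instances of ≤ 256 characters; optimality-preservation on
populations of 20 sequences × 20 kb over 3 references and 3 seeds;
reference sweeps on 4-kb populations with 5 references. These sizes were
chosen so the whole suite completes in seconds while every claim is still
exercised on inputs hundreds of RMEs deep.

## Numerical and degenerate-input choices

- Positions are 0-based, intervals half-open; `offset(f, rme_i)` is the
  cumulative size of the preceding RMEs.
- A one-character remainder emits `(ref_0, p, 0, char)` with `p = 0` —
  equivalent to the `s = pre` branch at `|pre| = 1`.
- Empty sequences and empty reference sets are rejected; an empty input
  *database* yields an FSD with a manifest and no factorizations.
- Power-law fits are ordinary least squares on `log(count)` vs `log(n)`;
  R² is reported on the log scale, and constant data returns exponent 0
  with R² = 1 by convention (the fit is exact).
- The graph-shape example carries mismatch characters that appear as
  ASCII codes in some renderings; they are decoded to characters
  (71/67/65 → G/C/A) and the fixture is used for graph-shape checks only,
  never unfolded (its underlying raw sequences are not available).

## Known limitations

- No compressed-suffix-tree backend (the index interface admits one); no
  entropy coding of RMEs — the FSD measures factorization size, not final
  compressed bytes.
- No combined left+right extension and no recursive extension against
  already-extended references.
- Single-threaded; suffix-array construction is O(n log² n), adequate for
  chromosome-arm scale but not optimized for multi-gigabase references.
- Approximate (mismatch-tolerant) matches inside a single RME are out of
  scope.
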