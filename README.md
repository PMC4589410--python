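# mrfact — referential factorization against multiple references

Population-scale sequencing projects produce thousands of genomes that
differ from one another by a fraction of a percent. `mrfact` compresses
such collections by *referential factorization*: each sequence is encoded
as an ordered list of **referential match entries** (RMEs), quadruples
`(id, s, l, m)` that point at a length-`l` match starting at position `s`
of reference `id`, followed by one literal mismatch character `m`. The
*unfolding* of a factorization `f = [rme_1, …, rme_n]`,

```
unfold(f) = id_1(s_1, l_1) ∘ m_1 ∘ … ∘ id_n(s_n, l_n) ∘ m_n ,
```

reproduces the input exactly. With several references `REF = {ref_1, …,
ref_m}` available, a greedy left-to-right parse that always takes the
longest prefix found in *any* reference yields the minimal number of RMEs
(under uniform RME cost). The package implements, on top of that core:

- two index backends for the longest-prefix query — an exact suffix-array
  index (`esa`) and a k-mer seed-and-extend index (`kmer`);
- three **prediction heuristics** that skip index lookups by exploiting
  factorization history: local matching (`loma`) and the RME-graph based
  `succ`/`posi` predictors, the latter two provably optimality-preserving;
- **reference extension** (`left` / `right`): factorize everything against
  a single reference, then rewrite factorizations against the *factorized*
  remaining references, so only one index is ever held in memory;
- a plain-text **FSD** (factorized sequence database) file format with
  checksum-guarded unfolding, a `mrf` command line, and a synthetic
  population generator with human-like / A. thaliana-like / yeast-like
  similarity presets.

## Worked example

The package's running example is one reference and two nearly identical
sequences (the second is the first with one extra leading `A`):

```python
from mrfact import ReferenceSet, factorize_optimal, unfold

ref1 = "AAGCTCGGGAGGTGGCCAGGCGGCAGGAAGGCGCACCC"
s1   = "TAGGAGCTCGGGAGGGCCAGGCGGCAGGAAGGCGCACCC"
s2   = "ATAGGAGCTCGGGAGGGCCAGGCGGCAGGAAGGCGCACCC"

refs = ReferenceSet([("ref1", ref1)])
f1 = factorize_optimal(s1, refs, "s1")
f2 = factorize_optimal(s2, refs, "s2")
print(f1.rmes)
print(f2.rmes)
assert unfold(f1, refs) == s1 and unfold(f2, refs) == s2
```

prints (as `(ref_id, start, length, mismatch)` tuples)

```
[RME(ref_id=0, start=4, length=1, mismatch='A'), RME(ref_id=0, start=7, length=4, mismatch='C'), RME(ref_id=0, start=4, length=8, mismatch='G'), RME(ref_id=0, start=15, length=22, mismatch='C')]
[RME(ref_id=0, start=0, length=1, mismatch='T'), RME(ref_id=0, start=24, length=4, mismatch='G'), RME(ref_id=0, start=3, length=9, mismatch='G'), RME(ref_id=0, start=15, length=22, mismatch='C')]
```

Each 39/40-character sequence is stored as four RMEs. The one-character
shift makes `f1` and `f2` share only their final RME, which is why
right-extension cannot compress `f2` further — but left-extension, which
compares the *unfolded* sequences character-wise leftward from a shared
anchor RME, collapses the last three RMEs of `f2` into a single pointer
into factorized `s1`:

```python
from mrfact import build_plan, left_extend
plan = build_plan([("ref1", ref1), ("s1", s1)])
print(left_extend(f2, plan).rmes)
# [RME(ref_id=0, start=0, length=1, mismatch='T'), RME(ref_id=1, start=1, length=37, mismatch='C')]
```

`ref_id=1` addresses the factorized reference `s1`; `s2` now costs 2 RMEs
instead of 4.

The same workflow from the shell:

```sh
mrf simulate --profile human-like --base-length 20000 --n-refs 5 \
    --n-seqs 20 --seed 7 --out-refs refs.fa --out-seqs seqs.fa
mrf factorize --refs refs.fa --in seqs.fa --out db.fsd --predict succ
mrf stats --fsd db.fsd
mrf unfold --fsd db.fsd --refs refs.fa --out restored.fa
mrf bench --refs refs.fa --in seqs.fa --sweep-refs 1..5
```

`mrf bench` sweeps the number of references and reports the mean RME count
per sequence, which decays like a power law `a · n^b`; the fitted curve is
printed alongside the TSV table.

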