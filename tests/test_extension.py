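"""Reference extension: rewrite of single-reference factorizations against
factorized references, preserving unfolding and never adding RMEs."""

import numpy as np
import pytest

from mrfact import (FSD, FactorizerConfig, RME, ReferenceSet, build_plan,
                    factorize_optimal, factorize_with_extension, left_extend,
                    right_extend, unfold)

from conftest import REF1, S1, S2, mutate_snps, random_dna


@pytest.fixture
def example_plan():
    return build_plan([("ref1", REF1), ("s1", S1)])


class TestBuildPlan:
    def test_single_reference_plan_is_empty(self):
        plan = build_plan([("ref1", REF1)])
        assert plan.n_factorized == 0 and plan.occ_index == {}

    def test_no_references_rejected(self):
        with pytest.raises(ValueError):
            build_plan([])

    def test_worked_example_reference_factorization(self, example_plan):
        assert example_plan.fsd_ref[0].rmes == [
            RME(0, 4, 1, "A"), RME(0, 7, 4, "C"), RME(0, 4, 8, "G"),
            RME(0, 15, 22, "C")]
        assert example_plan.unfolded == [S1]

    def test_occurrence_index_covers_all_rmes(self, example_plan):
        f = example_plan.fsd_ref[0]
        for j, (rme, off) in enumerate(zip(f.rmes, f.offsets())):
            assert (0, j, off) in example_plan.occ_index[rme]


class TestRightExtend:
    def test_single_shared_terminal_rme_leaves_f_unchanged(self, example_plan):
        # s2's factorization shares only its last RME with s1's: a run of
        # one is never rewritten
        base = example_plan.base
        f2 = factorize_optimal(S2, base, "s2")
        assert right_extend(f2, example_plan).rmes == f2.rmes

    def test_shared_prefix_run_collapses(self):
        """A sequence repeating a factorized reference's parse collapses the
        shared run into one RME pointing into the unfolded reference."""
        rng = np.random.default_rng(31)
        ref = random_dna(rng, 500)
        other = mutate_snps(rng, ref, 0.03)
        plan = build_plan([("r", ref), ("o", other)])
        base = plan.base
        f = factorize_optimal(other, base, "dup")
        assert len(f) >= 3
        got = right_extend(f, plan)
        assert len(got) < len(f)
        assert unfold(got, base, _fsd_for(plan)) == other

    def test_count_never_increases(self, small_population):
        refs_items, seqs = small_population
        plan = build_plan(refs_items[:2])
        for name, s in seqs:
            f = factorize_optimal(s, plan.base, name)
            got = right_extend(f, plan)
            assert len(got) <= len(f)
            assert unfold(got, plan.base, _fsd_for(plan)) == s


def _fsd_for(plan):
    """Minimal FSD carrying the plan's factorized references for unfolding."""
    from mrfact import ManifestEntry, sha1_of
    manifest = [ManifestEntry("raw", 0, plan.base.name(0),
                              len(plan.base.sequence(0)),
                              sha1_of(plan.base.sequence(0)))]
    for r, uf in enumerate(plan.unfolded):
        manifest.append(ManifestEntry("factorized", 1 + r,
                                      plan.fsd_ref[r].seq_name, len(uf),
                                      sha1_of(uf)))
    return FSD(manifest, plan.fsd_ref, [])


class TestLeftExtend:
    def test_worked_example_three_rmes_collapse_to_one(self, example_plan):
        f2 = factorize_optimal(S2, example_plan.base, "s2")
        got = left_extend(f2, example_plan)
        assert len(got) == 2
        assert got.rmes[0] == f2.rmes[0]
        replacement = got.rmes[1]
        assert replacement.ref_id == 1  # points into factorized s1
        # the replacement spans the last three original RMEs character-wise
        assert replacement.size == sum(r.size for r in f2.rmes[1:])
        assert unfold(got, example_plan.base, _fsd_for(example_plan)) == S2

    def test_no_shared_rme_leaves_f_unchanged(self):
        plan = build_plan([("r", "ACGTACGTACGTACGT"), ("o", "ACGTACGTACGTAGGT")])
        f = factorize_optimal("TTTTTTTT", plan.base, "x")
        assert left_extend(f, plan).rmes == f.rmes

    def test_round_trip_on_population(self, small_population):
        refs_items, seqs = small_population
        plan = build_plan(refs_items[:3])
        fsd = _fsd_for(plan)
        for name, s in seqs:
            f = factorize_optimal(s, plan.base, name)
            got = left_extend(f, plan)
            assert len(got) <= len(f)
            assert unfold(got, plan.base, fsd) == s

    def test_left_at_most_right_on_shifted_duplicate(self, example_plan):
        """The worked example's pattern: a one-character shift hides the
        similarity from RME-symbol matching but not from character-wise
        leftward extension."""
        f2 = factorize_optimal(S2, example_plan.base, "s2")
        left = left_extend(f2, example_plan)
        right = right_extend(f2, example_plan)
        assert len(left) < len(right)


class TestFactorizeWithExtension:
    def test_extension_none_equals_plain_db(self, small_population):
        refs_items, seqs = small_population
        from mrfact import factorize_db
        plain = factorize_db(seqs, ReferenceSet(refs_items))
        viaext = factorize_with_extension(seqs, refs_items, FactorizerConfig())
        assert [f.rmes for f in plain.factorizations] == \
            [f.rmes for f in viaext.factorizations]

    def test_worked_example_left_mode(self):
        fsd = factorize_with_extension(
            [("s2", S2)], [("ref1", REF1), ("s1", S1)],
            FactorizerConfig(extension="left"))
        assert len(fsd.factorizations[0]) == 2
        kinds = [e.kind for e in fsd.manifest]
        assert kinds == ["raw", "factorized"]
        base = ReferenceSet([("ref1", REF1)])
        assert unfold(fsd.factorizations[0], base, fsd) == S2

    @pytest.mark.parametrize("mode", ["left", "right"])
    def test_round_trip_and_monotonicity(self, small_population, mode):
        refs_items, seqs = small_population
        cfg = FactorizerConfig(extension=mode)
        fsd = factorize_with_extension(seqs, refs_items, cfg)
        base = ReferenceSet(refs_items[:1])
        for (name, s), f, before in zip(seqs, fsd.factorizations,
                                        fsd.stats["rmes_before_extension"]):
            assert unfold(f, base, fsd) == s
            assert len(f) <= before

    def test_only_one_reference_index_is_built(self, small_population):
        """The memory contract: with extension, only ref_1 is indexed even
        though five references contribute."""
        refs_items, seqs = small_population
        refs = ReferenceSet(refs_items)
        fsd = factorize_with_extension(seqs, refs, FactorizerConfig(extension="left"))
        assert refs.indexes_built == 0
        assert fsd.stats["indexes_built"] == 1

    @pytest.mark.parametrize("predictor", ["succ", "posi"])
    def test_graph_predictors_compose_with_extension(self, small_population,
                                                     predictor):
        refs_items, seqs = small_population
        cfg = FactorizerConfig(predictor=predictor, extension="right")
        fsd = factorize_with_extension(seqs, refs_items, cfg)
        base = ReferenceSet(refs_items[:1])
        for (name, s), f in zip(seqs, fsd.factorizations):
            assert unfold(f, base, fsd) == s
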