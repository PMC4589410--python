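"""Behaviour of the predict functions: locality window, graph scans,
successor and position candidate sets, and soundness of every candidate."""

import numpy as np
import pytest

from mrfact import (FactorizerConfig, Prediction, RME, RMEGraph,
                    ReferenceSet, factorize_db, factorize_optimal,
                    predict_graph_all, predict_loma, predict_posi,
                    predict_succ, rme_matches)

from conftest import F1_RMES, REF1, S1, mutate_snps, random_dna


class TestLoma:
    REF = "AAAACCCCGGGGTTTT"

    def test_none_at_sequence_start(self):
        refs = ReferenceSet([("r", self.REF)])
        assert predict_loma("ACGT", 0, None, refs).candidate is None

    def test_no_valid_position_past_reference_end(self):
        refs = ReferenceSet([("r", self.REF)])
        prme = RME(0, 10, 5, "T")  # ends at the last reference position
        got = predict_loma("TTTT", 0, prme, refs, delta_max=0, l_min=1)
        assert got.candidate is None

    def test_snp_continuation_found_at_delta_zero(self):
        # sequence continues the reference after prme with one SNP
        refs = ReferenceSet([("r", self.REF)])
        prme = RME(0, 0, 3, "G")  # consumed AAAA+G; next ref position is 5
        s_rest = self.REF[5:11] + "A"  # CCCGGG then a SNP
        got = predict_loma(s_rest, 0, prme, refs, delta_max=10, l_min=4)
        assert got.candidate == RME(0, 5, 6, "A")
        assert got.lookup_avoided

    def test_matches_below_l_min_rejected(self):
        refs = ReferenceSet([("r", self.REF)])
        prme = RME(0, 0, 3, "G")
        s_rest = self.REF[5:8] + "AAAAAA"  # no window alignment matches 8 chars
        got = predict_loma(s_rest, 0, prme, refs, delta_max=10, l_min=8)
        assert got.candidate is None

    def test_candidate_never_shorter_than_l_min(self):
        rng = np.random.default_rng(2)
        ref = random_dna(rng, 500)
        s = mutate_snps(rng, ref, 0.05)
        refs = ReferenceSet([("r", ref)])
        fsd = factorize_db([("s", s)], refs,
                           FactorizerConfig(predictor="loma", l_min=6))
        # re-run the predictor over the emitted parse and check lengths
        pos = 0
        prme = None
        for rme in fsd.factorizations[0].rmes:
            if prme is not None:
                got = predict_loma(s, pos, prme, refs, 10, 6)
                if got.candidate is not None:
                    assert got.candidate.length >= 6
            pos += rme.size
            prme = rme


class TestGraphAll:
    def test_empty_graph_predicts_nothing(self, single_ref):
        got = predict_graph_all(S1, 0, None, single_ref, RMEGraph())
        assert got == Prediction(None, False)

    def test_first_node_of_prior_factorization_matches(self, single_ref):
        g = RMEGraph().add(F1_RMES)
        got = predict_graph_all(S1, 0, None, single_ref, g)
        assert got.candidate == RME(0, 4, 1, "A")

    def test_counts_equal_base_on_population(self, small_population):
        refs_items, seqs = small_population
        base = factorize_db(seqs, ReferenceSet(refs_items))
        got = factorize_db(seqs, ReferenceSet(refs_items),
                           FactorizerConfig(predictor="graph"))
        assert [len(f) for f in got.factorizations] == \
            [len(f) for f in base.factorizations]


class TestSuccAndPosi:
    def test_unknown_prme_has_no_successors(self, single_ref):
        g = RMEGraph().add(F1_RMES)
        stranger = RME(0, 30, 2, "N")
        assert predict_succ(S1, 0, stranger, single_ref, g).candidate is None
        assert predict_posi(S1, 2, stranger, single_ref, g).candidate is None

    def test_succ_predicts_interior_rmes_of_duplicate(self, single_ref):
        g = RMEGraph().add(F1_RMES)
        # after the first RME of s1, the second is a graph successor
        got = predict_succ(S1, 2, RME(0, 4, 1, "A"), single_ref, g)
        assert got.candidate == RME(0, 7, 4, "C")

    def test_posi_predicts_where_succ_fails(self):
        """Two sequences share a deviation at the same reference position
        but reach it through different preceding RMEs: SUCC has no edge
        from the new predecessor, POSI keys on the reference end position."""
        rng = np.random.default_rng(21)
        ref = random_dna(rng, 400)
        snp1 = "T" if ref[200] != "T" else "A"
        snp2 = "T" if ref[300] != "T" else "A"
        core = snp1 + ref[201:300] + snp2 + ref[301:]
        sa = ref[:200] + core
        head_b = mutate_snps(rng, ref[:100], 0.08) + ref[100:200]
        assert head_b != ref[:200]
        sb = head_b + core
        refs = ReferenceSet([("r", ref)])
        fa = factorize_optimal(sa, refs, "a")
        fb = factorize_optimal(sb, refs, "b")
        shared = RME(0, 201, 99, snp2)
        assert fa.rmes[0] == RME(0, 0, 200, snp1)
        assert fa.rmes[1] == shared
        g = RMEGraph().add(fa)
        j = fb.rmes.index(shared)
        prme_b = fb.rmes[j - 1]
        pos_b = sum(r.size for r in fb.rmes[:j])
        # predecessors differ, but both end at reference position 201
        assert prme_b != fa.rmes[0]
        assert prme_b.ref_end == fa.rmes[0].ref_end == 201
        succ = predict_succ(sb, pos_b, prme_b, refs, g)
        posi = predict_posi(sb, pos_b, prme_b, refs, g)
        assert succ.candidate is None
        assert posi.candidate == shared

    def test_succ_candidates_subset_of_posi_candidates(self, small_population):
        refs_items, seqs = small_population
        fsd = factorize_db(seqs, ReferenceSet(refs_items))
        g = RMEGraph(window=None)
        for f in fsd.factorizations:
            g.add(f)
        checked = 0
        for node in g.nodes():
            succ = set(g.successors_of(node))
            posi = set(g.successors_by_end_pos(node.ref_id, node.ref_end))
            assert succ <= posi
            checked += bool(succ)
        assert checked > 0

    def test_every_candidate_is_sound(self, small_population):
        """Any non-none prediction satisfies the matching predicate against
        the remaining suffix, for all three graph predictors."""
        refs_items, seqs = small_population
        refs = ReferenceSet(refs_items)
        fsd = factorize_db(seqs[:3], refs)
        g = RMEGraph(window=None)
        for f in fsd.factorizations:
            g.add(f)
        name, s = seqs[3]
        f = factorize_optimal(s, refs)
        pos = 0
        prme = None
        for rme in f.rmes:
            if prme is not None:
                for fn in (predict_graph_all, predict_succ, predict_posi):
                    got = fn(s, pos, prme, refs, g)
                    if got.candidate is not None:
                        assert rme_matches(got.candidate, s, refs, start=pos)
            pos += rme.size
            prme = rme
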