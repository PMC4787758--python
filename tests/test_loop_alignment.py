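import numpy as np
import pytest

from star3d.basepair_annotation import BasePair
from star3d.consensus_tree import consensus_from_clique
from star3d.geometry import RigidTransform, random_rigid_transform
from star3d.loop_alignment import (FORBIDDEN, LoopPair, ScoringParams, align_loop_pair,
                                   alpha, beta, extract_loop_pairs)
from star3d.stack_matching import EStack, EStackPair
from star3d.synthetic_fixtures import TopologySpec, build_structure

from conftest import chain_from_points
from oracles import NEG, best_affine_alignment_score

PARAMS = ScoringParams()


def simple_tree(chain, intervals):
    S = [EStackPair(EStack(*iv), EStack(*iv), 0.0, RigidTransform.identity())
         for iv in intervals]
    return consensus_from_clique(list(range(len(S))), S, chain, chain)


class TestAlpha:
    @pytest.mark.parametrize("d,expected", [
        (0.0, PARAMS.match_score),
        (1.9, PARAMS.match_score),
        (2.0, 0.5 * PARAMS.match_score),
        (3.0, 0.5 * PARAMS.match_score),
        (4.0, PARAMS.mismatch_score),
        (7.9, PARAMS.mismatch_score),
        (8.0, FORBIDDEN),
        (8.5, FORBIDDEN),
    ])
    def test_bands(self, d, expected):
        assert alpha(d, PARAMS) == expected


class TestExtractLoopPairs:
    def test_single_stem_hairpin_gives_three_slots(self):
        chain = build_structure(TopologySpec(bracket="..((((....)))).."))
        tree = simple_tree(chain, [(3, 14, 4)])
        loops = extract_loop_pairs(tree)
        assert [(lp.seg_a, lp.context) for lp in loops] == [
            ((1, 2), "exterior"), ((7, 10), "hairpin"), ((15, 16), "exterior")]

    def test_two_juxtaposed_children(self):
        chain = build_structure(TopologySpec(bracket="..((((....))))..(((......))).."))
        tree = simple_tree(chain, [(3, 14, 4), (17, 28, 3)])
        loops = extract_loop_pairs(tree)
        assert [lp.seg_a for lp in loops] == [
            (1, 2), (7, 10), (15, 16), (20, 25), (29, 30)]
        assert [lp.context for lp in loops] == [
            "exterior", "hairpin", "exterior", "hairpin", "exterior"]

    def test_empty_consensus_gives_whole_chain_loop(self):
        chain = build_structure(TopologySpec(bracket="((((....))))"))
        tree = simple_tree(chain, [])
        loops = extract_loop_pairs(tree)
        assert [lp.seg_a for lp in loops] == [(1, 12)]

    def test_partial_stack_coverage_extends_the_hairpin(self):
        # consensus covers only the outer 2 pairs; the rest is loop
        chain = build_structure(TopologySpec(bracket="((((....))))"))
        tree = simple_tree(chain, [(1, 12, 2)])
        loops = extract_loop_pairs(tree)
        assert [lp.seg_a for lp in loops] == [(1, 0), (3, 10), (13, 12)]


class TestBeta:
    def test_no_partners_gives_zero(self, hairpin_chain):
        assert beta(6, 6, hairpin_chain, hairpin_chain, [], [],
                    RigidTransform.identity(), PARAMS) == 0.0

    def test_single_matching_partner(self, hairpin_chain):
        lp = [BasePair(6, 11)]
        bonus = beta(6, 6, hairpin_chain, hairpin_chain, lp, lp,
                     RigidTransform.identity(), PARAMS)
        assert bonus == PARAMS.pair_bonus

    def test_distant_partner_is_invalid(self, hairpin_chain):
        moved = hairpin_chain.transformed(
            RigidTransform(np.eye(3), [100.0, 0.0, 0.0]))
        bonus = beta(6, 6, hairpin_chain, moved, [BasePair(6, 11)], [BasePair(6, 11)],
                     RigidTransform.identity(), PARAMS)
        assert bonus == 0.0

    def test_bipartite_matching_counts_best_assignment(self, hairpin_chain):
        # A-side residue 6 pairs with 2 and 11 (different edges); B-side the same.
        lp_a = [BasePair(2, 6, edge3="Hoogsteen"), BasePair(6, 11, edge5="WC")]
        bonus = beta(6, 6, hairpin_chain, hairpin_chain, lp_a, lp_a,
                     RigidTransform.identity(), PARAMS)
        assert bonus == 2 * PARAMS.pair_bonus


class TestAlignLoopPair:
    def test_empty_against_nonempty_is_pure_gap(self, hairpin_chain):
        lp = LoopPair((1, 0), (5, 8), "hairpin")
        aln = align_loop_pair(lp, hairpin_chain, hairpin_chain,
                              RigidTransform.identity(), PARAMS)
        assert aln.score == pytest.approx(PARAMS.gap_open + 4 * PARAMS.gap_extend)
        assert aln.columns == [(None, 5), (None, 6), (None, 7), (None, 8)]

    def test_both_empty_is_trivial(self, hairpin_chain):
        lp = LoopPair((3, 2), (9, 8), "hairpin")
        aln = align_loop_pair(lp, hairpin_chain, hairpin_chain,
                              RigidTransform.identity(), PARAMS)
        assert aln.score == 0.0 and aln.columns == [] and aln.cells == 0

    def test_identical_segments_match_everywhere(self, hairpin_chain):
        lp = LoopPair((5, 8), (5, 8), "hairpin")
        aln = align_loop_pair(lp, hairpin_chain, hairpin_chain,
                              RigidTransform.identity(), PARAMS)
        assert aln.columns == [(5, 5), (6, 6), (7, 7), (8, 8)]
        assert aln.score == pytest.approx(4 * PARAMS.match_score)

    @pytest.mark.parametrize("seed", range(15))
    def test_score_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(1, 7, size=2)
        A = chain_from_points(rng.normal(scale=4.0, size=(int(n1), 3)))
        B = chain_from_points(rng.normal(scale=4.0, size=(int(n2), 3)))
        tf = random_rigid_transform(rng, max_translation=3.0)
        lp = LoopPair((1, int(n1)), (1, int(n2)), "exterior")
        aln = align_loop_pair(lp, A, B, tf, PARAMS)

        # independent substitution matrix from explicit window arithmetic
        sub = np.zeros((int(n1), int(n2)))
        for i in range(int(n1)):
            for j in range(int(n2)):
                offs = [o for o in (-1, 0, 1) if 0 <= i + o < n1 and 0 <= j + o < n2]
                pa = tf.apply(A.rep_points([i + o + 1 for o in offs]))
                pb = B.rep_points([j + o + 1 for o in offs])
                d = np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1)))
                if d >= 2 * PARAMS.r_c:
                    sub[i, j] = NEG
                elif d >= PARAMS.r_c:
                    sub[i, j] = PARAMS.mismatch_score
                elif d >= 0.5 * PARAMS.r_c:
                    sub[i, j] = 0.5 * PARAMS.match_score
                else:
                    sub[i, j] = PARAMS.match_score
        expected = best_affine_alignment_score(sub, PARAMS.gap_open, PARAMS.gap_extend)
        assert aln.score == pytest.approx(expected, abs=1e-9)

    def test_columns_strictly_monotone(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            n1, n2 = rng.integers(1, 8, size=2)
            A = chain_from_points(rng.normal(scale=5.0, size=(int(n1), 3)))
            B = chain_from_points(rng.normal(scale=5.0, size=(int(n2), 3)))
            lp = LoopPair((1, int(n1)), (1, int(n2)), "exterior")
            aln = align_loop_pair(lp, A, B, RigidTransform.identity(), PARAMS)
            seq_a = [a for a, _ in aln.columns if a is not None]
            seq_b = [b for _, b in aln.columns if b is not None]
            assert seq_a == sorted(set(seq_a)) and seq_b == sorted(set(seq_b))
            aligned = [c for c in aln.columns if None not in c]
            assert len(aligned) <= min(n1, n2)
            assert aln.cells == n1 * n2

    def test_score_invariant_under_joint_transform(self):
        rng = np.random.default_rng(21)
        A = chain_from_points(rng.normal(scale=4.0, size=(5, 3)))
        B = chain_from_points(rng.normal(scale=4.0, size=(6, 3)))
        anchor = random_rigid_transform(rng, max_translation=2.0)
        lp = LoopPair((1, 5), (1, 6), "exterior")
        s0 = align_loop_pair(lp, A, B, anchor, PARAMS).score
        g = random_rigid_transform(rng)
        A2 = A.transformed(g)
        B2 = B.transformed(g)
        # conjugate the anchor so the relative geometry is unchanged
        anchor2 = g.compose(anchor).compose(g.inverse())
        s1 = align_loop_pair(lp, A2, B2, anchor2, PARAMS).score
        assert s0 == pytest.approx(s1, abs=1e-9)
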