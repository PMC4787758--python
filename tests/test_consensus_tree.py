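import networkx as nx
import numpy as np
import pytest

from star3d.basepair_annotation import BasePair
from star3d.consensus_tree import (LemmaViolationError, StackRelation,
                                   build_compat_graph, classify_relation,
                                   compatible, consensus_from_clique,
                                   demoted_pairs, maximum_clique,
                                   tree_debug_text)
from star3d.geometry import RigidTransform
from star3d.stack_matching import EStack, EStackPair
from star3d.synthetic_fixtures import TopologySpec, build_structure

from oracles import max_clique_size

NESTED_BRACKET = "(((..((((....))))..)))"


@pytest.fixture(scope="module")
def nested_chain():
    return build_structure(TopologySpec(bracket=NESTED_BRACKET))


def estack_pair(qa, qb=None, rmsd=0.0):
    return EStackPair(EStack(*qa), EStack(*(qb or qa)), rmsd,
                      RigidTransform.identity())


class TestClassifyRelation:
    @pytest.mark.parametrize("q1,q2,expected", [
        ((1, 20, 3), (5, 15, 2), StackRelation.ENCLOSES),
        ((5, 15, 2), (1, 20, 3), StackRelation.ENCLOSED_BY),
        ((1, 8, 2), (10, 20, 3), StackRelation.BEFORE),
        ((10, 20, 3), (1, 8, 2), StackRelation.AFTER),
        ((1, 10, 4), (3, 12, 4), StackRelation.OVERLAP),
    ])
    def test_examples(self, q1, q2, expected):
        assert classify_relation(EStack(*q1), EStack(*q2)) is expected

    def test_enclosure_is_relative_to_innermost_pair(self):
        # [5, 15] touches the innermost pair (4, 17) of (1, 20, l=4): overlap
        assert classify_relation(EStack(1, 20, 4), EStack(4, 17, 2)) \
            is StackRelation.OVERLAP
        assert classify_relation(EStack(1, 20, 3), EStack(4, 17, 2)) \
            is StackRelation.ENCLOSES

    def test_self_relation_undefined(self):
        with pytest.raises(ValueError):
            classify_relation(EStack(1, 10, 2), EStack(1, 10, 2))


class TestCompatGraph:
    def nested_pairs(self):
        return [estack_pair((1, 22, 3)), estack_pair((6, 17, 4))]

    def test_shared_transform_creates_edge(self, nested_chain):
        S = self.nested_pairs()
        g = build_compat_graph(S, nested_chain, nested_chain, r_c=4.0)
        assert g.has_edge(0, 1)

    def test_displaced_partner_breaks_edge(self, nested_chain):
        S = self.nested_pairs()
        moved = build_structure(TopologySpec(bracket=NESTED_BRACKET))
        for res in moved.residues[5:17]:      # inner stack residues 6..17
            for name in res.atoms:
                res.atoms[name] = res.atoms[name] + np.array([20.0, 0, 0])
            res.rep_point = res.rep_point + np.array([20.0, 0, 0])
        g = build_compat_graph(S, nested_chain, moved, r_c=4.0)
        assert not g.has_edge(0, 1)

    def test_relation_mismatch_breaks_edge(self):
        s1 = EStackPair(EStack(1, 22, 3), EStack(1, 8, 3), 0.0, RigidTransform.identity())
        s2 = EStackPair(EStack(6, 17, 4), EStack(10, 20, 4), 0.0, RigidTransform.identity())
        assert not compatible(s1, s2)   # encloses in A but juxtaposed in B

    def test_overlap_never_connected(self, nested_chain):
        S = [estack_pair((1, 22, 3)), estack_pair((2, 21, 3))]
        g = build_compat_graph(S, nested_chain, nested_chain, r_c=100.0)
        assert not g.has_edge(0, 1)


class TestMaximumClique:
    def test_triangle(self):
        g = nx.complete_graph(3)
        assert maximum_clique(g) == [0, 1, 2]

    def test_path_graph_gives_two(self):
        g = nx.path_graph(3)
        assert len(maximum_clique(g)) == 2

    def test_empty_graph(self):
        assert maximum_clique(nx.Graph()) == []

    def test_isolated_vertices_give_singleton(self):
        g = nx.Graph()
        g.add_nodes_from([0, 1, 2])
        assert len(maximum_clique(g)) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_size_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 16))
        g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(0, 2**31)))
        assert len(maximum_clique(g)) == max_clique_size(n, g.edges)

    def test_quality_tiebreak_prefers_longer_stacks(self):
        S = [estack_pair((1, 10, 2)), estack_pair((20, 40, 5)),
             estack_pair((50, 70, 3))]
        g = nx.Graph()
        g.add_nodes_from([0, 1, 2])
        assert maximum_clique(g, S) == [1]


class TestConsensusFromClique:
    def test_enclosure_chain(self, nested_chain):
        S = [estack_pair((1, 22, 3)), estack_pair((6, 17, 4))]
        tree = consensus_from_clique([0, 1], S, nested_chain, nested_chain)
        assert len(tree.root.children) == 1
        child = tree.root.children[0]
        assert child.a == EStack(1, 22, 3)
        assert len(child.children) == 1
        assert child.children[0].a == EStack(6, 17, 4)
        assert tree.rmsd < 1e-9

    def test_juxtaposed_children_ordered(self, nested_chain):
        S = [estack_pair((10, 20, 2)), estack_pair((1, 8, 2))]
        tree = consensus_from_clique([0, 1], S, nested_chain, nested_chain)
        assert [c.a.b for c in tree.root.children] == [1, 10]

    def test_empty_clique_gives_root_only(self, nested_chain):
        S = [estack_pair((1, 22, 3))]
        tree = consensus_from_clique([], S, nested_chain, nested_chain)
        assert tree.root.children == []
        assert np.allclose(tree.transform.rotation, np.eye(3))

    def test_incompatible_sides_raise_lemma_violation(self, nested_chain):
        s1 = EStackPair(EStack(1, 22, 3), EStack(1, 8, 3), 0.0, RigidTransform.identity())
        s2 = EStackPair(EStack(6, 17, 4), EStack(10, 20, 4), 0.0, RigidTransform.identity())
        with pytest.raises(LemmaViolationError):
            consensus_from_clique([0, 1], [s1, s2], nested_chain, nested_chain)

    def test_demoted_pairs_are_uncovered_nested(self, nested_chain):
        S = [estack_pair((6, 17, 4))]
        tree = consensus_from_clique([0], S, nested_chain, nested_chain)
        nested = [BasePair(1, 22), BasePair(2, 21), BasePair(3, 20),
                  BasePair(6, 17), BasePair(7, 16), BasePair(8, 15), BasePair(9, 14)]
        left_out = demoted_pairs(tree, nested, "a")
        assert {p.key for p in left_out} == {(1, 22), (2, 21), (3, 20)}

    def test_debug_text_mentions_every_node(self, nested_chain):
        S = [estack_pair((1, 22, 3)), estack_pair((6, 17, 4))]
        tree = consensus_from_clique([0, 1], S, nested_chain, nested_chain)
        text = tree_debug_text(tree)
        assert "root" in text and "s0" in text and "s1" in text
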