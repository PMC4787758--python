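"""Consensus assembly: order e-stack pairs into a tree-like anchor.

Within one chain two e-stacks either overlap, enclose one another, or
are juxtaposed.  Two e-stack pairs are compatible when they relate the
same way (and not by overlap) in both chains; a compatibility-graph
edge additionally requires the joint Kabsch RMSD of the concatenated
coordinates to stay below r_c, i.e. the two pairs share one rigid
transform.  The maximum clique of this graph yields the consensus: an
ordered tree (pseudo-root spanning the whole chain) that is provably
identical on the A side and the B side, and whose union of stack
residues defines the global anchor transform.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .geometry import RigidTransform, kabsch
from .stack_matching import EStack, EStackPair, estack_residues

__all__ = ["StackRelation", "classify_relation", "build_compat_graph",
           "maximum_clique", "consensus_from_clique", "ConsensusNode",
           "ConsensusTree", "LemmaViolationError", "demoted_pairs",
           "tree_signature"]


class StackRelation(enum.Enum):
    OVERLAP = "overlap"
    ENCLOSES = "encloses"
    ENCLOSED_BY = "enclosed_by"
    BEFORE = "before_juxtaposed"
    AFTER = "after_juxtaposed"


_MIRROR = {StackRelation.ENCLOSES: StackRelation.ENCLOSED_BY,
           StackRelation.ENCLOSED_BY: StackRelation.ENCLOSES,
           StackRelation.BEFORE: StackRelation.AFTER,
           StackRelation.AFTER: StackRelation.BEFORE,
           StackRelation.OVERLAP: StackRelation.OVERLAP}


class LemmaViolationError(AssertionError):
    """A compatible clique produced differing A/B trees (must be unreachable)."""


def _encloses(q1: EStack, q2: EStack) -> bool:
    """q2 sits strictly inside q1's innermost base pair."""
    return q2.b > q1.b + q1.l - 1 and q2.e < q1.e - q1.l + 1


def classify_relation(q1: EStack, q2: EStack) -> StackRelation:
    if q1 == q2:
        raise ValueError("relation of an e-stack with itself is undefined")
    if _encloses(q1, q2):
        return StackRelation.ENCLOSES
    if _encloses(q2, q1):
        return StackRelation.ENCLOSED_BY
    if q1.e < q2.b:
        return StackRelation.BEFORE
    if q2.e < q1.b:
        return StackRelation.AFTER
    return StackRelation.OVERLAP


def compatible(s_i: EStackPair, s_j: EStackPair) -> bool:
    if s_i.a == s_j.a or s_i.b == s_j.b:
        return False        # sharing an e-stack means overlapping residues
    rel_a = classify_relation(s_i.a, s_j.a)
    rel_b = classify_relation(s_i.b, s_j.b)
    return rel_a == rel_b and rel_a is not StackRelation.OVERLAP


def build_compat_graph(S: list[EStackPair], chain_a, chain_b,
                       r_c: float = 4.0) -> nx.Graph:
    """Vertices are e-stack pair indices; edges join compatible pairs
    whose concatenated coordinates superpose jointly within r_c."""
    graph = nx.Graph()
    graph.add_nodes_from(range(len(S)))
    coords_a = [chain_a.rep_points(estack_residues(s.a)) for s in S]
    coords_b = [chain_b.rep_points(estack_residues(s.b)) for s in S]
    for i in range(len(S)):
        for j in range(i + 1, len(S)):
            if not compatible(S[i], S[j]):
                continue
            pa = np.vstack([coords_a[i], coords_a[j]])
            pb = np.vstack([coords_b[i], coords_b[j]])
            _, joint_rmsd = kabsch(pa, pb)
            if joint_rmsd < r_c:
                graph.add_edge(i, j, rmsd=joint_rmsd)
    return graph


def maximum_clique(graph: nx.Graph, S: list[EStackPair] | None = None) -> list[int]:
    """Best maximum clique via Bron-Kerbosch enumeration (networkx).

    Among maximum-cardinality cliques, prefer the largest total aligned
    stack length, then the smallest total RMSD, then the lexicographically
    smallest vertex set.  An empty graph yields an empty clique; isolated
    vertices yield singletons.
    """
    if graph.number_of_nodes() == 0:
        return []

    def quality(clique):
        size = len(clique)
        total_l = sum(S[v].a.l for v in clique) if S is not None else 0
        total_rmsd = sum(S[v].rmsd for v in clique) if S is not None else 0.0
        return (size, total_l, -total_rmsd, tuple(-v for v in sorted(clique)))

    best = max(nx.find_cliques(graph), key=quality)
    return sorted(best)


@dataclass
class ConsensusNode:
    member: int | None            # index into S; None for the pseudo-root
    a: EStack
    b: EStack
    children: list["ConsensusNode"] = field(default_factory=list)

    @property
    def is_root(self) -> bool:
        return self.member is None


@dataclass
class ConsensusTree:
    root: ConsensusNode
    members: list[int]
    pairs: list[EStackPair]       # clique members, indexable by position
    transform: RigidTransform
    rmsd: float = 0.0

    def nodes(self) -> list[ConsensusNode]:
        out = []

        def walk(node):
            out.append(node)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out


def _build_side_tree(intervals: list[EStack], n: int) -> dict:
    """parent[index] (None for root) + ordered children lists, by enclosure."""
    root = EStack(0, n + 1, 0)
    parent: dict[int, int | None] = {}
    for i, q in enumerate(intervals):
        best, best_span = None, None
        for j, other in enumerate(intervals):
            if i != j and _encloses(other, q):
                span = other.e - other.b
                if best_span is None or span < best_span:
                    best, best_span = j, span
        parent[i] = best
    children: dict[int | None, list[int]] = {None: []}
    for i in range(len(intervals)):
        children.setdefault(i, [])
    for i, p in parent.items():
        children.setdefault(p, []).append(i)
    for p in children:
        children[p].sort(key=lambda i: intervals[i].b)   # juxtaposition order
    return children


def consensus_from_clique(clique: list[int], S: list[EStackPair],
                          chain_a, chain_b) -> ConsensusTree:
    """Build the ordered consensus tree for a pairwise-compatible clique.

    The A-side tree is built by direct enclosure and juxtaposition; the
    B-side tree is built independently and must be identical (the
    executable form of the identical-tree lemma).  The anchor transform
    is a fresh Kabsch fit over all consensus stack residues; an empty
    clique degrades to a root-only tree with the identity transform.
    """
    members = sorted(clique)
    pairs = [S[v] for v in members]
    n_a, n_b = len(chain_a), len(chain_b)
    kids_a = _build_side_tree([p.a for p in pairs], n_a)
    kids_b = _build_side_tree([p.b for p in pairs], n_b)
    if kids_a != kids_b:
        raise LemmaViolationError(
            "A-side and B-side consensus trees differ for a compatible clique")

    root = ConsensusNode(None, EStack(0, n_a + 1, 0), EStack(0, n_b + 1, 0))

    def attach(parent_node, key):
        for i in kids_a.get(key, []):
            node = ConsensusNode(members[i], pairs[i].a, pairs[i].b)
            parent_node.children.append(node)
            attach(node, i)

    attach(root, None)

    if pairs:
        coords_a = np.vstack([chain_a.rep_points(estack_residues(p.a)) for p in pairs])
        coords_b = np.vstack([chain_b.rep_points(estack_residues(p.b)) for p in pairs])
        transform, rmsd = kabsch(coords_a, coords_b)
    else:
        transform, rmsd = RigidTransform.identity(), 0.0
    return ConsensusTree(root=root, members=members, pairs=pairs,
                         transform=transform, rmsd=rmsd)


def demoted_pairs(tree: ConsensusTree, nested, side: str) -> list:
    """Nested canonical pairs not covered by the consensus stacks.

    These re-enter the computation as loop interactions ("side" selects
    the chain: 'a' or 'b').
    """
    covered = set()
    for p in tree.pairs:
        q = p.a if side == "a" else p.b
        for t in range(q.l):
            covered.add((q.b + t, q.e - t))
    return [bp for bp in nested if bp.key not in covered]


def tree_signature(tree: ConsensusTree, side: str = "a") -> tuple:
    """Pre-order (member, depth) signature used by the lemma property tests."""
    out = []

    def walk(node, depth):
        out.append((node.member, depth))
        for c in node.children:
            walk(c, depth + 1)

    walk(tree.root, 0)
    return tuple(out)


def graph_debug_text(graph: nx.Graph, S: list[EStackPair]) -> str:
    lines = [f"vertices: {graph.number_of_nodes()}"]
    for v in graph.nodes:
        s = S[v]
        lines.append(f"  v{v}: A({s.a.b},{s.a.e},l={s.a.l}) "
                     f"B({s.b.b},{s.b.e},l={s.b.l}) rmsd={s.rmsd:.3f}")
    lines.append(f"edges: {graph.number_of_edges()}")
    for u, v, data in graph.edges(data=True):
        lines.append(f"  v{u} -- v{v} joint_rmsd={data.get('rmsd', float('nan')):.3f}")
    return "\n".join(lines)


def tree_debug_text(tree: ConsensusTree) -> str:
    lines = []

    def walk(node, depth):
        tag = "root" if node.is_root else f"s{node.member}"
        lines.append("  " * depth +
                     f"{tag} A[{node.a.b},{node.a.e}]x{node.a.l} "
                     f"B[{node.b.b},{node.b.e}]x{node.b.l}")
        for c in node.children:
            walk(c, depth + 1)

    walk(tree.root, 0)
    return "\n".join(lines)
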