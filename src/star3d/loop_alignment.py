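"""Anchored loop alignment with an affine-gap three-state DP.

Every region outside the consensus stacks is a loop; matched loops are
read off the consensus tree slot by slot, so the work scales with the
sum of per-slot length products rather than the product of the total
loop lengths.  Substitution scores are purely three-dimensional: the
alpha term bands the RMSD of 3-nt backbone windows superposed under the
*fixed* consensus transform (no refitting), and the beta term rewards
matched loop-region pairing interactions via a tiny exact bipartite
matching (each base has at most one partner per pairing edge).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .basepair_annotation import BasePair
from .consensus_tree import ConsensusNode, ConsensusTree
from .geometry import RigidTransform, rmsd_under

__all__ = ["ScoringParams", "LoopPair", "LoopAlignment", "extract_loop_pairs",
           "alpha", "beta", "align_loop_pair", "FORBIDDEN"]

#: sentinel strictly dominated by every finite score; arithmetic saturates
FORBIDDEN = -1e18


@dataclass(frozen=True)
class ScoringParams:
    match_score: float = 2.0
    mismatch_score: float = -1.0
    gap_open: float = -3.0
    gap_extend: float = -0.5
    pair_bonus: float = 1.0
    r_c: float = 4.0

    def __post_init__(self):
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be non-positive")
        if not self.mismatch_score < 0 < self.match_score:
            raise ValueError("need mismatch_score < 0 < match_score")


@dataclass(frozen=True)
class LoopPair:
    seg_a: tuple[int, int]       # inclusive 1-based interval; empty if start > end
    seg_b: tuple[int, int]
    context: str                 # hairpin | internal | multiloop-segment | exterior

    @property
    def residues_a(self) -> list[int]:
        return list(range(self.seg_a[0], self.seg_a[1] + 1))

    @property
    def residues_b(self) -> list[int]:
        return list(range(self.seg_b[0], self.seg_b[1] + 1))


@dataclass
class LoopAlignment:
    columns: list[tuple[int | None, int | None]]   # chain-level indices
    score: float
    cells: int                                     # DP cells filled (n1*n2)


def _inner_span(q) -> tuple[int, int]:
    """Residues strictly inside an e-stack's innermost pair (root: whole chain)."""
    if q.l == 0:
        return (q.b + 1, q.e - 1)
    return (q.b + q.l, q.e - q.l)


def extract_loop_pairs(tree: ConsensusTree) -> list[LoopPair]:
    """Matched loop segments in 5'->3' order of chain A.

    Depth-first, in-order: for each node the segments before, between
    and after its ordered children are emitted, with the node's own
    subtrees interleaved; leaves contribute their hairpin segment.
    Empty segments are kept so slot counts match on both sides.
    """
    out: list[LoopPair] = []

    def context_of(node: ConsensusNode) -> str:
        if node.is_root:
            return "exterior"
        if not node.children:
            return "hairpin"
        return "internal" if len(node.children) == 1 else "multiloop-segment"

    def walk(node: ConsensusNode):
        lo_a, hi_a = _inner_span(node.a)
        lo_b, hi_b = _inner_span(node.b)
        ctx = context_of(node)
        bounds_a = [lo_a] + [x for c in node.children for x in (c.a.b - 1, c.a.e + 1)] + [hi_a]
        bounds_b = [lo_b] + [x for c in node.children for x in (c.b.b - 1, c.b.e + 1)] + [hi_b]
        for slot in range(len(node.children) + 1):
            seg_a = (bounds_a[2 * slot], bounds_a[2 * slot + 1])
            seg_b = (bounds_b[2 * slot], bounds_b[2 * slot + 1])
            out.append(LoopPair(seg_a, seg_b, ctx))
            if slot < len(node.children):
                walk(node.children[slot])

    walk(tree.root)
    return out


def _window_rmsd(chain_a, chain_b, list_a: list[int], list_b: list[int],
                 ta: int, tb: int, transform: RigidTransform) -> float:
    """RMSD of matching 3-nt windows; offsets kept only if valid on both sides."""
    offsets = [o for o in (-1, 0, 1)
               if 0 <= ta + o < len(list_a) and 0 <= tb + o < len(list_b)]
    wa = [list_a[ta + o] for o in offsets]
    wb = [list_b[tb + o] for o in offsets]
    return rmsd_under(transform, chain_a.rep_points(wa), chain_b.rep_points(wb))


def alpha(d: float, params: ScoringParams) -> float:
    """Banded substitution score from the anchored 3D distance d."""
    if d >= 2 * params.r_c:
        return FORBIDDEN
    if d >= params.r_c:
        return params.mismatch_score
    if d >= 0.5 * params.r_c:
        return 0.5 * params.match_score
    return params.match_score


def _partners(idx: int, loop_pairs: list[BasePair]) -> list[int]:
    """Up to three pairing partners of a residue, one per pairing edge."""
    by_edge: dict[str, int] = {}
    for bp in loop_pairs:
        if bp.i == idx:
            by_edge.setdefault(bp.edge5, bp.j)
        elif bp.j == idx:
            by_edge.setdefault(bp.edge3, bp.i)
    return list(by_edge.values())[:3]


def beta(ia: int, ib: int, chain_a, chain_b, loop_pairs_a: list[BasePair],
         loop_pairs_b: list[BasePair], transform: RigidTransform,
         params: ScoringParams) -> float:
    """Bonus for matched loop-region pairing partners.

    An edge between partner a and partner b is valid when their 3-nt
    windows (chain-level, truncated at the termini) superpose under the
    anchor transform within r_c; the maximum bipartite matching over the
    at-most-3x3 validity matrix is found by enumeration.
    """
    pa = _partners(ia, loop_pairs_a)
    pb = _partners(ib, loop_pairs_b)
    if not pa or not pb:
        return 0.0
    all_a = list(range(1, len(chain_a) + 1))
    all_b = list(range(1, len(chain_b) + 1))
    valid = np.zeros((len(pa), len(pb)), dtype=bool)
    for x, a in enumerate(pa):
        for y, b in enumerate(pb):
            d = _window_rmsd(chain_a, chain_b, all_a, all_b, a - 1, b - 1, transform)
            valid[x, y] = d < params.r_c
    best = 0
    small, large, mat = ((pa, pb, valid) if len(pa) <= len(pb)
                         else (pb, pa, valid.T))
    for perm in itertools.permutations(range(len(large)), len(small)):
        best = max(best, sum(1 for x, y in enumerate(perm) if mat[x, y]))
    return params.pair_bonus * best


def align_loop_pair(lp: LoopPair, chain_a, chain_b, transform: RigidTransform,
                    params: ScoringParams,
                    loop_pairs_a: list[BasePair] | None = None,
                    loop_pairs_b: list[BasePair] | None = None) -> LoopAlignment:
    """Three-state affine-gap DP over one matched loop pair.

    States I (insertion in A), D (deletion), M (substitution) with
    boundary conditions M00=I00=D00=0, Mi0=M0j=-inf, Ii0=eo+ee*i,
    D0j=eo+ee*j, I0j=Di0=-inf; the substitution score is alpha + beta
    and a forbidden alpha (too distant in 3D) saturates to -inf so such
    residues can only be gapped.
    """
    res_a = lp.residues_a
    res_b = lp.residues_b
    loop_pairs_a = loop_pairs_a or []
    loop_pairs_b = loop_pairs_b or []
    n1, n2 = len(res_a), len(res_b)
    eo, ee = params.gap_open, params.gap_extend

    if n1 == 0 and n2 == 0:
        return LoopAlignment([], 0.0, 0)
    if n1 == 0:
        return LoopAlignment([(None, b) for b in res_b], eo + ee * n2, 0)
    if n2 == 0:
        return LoopAlignment([(a, None) for a in res_a], eo + ee * n1, 0)

    sub = np.empty((n1, n2))
    for x in range(n1):
        for y in range(n2):
            d = _window_rmsd(chain_a, chain_b, res_a, res_b, x, y, transform)
            a_score = alpha(d, params)
            if a_score <= FORBIDDEN:
                sub[x, y] = FORBIDDEN
            else:
                sub[x, y] = a_score + beta(res_a[x], res_b[y], chain_a, chain_b,
                                           loop_pairs_a, loop_pairs_b,
                                           transform, params)

    NEG = FORBIDDEN
    I = np.full((n1 + 1, n2 + 1), NEG)
    D = np.full((n1 + 1, n2 + 1), NEG)
    M = np.full((n1 + 1, n2 + 1), NEG)
    M[0, 0] = I[0, 0] = D[0, 0] = 0.0
    for i in range(1, n1 + 1):
        I[i, 0] = eo + ee * i
    for j in range(1, n2 + 1):
        D[0, j] = eo + ee * j

    # predecessor state per cell: 0=I, 1=D, 2=M
    ptr_i = np.zeros((n1 + 1, n2 + 1), dtype=np.int8)
    ptr_d = np.zeros((n1 + 1, n2 + 1), dtype=np.int8)
    ptr_m = np.zeros((n1 + 1, n2 + 1), dtype=np.int8)

    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            cand = (I[i - 1, j] + ee, D[i - 1, j] + eo + ee, M[i - 1, j] + eo + ee)
            ptr_i[i, j] = int(np.argmax(cand))
            I[i, j] = max(cand[ptr_i[i, j]], NEG)

            cand = (I[i, j - 1] + eo + ee, D[i, j - 1] + ee, M[i, j - 1] + eo + ee)
            ptr_d[i, j] = int(np.argmax(cand))
            D[i, j] = max(cand[ptr_d[i, j]], NEG)

            if sub[i - 1, j - 1] <= FORBIDDEN:
                M[i, j] = NEG
            else:
                cand = (I[i - 1, j - 1], D[i - 1, j - 1], M[i - 1, j - 1])
                ptr_m[i, j] = int(np.argmax(cand))
                M[i, j] = max(cand[ptr_m[i, j]] + sub[i - 1, j - 1], NEG)

    finals = (I[n1, n2], D[n1, n2], M[n1, n2])
    state = int(np.argmax(finals))
    score = finals[state]

    columns: list[tuple[int | None, int | None]] = []
    i, j = n1, n2
    while i > 0 or j > 0:
        if i == 0:
            columns.append((None, res_b[j - 1]))
            j -= 1
            continue
        if j == 0:
            columns.append((res_a[i - 1], None))
            i -= 1
            continue
        if state == 0:
            columns.append((res_a[i - 1], None))
            state = int(ptr_i[i, j])
            i -= 1
        elif state == 1:
            columns.append((None, res_b[j - 1]))
            state = int(ptr_d[i, j])
            j -= 1
        else:
            columns.append((res_a[i - 1], res_b[j - 1]))
            state = int(ptr_m[i, j])
            i -= 1
            j -= 1
    columns.reverse()
    return LoopAlignment(columns, float(score), n1 * n2)
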