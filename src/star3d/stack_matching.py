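"""Conserved-stack detection: k-stacks, the conservation matrix, e-stacks.

A stack of l pairs is decomposed into l - k + 1 overlapping k-stacks.
Two k-stacks from the two chains are 3D-conserved when the Kabsch RMSD
of their representative points (5' strand then 3' strand, both read
5'->3') is below the cutoff r_c.  Consecutive matches along a diagonal
of the conservation matrix, when both k-stacks step one pair inward in
their parent stacks, merge into extended-stack (e-stack) pairs; these
are ranked by the significance score RMSD - 0.1 * l and capped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .basepair_annotation import Stack
from .geometry import RigidTransform, kabsch

__all__ = ["KStack", "EStack", "EStackPair", "enumerate_kstacks",
           "conservation_matrix", "extend_estacks", "rank_and_filter",
           "estack_residues", "estack_correspondence"]

DEFAULT_K = 3
DEFAULT_RC = 4.0
DEFAULT_MAX_ESTACKS = 200


class EStack(NamedTuple):
    b: int
    e: int
    l: int


@dataclass(frozen=True)
class KStack:
    b: int
    e: int
    k: int
    parent: Stack

    def residues(self) -> list[int]:
        """5' strand ascending then 3' strand ascending."""
        five = list(range(self.b, self.b + self.k))
        three = list(range(self.e - self.k + 1, self.e + 1))
        return five + three


@dataclass
class EStackPair:
    a: EStack
    b: EStack
    rmsd: float
    transform: RigidTransform
    score: float = 0.0

    def __post_init__(self):
        if self.a.l != self.b.l:
            raise ValueError("matched e-stacks must have equal length")


def estack_residues(q: EStack) -> list[int]:
    """Residue indices of an e-stack, 5' strand then 3' strand, ascending."""
    return list(range(q.b, q.b + q.l)) + list(range(q.e - q.l + 1, q.e + 1))


def estack_correspondence(pair: EStackPair) -> list[tuple[int, int]]:
    """Per-pair residue mapping: 5'-to-5' ascending, 3'-to-3' by pair rank."""
    out = [(pair.a.b + t, pair.b.b + t) for t in range(pair.a.l)]
    out += [(pair.a.e - t, pair.b.e - t) for t in reversed(range(pair.a.l))]
    return out


def enumerate_kstacks(stacks: list[Stack], k: int = DEFAULT_K) -> list[KStack]:
    """Every stack with l >= k contributes exactly l - k + 1 k-stacks."""
    if k < 2:
        raise ValueError("k-stacks need at least 2 base pairs")
    out = []
    for s in stacks:
        for t in range(s.l - k + 1):
            out.append(KStack(b=s.b + t, e=s.e - t, k=k, parent=s))
    out.sort(key=lambda p: (p.b, p.e))
    return out


def conservation_matrix(chain_a, chain_b, PA: list[KStack], PB: list[KStack],
                        r_c: float = DEFAULT_RC) -> np.ndarray:
    """Binary matrix C[i, j] = 1 iff the k-stacks superpose within r_c."""
    coords_a = [chain_a.rep_points(p.residues()) for p in PA]
    coords_b = [chain_b.rep_points(p.residues()) for p in PB]
    C = np.zeros((len(PA), len(PB)), dtype=np.uint8)
    for i, ca in enumerate(coords_a):
        for j, cb in enumerate(coords_b):
            _, rmsd = kabsch(ca, cb)
            if rmsd < r_c:
                C[i, j] = 1
    return C


def _steps_inward(p: KStack, q: KStack) -> bool:
    return q.b == p.b + 1 and q.e == p.e - 1


def extend_estacks(C: np.ndarray, PA: list[KStack], PB: list[KStack],
                   chain_a, chain_b) -> list[EStackPair]:
    """Merge maximal diagonal runs of conserved k-stacks into e-stack pairs.

    A run continues from (i, j) to (i+1, j+1) only when both successor
    k-stacks step exactly one pair inward in the same parent stack; the
    merged pair gets a fresh Kabsch fit over its full coordinates.
    """
    n_a, n_b = C.shape
    out = []
    for i in range(n_a):
        for j in range(n_b):
            if not C[i, j]:
                continue
            if (i > 0 and j > 0 and C[i - 1, j - 1]
                    and _steps_inward(PA[i - 1], PA[i])
                    and _steps_inward(PB[j - 1], PB[j])):
                continue                      # not the start of its run
            run = 1
            while (i + run < n_a and j + run < n_b
                   and C[i + run, j + run]
                   and _steps_inward(PA[i + run - 1], PA[i + run])
                   and _steps_inward(PB[j + run - 1], PB[j + run])):
                run += 1
            k = PA[i].k
            l = k + run - 1
            qa = EStack(PA[i].b, PA[i].e, l)
            qb = EStack(PB[j].b, PB[j].e, l)
            transform, rmsd = kabsch(chain_a.rep_points(estack_residues(qa)),
                                     chain_b.rep_points(estack_residues(qb)))
            out.append(EStackPair(qa, qb, rmsd, transform))
    out.sort(key=lambda s: (s.a.b, s.a.e, s.b.b, s.b.e))
    return out


def rank_and_filter(S: list[EStackPair],
                    max_pairs: int = DEFAULT_MAX_ESTACKS) -> list[EStackPair]:
    """Keep the most significant e-stack pairs.

    Significance score = RMSD - 0.1 * l, sorted ascending (lower is more
    significant); ties favour longer pairs, then 5'-most positions.
    """
    for s in S:
        s.score = s.rmsd - 0.1 * s.a.l
    ranked = sorted(S, key=lambda s: (s.score, -s.a.l, s.a.b, s.b.b))
    return ranked[:max_pairs]
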