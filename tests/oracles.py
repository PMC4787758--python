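"""Independent reference implementations used only to check star3d.

Each oracle deliberately uses a different algorithm from the package:
quaternion superposition instead of SVD Kabsch, exhaustive subset
enumeration instead of interval DP / Bron-Kerbosch, and full path
enumeration instead of the affine-gap DP.
"""

from __future__ import annotations

import itertools

import numpy as np

NEG = -1e18


def quaternion_rmsd(P, Q) -> float:
    """Minimal RMSD of P onto Q via Horn's quaternion method."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    M = P.T @ Q
    sxx, sxy, sxz = M[0]
    syx, syy, syz = M[1]
    szx, szy, szz = M[2]
    K = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    e2 = (P * P).sum() + (Q * Q).sum() - 2.0 * lam
    return float(np.sqrt(max(e2, 0.0) / len(P)))


def crossing(p1, p2) -> bool:
    (i1, j1), (i2, j2) = sorted([p1, p2])
    return i1 < i2 < j1 < j2


def max_noncrossing_subset(pairs) -> int:
    """Largest mutually non-crossing subset, by exhaustive enumeration."""
    pairs = list(pairs)
    best = 0
    for mask in range(1 << len(pairs)):
        subset = [pairs[t] for t in range(len(pairs)) if mask >> t & 1]
        if len(subset) <= best:
            continue
        if all(not crossing(a, b) for a, b in itertools.combinations(subset, 2)):
            best = len(subset)
    return best


def max_clique_size(n_vertices, edges) -> int:
    """Largest clique, by exhaustive subset enumeration."""
    edge_set = {frozenset(e) for e in edges}
    best = 0
    for mask in range(1 << n_vertices):
        members = [v for v in range(n_vertices) if mask >> v & 1]
        if len(members) <= best:
            continue
        if all(frozenset((u, v)) in edge_set
               for u, v in itertools.combinations(members, 2)):
            best = len(members)
    return best


def best_affine_alignment_score(sub, gap_open, gap_extend) -> float:
    """Optimal monotone alignment score by enumerating every path.

    ``sub[i, j]`` is the substitution score (NEG = forbidden); each
    maximal gap run of length L costs gap_open + gap_extend * L.
    """
    n1, n2 = sub.shape

    best = [NEG]

    def walk(i, j, score, last):
        if score <= NEG:
            return
        if i == n1 and j == n2:
            best[0] = max(best[0], score)
            return
        if i < n1 and j < n2 and sub[i, j] > NEG:
            walk(i + 1, j + 1, score + sub[i, j], "M")
        if i < n1:
            extra = gap_extend if last == "I" else gap_open + gap_extend
            walk(i + 1, j, score + extra, "I")
        if j < n2:
            extra = gap_extend if last == "D" else gap_open + gap_extend
            walk(i, j + 1, score + extra, "D")

    walk(0, 0, 0.0, "start")
    return best[0]


def random_pair_instance(rng: np.random.Generator, n_pairs: int, n_res: int = 30):
    """Random base-pair endpoints, each residue used at most once."""
    endpoints = rng.choice(np.arange(1, n_res + 1), size=2 * n_pairs, replace=False)
    rng.shuffle(endpoints)
    return [tuple(sorted((int(endpoints[2 * t]), int(endpoints[2 * t + 1]))))
            for t in range(n_pairs)]
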