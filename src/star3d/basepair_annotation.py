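"""Geometric base-pair detection and secondary-structure decomposition.

Pairing interactions are detected from the coordinates alone: a C1'-C1'
distance gate, at least two donor-acceptor heavy-atom contacts between
edge atoms, and near-coplanar base planes.  Canonical pairs (A-U, C-G
and the G-U wobble, on Watson-Crick edges) form the secondary structure;
after a maximum-cardinality non-crossing subset is extracted the
remainder (crossing pairs, non-canonical pairs, and later any stack
demoted from the consensus) is kept as loop interactions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "BasePair", "Stack", "SecondaryStructure", "GeometryParams",
    "annotate_basepairs", "supply_basepairs", "resolve_pair_conflicts",
    "remove_pseudoknots", "decompose_stacks", "expand_stacks", "to_dotbracket",
]

CANONICAL_COMBOS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}

#: donor-acceptor atom name pairs checked for each canonical combination
#: (first atom on the first-named base).
CANONICAL_CONTACTS = {
    ("A", "U"): [("N1", "N3"), ("N6", "O4")],
    ("G", "C"): [("N1", "N3"), ("O6", "N4"), ("N2", "O2")],
    ("G", "U"): [("O6", "N3"), ("N1", "O2")],
}

WC_EDGE = {"A": {"N1", "N6"}, "G": {"N1", "O6", "N2"},
           "C": {"N3", "N4", "O2"}, "U": {"N3", "O4", "O2"}}
HOOGSTEEN_EDGE = {"A": {"N7", "N6"}, "G": {"N7", "O6"}, "C": {"N4"}, "U": {"O4"}}
SUGAR_EDGE = {"A": {"N3", "C2"}, "G": {"N3", "N2"}, "C": {"O2"}, "U": {"O2"}}

_BASE_PLANE_ATOMS = {"N1", "N3", "N6", "N4", "O6", "O4", "N2", "O2", "N7", "N9", "C2", "C4", "C6", "C8", "C5"}


@dataclass(frozen=True)
class BasePair:
    i: int
    j: int
    edge5: str = "WC"
    edge3: str = "WC"
    canonical: bool = False
    score: float = 0.0       # mean contact distance; lower is better

    def __post_init__(self):
        if not self.i < self.j:
            raise ValueError(f"base pair requires i < j, got ({self.i}, {self.j})")

    @property
    def key(self) -> tuple[int, int]:
        return (self.i, self.j)


@dataclass(frozen=True)
class Stack:
    """Maximal run of consecutively nested canonical pairs."""
    b: int   # leftmost 5' base
    e: int   # rightmost 3' base
    l: int   # number of base pairs

    def pair_keys(self) -> list[tuple[int, int]]:
        return [(self.b + t, self.e - t) for t in range(self.l)]


@dataclass
class SecondaryStructure:
    nested: list[BasePair] = field(default_factory=list)
    loop_pairs: list[BasePair] = field(default_factory=list)


@dataclass(frozen=True)
class GeometryParams:
    c1_min: float = 8.0
    c1_max: float = 12.0
    c1_canonical: float = 10.4
    c1_canonical_tol: float = 1.5
    contact_max: float = 3.5
    min_contacts: int = 2
    plane_angle_max_deg: float = 65.0
    min_separation: int = 4     # minimum hairpin loop of 3 unpaired residues


def _base_plane_normal(residue) -> np.ndarray | None:
    pts = [xyz for name, xyz in residue.atoms.items() if name in _BASE_PLANE_ATOMS]
    if len(pts) < 3:
        return None
    arr = np.asarray(pts, float)
    arr = arr - arr.mean(axis=0)
    _, _, vt = np.linalg.svd(arr)
    return vt[2]


def _edge_of(base: str, atom: str) -> str:
    if atom in WC_EDGE.get(base, ()):
        return "WC"
    if atom in HOOGSTEEN_EDGE.get(base, ()):
        return "Hoogsteen"
    if atom in SUGAR_EDGE.get(base, ()):
        return "Sugar"
    return "WC"


def _dominant_edge(base: str, atoms: list[str]) -> str:
    if not atoms:
        return "WC"
    edges = [_edge_of(base, a) for a in atoms]
    return max(set(edges), key=edges.count)


def annotate_basepairs(chain, params: GeometryParams = GeometryParams()) -> list[BasePair]:
    """Detect pairing interactions geometrically.

    Chains without base atoms (representative-point-only fixtures) yield
    an empty result with a warning; use :func:`supply_basepairs` there.
    """
    n = len(chain)
    c1 = np.full((n, 3), np.nan)
    for r in chain.residues:
        if "C1'" in r.atoms:
            c1[r.index - 1] = r.atoms["C1'"]
    if np.isnan(c1).all():
        logger.warning("chain %s has no C1' atoms; geometric annotation skipped",
                       getattr(chain, "label", "?"))
        return []
    normals = [_base_plane_normal(r) for r in chain.residues]
    cos_max = np.cos(np.radians(params.plane_angle_max_deg))

    pairs: list[BasePair] = []
    for i in range(1, n + 1):
        if np.isnan(c1[i - 1]).any():
            continue
        for j in range(i + params.min_separation, n + 1):
            if np.isnan(c1[j - 1]).any():
                continue
            dist = float(np.linalg.norm(c1[i - 1] - c1[j - 1]))
            if not params.c1_min <= dist <= params.c1_max:
                continue
            ri, rj = chain[i], chain[j]
            combo = (ri.base, rj.base)
            canonical_combo = combo in CANONICAL_COMBOS
            if canonical_combo and abs(dist - params.c1_canonical) > params.c1_canonical_tol:
                continue
            contacts = _contacts(ri, rj, params)
            if len(contacts) < params.min_contacts:
                continue
            ni, nj = normals[i - 1], normals[j - 1]
            if ni is None or nj is None or abs(float(np.dot(ni, nj))) < cos_max:
                continue
            atoms_i = [a for a, _, _ in contacts]
            atoms_j = [b for _, b, _ in contacts]
            edge5 = _dominant_edge(ri.base, atoms_i)
            edge3 = _dominant_edge(rj.base, atoms_j)
            canonical = canonical_combo and edge5 == "WC" and edge3 == "WC"
            score = float(np.mean([d for _, _, d in contacts]))
            pairs.append(BasePair(i, j, edge5, edge3, canonical, score))
    return pairs


def _contacts(ri, rj, params: GeometryParams):
    """Donor-acceptor contacts < contact_max between edge atoms.

    Canonical combinations use the specific H-bond atom table; anything
    else counts close approaches between any Watson-Crick edge atoms.
    """
    combo = (ri.base, rj.base)
    out = []
    if combo in CANONICAL_CONTACTS or combo[::-1] in CANONICAL_CONTACTS:
        flipped = combo not in CANONICAL_CONTACTS
        table = CANONICAL_CONTACTS[combo[::-1] if flipped else combo]
        for a, b in table:
            if flipped:
                a, b = b, a
            if a in ri.atoms and b in rj.atoms:
                d = float(np.linalg.norm(ri.atoms[a] - rj.atoms[b]))
                if d < params.contact_max:
                    out.append((a, b, d))
        return out
    edge_i = WC_EDGE.get(ri.base, set()) | HOOGSTEEN_EDGE.get(ri.base, set())
    edge_j = WC_EDGE.get(rj.base, set()) | HOOGSTEEN_EDGE.get(rj.base, set())
    for a in edge_i & set(ri.atoms):
        for b in edge_j & set(rj.atoms):
            d = float(np.linalg.norm(ri.atoms[a] - rj.atoms[b]))
            if d < params.contact_max:
                out.append((a, b, d))
    return out


def supply_basepairs(pair_table, chain) -> list[BasePair]:
    """Read a whitespace table with columns i, j, edge5, edge3.

    The canonical flag is recomputed from the chain sequence; malformed
    rows (i >= j, out-of-range indices) are reported and skipped.
    """
    pairs = []
    for lineno, line in enumerate(Path(pair_table).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 2:
            logger.warning("%s:%d: expected at least two columns", pair_table, lineno)
            continue
        try:
            i, j = int(fields[0]), int(fields[1])
        except ValueError:
            logger.warning("%s:%d: non-integer indices", pair_table, lineno)
            continue
        edge5 = fields[2] if len(fields) > 2 else "WC"
        edge3 = fields[3] if len(fields) > 3 else "WC"
        if i >= j:
            logger.warning("%s:%d: rejected pair (%d, %d): i >= j", pair_table, lineno, i, j)
            continue
        if not (1 <= i <= len(chain) and 1 <= j <= len(chain)):
            logger.warning("%s:%d: rejected pair (%d, %d): out of range", pair_table, lineno, i, j)
            continue
        canonical = ((chain[i].base, chain[j].base) in CANONICAL_COMBOS
                     and edge5 == "WC" and edge3 == "WC")
        pairs.append(BasePair(i, j, edge5, edge3, canonical))
    return pairs


def resolve_pair_conflicts(pairs: list[BasePair]) -> tuple[list[BasePair], list[BasePair]]:
    """One canonical pair per residue: keep best geometric score first."""
    kept, dropped = [], []
    used: set[int] = set()
    for p in sorted(pairs, key=lambda p: (p.score, p.i, p.j)):
        if p.i in used or p.j in used:
            dropped.append(p)
        else:
            kept.append(p)
            used.update((p.i, p.j))
    kept.sort(key=lambda p: p.key)
    return kept, dropped


def remove_pseudoknots(pairs: list[BasePair]) -> tuple[list[BasePair], list[BasePair]]:
    """Split canonical pairs into a maximum non-crossing subset and the rest.

    Interval DP over the sorted endpoint coordinates; the objective is
    cardinality first, then a helix-contiguity bonus (adjacent nested
    pairs kept together), with a deterministic traceback.
    """
    if not pairs:
        return [], []
    by_i = {p.i: p for p in pairs}
    if len(by_i) != len(pairs):
        raise ValueError("residue participates in several pairs; resolve conflicts first")
    coords = sorted({c for p in pairs for c in (p.i, p.j)})
    pos = {c: t for t, c in enumerate(coords)}
    m = len(coords)
    pair_at: dict[int, int] = {}     # coordinate slot of i -> slot of j
    for p in pairs:
        pair_at[pos[p.i]] = pos[p.j]

    import functools

    @functools.lru_cache(maxsize=None)
    def g(a: int, b: int) -> int:
        """Best score inside slots (a, b) given the pair (a, b) is chosen."""
        inner = f(a + 1, b - 1)
        if pair_at.get(a + 1) == b - 1:
            inner = max(inner, g(a + 1, b - 1) + 1)   # contiguity bonus
        return 1000 + inner

    @functools.lru_cache(maxsize=None)
    def f(a: int, b: int) -> int:
        if a > b:
            return 0
        best = f(a + 1, b)
        j = pair_at.get(a)
        if j is not None and j <= b:
            best = max(best, g(a, j) + f(j + 1, b))
        return best

    chosen: list[BasePair] = []

    def trace_f(a: int, b: int):
        while a <= b:
            j = pair_at.get(a)
            if j is not None and j <= b and g(a, j) + f(j + 1, b) == f(a, b):
                trace_g(a, j)
                a = j + 1
            else:
                a += 1

    def trace_g(a: int, b: int):
        chosen.append(by_i[coords[a]])
        if pair_at.get(a + 1) == b - 1 and g(a + 1, b - 1) + 1 + 1000 == g(a, b):
            trace_g(a + 1, b - 1)
        else:
            trace_f(a + 1, b - 1)

    trace_f(0, m - 1)
    chosen_keys = {p.key for p in chosen}
    nested = sorted(chosen, key=lambda p: p.key)
    crossing = sorted((p for p in pairs if p.key not in chosen_keys), key=lambda p: p.key)
    return nested, crossing


def decompose_stacks(nested: list[BasePair]) -> list[Stack]:
    """Maximal runs of consecutively nested pairs, sorted by leftmost base."""
    keys = {p.key for p in nested}
    stacks = []
    for (i, j) in sorted(keys):
        if (i - 1, j + 1) in keys:
            continue                      # not the outermost pair of its run
        l = 1
        while (i + l, j - l) in keys:
            l += 1
        stacks.append(Stack(b=i, e=j, l=l))
    return stacks


def expand_stacks(stacks: list[Stack]) -> set[tuple[int, int]]:
    return {k for s in stacks for k in s.pair_keys()}


def to_dotbracket(n: int, nested: list[BasePair]) -> str:
    out = ["."] * n
    for p in nested:
        out[p.i - 1] = "("
        out[p.j - 1] = ")"
    return "".join(out)
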