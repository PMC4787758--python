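"""Idealised RNA 3D structure generator for testing and simulation.

Stems are realised as ideal A-form double helices (rise 2.81 Å, twist
32.7°/bp, C1'-C1' width 10.4 Å across a pair); hairpin loops are laid on
a semicircular arc bridging the closing pair, and multi-branch / internal
loops on a circle whose radius is solved so that every attachment chord
(6.5 Å between single residues, 10.4 Å across a helix opening) fits
exactly.  Each residue carries the six backbone atoms plus a minimal
base (C1', glycosidic nitrogen and Watson-Crick edge atoms), placed so
that paired bases satisfy the geometric annotator's gates and unpaired
bases point away from their loop centre.  Gaussian per-atom noise and a
rigid motion can be applied reproducibly from a seed.

These fixtures are deliberately minimal: they are mutually superposable
and annotatable, not crystallographically faithful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import RigidTransform
from .structure_io import (BACKBONE_ATOMS, Residue, ResidueChain,
                           backbone_rep_point, write_pdb)

__all__ = ["TopologySpec", "build_structure", "make_pair", "HELIX_RISE",
           "HELIX_TWIST_DEG", "PAIR_HALF_WIDTH"]

HELIX_RISE = 2.81          # Å per base pair along the helix axis
HELIX_TWIST_DEG = 32.7     # degrees per base pair
PAIR_HALF_WIDTH = 5.2      # half the C1'-C1' distance across a pair (Å)
LOOP_SPACING = 6.5         # chord between consecutive loop residues (Å)
STEM_MARGIN = 4.0          # extra clearance around stems on the exterior

#: backbone atom offsets in the residue frame (x toward the base,
#: z along the local helix axis / loop normal)
_BACKBONE_OFFSETS = {
    "P":   (-1.5, 1.2, -2.6),
    "O5'": (-1.2, 0.9, -1.6),
    "C5'": (-0.8, 0.5, -1.0),
    "C4'": (-0.5, 0.2, -0.4),
    "C3'": (-0.9, -0.6, 0.3),
    "O3'": (-1.3, -1.0, 1.2),
}

#: minimal base atoms (x, y) in the residue frame; the edge atoms sit
#: near the pair centre so canonical partners make the H-bond gates with
#: a margin that survives 0.3 Å per-atom noise (placement is tuned for
#: annotation robustness, not stereochemistry).
_BASE_OFFSETS = {
    "A": {"N9": (1.5, 0.0), "C2": (3.6, -0.5), "N1": (5.0, -1.1), "N6": (5.0, 1.1)},
    "G": {"N9": (1.5, 0.0), "N2": (5.05, -1.6), "N1": (5.0, -1.1), "O6": (5.0, 1.1)},
    "C": {"N1": (1.5, 0.0), "O2": (5.05, -1.6), "N3": (5.0, -1.1), "N4": (5.0, 1.1)},
    "U": {"N1": (1.5, 0.0), "O2": (4.9, -1.4), "N3": (5.0, -1.1), "O4": (5.0, 1.1)},
}

_COMPLEMENT = {"G": "C", "C": "G", "A": "U", "U": "A"}
_CANONICAL_COMBOS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}


@dataclass
class TopologySpec:
    """Declarative description of one synthetic structure."""

    bracket: str
    sequence: str | None = None
    rise: float = HELIX_RISE
    twist_deg: float = HELIX_TWIST_DEG
    noise_sigma: float = 0.0
    seed: int = 0
    label: str = "synthetic"

    def __post_init__(self):
        pairs = bracket_pairs(self.bracket)
        if self.sequence is None:
            self.sequence = _auto_sequence(self.bracket, pairs)
        if len(self.sequence) != len(self.bracket):
            raise ValueError("sequence and bracket lengths differ")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        for i, j in pairs.items():
            if i < j and (self.sequence[i - 1], self.sequence[j - 1]) not in _CANONICAL_COMBOS:
                raise ValueError(
                    f"positions {i},{j} pair non-canonically "
                    f"({self.sequence[i - 1]}-{self.sequence[j - 1]})")


def bracket_pairs(bracket: str) -> dict[int, int]:
    """1-based pair map from a balanced dot-bracket string (both directions)."""
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for pos, ch in enumerate(bracket, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced bracket at position {pos}")
            i = stack.pop()
            if pos - i < 4:
                raise ValueError(f"hairpin closed by pair ({i},{pos}) is too tight")
            pairs[i] = pos
            pairs[pos] = i
        elif ch != ".":
            raise ValueError(f"unsupported bracket character {ch!r}")
    if stack:
        raise ValueError("unbalanced bracket: unclosed '('")
    return pairs


def _auto_sequence(bracket: str, pairs: dict[int, int]) -> str:
    """Default sequence: G/C alternating in stems, A elsewhere."""
    seq = ["A"] * len(bracket)
    for i, j in sorted(pairs.items()):
        if i < j:
            base = "G" if i % 2 else "C"
            seq[i - 1] = base
            seq[j - 1] = _COMPLEMENT[base]
    return "".join(seq)


# ---------------------------------------------------------------------------
# secondary-structure tree

@dataclass
class _Helix:
    pairs: list[tuple[int, int]]
    inner: list = field(default_factory=list)   # items of the enclosed loop


def _loop_items(lo: int, hi: int, pairs: dict[int, int]):
    """Items (ints for unpaired residues, _Helix for stems) in [lo, hi]."""
    items = []
    x = lo
    while x <= hi:
        j = pairs.get(x)
        if j is None or j < x:
            items.append(x)
            x += 1
        else:
            hpairs = [(x, j)]
            while pairs.get(hpairs[-1][0] + 1) == hpairs[-1][1] - 1:
                hpairs.append((hpairs[-1][0] + 1, hpairs[-1][1] - 1))
            bi, bj = hpairs[-1]
            helix = _Helix(hpairs)
            helix.inner = _loop_items(bi + 1, bj - 1, pairs)
            items.append(helix)
            x = j + 1
    return items


# ---------------------------------------------------------------------------
# 3D layout

def _rotate_about(v, axis, theta):
    axis = axis / np.linalg.norm(axis)
    return (v * math.cos(theta)
            + np.cross(axis, v) * math.sin(theta)
            + axis * float(np.dot(axis, v)) * (1 - math.cos(theta)))


class _Layout:
    """Accumulates a frame (C1' origin, x/y/z axes) per residue."""

    def __init__(self, spec: TopologySpec):
        self.spec = spec
        self.frames: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}

    def set_frame(self, idx, c1, xhat, zhat):
        yhat = np.cross(zhat, xhat)
        self.frames[idx] = (np.asarray(c1, float), xhat, yhat, zhat)

    # -- helices ------------------------------------------------------------

    def place_helix(self, helix: _Helix, origin, axis, u0):
        rise, twist = self.spec.rise, math.radians(self.spec.twist_deg)
        for t, (i, j) in enumerate(helix.pairs):
            u = _rotate_about(u0, axis, twist * t)
            centre = origin + axis * (rise * t)
            self.set_frame(i, centre - PAIR_HALF_WIDTH * u, u, axis)
            self.set_frame(j, centre + PAIR_HALF_WIDTH * u, -u, axis)
        top = len(helix.pairs) - 1
        u_top = _rotate_about(u0, axis, twist * top)
        m_top = origin + axis * (rise * top)
        children = [it for it in helix.inner if isinstance(it, _Helix)]
        if children:
            self.place_ring(helix.inner, m_top, axis, u_top)
        else:
            self.place_arc(helix.inner, m_top, axis, u_top)

    # -- hairpin loops ------------------------------------------------------

    def place_arc(self, items, m_top, axis, u_top):
        """Semicircular arc over the closing pair; radius equals the pair
        half-width so loops of different lengths share one geometry."""
        n = len(items)
        for i, idx in enumerate(items, start=1):
            phi = math.pi * (1 - i / (n + 1))
            radial = math.cos(phi) * u_top + math.sin(phi) * axis
            c1 = m_top + PAIR_HALF_WIDTH * radial
            self.set_frame(idx, c1, radial, np.cross(axis, u_top))

    # -- multibranch / internal loops ---------------------------------------

    def place_ring(self, items, m_top, axis, u_top):
        """Circle through the two anchor C1' points and every loop item.

        Chord widths: 10.4 Å across each helix opening (and across the
        incoming closing pair), 6.5 Å between any other neighbours.  The
        radius is solved by bisection so the widths sum to a full turn.
        Child helices grow radially outward in the loop plane.
        """
        chords = []
        for it in items:
            if isinstance(it, _Helix):
                chords.append(LOOP_SPACING)          # previous point -> 5' attachment
                chords.append(2 * PAIR_HALF_WIDTH)   # across the child opening
            else:
                chords.append(LOOP_SPACING)
        chords.append(LOOP_SPACING)                  # last point -> 3' anchor
        chords.append(2 * PAIR_HALF_WIDTH)           # closing pair A2 -> A1
        radius = _solve_ring_radius(chords)

        v = np.cross(axis, u_top)
        h = math.sqrt(max(radius ** 2 - PAIR_HALF_WIDTH ** 2, 0.0))
        centre = m_top + h * v
        theta = math.atan2(-h, -PAIR_HALF_WIDTH)     # angle of the 5' anchor

        def pos(angle):
            return centre + radius * (math.cos(angle) * u_top + math.sin(angle) * v)

        def advance(angle, chord):
            return angle - 2 * math.asin(min(chord / (2 * radius), 1.0))

        for it in items:
            if isinstance(it, _Helix):
                theta = advance(theta, LOOP_SPACING)
                pb = pos(theta)
                theta = advance(theta, 2 * PAIR_HALF_WIDTH)
                pe = pos(theta)
                m_child = (pb + pe) / 2
                u_child = (pe - pb) / np.linalg.norm(pe - pb)
                w_child = m_child - centre
                w_child = w_child / np.linalg.norm(w_child)
                self.place_helix(it, m_child, w_child, u_child)
            else:
                theta = advance(theta, LOOP_SPACING)
                p = pos(theta)
                radial = (p - centre) / radius
                self.set_frame(it, p, radial, axis)

    # -- exterior -----------------------------------------------------------

    def place_exterior(self, items):
        x = 0.0
        ex, ey, ez = np.eye(3)
        for it in items:
            if isinstance(it, _Helix):
                x += STEM_MARGIN
                origin = np.array([x + PAIR_HALF_WIDTH, 0.0, 0.0])
                self.place_helix(it, origin, ez.copy(), ex.copy())
                x += 2 * PAIR_HALF_WIDTH + STEM_MARGIN + LOOP_SPACING
            else:
                self.set_frame(it, np.array([x, 0.0, 0.0]), -ez.copy(), ey.copy())
                x += LOOP_SPACING


def _solve_ring_radius(chords) -> float:
    """Radius R with sum(2*asin(c/2R)) == 2*pi, R >= max(c)/2."""
    def turn(r):
        return sum(2 * math.asin(min(c / (2 * r), 1.0)) for c in chords)

    lo = max(chords) / 2
    hi = max(sum(chords), 2 * lo + 1.0)
    if turn(lo) < 2 * math.pi:
        return lo  # degenerate tiny loop; smallest legal circle
    for _ in range(80):
        mid = (lo + hi) / 2
        if turn(mid) > 2 * math.pi:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


# ---------------------------------------------------------------------------
# residue construction

def build_structure(spec: TopologySpec) -> ResidueChain:
    """Realise a topology spec as a chain with backbone and base atoms."""
    pairs = bracket_pairs(spec.bracket)
    items = _loop_items(1, len(spec.bracket), pairs)
    layout = _Layout(spec)
    layout.place_exterior(items)

    rng = np.random.default_rng(spec.seed)
    residues = []
    for idx in range(1, len(spec.bracket) + 1):
        c1, xhat, yhat, zhat = layout.frames[idx]
        base = spec.sequence[idx - 1]
        atoms = {"C1'": c1.copy()}
        for name, (ox, oy, oz) in _BACKBONE_OFFSETS.items():
            atoms[name] = c1 + ox * xhat + oy * yhat + oz * zhat
        for name, (ox, oy) in _BASE_OFFSETS[base].items():
            atoms[name] = c1 + ox * xhat + oy * yhat
        if spec.noise_sigma > 0:
            for name in atoms:
                atoms[name] = atoms[name] + rng.normal(0.0, spec.noise_sigma, size=3)
        res = Residue(index=idx, base=base, author_id=f"A/{idx}", atoms=atoms)
        res.rep_point = backbone_rep_point(res)
        residues.append(res)
    return ResidueChain(label=spec.label, residues=residues)


def make_pair(spec_a: TopologySpec, spec_b: TopologySpec,
              rigid_motion: RigidTransform | None = None,
              out_a=None, out_b=None) -> tuple[ResidueChain, ResidueChain]:
    """Build two structures, rigidly move B, optionally write PDB files."""
    chain_a = build_structure(spec_a)
    chain_b = build_structure(spec_b)
    if rigid_motion is not None:
        chain_b = chain_b.transformed(rigid_motion)
    if out_a is not None:
        write_pdb(out_a, [("A", chain_a)])
    if out_b is not None:
        write_pdb(out_b, [("B", chain_b)])
    return chain_a, chain_b
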