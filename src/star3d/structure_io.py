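"""RNA chain model and PDB input/output.

A parsed chain is an ordered, 1-based list of nucleotides; each residue
carries its atoms and one backbone representative point (the geometric
centre of whichever of the six backbone atoms C3', C4', C5', O3', O5'
and P are present).  Internal indices are consecutive 1..n; the original
author chain/residue numbering is retained only for reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser

from .geometry import RigidTransform

logger = logging.getLogger(__name__)

__all__ = [
    "Residue", "ResidueChain", "StructureError", "UnknownChainError",
    "EmptyChainError", "NoRepresentativeError", "parse_structure",
    "backbone_rep_point", "write_pdb", "BACKBONE_ATOMS",
]

#: the six backbone atoms whose geometric centre represents a nucleotide
BACKBONE_ATOMS = ("P", "O5'", "C5'", "C4'", "C3'", "O3'")

STANDARD_BASES = {"A", "C", "G", "U"}

#: modified nucleotides mapped onto their parent base; anything not
#: listed here (and not a standard base) is dropped with a warning.
MODIFIED_PARENT = {
    "PSU": "U", "H2U": "U", "5MU": "U", "4SU": "U", "UR3": "U", "OMU": "U",
    "1MA": "A", "MA6": "A", "A2M": "A", "6MZ": "A",
    "5MC": "C", "OMC": "C", "4OC": "C",
    "OMG": "G", "2MG": "G", "M2G": "G", "7MG": "G", "1MG": "G", "G7M": "G",
}


class StructureError(Exception):
    """Base class for structure input errors."""


class UnknownChainError(StructureError):
    pass


class EmptyChainError(StructureError):
    pass


class NoRepresentativeError(StructureError):
    """None of the six backbone atoms is present."""


@dataclass
class Residue:
    index: int                      # 1-based position in the parsed chain
    base: str                       # one-letter code, A/C/G/U for standards
    author_id: str                  # chain + author number + insertion code
    atoms: dict[str, np.ndarray] = field(default_factory=dict)
    rep_point: np.ndarray | None = None

    def has_atom(self, name: str) -> bool:
        return name in self.atoms

    def transformed(self, transform: RigidTransform) -> "Residue":
        atoms = {n: transform.apply_point(p) for n, p in self.atoms.items()}
        rep = transform.apply_point(self.rep_point) if self.rep_point is not None else None
        return Residue(self.index, self.base, self.author_id, atoms, rep)


@dataclass
class ResidueChain:
    label: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, index: int) -> Residue:
        """1-based residue access, matching the A[i] convention."""
        if not 1 <= index <= len(self.residues):
            raise IndexError(f"residue index {index} outside 1..{len(self.residues)}")
        return self.residues[index - 1]

    @property
    def sequence(self) -> str:
        return "".join(r.base for r in self.residues)

    def rep_points(self, indices=None) -> np.ndarray:
        """(n, 3) representative points, optionally for a 1-based index list."""
        if indices is None:
            return np.array([r.rep_point for r in self.residues], dtype=float)
        return np.array([self[i].rep_point for i in indices], dtype=float)

    def transformed(self, transform: RigidTransform) -> "ResidueChain":
        return ResidueChain(self.label, [r.transformed(transform) for r in self.residues])


def backbone_rep_point(residue: Residue) -> np.ndarray:
    """Arithmetic mean of the backbone atoms present (partial sets allowed)."""
    pts = [residue.atoms[n] for n in BACKBONE_ATOMS if n in residue.atoms]
    if not pts:
        raise NoRepresentativeError(
            f"residue {residue.author_id} has none of the six backbone atoms")
    return np.mean(pts, axis=0)


def _select_altloc(atom):
    """Resolve a possibly disordered atom to its highest-occupancy variant."""
    if atom.is_disordered():
        variants = atom.disordered_get_list()
        return max(variants, key=lambda a: (a.get_occupancy() or 0.0))
    return atom


def parse_structure(path, chain_id: str, model_index: int = 1) -> ResidueChain:
    """Parse one RNA chain from a PDB file.

    Only standard nucleotides (plus modified bases mappable to a parent)
    are kept; residues lacking all six backbone atoms are dropped with a
    warning; survivors are renumbered 1..n in file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such structure file: {path}")
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    models = list(structure)
    if not models:
        raise StructureError(f"{path} contains no coordinate models")
    if not 1 <= model_index <= len(models):
        raise StructureError(
            f"model {model_index} requested but {path} has {len(models)} model(s)")
    model = models[model_index - 1]
    chain = None
    for c in model:
        if c.id == chain_id:
            chain = c
            break
    if chain is None:
        available = ", ".join(sorted(c.id for c in model))
        raise UnknownChainError(
            f"chain {chain_id!r} not found in {path} (available: {available})")

    residues: list[Residue] = []
    for res in chain:
        resname = res.get_resname().strip()
        base = resname if resname in STANDARD_BASES else MODIFIED_PARENT.get(resname)
        if base is None:
            if resname not in {"HOH", "WAT"}:
                logger.debug("skipping non-nucleotide residue %s in %s", resname, path)
            continue
        _, resseq, icode = res.get_id()
        author = f"{chain_id}/{resseq}{icode.strip()}"
        atoms = {}
        for atom in res:
            atom = _select_altloc(atom)
            atoms[atom.get_name()] = np.asarray(atom.get_coord(), dtype=float)
        residue = Residue(index=0, base=base, author_id=author, atoms=atoms)
        try:
            residue.rep_point = backbone_rep_point(residue)
        except NoRepresentativeError:
            logger.warning("dropping residue %s: no backbone atoms", author)
            continue
        residues.append(residue)

    if not residues:
        raise EmptyChainError(f"chain {chain_id!r} of {path} contains no nucleotides")
    for i, r in enumerate(residues, start=1):
        r.index = i
    return ResidueChain(label=f"{path.name}:{chain_id}", residues=residues)


def _element_of(atom_name: str) -> str:
    return atom_name.strip("'0123456789")[:1] or "C"


def write_pdb(path, chains: list[tuple[str, ResidueChain]]) -> None:
    """Write chains as plain ATOM records (one model, TER per chain)."""
    serial = 1
    lines = []
    for chain_id, chain in chains:
        for res in chain.residues:
            for name, xyz in res.atoms.items():
                pdb_name = name if len(name) >= 4 else f" {name:<3}"
                lines.append(
                    f"ATOM  {serial:5d} {pdb_name}{'':1}{res.base:>3} {chain_id:1}"
                    f"{res.index:4d}{'':1}   "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {_element_of(name):>2}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      {'':1}{chain_id:1}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
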