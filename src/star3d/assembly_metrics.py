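"""Final assembly: merge stack and loop alignments, score, write outputs.

The consensus e-stack columns (fixed inside-stack correspondence) and
the loop-alignment columns are interleaved in 5'->3' order of chain A;
monotonicity in chain B is guaranteed by the tree construction and
asserted.  Alignment quality is summarised as PSI (percentage of
aligned nucleotides within 4 Å of the superposition, normalised by the
shorter chain) and PSS (percentage of aligned base pairs within 4 Å,
normalised by the smaller annotated pair count); the 4 Å threshold is a
constant of the metric, deliberately independent of the tunable r_c.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .basepair_annotation import BasePair
from .consensus_tree import ConsensusNode, ConsensusTree
from .geometry import RigidTransform, rmsd_under
from .loop_alignment import LoopAlignment
from .structure_io import ResidueChain, write_pdb

__all__ = ["GlobalAlignment", "assemble", "compute_psi", "compute_pss",
           "aligned_rmsd", "write_outputs", "PSI_CUTOFF"]

PSI_CUTOFF = 4.0   # Å; metric constant, not the tunable r_c


@dataclass
class GlobalAlignment:
    columns: list[tuple[int | None, int | None, str]]   # (iA, iB, provenance)
    transform: RigidTransform
    psi: float = 0.0
    pss: float | None = None
    aligned_rmsd: float = float("nan")
    metadata: dict = field(default_factory=dict)

    @property
    def aligned_columns(self) -> list[tuple[int, int]]:
        return [(a, b) for a, b, _ in self.columns if a is not None and b is not None]


class MonotonicityError(AssertionError):
    """Assembled columns are disordered (must be unreachable)."""


def assemble(tree: ConsensusTree, loop_alignments: list[LoopAlignment],
             chain_a: ResidueChain, chain_b: ResidueChain) -> GlobalAlignment:
    """Interleave consensus stack columns and loop columns in tree order.

    ``loop_alignments`` must be in the order produced by
    :func:`star3d.loop_alignment.extract_loop_pairs` for the same tree.
    """
    loops = iter(loop_alignments)
    columns: list[tuple[int | None, int | None, str]] = []

    def emit(node: ConsensusNode):
        if not node.is_root:
            for t in range(node.a.l):
                columns.append((node.a.b + t, node.b.b + t, "stack"))
        for slot in range(len(node.children) + 1):
            la = next(loops)
            for a, b in la.columns:
                columns.append((a, b, "loop"))
            if slot < len(node.children):
                emit(node.children[slot])
        if not node.is_root:
            for t in reversed(range(node.a.l)):
                columns.append((node.a.e - t, node.b.e - t, "stack"))

    emit(tree.root)
    rest = list(loops)
    if rest:
        raise ValueError(f"{len(rest)} unconsumed loop alignments")

    for chain_pos in (0, 1):
        seq = [c[chain_pos] for c in columns if c[chain_pos] is not None]
        if any(y <= x for x, y in zip(seq, seq[1:])):
            raise MonotonicityError(f"disordered columns in chain {'AB'[chain_pos]}")

    aln = GlobalAlignment(columns=columns, transform=tree.transform)
    aln.psi = compute_psi(aln, chain_a, chain_b)
    aln.aligned_rmsd = aligned_rmsd(aln, chain_a, chain_b)
    return aln


def _within_cutoff(aln: GlobalAlignment, chain_a, chain_b) -> dict[tuple[int, int], bool]:
    pairs = aln.aligned_columns
    if not pairs:
        return {}
    pa = chain_a.rep_points([a for a, _ in pairs])
    pb = chain_b.rep_points([b for _, b in pairs])
    dist = np.linalg.norm(aln.transform.apply(pa) - pb, axis=1)
    return {col: bool(d <= PSI_CUTOFF) for col, d in zip(pairs, dist)}


def compute_psi(aln: GlobalAlignment, chain_a: ResidueChain,
                chain_b: ResidueChain) -> float:
    """Aligned nucleotides within 4 Å / length of the shorter chain, x100."""
    close = _within_cutoff(aln, chain_a, chain_b)
    count = sum(close.values())
    return 100.0 * count / min(len(chain_a), len(chain_b))


def compute_pss(aln: GlobalAlignment, pairs_a: list[BasePair],
                pairs_b: list[BasePair], chain_a: ResidueChain,
                chain_b: ResidueChain) -> float | None:
    """Aligned base pairs within 4 Å / smaller annotated pair count, x100.

    A pair (i, j) of A counts when both residues are aligned, their
    partners form an annotated pair of B, and both columns sit within
    the 4 Å cutoff.  Returns None (not applicable) when either chain
    has no annotated pairs.
    """
    if not pairs_a or not pairs_b:
        return None
    close = _within_cutoff(aln, chain_a, chain_b)
    mapping = dict(aln.aligned_columns)
    keys_b = {p.key for p in pairs_b}
    count = 0
    for p in pairs_a:
        bi, bj = mapping.get(p.i), mapping.get(p.j)
        if bi is None or bj is None:
            continue
        if (min(bi, bj), max(bi, bj)) not in keys_b:
            continue
        if close.get((p.i, bi)) and close.get((p.j, bj)):
            count += 1
    return 100.0 * count / min(len(pairs_a), len(pairs_b))


def aligned_rmsd(aln: GlobalAlignment, chain_a: ResidueChain,
                 chain_b: ResidueChain) -> float:
    pairs = aln.aligned_columns
    if not pairs:
        return float("nan")
    pa = chain_a.rep_points([a for a, _ in pairs])
    pb = chain_b.rep_points([b for _, b in pairs])
    return rmsd_under(aln.transform, pa, pb)


# ---------------------------------------------------------------------------
# output files

def _gapped_sequences(aln: GlobalAlignment, chain_a, chain_b) -> tuple[str, str]:
    sa, sb = [], []
    for a, b, _ in aln.columns:
        sa.append(chain_a[a].base if a is not None else "-")
        sb.append(chain_b[b].base if b is not None else "-")
    return "".join(sa), "".join(sb)


def write_outputs(aln: GlobalAlignment, chain_a: ResidueChain,
                  chain_b: ResidueChain, out_dir) -> dict[str, Path]:
    """Write the mapping TSV, gapped FASTA, superposed PDB and summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    mapping = out_dir / "mapping.tsv"
    lines = [f"# chain_a: {chain_a.label}", f"# chain_b: {chain_b.label}"]
    flat = list(aln.transform.rotation.flatten()) + list(aln.transform.translation)
    lines.append("# transform: " + " ".join(f"{v:.9f}" for v in flat))
    lines.append("idx_a\tauthor_a\tbase_a\tidx_b\tauthor_b\tbase_b\tprovenance")
    for a, b, prov in aln.columns:
        ra = chain_a[a] if a is not None else None
        rb = chain_b[b] if b is not None else None
        lines.append("\t".join([
            str(a) if a is not None else "-",
            ra.author_id if ra else "-",
            ra.base if ra else "-",
            str(b) if b is not None else "-",
            rb.author_id if rb else "-",
            rb.base if rb else "-",
            prov,
        ]))
    mapping.write_text("\n".join(lines) + "\n")
    paths["mapping"] = mapping

    fasta = out_dir / "alignment.fasta"
    sa, sb = _gapped_sequences(aln, chain_a, chain_b)
    fasta.write_text(f">{chain_a.label}\n{sa}\n>{chain_b.label}\n{sb}\n")
    paths["fasta"] = fasta

    superposed = out_dir / "superposed.pdb"
    write_pdb(superposed, [("A", chain_a.transformed(aln.transform)), ("B", chain_b)])
    paths["superposed"] = superposed

    summary = out_dir / "summary.txt"
    md = aln.metadata
    text = [
        f"chain_a            {chain_a.label} ({len(chain_a)} nt)",
        f"chain_b            {chain_b.label} ({len(chain_b)} nt)",
        f"aligned_columns    {len(aln.aligned_columns)}",
        f"psi                {aln.psi:.1f}",
        f"pss                {'n/a' if aln.pss is None else f'{aln.pss:.1f}'}",
        f"aligned_rmsd       {aln.aligned_rmsd:.4f}",
    ]
    for key in sorted(md):
        text.append(f"{key:<18} {md[key]}")
    summary.write_text("\n".join(text) + "\n")
    paths["summary"] = summary
    return paths
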