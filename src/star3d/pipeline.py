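"""End-to-end pairwise alignment driver.

Orchestrates the stages: base-pair annotation, pseudoknot removal,
stack decomposition, k-stack matching, e-stack extension and ranking,
compatibility-graph maximum clique, consensus tree, anchored loop
alignment and final assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import basepair_annotation as bpa
from . import consensus_tree as ct
from . import loop_alignment as la
from . import stack_matching as sm
from .assembly_metrics import GlobalAlignment, assemble, compute_pss
from .loop_alignment import ScoringParams
from .structure_io import ResidueChain

__all__ = ["AlignParams", "AlignmentResult", "NoAlignmentError", "align_chains"]


class NoAlignmentError(Exception):
    """No e-stack pair of size >= k exists; the method cannot anchor."""


@dataclass(frozen=True)
class AlignParams:
    k: int = sm.DEFAULT_K
    r_c: float = sm.DEFAULT_RC
    max_estacks: int = sm.DEFAULT_MAX_ESTACKS
    scoring: ScoringParams = field(default_factory=ScoringParams)


@dataclass
class AlignmentResult:
    alignment: GlobalAlignment
    tree: ct.ConsensusTree
    estacks: list[sm.EStackPair]
    loop_pairs: list[la.LoopPair]
    loop_alignments: list[la.LoopAlignment]
    secondary_a: bpa.SecondaryStructure
    secondary_b: bpa.SecondaryStructure
    annotated_a: list[bpa.BasePair]
    annotated_b: list[bpa.BasePair]

    @property
    def loop_cells(self) -> int:
        return sum(l.cells for l in self.loop_alignments)


def _secondary(chain: ResidueChain,
               supplied: list[bpa.BasePair] | None) -> tuple[list[bpa.BasePair],
                                                             bpa.SecondaryStructure,
                                                             list[bpa.Stack]]:
    annotated = supplied if supplied is not None else bpa.annotate_basepairs(chain)
    canonical = [p for p in annotated if p.canonical]
    non_canonical = [p for p in annotated if not p.canonical]
    resolved, conflicted = bpa.resolve_pair_conflicts(canonical)
    nested, crossing = bpa.remove_pseudoknots(resolved)
    ss = bpa.SecondaryStructure(nested=nested,
                                loop_pairs=non_canonical + conflicted + crossing)
    stacks = bpa.decompose_stacks(nested)
    return annotated, ss, stacks


def align_chains(chain_a: ResidueChain, chain_b: ResidueChain,
                 params: AlignParams = AlignParams(),
                 pairs_a: list[bpa.BasePair] | None = None,
                 pairs_b: list[bpa.BasePair] | None = None) -> AlignmentResult:
    """Align two RNA chains; raises :class:`NoAlignmentError` when no
    conserved stack of at least k pairs can be matched."""
    annotated_a, ss_a, stacks_a = _secondary(chain_a, pairs_a)
    annotated_b, ss_b, stacks_b = _secondary(chain_b, pairs_b)

    PA = sm.enumerate_kstacks(stacks_a, params.k)
    PB = sm.enumerate_kstacks(stacks_b, params.k)
    if not PA or not PB:
        raise NoAlignmentError(
            f"no stack of >= {params.k} base pairs in one of the inputs")
    C = sm.conservation_matrix(chain_a, chain_b, PA, PB, params.r_c)
    estacks = sm.extend_estacks(C, PA, PB, chain_a, chain_b)
    if not estacks:
        raise NoAlignmentError("no 3D-conserved stack region below the RMSD cutoff")
    estacks = sm.rank_and_filter(estacks, params.max_estacks)

    graph = ct.build_compat_graph(estacks, chain_a, chain_b, params.r_c)
    clique = ct.maximum_clique(graph, estacks)
    tree = ct.consensus_from_clique(clique, estacks, chain_a, chain_b)

    # stacks that did not make the consensus act as loop interactions
    loops_a = ss_a.loop_pairs + ct.demoted_pairs(tree, ss_a.nested, "a")
    loops_b = ss_b.loop_pairs + ct.demoted_pairs(tree, ss_b.nested, "b")

    loop_pairs = la.extract_loop_pairs(tree)
    loop_alignments = [
        la.align_loop_pair(lp, chain_a, chain_b, tree.transform, params.scoring,
                           loops_a, loops_b)
        for lp in loop_pairs
    ]

    alignment = assemble(tree, loop_alignments, chain_a, chain_b)
    alignment.pss = compute_pss(alignment, annotated_a, annotated_b,
                                chain_a, chain_b)
    alignment.metadata.update({
        "k": params.k,
        "r_c": params.r_c,
        "clique_size": len(clique),
        "estack_pairs": len(estacks),
        "consensus_rmsd": round(tree.rmsd, 4),
        "loop_dp_cells": sum(l.cells for l in loop_alignments),
    })
    return AlignmentResult(alignment=alignment, tree=tree, estacks=estacks,
                           loop_pairs=loop_pairs, loop_alignments=loop_alignments,
                           secondary_a=ss_a, secondary_b=ss_b,
                           annotated_a=annotated_a, annotated_b=annotated_b)
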