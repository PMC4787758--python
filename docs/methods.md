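# Methods

## Model

`star3d` treats an RNA 3D structural alignment as a two-level problem.
The helical stacks of the secondary structure are the conserved,
rigid, easily annotated part of an RNA; the loops are variable and are
best compared only against their topological counterparts. The aligner
therefore (i) finds stack regions whose 3D coordinates superpose, (ii)
selects a mutually consistent subset of those matches — consistent both
in secondary-structure topology and in sharing one rigid transform —
and (iii) aligns the loop regions under that fixed transform. No
post-hoc refinement of the superposition is performed: the final
transform is exactly the consensus-stack fit.

Assumptions inherited from this design:

* insertions/deletions inside conserved helices are rare, so stack
  matching is ungapped (k-stack diagonal extension);
* stacks are more conserved than loops, so the stack transform is a
  valid anchor for all loop-distance computations;
* the secondary structure used for anchoring is pseudoknot-free;
  crossing pairs, non-canonical pairs and any helix left out of the
  consensus re-enter as "loop interactions" scored by the pairing
  bonus.

All RMSDs use one representative point per nucleotide — the geometric
centre of the backbone atoms C3', C4', C5', O3', O5' and P that are
present (residues with none of the six are dropped on parsing).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 3 | base pairs per k-stack; 2 rescues very short helices |
| `r_c` | 4.0 Å | RMSD cutoff for k-stack matches, graph edges and the loop distance bands |
| `max_estacks` | 200 | e-stack pairs kept after ranking by RMSD − 0.1·l |
| `match_score` | +2.0 | loop substitution when the 3-nt window distance < 0.5·r_c |
| `mismatch_score` | −1.0 | window distance in [r_c, 2·r_c); beyond 2·r_c alignment is forbidden |
| `gap_open`, `gap_extend` | −3.0, −0.5 | affine gap penalties of the loop DP |
| `pair_bonus` | +1.0 | per matched loop-region pairing interaction |

The loop-scoring magnitudes are conventional affine-gap ratios; only
their relative sizes matter for the behaviours the tests pin down
(all-match diagonals on rigid copies, clean gap runs for loop-length
differences). The PSI/PSS distance threshold is a separate constant
(4 Å) and deliberately does not follow `r_c`.

## Geometric base-pair annotation

Pairing interactions are detected from coordinates alone: C1'–C1'
distance in [8, 12] Å (10.4 ± 1.5 Å for canonical candidates), at least
two donor–acceptor heavy-atom contacts < 3.5 Å between the edge atoms
appropriate for the base combination, base-plane normals within 65°,
and a minimum separation |j − i| ≥ 4 (three unpaired residues per
hairpin). Canonical pairs are A-U, C-G and G-U on Watson-Crick edges.
When a residue acquires several canonical partners the geometrically
best (smallest mean contact distance) wins. This detector is an
intentionally simple stand-in for a full annotation program; users with
trusted annotations can inject them as a table (`--pairs-a/--pairs-b`).

Pseudoknot removal is exact: an interval DP over the pair endpoints
returns a maximum-cardinality non-crossing subset. Ties are broken
toward helix contiguity (adjacent nested pairs kept together) with a
deterministic traceback; only the cardinality is contract-tested
against the exhaustive oracle.

## Consensus construction

Relations between e-stacks are decided on intervals: q1 encloses q2
only when q2 lies strictly inside q1's *innermost* base pair, so
anchor helices can never interleave residues; otherwise disjoint
intervals are juxtaposed and anything else overlaps. Maximal cliques
are enumerated with Bron-Kerbosch (networkx `find_cliques`); among
maximum cliques the choice is (largest total stack length, smallest
total RMSD, lexicographic), recorded in the output metadata. A
single-vertex graph still anchors an alignment, letting lone hairpins
align. The identical-tree property of compatible cliques is asserted at
construction time and exercised as a randomized end-to-end test.

## Loop alignment

Matched loops are read off the consensus tree slot by slot: each leaf
contributes its hairpin, each internal node the segments between its
ordered children, the pseudo-root the exterior segments. Multiloop
segments are aligned slot-by-slot, not concatenated, which is what
makes total loop work equal the sum of per-slot length products (the
anchored-economy property). The DP is the standard three-state affine
recursion with boundary conditions M00 = I00 = D00 = 0,
M(i,0) = M(0,j) = −∞, I(i,0) = gap_open + gap_extend·i,
D(0,j) = gap_open + gap_extend·j, I(0,j) = D(i,0) = −∞. "Forbidden"
substitutions (window distance ≥ 2·r_c) are a saturating sentinel
(−1e18): such residues can only be gapped, and scores never underflow.

Distance windows are 3 nt, truncated at segment termini by keeping
only the offsets valid on *both* sides (no coordinates are invented at
boundaries). The pairing bonus collects up to three partners per
residue (one per Watson-Crick/Hoogsteen/Sugar edge) from the
loop-interaction sets, validates partner matches by the same 3-nt
window distance at chain level, and takes an exact maximum bipartite
matching over the ≤ 3×3 validity matrix. Empty-vs-empty loop slots
score 0; empty-vs-filled costs one affine gap run.

## Synthetic structures

The generator realises any non-crossing dot-bracket topology: stems as
ideal A-form helices (rise 2.81 Å, twist 32.7°/bp, C1'–C1' width
10.4 Å), hairpin loops on a semicircular arc bridging the closing pair
(fixed radius, so loops of different lengths stay superposable — this
is what makes loop-length discrimination testable), and multibranch /
internal loops on a circle whose radius is solved by bisection so that
all attachment chords fit exactly, with child helices growing radially
outward. Default sequences use G/C in stems and A elsewhere. Per-atom
Gaussian noise (reproducible from a seed) and arbitrary rigid motions
model coordinate error and crystal-frame differences.

Bases are minimal: C1', the glycosidic nitrogen and the Watson-Crick
edge atoms, placed so that canonical partners pass the annotator's
H-bond gates with a margin chosen to survive 0.3 Å per-atom noise
(measured failure rate of the standard two-stem fixture: ~0.5% of
seeds; wobble pairs are slightly more fragile, ~1% per pair). The
fixtures deliberately omit what real RNA has: sequence-dependent helix
geometry, sugar pucker, base stacking, tertiary contacts, correlated
(rigid-body) coordinate error and crowding. Passing tests on these
fixtures therefore demonstrates the correctness of the algorithmic
pipeline — annotation gates, combinatorial kernels, anchored DP,
metric arithmetic — not performance on experimental structures.

## Numerical choices and degeneracies

* Kabsch via SVD with determinant correction; reflections are
  impossible by construction and rejected by `RigidTransform`.
* k-stack RMSD correspondence concatenates the 5' strand then the 3'
  strand, both in ascending index order, identically in both chains;
  any consistent order gives the same RMSD.
* `rank_and_filter` ties: larger stack first, then 5'-most positions.
* Degenerate inputs: chains without base atoms annotate to the empty
  set with a warning; structures without any helix of ≥ k pairs raise
  a distinct "no alignment" condition (CLI exit status 2); an empty
  clique degrades to a root-only tree and one whole-chain loop pair.
* Problem sizes in the test battery (≥ 100 randomized end-to-end runs)
  use chains of 12–40 nt, which exercises every code path while keeping
  the default suite in a few seconds.

## Known limitations

* The geometric annotator is not a full edge-classification program;
  non-canonical pairs get a coarse dominant-edge label.
* The pseudoknot DP is exponential-free but cubic in the number of
  pair endpoints; fine for chains where it is exact cardinality that
  matters, slow for ribosome-scale inputs with thousands of pairs.
* Loop partner matching is a per-column heuristic; crossing-aware
  optimal matching of pseudoknotted interactions is out of scope.
* Only the first model of multi-model files is used unless another is
  requested; mmCIF, protein chains and ligands are not parsed.
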