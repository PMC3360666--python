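# Methods

## Problem

Phage-display screening against an antibody yields short peptides
(mimotopes) that mimic the binding behaviour of the antibody's native
epitope.  Conformational epitopes are spatially contiguous but
sequence-discontinuous, so mapping mimotopes back onto the antigen requires
its 3D structure: the package searches for simple paths of solvent-exposed
residues whose spelled sequence resembles each mimotope, and aggregates
significant paths into a single candidate epitope.  Two independent engines
implement this search; an ensemble layer combines them.

## Surface model

A chain is read from standard PDB (ATOM records; MSE kept as Met, other
heteroatoms dropped, altlocs resolved to highest occupancy).  Solvent
accessibility is computed with a rolling-probe (Shrake–Rupley) algorithm:
probe radius 1.4 Å, element van der Waals radii (C 1.70, N 1.55, O 1.52,
S 1.80, Se 1.90 Å), 256 quasi-uniform test points per atom on a
golden-section spiral.  Relative accessibility divides the summed heavy-atom
area by the residue's theoretical Gly-X-Gly maximum (Tien et al. 2013),
clipped to [0, 1].  A residue is *surface* when relative SASA ≥ 0.10
(configurable).  Every residue carries a Cβ coordinate; glycine and residues
with no deposited Cβ fall back to Cα so patch centring is always defined.
The chain is treated in isolation — no occlusion by other chains of the
complex — because the mapping targets the antigen surface as presented to
solution-phase peptides.

## Graphs

Nodes are surface residues; edges join pairs whose Cβ–Cβ Euclidean distance
is below a threshold.

*Whole-surface graph* (ACO engine): fixed threshold, default 8.0 Å.  The
value is a package default in the mid-range of the patch bounds below; it is
not inherited from any published parameterization.

*Patches* (patch engine): one patch per surface residue, all surface
residues within 15 Å of the centre's Cβ.  The 15 Å radius is chosen so a
typical conformational epitope fits inside one patch.  Each patch graph is
built at an adaptive distance threshold (ADT): the smallest threshold within
[4, 12] Å whose graph reaches a target *compactness* of 0.25, where
compactness is edge density 2|E|/(|V|(|V|−1)).  Density is a scale-free
uniformity measure that produces the intended behaviour — longer thresholds
in loose regions, shorter in dense ones — and because it is monotone in the
threshold the ADT is read directly off the sorted pairwise-distance ladder.
If the target is unreachable within bounds, the upper bound is used and a
warning logged (never an exception).  Compactness is regulated per patch,
not globally.

## Path/peptide similarity

A path of m residues is aligned to a peptide of n ≥ m positions: every path
residue is matched, in order, to an increasing subsequence of peptide
positions; each of the n − m unmatched peptide positions pays a gap penalty
(default 4 on the BLOSUM62 scale); matched pairs score by a substitution
matrix (default BLOSUM62; any Biopython matrix name accepted).  Skips are
peptide-side only: mimotopes may carry non-contact residues, but a predicted
surface path must be spatially contiguous.  Both peptide orientations are
scored and the better kept, since the binding direction is unknown.  The
assignment optimum is a small DP whose row i already contains the optimum of
the length-(i+1) path prefix, which the ACO engine exploits (below).

## Patch engine (dynamic programming + branch and bound)

Per patch graph and peptide, the engine finds the highest-scoring simple
path of length ≤ n.  DP state: (current node, visited-set bitmask, last
matched peptide position).  States are expanded layer by layer (layer =
path length); equal states keep the best score; a state is pruned when its
score plus an optimistic completion bound — every remaining peptide position
either stays skipped or gains its column maximum, ignoring adjacency —
cannot beat the incumbent.  The bound is admissible, so with an unlimited
beam the search is exact (verified against exhaustive path enumeration).
The default beam keeps the best 200 states per layer; a beam can only lose
score, never gain.  Layers are expanded as flat numpy arrays (node, mask,
position, score, parent), which keeps the per-layer work vectorized.

Patch score = Σ over panel peptides of −log10 p of the peptide's best
alignment in the patch.  The top-scoring patch (ties: more significant
peptides, then smallest centre residue key) contributes the union of its
significant (p ≤ 0.05) alignments' residues as prediction set A.  Patches
that share an identical member set necessarily produce the identical graph,
so their alignments and backgrounds are computed once and shared.

## Whole-surface engine (ant colony optimization)

Per peptide, ants grow simple paths on the whole-surface graph: the start
node is drawn ∝ a node heuristic η = exp(h/2), where h is the node's best
substitution score against any peptide position; successors are drawn among
unvisited neighbours ∝ pheromone^α · η^β.  A completed walk is scored at its
best-scoring prefix (free, from the assignment DP), so a promising short
path is not penalized for the tail the ant happened to append.  After each
iteration pheromone evaporates (rate 0.1) and the global-best path's edges
receive a constant unit deposit — substitution scores can be negative, so a
score-proportional deposit would be ill-defined — with a 1e-6 floor.
Defaults: 20 ants, 100 iterations, α = 1, β = 2, all configurable; the
global best is monotonically non-decreasing and every run is reproducible
from its seed (per-peptide sub-streams are derived from the run seed by
peptide index, so panel order does not perturb unrelated peptides).

Significant (p ≤ 0.05) best paths form a weighted path graph — node weight
−log10 p, edge when two paths share a residue — whose connected components
are found by DFS; the component with the largest summed weight contributes
its residue union as prediction set B.  Path linkage by residue sharing is
the default; spatial proximity linkage is available in config.

## Significance

A path score is rated against an empirical background: N random peptides of
the same length (default N = 999; the test suite and acceptance script use
99) are scored by the *same* engine on the *same* graph, and

    p = (1 + #{background ≥ score}) / (N + 1) ∈ (0, 1].

Backgrounds are cached per (graph, length), so panels with repeated peptide
lengths pay for one background per graph — this is what makes per-patch
backgrounds affordable.  The default null draws letters i.i.d. uniformly
over the 20-letter alphabet; a composition-preserving shuffle of the query
is available via config (note it defeats the per-length cache, since each
query then needs its own background).  Under the null the P-value is
approximately uniform by construction; no extreme-value fit is attempted.

## Ensemble

With A (patch engine) and B (whole-surface engine) as residue-key sets:
Union A∪B maximizes sensitivity, Intersection A∩B realizes mutual
verification, and Consistency = |A∩B| / |A∪B| summarizes agreement, banded
as ≥ 0.5 almost certain, [0.25, 0.5) likely, (0, 0.25) possible, 0 failed.
Band boundaries are inclusive on the upper side.  When both sets are empty
the Consistency is 0 by convention (reference cases with empty
intersections report 0 rather than 0/0).  Residue identity is the
(chain, number, insertion-code) triple, never the amino-acid letter.  The
inclusion–exclusion identity |A|+|B| = |A∩B|+|A∪B| is asserted on every
call.

## Evaluation

Counting happens on the surface-residue universe of the designated chain
(configurable to all residues): the annotated epitope is positive,
everything else negative.  Se = TP/(TP+FN), Sp = TN/(TN+FP), Pr = TP/PE
with PE = TP+FP and Pr ≡ 0 when PE = 0.  Table aggregation is the
unweighted per-column mean, displayed to 3 decimals and compared at 5e-4.
The package ships the published reference benchmark (27 antibody–antigen
cases; per-engine TP/PE/Se/Sp/Pr, ensemble sizes and Consistency) as TSV
data; one row of it (20/54 vs a Union denominator of 69) is internally
inconsistent as printed and is shipped verbatim.

## Synthetic fixtures

`make_antigen(n, seed)` places Cα atoms on concentric ~3.8 Å-spaced shells
(a globular lattice with a buried core), adds 0.25 Å jitter, rejects
clashes < 2 Å, assigns a uniform-random sequence, and points Cβ 1.5 Å
radially outward.  A planted epitope of 8–12 surface residues grows outward
from a random exposed seed residue under the constraint that all pairs stay
within 15 Å (it fits a single patch).  `make_panel` spells peptides along
random walks through the epitope's 8 Å adjacency (simple paths preferred,
revisits only when the epitope admits no long-enough simple path), mutates
each position with probability 0.2, and replaces a noise fraction (default
conditions: 20 peptides of length 8, noise 0.2) with uniform-random
peptides.

What the fixtures do *not* emulate: real side-chain packing, non-uniform
amino-acid composition, binding energetics, antibody geometry, or panels
with position-biased phage libraries.  Passing recovery tests therefore
demonstrates that the engines can retrieve a geometrically planted signal
from realistic-sized inputs, not that their sensitivity on real
antibody–antigen complexes matches any published figure; reproducing the
published per-case benchmark would require the original structures, panels
and epitope annotations, which are out of scope.

## Numerical choices and degenerate inputs

Problem sizes in the test suite and acceptance script are desk-scale by
design: 60-residue antigens, 20×8 panels, 99-sample backgrounds, 100-graph
oracle sweeps.  Single-residue graphs return length-1 alignments; an
engine that finds no significant alignment returns an empty prediction set
(a legal outcome, mirroring benchmark rows with TP/PE = 0); under the
combined method one engine's failure keeps the surviving side and a failed
band, and only a double failure aborts.  Ties everywhere break
deterministically (score, then count, then smallest residue key), so
predictions are independent of input order, and whole-run JSON output is
byte-identical across repeated seeded runs.

## Known limitations

- Best-path P-values lose power when a peptide's letters are common on the
  antigen surface: decoy paths elsewhere score comparably and the engines
  correctly return small or empty sets.  On synthetic fixtures whose
  epitope letters happen to be undistinguished this makes the
  whole-surface engine the weaker of the two, which is visible in the
  recovery rates.
- The visited-set bitmask uses a single machine word for graphs up to 62
  nodes and falls back to arbitrary-precision integers above that (slower,
  same results).
- mmCIF input, live PDB fetching, motif (pattern) queries and >2-engine
  ensembles are out of scope.
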