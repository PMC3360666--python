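"""Patch-based engine: align mimotopes to simple residue paths by dynamic
programming with branch-and-bound pruning.

A mimotope is aligned to a simple path on a patch graph: every path residue
is matched, in order, to an increasing subsequence of peptide positions, and
each unmatched peptide position pays a gap penalty.  The path must be
spatially contiguous (consecutive residues adjacent in the graph); skips are
allowed only on the peptide side, because affinity-selected peptides may
carry non-contact residues while a predicted epitope should not have spatial
holes.  Both peptide orientations are scored and the better one kept.

The search over paths is a layered DP whose state is (current node,
visited-set fingerprint, last matched peptide position).  States whose score
plus an optimistic completion bound cannot beat the incumbent are pruned
(branch and bound); a beam limit per layer bounds work on large patches and
with an unlimited beam the search is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .candidate_assembly import PredictionSet, select_top_patch, top_patch_index
from .structure_io import AntigenChain, Residue
from .surface_graph import (
    DEFAULT_ADT_BOUNDS,
    DEFAULT_PATCH_RADIUS,
    DEFAULT_TARGET_COMPACTNESS,
    SurfaceGraph,
    _graph_from_residues,
    extract_patches,
    regulate_adt,
)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

DEFAULT_GAP_PENALTY = 4.0
DEFAULT_BEAM_WIDTH = 200
NEG_INF = -1e18


class PeptideError(ValueError):
    pass


@dataclass(frozen=True)
class Peptide:
    """A mimotope sequence (uppercase, 20 standard letters only)."""

    name: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 1:
            raise PeptideError(f"peptide {self.name!r} is empty")
        bad = sorted({c for c in seq if c not in AA_INDEX})
        if bad:
            raise PeptideError(
                f"peptide {self.name!r} contains non-standard letters: {''.join(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def indices(self) -> np.ndarray:
        return np.array([AA_INDEX[c] for c in self.sequence], dtype=np.int64)


@lru_cache(maxsize=None)
def load_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """A 20×20 substitution matrix over :data:`AA_ALPHABET` order."""
    from Bio.Align import substitution_matrices

    raw = substitution_matrices.load(name)
    m = np.zeros((20, 20))
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            m[i, j] = raw[a, b]
    return m


@dataclass
class PathAlignment:
    """A simple residue path aligned to one peptide."""

    path: list[Residue]
    peptide: Peptide
    orientation: str  # "forward" | "reverse"
    score: float
    p_value: float | None = None

    def residue_keys(self) -> frozenset:
        return frozenset(r.key for r in self.path)

    def __len__(self) -> int:
        return len(self.path)


def _path_indices(path) -> np.ndarray:
    idx = []
    for item in path:
        aa = item.aa if isinstance(item, Residue) else item
        if aa not in AA_INDEX:
            raise PeptideError(f"non-standard residue letter {aa!r} in path")
        idx.append(AA_INDEX[aa])
    return np.array(idx, dtype=np.int64)


def _best_assignment(S: np.ndarray) -> float:
    """Best order-preserving matching of all m rows to an increasing
    subsequence of the n ≥ m columns of score table ``S``."""
    m, n = S.shape
    prev = np.maximum.accumulate(S[0])
    for i in range(1, m):
        cand = np.full(n, NEG_INF)
        cand[i:] = prev[i - 1 : n - 1] + S[i, i:]
        prev = np.maximum.accumulate(cand)
    return float(prev[-1])


def score_path(
    path,
    peptide: Peptide,
    matrix: np.ndarray | None = None,
    gap_penalty: float = DEFAULT_GAP_PENALTY,
) -> float:
    """Similarity between a residue path and a mimotope.

    Maximum over the two peptide orientations of the summed substitution
    scores of an order-preserving, path-contiguous matching, minus
    ``gap_penalty`` for each skipped peptide position.  Requires
    ``len(path) <= len(peptide)``.
    """
    if matrix is None:
        matrix = load_matrix()
    p_idx = _path_indices(path)
    q_idx = peptide.indices
    m, n = len(p_idx), len(q_idx)
    if m == 0:
        raise ValueError("path is empty")
    if m > n:
        raise ValueError(f"path length {m} exceeds peptide length {n}")
    best = NEG_INF
    for q in (q_idx, q_idx[::-1]):
        best = max(best, _best_assignment(matrix[np.ix_(p_idx, q)]))
    return best - gap_penalty * (n - m)


def best_prefix_score(
    path,
    peptide: Peptide,
    matrix: np.ndarray | None = None,
    gap_penalty: float = DEFAULT_GAP_PENALTY,
) -> tuple[float, int]:
    """Best :func:`score_path` value over all non-empty prefixes of ``path``.

    The assignment DP yields every prefix's optimum in a single pass, so
    trying all prefixes costs no more than scoring the full path.  Returns
    ``(score, prefix_length)``; ties prefer the shorter prefix.
    """
    if matrix is None:
        matrix = load_matrix()
    p_idx = _path_indices(path)
    q_idx = peptide.indices
    m, n = len(p_idx), len(q_idx)
    if m == 0:
        raise ValueError("path is empty")
    m = min(m, n)
    best, best_len = NEG_INF, 1
    for q in (q_idx, q_idx[::-1]):
        S = matrix[np.ix_(p_idx[:m], q)]
        prev = np.maximum.accumulate(S[0])
        for i in range(m):
            if i > 0:
                cand = np.full(n, NEG_INF)
                cand[i:] = prev[i - 1 : n - 1] + S[i, i:]
                prev = np.maximum.accumulate(cand)
            val = float(prev[-1]) - gap_penalty * (n - (i + 1))
            if val > best:
                best, best_len = val, i + 1
    return best, best_len


def score_path_detail(
    path,
    peptide: Peptide,
    matrix: np.ndarray | None = None,
    gap_penalty: float = DEFAULT_GAP_PENALTY,
) -> tuple[float, str]:
    """Like :func:`score_path` but also reports the winning orientation."""
    if matrix is None:
        matrix = load_matrix()
    p_idx = _path_indices(path)
    q_idx = peptide.indices
    n, m = len(q_idx), len(p_idx)
    fwd = _best_assignment(matrix[np.ix_(p_idx, q_idx)])
    rev = _best_assignment(matrix[np.ix_(p_idx, q_idx[::-1])])
    gap = gap_penalty * (n - m)
    if rev > fwd:
        return rev - gap, "reverse"
    return fwd - gap, "forward"


def _completion_bound(score, k, last_j, L, gap_penalty, suffix_gain):
    """Optimistic final score from a k-long path whose last match is at
    peptide position ``last_j``: every remaining peptide position is either
    skipped (already charged) or matched at its per-column maximum."""
    return score - gap_penalty * (L - k) + suffix_gain[last_j + 1]


def _search_one_orientation(graph, pep_idx, matrix, gap_penalty, beam_width):
    indptr, indices, aa_index = graph.adjacency_arrays()
    n = len(aa_index)
    L = len(pep_idx)
    S = matrix[aa_index][:, pep_idx]  # node × peptide-position score table
    maxcol = matrix[:, pep_idx].max(axis=0)
    # suffix_gain[j] = optimistic gain from peptide positions ≥ j
    gain = np.maximum(0.0, gap_penalty + maxcol)
    suffix_gain = np.zeros(L + 1)
    suffix_gain[:L] = gain[::-1].cumsum()[::-1]

    use_obj = n > 62
    mask_one = (np.ones(n, dtype=object) if use_obj else np.ones(n, dtype=np.int64))

    nodes = np.repeat(np.arange(n, dtype=np.int64), L)
    jpos = np.tile(np.arange(L, dtype=np.int64), n)
    scores = S[nodes, jpos]
    masks = mask_one[nodes] << nodes
    parents = np.full(len(nodes), -1, dtype=np.int64)
    layers = []

    best_val = NEG_INF
    best_ref = None  # (layer, state index)
    max_len = min(n, L)
    deg = indptr[1:] - indptr[:-1]

    for k in range(1, max_len + 1):
        if len(nodes) == 0:
            break
        # prune states that cannot beat the incumbent even in the best case
        bounds = scores - gap_penalty * (L - k) + suffix_gain[jpos + 1]
        keep = bounds >= best_val - 1e-9
        nodes, jpos, scores, masks, parents = (
            nodes[keep], jpos[keep], scores[keep], masks[keep], parents[keep],
        )
        if len(nodes) == 0:
            break
        # deduplicate identical (mask, node, j) states, keeping the best score
        if not use_obj and len(nodes) > 1:
            order = np.lexsort((-scores, jpos, nodes, masks))
            nodes, jpos, scores, masks, parents = (
                nodes[order], jpos[order], scores[order], masks[order], parents[order],
            )
            first = np.ones(len(nodes), dtype=bool)
            same = (
                (nodes[1:] == nodes[:-1])
                & (jpos[1:] == jpos[:-1])
                & (masks[1:] == masks[:-1])
            )
            first[1:] = ~same
            nodes, jpos, scores, masks, parents = (
                nodes[first], jpos[first], scores[first], masks[first], parents[first],
            )
        # beam truncation (beam_width=None means exact search)
        if beam_width is not None and len(nodes) > beam_width:
            top = np.argpartition(-scores, beam_width - 1)[:beam_width]
            nodes, jpos, scores, masks, parents = (
                nodes[top], jpos[top], scores[top], masks[top], parents[top],
            )
        layers.append((nodes, jpos, parents))
        # a path may stop at this layer
        stop = scores - gap_penalty * (L - k)
        i_best = int(np.argmax(stop))
        if stop[i_best] > best_val:
            best_val = float(stop[i_best])
            best_ref = (k - 1, i_best)
        if k == max_len:
            break
        # expand: every unvisited neighbour × every later peptide position
        rep = np.repeat(np.arange(len(nodes)), deg[nodes])
        if len(rep) == 0:
            break
        nbr = np.concatenate([indices[indptr[v] : indptr[v + 1]] for v in nodes])
        unvisited = ((masks[rep] >> nbr) & 1) == 0
        if use_obj:
            unvisited = unvisited.astype(bool)
        rep, nbr = rep[unvisited], nbr[unvisited]
        if len(rep) == 0:
            break
        counts = (L - 1) - jpos[rep]
        pos = counts > 0
        rep, nbr, counts = rep[pos], nbr[pos], counts[pos]
        if len(rep) == 0:
            break
        rep2 = np.repeat(np.arange(len(rep)), counts)
        offsets = np.arange(int(counts.sum())) - np.repeat(
            np.concatenate(([0], counts.cumsum()[:-1])), counts
        )
        new_j = jpos[rep][rep2] + 1 + offsets
        parent_state = rep[rep2]
        new_nodes = nbr[rep2]
        new_scores = scores[parent_state] + S[new_nodes, new_j]
        new_masks = masks[parent_state] | (mask_one[new_nodes] << new_nodes)
        nodes, jpos, scores, masks, parents = (
            new_nodes, new_j, new_scores, new_masks, parent_state,
        )

    if best_ref is None:
        return NEG_INF, []
    # walk parent pointers back to the start of the path
    layer, idx = best_ref
    rev = []
    while layer >= 0:
        l_nodes, _, l_parents = layers[layer]
        rev.append(int(l_nodes[idx]))
        idx = int(l_parents[idx])
        layer -= 1
    return best_val, rev[::-1]


def best_alignment_in_patch(
    patch_graph: SurfaceGraph,
    peptide: Peptide,
    matrix: np.ndarray | None = None,
    gap_penalty: float = DEFAULT_GAP_PENALTY,
    beam_width: int | None = DEFAULT_BEAM_WIDTH,
) -> PathAlignment:
    """Highest-scoring simple path of length ≤ len(peptide) in a patch graph.

    With ``beam_width=None`` the layered DP with branch-and-bound is exact;
    a finite beam keeps only the best states per layer and can only lose
    score, never gain it.
    """
    if matrix is None:
        matrix = load_matrix()
    if patch_graph.n_nodes == 0:
        raise ValueError("patch graph is empty")
    q_idx = peptide.indices
    best = (NEG_INF, [], "forward")
    for label, q in (("forward", q_idx), ("reverse", q_idx[::-1])):
        val, node_path = _search_one_orientation(
            patch_graph, q, matrix, gap_penalty, beam_width
        )
        if val > best[0]:
            best = (val, node_path, label)
    _, node_path, orientation = best
    path = [patch_graph.residues[i] for i in node_path]
    # canonical score: recomputation from the path itself
    score = score_path(path, peptide, matrix, gap_penalty)
    return PathAlignment(path=path, peptide=peptide, orientation=orientation, score=score)


@dataclass
class MimoProParams:
    """Tunables of the patch-based engine (all configurable)."""

    patch_radius: float = DEFAULT_PATCH_RADIUS
    target_compactness: float = DEFAULT_TARGET_COMPACTNESS
    adt_bounds: tuple[float, float] = DEFAULT_ADT_BOUNDS
    matrix_name: str = "BLOSUM62"
    gap_penalty: float = DEFAULT_GAP_PENALTY
    beam_width: int | None = DEFAULT_BEAM_WIDTH
    p_cutoff: float = 0.05
    n_background: int = 999
    null_model: str = "uniform"
    seed: int = 0


@dataclass
class MimoProRun:
    prediction: PredictionSet
    patch_results: list  # (Patch, patch score, significant alignments)
    alignments: dict  # peptide name -> (PathAlignment, p) in the top patch


def mimopro_run(chain: AntigenChain, panel: list[Peptide], params: MimoProParams | None = None) -> MimoProRun:
    """Full patch-engine run, keeping per-patch diagnostics.

    Every patch is scored as Σ over peptides of −log10(p) of its best path
    alignment; the top patch's significant alignments (p ≤ cutoff) yield the
    predicted residue set.
    """
    from .significance import BackgroundCache

    if params is None:
        params = MimoProParams()
    if not panel:
        raise ValueError("need at least one peptide")
    if not chain.surface_residues:
        raise ValueError("chain has no classified surface residues")
    matrix = load_matrix(params.matrix_name)
    patches = extract_patches(chain, params.patch_radius)
    cache = BackgroundCache()
    # patches sharing one member set produce one graph under the ADT, so
    # their alignments and backgrounds are computed once and shared
    groups: dict[frozenset, list[int]] = {}
    for idx, patch in enumerate(patches):
        groups.setdefault(frozenset(r.key for r in patch.members), []).append(idx)
    scored = [None] * len(patches)
    for members_key in sorted(groups, key=lambda k: min(groups[k])):
        idxs = groups[members_key]
        rep = min(idxs)
        patch = patches[rep]
        if patch.size >= 2:
            graph = regulate_adt(patch, params.target_compactness, params.adt_bounds)
        else:
            graph = _graph_from_residues(patch.members, params.adt_bounds[0])
        for i in idxs:
            patches[i].graph = graph

        def engine(seq: str, _g=graph) -> float:
            return best_alignment_in_patch(
                _g, Peptide("bg", seq), matrix, params.gap_penalty, params.beam_width
            ).score

        patch_score = 0.0
        sig_alignments = []
        per_pep = {}
        for pep in panel:
            aln = best_alignment_in_patch(
                graph, pep, matrix, params.gap_penalty, params.beam_width
            )
            bg = cache.get_or_build(
                graph,
                len(pep),
                params.n_background,
                engine,
                seed=np.random.SeedSequence(params.seed, spawn_key=(rep, len(pep))),
                null_model=params.null_model,
                query=pep.sequence,
            )
            aln.p_value = bg.empirical_p(aln.score)
            patch_score += -math.log10(aln.p_value)
            per_pep[pep.name] = (aln, aln.p_value)
            if aln.p_value <= params.p_cutoff:
                sig_alignments.append(aln)
        for i in idxs:
            scored[i] = (patches[i], patch_score, sig_alignments, per_pep)

    entries = [(patch, score, sig) for patch, score, sig, _ in scored]
    prediction = select_top_patch(entries, source="mimopro")
    top_idx = top_patch_index(entries)
    return MimoProRun(
        prediction=prediction,
        patch_results=entries,
        alignments=scored[top_idx][3],
    )


def run_mimopro(
    chain: AntigenChain, panel: list[Peptide], params: MimoProParams | None = None
) -> PredictionSet:
    """Patch-engine prediction: residue set of the top-scoring patch."""
    return mimopro_run(chain, panel, params).prediction
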