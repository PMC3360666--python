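"""Whole-surface engine: ant-colony optimization over the surface graph.

Each ant grows a simple path: the start node is sampled proportionally to a
node heuristic (the best substitution score of that residue against any
peptide position), and each successor is sampled among unvisited neighbours
with probability ∝ pheromone^alpha × heuristic^beta.  Completed paths are
scored by the same path/peptide similarity used by the patch engine.  After
every iteration the pheromone field evaporates and the global-best path
receives a constant deposit (substitution scores can be negative, so a
score-proportional deposit would be ill-defined); a floor keeps all levels
positive.  The global best is therefore monotonically non-decreasing over
iterations, and the whole search is reproducible from its seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .candidate_assembly import PredictionSet, cluster_paths
from .peptide_align import (
    DEFAULT_GAP_PENALTY,
    PathAlignment,
    Peptide,
    best_prefix_score,
    load_matrix,
    score_path_detail,
)
from .structure_io import AntigenChain
from .surface_graph import SurfaceGraph, build_surface_graph

PHEROMONE_FLOOR = 1e-6
DEFAULT_SURFACE_THRESHOLD = 8.0


@dataclass
class AcoParams:
    n_ants: int = 20
    n_iterations: int = 100
    evaporation: float = 0.1
    alpha: float = 1.0
    beta: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_ants < 1 or self.n_iterations < 1:
            raise ValueError("ant and iteration counts must be >= 1")
        if not 0 < self.evaporation < 1:
            raise ValueError("evaporation must be in (0, 1)")


class PheromoneState:
    """Per-edge pheromone levels, stored on the CSR edge array."""

    def __init__(self, n_edges: int, initial: float = 1.0):
        self.levels = np.full(n_edges, initial)

    def evaporate(self, rho: float) -> None:
        self.levels *= 1.0 - rho
        np.maximum(self.levels, PHEROMONE_FLOOR, out=self.levels)

    def deposit(self, edge_ids, amount: float = 1.0) -> None:
        self.levels[edge_ids] += amount


def _ant_walk(indptr, indices, tau, eta_pow, start, max_len, visited, stamp, alpha, rng):
    """Grow one simple path; returns node list and CSR edge slots used."""
    path = [start]
    edges = []
    visited[start] = stamp
    node = start
    while len(path) < max_len:
        lo, hi = indptr[node], indptr[node + 1]
        nbrs = indices[lo:hi]
        if len(nbrs) == 0:
            break
        w = (tau[lo:hi] ** alpha) * eta_pow[nbrs]
        w = np.where(visited[nbrs] == stamp, 0.0, w)
        total = w.sum()
        if total <= 0:
            break
        c = np.cumsum(w)
        pick = int(np.searchsorted(c, rng.random() * total, side="right"))
        pick = min(pick, len(nbrs) - 1)
        nxt = int(nbrs[pick])
        edges.append(lo + pick)
        path.append(nxt)
        visited[nxt] = stamp
        node = nxt
    return path, edges


def aco_best_path(
    graph: SurfaceGraph,
    peptide: Peptide,
    matrix: np.ndarray | None = None,
    params: AcoParams | None = None,
    gap_penalty: float = DEFAULT_GAP_PENALTY,
    rng: np.random.Generator | None = None,
    return_trace: bool = False,
):
    """Best simple path for one peptide found by the ant colony.

    Paths are capped at the peptide length.  With ``return_trace=True`` the
    per-iteration global-best score history is returned alongside the
    alignment (used to check monotone improvement).
    """
    if params is None:
        params = AcoParams()
    if matrix is None:
        matrix = load_matrix()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if graph.n_nodes == 0:
        raise ValueError("surface graph is empty")
    indptr, indices, aa_index = graph.adjacency_arrays()
    L = len(peptide)
    S = matrix[aa_index][:, peptide.indices]
    h = S.max(axis=1)  # best substitution score vs any peptide position
    eta = np.exp(0.5 * h)  # positive heuristic, monotone in h
    eta_pow = eta ** params.beta
    start_p = eta / eta.sum()

    n = graph.n_nodes
    tau = PheromoneState(len(indices))
    visited = np.zeros(n, dtype=np.int64)
    stamp = 0
    best_score = -np.inf
    best_path: list[int] = []
    trace = []

    for _ in range(params.n_iterations):
        starts = rng.choice(n, size=params.n_ants, p=start_p)
        iteration_best = None
        for a in range(params.n_ants):
            stamp += 1
            path, edges = _ant_walk(
                indptr, indices, tau.levels, eta_pow, int(starts[a]),
                min(L, n), visited, stamp, params.alpha, rng,
            )
            residues = [graph.residues[i] for i in path]
            # a walk's best-scoring prefix counts: a promising short path
            # must not be penalized for the tail the ant happened to add
            score, plen = best_prefix_score(residues, peptide, matrix, gap_penalty)
            if score > best_score:
                best_score = score
                best_path = path[:plen]
                iteration_best = edges[: plen - 1]
        tau.evaporate(params.evaporation)
        if best_path:
            if iteration_best is None:
                # re-derive CSR slots of the reigning global-best path
                iteration_best = _edge_slots(indptr, indices, best_path)
            tau.deposit(np.asarray(iteration_best, dtype=np.int64))
        trace.append(best_score)

    residues = [graph.residues[i] for i in best_path]
    final_score, orientation = score_path_detail(residues, peptide, matrix, gap_penalty)
    aln = PathAlignment(
        path=residues, peptide=peptide, orientation=orientation, score=final_score
    )
    return (aln, trace) if return_trace else aln


def _edge_slots(indptr, indices, path):
    slots = []
    for u, v in zip(path, path[1:]):
        lo, hi = indptr[u], indptr[u + 1]
        slots.append(int(lo + np.searchsorted(indices[lo:hi], v)))
    return slots


@dataclass
class Pep3dParams:
    """Tunables of the whole-surface ACO engine."""

    surface_threshold: float = DEFAULT_SURFACE_THRESHOLD
    aco: AcoParams = None
    matrix_name: str = "BLOSUM62"
    gap_penalty: float = DEFAULT_GAP_PENALTY
    p_cutoff: float = 0.05
    n_background: int = 999
    null_model: str = "uniform"
    seed: int = 0

    def __post_init__(self):
        if self.aco is None:
            self.aco = AcoParams(seed=self.seed)


@dataclass
class Pep3dRun:
    prediction: PredictionSet
    alignments: dict  # peptide name -> (PathAlignment, p)


def pep3d_run(
    chain: AntigenChain, panel: list[Peptide], params: Pep3dParams | None = None
) -> Pep3dRun:
    """Full whole-surface run with per-peptide diagnostics.

    Sub-streams of the run RNG are derived per peptide index so that the
    panel order does not perturb unrelated peptides; backgrounds get their
    own deterministic streams keyed by peptide length.
    """
    from .significance import BackgroundCache

    if params is None:
        params = Pep3dParams()
    if not panel:
        raise ValueError("need at least one peptide")
    matrix = load_matrix(params.matrix_name)
    graph = build_surface_graph(chain, params.surface_threshold)
    cache = BackgroundCache()

    def engine(seq: str, sub_seed) -> float:
        pep = Peptide("bg", seq)
        rng = np.random.default_rng(sub_seed)
        return aco_best_path(
            graph, pep, matrix, params.aco, params.gap_penalty, rng=rng
        ).score

    significant = []
    per_pep = {}
    for i, pep in enumerate(panel):
        rng = np.random.default_rng(np.random.SeedSequence(params.seed, spawn_key=(0, i)))
        aln = aco_best_path(graph, pep, matrix, params.aco, params.gap_penalty, rng=rng)
        bg_seed = np.random.SeedSequence(params.seed, spawn_key=(1, len(pep)))
        bg = cache.get_or_build(
            graph,
            len(pep),
            params.n_background,
            # every background peptide searches with its own deterministic
            # stream derived from its sequence (crc32 is platform-stable)
            lambda s: engine(
                s, np.random.SeedSequence(params.seed, spawn_key=(2, zlib.crc32(s.encode())))
            ),
            seed=bg_seed,
            null_model=params.null_model,
            query=pep.sequence,
        )
        aln.p_value = bg.empirical_p(aln.score)
        per_pep[pep.name] = (aln, aln.p_value)
        if aln.p_value <= params.p_cutoff:
            significant.append(aln)

    prediction = cluster_paths(significant, source="pep3d")
    return Pep3dRun(prediction=prediction, alignments=per_pep)


def run_pep3d(
    chain: AntigenChain, panel: list[Peptide], params: Pep3dParams | None = None
) -> PredictionSet:
    """Whole-surface engine prediction: DFS-clustered significant paths."""
    return pep3d_run(chain, panel, params).prediction
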