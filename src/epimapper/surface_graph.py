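"""Residue graphs over the antigen surface.

Two flavours are used by the search engines: a single whole-surface graph
built at a fixed Cβ–Cβ distance threshold, and overlapping 15 Å patches
centered at each surface residue's Cβ whose internal graph is built at an
adaptive distance threshold (ADT) chosen so every patch graph reaches a
common target compactness (edge density).  A longer threshold is thereby
used in loose regions and a shorter one in densely packed regions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .structure_io import AntigenChain, Residue, ResidueKey

logger = logging.getLogger(__name__)

DEFAULT_PATCH_RADIUS = 15.0
DEFAULT_TARGET_COMPACTNESS = 0.25
DEFAULT_ADT_BOUNDS = (4.0, 12.0)

_graph_counter = itertools.count()


class EmptyGraphError(ValueError):
    pass


@dataclass
class SurfaceGraph:
    """Undirected residue graph with Cβ–Cβ distance edges.

    ``token`` identifies the graph instance for background-distribution
    caching.  ``compactness`` is the edge density 2|E| / (|V|(|V|−1)),
    defined as 0 for graphs with fewer than two nodes.
    """

    residues: list[Residue]
    threshold_used: float
    nx_graph: nx.Graph = field(repr=False)
    token: int = field(default_factory=lambda: next(_graph_counter))

    def __post_init__(self):
        self._csr = None

    @property
    def n_nodes(self) -> int:
        return len(self.residues)

    @property
    def n_edges(self) -> int:
        return self.nx_graph.number_of_edges()

    @property
    def compactness(self) -> float:
        n = self.n_nodes
        if n <= 1:
            return 0.0
        return 2.0 * self.n_edges / (n * (n - 1))

    def residue_by_key(self, key: ResidueKey) -> Residue:
        return self.nx_graph.nodes[key]["residue"]

    def adjacency_arrays(self):
        """CSR adjacency over node indices 0..n-1 (cached).

        Returns ``(indptr, indices, aa_index)`` where ``aa_index[i]`` is the
        row of node i's amino acid in the substitution-matrix alphabet.
        """
        if self._csr is None:
            from .peptide_align import AA_INDEX

            n = self.n_nodes
            index_of = {r.key: i for i, r in enumerate(self.residues)}
            nbrs: list[list[int]] = [[] for _ in range(n)]
            for u, v in self.nx_graph.edges():
                iu, iv = index_of[u], index_of[v]
                nbrs[iu].append(iv)
                nbrs[iv].append(iu)
            indptr = np.zeros(n + 1, dtype=np.int64)
            for i in range(n):
                nbrs[i].sort()
                indptr[i + 1] = indptr[i] + len(nbrs[i])
            indices = np.fromiter(
                (j for lst in nbrs for j in lst), dtype=np.int64, count=int(indptr[-1])
            )
            aa_index = np.array([AA_INDEX[r.aa] for r in self.residues], dtype=np.int64)
            self._csr = (indptr, indices, aa_index)
        return self._csr

    def write_edge_list(self, path) -> None:
        """Debug export: one edge per line as id<TAB>id<TAB>distance_Å."""
        with open(path, "w") as fh:
            fh.write("residue_a\tresidue_b\tdistance_A\n")
            for u, v, d in sorted(self.nx_graph.edges(data="distance")):
                fh.write(f"{_fmt_key(u)}\t{_fmt_key(v)}\t{d:.3f}\n")


def _fmt_key(key: ResidueKey) -> str:
    chain, num, icode = key
    return f"{chain}:{num}{icode}"


@dataclass
class Patch:
    """Surface residues within ``radius`` of the center residue's Cβ."""

    center: Residue
    radius: float
    members: list[Residue]
    graph: SurfaceGraph | None = None

    @property
    def size(self) -> int:
        return len(self.members)


def _graph_from_residues(residues: list[Residue], threshold: float) -> SurfaceGraph:
    g = nx.Graph()
    for r in residues:
        g.add_node(r.key, residue=r)
    if len(residues) >= 2:
        coords = np.array([r.cb_xyz for r in residues])
        dists = squareform(pdist(coords))
        n = len(residues)
        ii, jj = np.triu_indices(n, k=1)
        within = dists[ii, jj] <= threshold
        for i, j in zip(ii[within], jj[within]):
            g.add_edge(residues[i].key, residues[j].key, distance=float(dists[i, j]))
    return SurfaceGraph(residues=list(residues), threshold_used=float(threshold), nx_graph=g)


def build_surface_graph(chain: AntigenChain, threshold: float) -> SurfaceGraph:
    """Whole-surface graph: nodes are surface residues, edges join pairs with
    Cβ–Cβ distance ≤ ``threshold``."""
    if threshold <= 0:
        raise ValueError("distance threshold must be positive")
    surface = chain.surface_residues
    if not surface:
        raise EmptyGraphError("chain has no surface residues; classify_surface first?")
    return _graph_from_residues(surface, threshold)


def extract_patches(chain: AntigenChain, radius: float = DEFAULT_PATCH_RADIUS) -> list[Patch]:
    """One overlapping patch per surface residue (its own center)."""
    surface = chain.surface_residues
    if not surface:
        raise EmptyGraphError("chain has no surface residues; classify_surface first?")
    coords = np.array([r.cb_xyz for r in surface])
    tree = cKDTree(coords)
    patches = []
    for i, center in enumerate(surface):
        member_idx = sorted(tree.query_ball_point(coords[i], radius))
        patches.append(
            Patch(center=center, radius=radius, members=[surface[j] for j in member_idx])
        )
    return patches


def regulate_adt(
    patch: Patch,
    target_compactness: float = DEFAULT_TARGET_COMPACTNESS,
    bounds: tuple[float, float] = DEFAULT_ADT_BOUNDS,
) -> SurfaceGraph:
    """Build the patch graph at the adaptive distance threshold.

    The ADT is the smallest threshold within ``bounds`` at which the patch
    graph's compactness reaches ``target_compactness``.  Because compactness
    is non-decreasing in the threshold, the ADT is located directly on the
    sorted pairwise-distance ladder.  If the target is unreachable within
    bounds the upper bound is used and a warning logged.
    """
    if not 0 < target_compactness <= 1:
        raise ValueError("target compactness must be in (0, 1]")
    lo, hi = bounds
    if patch.size < 2:
        raise ValueError("patch must have at least 2 members")
    coords = np.array([r.cb_xyz for r in patch.members])
    dists = np.sort(pdist(coords))
    n = patch.size
    n_pairs = n * (n - 1) // 2
    # smallest edge count whose density meets the target
    k_needed = int(np.ceil(target_compactness * n_pairs - 1e-9))
    threshold = float(dists[k_needed - 1]) if 0 < k_needed <= n_pairs else hi
    if k_needed > n_pairs or threshold > hi:
        achieved = float((dists <= hi).sum()) * 2.0 / (n * (n - 1))
        logger.warning(
            "patch at %s: target compactness %.3f unreachable within ADT bounds "
            "[%g, %g] Å (achieves %.3f at upper bound)",
            _fmt_key(patch.center.key), target_compactness, lo, hi, achieved,
        )
        threshold = hi
    threshold = min(max(threshold, lo), hi)
    graph = _graph_from_residues(patch.members, threshold)
    patch.graph = graph
    return graph
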