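"""Assemble significant per-peptide alignments into one candidate epitope.

The whole-surface engine links significant path alignments that share at
least one residue into a weighted path graph, finds its connected components
by depth-first search, and returns the residue union of the component with
the largest summed −log10(p) weight.  The patch engine simply returns the
residue union of the significant alignments in the top-scoring patch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx

from .structure_io import ResidueKey


@dataclass(frozen=True)
class PredictionSet:
    """Set of predicted epitopic residues from one engine.

    Residues are identified by (chain_id, seq_num, icode) so repeated
    amino-acid types never collapse.
    """

    residues: frozenset[ResidueKey]
    source: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    def __bool__(self) -> bool:
        return bool(self.residues)

    @property
    def chain_ids(self) -> frozenset[str]:
        return frozenset(k[0] for k in self.residues)

    def sorted_keys(self) -> list[ResidueKey]:
        return sorted(self.residues)

    @staticmethod
    def empty(source: str = "") -> "PredictionSet":
        return PredictionSet(residues=frozenset(), source=source)


def _weight(alignment) -> float:
    p = alignment.p_value
    if p is None:
        raise ValueError("alignment has no P-value; score significance first")
    return -math.log10(p)


def build_path_graph(alignments) -> nx.Graph:
    """Weighted graph of alignments: edge iff two alignments share a residue."""
    g = nx.Graph()
    keysets = [a.residue_keys() for a in alignments]
    for i, a in enumerate(alignments):
        g.add_node(i, alignment=a, weight=_weight(a))
    for i in range(len(alignments)):
        for j in range(i + 1, len(alignments)):
            if keysets[i] & keysets[j]:
                g.add_edge(i, j)
    return g


def cluster_paths(alignments, source: str = "pep3d") -> PredictionSet:
    """DFS-cluster significant alignments; return the residue union of the
    component with the largest summed node weight.

    Ties between components are broken by the lexicographically smallest
    sorted residue-key list, so the result is independent of input order.
    """
    alignments = list(alignments)
    if not alignments:
        return PredictionSet.empty(source)
    g = build_path_graph(alignments)
    best = None
    for comp in nx.connected_components(g):  # DFS traversal
        weight = sum(g.nodes[i]["weight"] for i in comp)
        residues = sorted(
            frozenset().union(*(g.nodes[i]["alignment"].residue_keys() for i in comp))
        )
        cand_rank = (weight, tuple(map(_neg_rank, residues)))
        if best is None or cand_rank > best[0]:
            best = (cand_rank, residues)
    return PredictionSet(residues=frozenset(best[1]), source=source)


def _neg_rank(key: ResidueKey):
    # smaller residue keys should win ties -> invert for max() comparison
    chain, num, icode = key
    return (tuple(-ord(c) for c in chain), -num, tuple(-ord(c) for c in icode))


def top_patch_index(patch_scores) -> int:
    """Index of the winning patch: highest score, then most significant
    alignments, then smallest (chain, seq_num, icode) of the center."""
    if not patch_scores:
        raise ValueError("no patches to select from")

    def rank(item):
        idx, (patch, score, alignments) = item
        return (score, len(alignments), _neg_rank(patch.center.key))

    return max(enumerate(patch_scores), key=rank)[0]


def select_top_patch(patch_scores, source: str = "mimopro") -> PredictionSet:
    """Residue union of significant alignments in the argmax-score patch.

    ``patch_scores`` is a list of (patch, score, significant alignments).
    All-zero scores (no significant alignment anywhere) yield an empty set.
    """
    idx = top_patch_index(patch_scores)
    patch, score, alignments = patch_scores[idx]
    if score <= 0 or not alignments:
        return PredictionSet.empty(source)
    residues = frozenset().union(*(a.residue_keys() for a in alignments))
    return PredictionSet(residues=residues, source=source)
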