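"""Path/peptide scoring and the DP + branch-and-bound path search."""

import itertools

import numpy as np
import pytest

from epimapper.peptide_align import (
    AA_ALPHABET,
    Peptide,
    PeptideError,
    best_alignment_in_patch,
    best_prefix_score,
    load_matrix,
    score_path,
)
from epimapper.surface_graph import build_surface_graph

from conftest import make_chain

IDENTITY = np.eye(20)


def test_peptide_rejects_non_standard_letters():
    with pytest.raises(PeptideError, match="X"):
        Peptide("bad", "ACDX")
    with pytest.raises(PeptideError):
        Peptide("empty", "")


def test_exact_match_scores_full_identity():
    assert score_path("ACD", Peptide("p", "ACD"), IDENTITY, gap_penalty=1) == 3


def test_forced_skip_pays_gap_penalty():
    assert score_path("AC", Peptide("p", "ACD"), IDENTITY, gap_penalty=1) == 1


def test_path_longer_than_peptide_is_an_error():
    with pytest.raises(ValueError):
        score_path("ACDE", Peptide("p", "ACD"), IDENTITY)


def _oracle_score(path, pep, matrix, gap):
    """Exhaustive enumeration over orientations × skip placements."""
    m, n = len(path), len(pep)
    best = -np.inf
    for q in (pep, pep[::-1]):
        for cols in itertools.combinations(range(n), m):
            s = sum(
                matrix[AA_ALPHABET.index(path[i]), AA_ALPHABET.index(q[c])]
                for i, c in enumerate(cols)
            )
            best = max(best, s - gap * (n - m))
    return best


@pytest.mark.parametrize("seed", range(8))
def test_score_path_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    matrix = load_matrix()
    n = int(rng.integers(2, 7))
    m = int(rng.integers(1, n + 1))
    letters = np.array(list(AA_ALPHABET))
    path = "".join(letters[rng.integers(0, 20, m)])
    pep = "".join(letters[rng.integers(0, 20, n)])
    got = score_path(path, Peptide("p", pep), matrix, gap_penalty=4)
    assert got == pytest.approx(_oracle_score(path, pep, matrix, 4))


@pytest.mark.parametrize("seed", range(4))
def test_score_symmetric_under_joint_reversal(seed):
    rng = np.random.default_rng(100 + seed)
    letters = np.array(list(AA_ALPHABET))
    path = "".join(letters[rng.integers(0, 20, 4)])
    pep = "".join(letters[rng.integers(0, 20, 6)])
    matrix = load_matrix()
    assert score_path(path, Peptide("p", pep), matrix) == pytest.approx(
        score_path(path[::-1], Peptide("p", pep[::-1]), matrix)
    )


def test_best_prefix_never_below_full_path_score():
    rng = np.random.default_rng(5)
    letters = np.array(list(AA_ALPHABET))
    matrix = load_matrix()
    for _ in range(10):
        path = "".join(letters[rng.integers(0, 20, 6)])
        pep = Peptide("p", "".join(letters[rng.integers(0, 20, 8)]))
        best, plen = best_prefix_score(path, pep, matrix)
        assert best >= score_path(path, pep, matrix) - 1e-9
        assert best == pytest.approx(score_path(path[:plen], pep, matrix))


def _random_graph_chain(rng, n):
    coords = rng.uniform(0, 14, size=(n, 3))
    seq = "".join(np.array(list(AA_ALPHABET))[rng.integers(0, 20, n)])
    return make_chain(coords, seq)


def _exhaustive_best(graph, peptide, matrix, gap):
    """Brute force over all simple paths of length ≤ len(peptide)."""
    n = graph.n_nodes
    indptr, indices, _ = graph.adjacency_arrays()
    best = -np.inf

    def extend(path):
        nonlocal best
        residues = [graph.residues[i] for i in path]
        best = max(best, score_path(residues, peptide, matrix, gap))
        if len(path) == len(peptide):
            return
        for nxt in indices[indptr[path[-1]] : indptr[path[-1] + 1]]:
            if nxt not in path:
                extend(path + [int(nxt)])

    for start in range(n):
        extend([start])
    return best


def test_single_node_patch_alignment():
    g = build_surface_graph(make_chain([[0, 0, 0]], seq="A"), threshold=8)
    aln = best_alignment_in_patch(g, Peptide("p", "A"), IDENTITY, gap_penalty=1)
    assert len(aln.path) == 1 and aln.score == 1


@pytest.mark.parametrize("seed", range(12))
def test_exact_search_matches_simple_path_enumeration(seed):
    rng = np.random.default_rng(200 + seed)
    n = int(rng.integers(4, 9))
    chain = _random_graph_chain(rng, n)
    graph = build_surface_graph(chain, threshold=8)
    matrix = load_matrix()
    pep = Peptide("p", "".join(np.array(list(AA_ALPHABET))[rng.integers(0, 20, 4)]))
    aln = best_alignment_in_patch(graph, pep, matrix, beam_width=None)
    assert aln.score == pytest.approx(_exhaustive_best(graph, pep, matrix, 4.0))


@pytest.mark.parametrize("seed", range(5))
def test_beam_one_never_beats_exact(seed):
    rng = np.random.default_rng(300 + seed)
    chain = _random_graph_chain(rng, 7)
    graph = build_surface_graph(chain, threshold=8)
    matrix = load_matrix()
    pep = Peptide("p", "".join(np.array(list(AA_ALPHABET))[rng.integers(0, 20, 5)]))
    narrow = best_alignment_in_patch(graph, pep, matrix, beam_width=1)
    exact = best_alignment_in_patch(graph, pep, matrix, beam_width=None)
    assert narrow.score <= exact.score + 1e-9


def test_alignment_path_is_simple_and_adjacent(antigen60):
    graph = build_surface_graph(antigen60.chain, threshold=8)
    pep = Peptide("p", "WYSTACDE")
    aln = best_alignment_in_patch(graph, pep)
    keys = [r.key for r in aln.path]
    assert len(set(keys)) == len(keys)
    for a, b in zip(keys, keys[1:]):
        assert graph.nx_graph.has_edge(a, b)
    # score invariant: equals recomputation from path + peptide + matrix
    assert aln.score == pytest.approx(score_path(aln.path, pep))
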