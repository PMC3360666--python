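"""Surface-graph construction, patch extraction and the adaptive threshold."""

import itertools

import numpy as np
import pytest

from epimapper.surface_graph import (
    EmptyGraphError,
    build_surface_graph,
    extract_patches,
    regulate_adt,
)

from conftest import make_chain


def test_far_apart_residues_are_disconnected():
    g = build_surface_graph(make_chain([[0, 0, 0], [20, 0, 0]]), threshold=8)
    assert g.n_nodes == 2 and g.n_edges == 0
    assert g.compactness == 0.0


def test_collinear_chain_edges_and_compactness():
    g = build_surface_graph(make_chain([[0, 0, 0], [5, 0, 0], [10, 0, 0]]), threshold=6)
    edges = {tuple(sorted((u[1], v[1]))) for u, v in g.nx_graph.edges()}
    assert edges == {(1, 2), (2, 3)}
    assert g.compactness == pytest.approx(2 / 3)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_edges_match_all_pairs_oracle(seed):
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 25, size=(20, 3))
    thr = 9.0
    g = build_surface_graph(make_chain(coords), threshold=thr)
    got = {tuple(sorted((u[1], v[1]))) for u, v in g.nx_graph.edges()}
    expected = {
        (i + 1, j + 1)
        for i, j in itertools.combinations(range(20), 2)
        if np.linalg.norm(coords[i] - coords[j]) <= thr
    }
    assert got == expected
    for _, _, d in g.nx_graph.edges(data="distance"):
        assert d <= thr


def test_no_surface_residues_is_an_error():
    with pytest.raises(EmptyGraphError):
        build_surface_graph(make_chain([[0, 0, 0]], surface=False), threshold=8)


def test_single_residue_single_patch():
    patches = extract_patches(make_chain([[0, 0, 0]]), radius=15)
    assert len(patches) == 1 and patches[0].size == 1


def test_distant_residues_form_singleton_patches():
    patches = extract_patches(make_chain([[0, 0, 0], [20, 0, 0]]), radius=15)
    assert [p.size for p in patches] == [1, 1]


def test_patch_membership_matches_brute_force(antigen60):
    chain = antigen60.chain
    patches = extract_patches(chain, radius=15)
    surface = chain.surface_residues
    assert len(patches) == len(surface)
    for patch in patches:
        expected = {
            r.key
            for r in surface
            if np.linalg.norm(r.cb_xyz - patch.center.cb_xyz) <= 15.0
        }
        assert {r.key for r in patch.members} == expected
        assert patch.center.key in {r.key for r in patch.members}


def test_target_one_gives_complete_graph(antigen60):
    patch = extract_patches(antigen60.chain, radius=15)[0]
    g = regulate_adt(patch, target_compactness=1.0, bounds=(4, 50))
    assert g.compactness == pytest.approx(1.0)


def test_dense_patch_needs_shorter_threshold():
    rng = np.random.default_rng(7)
    dense = extract_patches(make_chain(rng.uniform(0, 8, (10, 3))), radius=15)[0]
    sparse = extract_patches(make_chain(rng.uniform(0, 16, (10, 3)) * [1, 1, 1]), radius=30)[0]
    gd = regulate_adt(dense, 0.25, bounds=(2, 40))
    gs = regulate_adt(sparse, 0.25, bounds=(2, 40))
    assert gd.threshold_used <= gs.threshold_used


@pytest.mark.parametrize("seed", [3, 4, 5])
def test_adt_matches_linear_scan_oracle(seed):
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 12, size=(8, 3))
    patch = extract_patches(make_chain(coords), radius=50)[0]
    target = 0.25
    g = regulate_adt(patch, target, bounds=(0.1, 50))
    # oracle: walk the sorted distance ladder until density reaches target
    dists = sorted(
        np.linalg.norm(coords[i] - coords[j])
        for i, j in itertools.combinations(range(8), 2)
    )
    n_pairs = len(dists)
    expected = next(
        d for k, d in enumerate(dists, 1) if 2 * k / (8 * 7) >= target
    )
    assert g.threshold_used == pytest.approx(expected)
    assert g.compactness >= target


def test_unreachable_target_clamps_to_upper_bound(caplog):
    patch = extract_patches(make_chain([[0, 0, 0], [30, 0, 0], [60, 0, 0]]), radius=100)[0]
    with caplog.at_level("WARNING"):
        g = regulate_adt(patch, target_compactness=0.9, bounds=(4, 12))
    assert g.threshold_used == 12
    assert g.n_edges == 0
    assert "unreachable" in caplog.text


def test_compactness_monotone_in_threshold():
    rng = np.random.default_rng(11)
    chain = make_chain(rng.uniform(0, 15, size=(12, 3)))
    values = [
        build_surface_graph(chain, threshold=t).compactness for t in (3, 6, 9, 12, 20)
    ]
    assert values == sorted(values)


def test_no_self_loops_and_symmetry(antigen60):
    g = build_surface_graph(antigen60.chain, threshold=8)
    for u, v in g.nx_graph.edges():
        assert u != v
        assert g.nx_graph.has_edge(v, u)
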