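"""Desk-scale synthetic antigens with planted epitopes and mimotope panels.

The generator emulates the benchmark situation — an antigen structure, a
spatially contiguous surface epitope, and a phage-display panel enriched for
peptides that spell surface paths through that epitope — without any
external structure download.  Coordinates are geometrically plausible (a
globular shell lattice with ~3.8 Å spacing, no clashes under 2 Å, buried
core and exposed surface) but make no claim of physical foldability; they
exist to exercise the SASA, graph and search code paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .candidate_assembly import PredictionSet
from .peptide_align import AA_ALPHABET, Peptide
from .structure_io import AntigenChain, Atom, Residue, classify_surface, write_pdb

CA_SPACING = 3.8
EPITOPE_PICK_RADIUS = 7.0  # Å around the seed residue; keeps all pairs ≤ 15 Å
DEFAULT_MUTATION_RATE = 0.2

_ALPHA = np.array(list(AA_ALPHABET))


@dataclass
class SyntheticAntigen:
    chain: AntigenChain  # classified (rel_sasa / is_surface populated)
    planted_epitope: PredictionSet
    seed: int

    @property
    def pdb_text(self) -> str:
        return write_pdb(self.chain)

    def write(self, path) -> None:
        write_pdb(self.chain, path)


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return radius * np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)], axis=1
    )


def _shell_lattice(n: int, rng: np.random.Generator) -> np.ndarray:
    """~3.8 Å-spaced points filling concentric shells (globular lattice)."""
    points = [np.zeros(3)]
    shell = 1
    while len(points) < n:
        r = shell * CA_SPACING
        capacity = max(int(round(4.0 * np.pi * r * r / CA_SPACING ** 2)), 6)
        count = min(capacity, n - len(points))
        points.extend(_fibonacci_sphere(capacity, r)[:count])
        shell += 1
    coords = np.array(points[:n])
    coords += rng.normal(scale=0.25, size=coords.shape)  # perturbation
    return coords


def make_antigen(n_residues: int, seed: int, rsa_threshold: float = 0.10) -> SyntheticAntigen:
    """Synthetic antigen chain with a planted surface epitope of 8–12 residues.

    The planted epitope is a cluster of surface residues all within 7 Å of a
    randomly chosen exposed seed residue, hence mutually within 15 Å — it
    fits inside a single 15 Å patch.
    """
    if n_residues < 20:
        raise ValueError("need at least 20 residues")
    rng = np.random.default_rng(seed)
    coords = _shell_lattice(n_residues, rng)
    assert pdist(coords).min() >= 2.0, "steric clash in generated lattice"
    centroid = coords.mean(axis=0)
    seq = _ALPHA[rng.integers(0, 20, size=n_residues)]
    residues = []
    for i in range(n_residues):
        ca = coords[i]
        out = ca - centroid
        norm = np.linalg.norm(out)
        direction = out / norm if norm > 1e-6 else _unit(rng)
        aa = str(seq[i])
        cb = ca if aa == "G" else ca + 1.5 * direction
        atoms = [Atom("CA", "C", ca)] + ([] if aa == "G" else [Atom("CB", "C", cb)])
        residues.append(
            Residue(chain_id="A", seq_num=i + 1, icode="", aa=aa,
                    ca_xyz=ca, cb_xyz=cb, atoms=atoms)
        )
    chain = classify_surface(
        AntigenChain(pdb_id=f"SYN{seed}", chain_id="A", residues=residues),
        rsa_threshold=rsa_threshold,
    )
    surface = chain.surface_residues
    size = int(rng.integers(8, 13))
    seed_res = surface[int(rng.integers(len(surface)))]
    near = sorted(
        (r for r in surface),
        key=lambda r: float(np.linalg.norm(r.cb_xyz - seed_res.cb_xyz)),
    )
    # grow the cluster outward from the seed, never letting any pair exceed
    # the 15 Å patch diameter, until the target size is reached
    members: list[Residue] = []
    for r in near:
        if all(np.linalg.norm(r.cb_xyz - m.cb_xyz) <= 15.0 for m in members):
            members.append(r)
        if len(members) == size:
            break
    epi_coords = np.array([r.cb_xyz for r in members])
    assert len(members) >= 5 and pdist(epi_coords).max() <= 15.0
    epitope = PredictionSet(frozenset(r.key for r in members), source="truth")
    return SyntheticAntigen(chain=chain, planted_epitope=epitope, seed=seed)


def _unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _epitope_adjacency(antigen: SyntheticAntigen, threshold: float = 8.0):
    members = [
        r for r in antigen.chain.residues if r.key in antigen.planted_epitope.residues
    ]
    nbrs = {r.key: [] for r in members}
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            if np.linalg.norm(a.cb_xyz - b.cb_xyz) <= threshold:
                nbrs[a.key].append(b)
                nbrs[b.key].append(a)
    return members, nbrs


def _random_simple_path(members, nbrs, length, rng):
    """Randomized DFS for a simple path of the requested length; if the
    epitope admits none, the longest path found is extended by a walk with
    revisits allowed."""
    best = []
    for start_i in rng.permutation(len(members)):
        stack = [[members[start_i]]]
        while stack:
            path = stack.pop()
            if len(path) > len(best):
                best = path
            if len(path) == length:
                return path
            seen = {r.key for r in path}
            nxt = [r for r in nbrs[path[-1].key] if r.key not in seen]
            for r in rng.permutation(len(nxt)):
                stack.append(path + [nxt[r]])
    path = list(best)
    while len(path) < length:
        options = nbrs[path[-1].key] or path[:1]
        path.append(options[int(rng.integers(len(options)))])
    return path


def make_panel(
    antigen: SyntheticAntigen,
    n_peptides: int,
    peptide_length: int,
    noise_fraction: float,
    seed: int,
    mutation_rate: float = DEFAULT_MUTATION_RATE,
) -> list[Peptide]:
    """Mimotope panel: epitope-path spellings plus uniform-random noise.

    Informative peptides spell the residue sequence of a random walk through
    the planted epitope (8 Å adjacency), with independent per-position
    mutation probability ``mutation_rate``; a ``noise_fraction`` share of the
    panel is replaced by uniform random peptides.
    """
    if peptide_length < 3:
        raise ValueError("peptide length must be >= 3")
    rng = np.random.default_rng(seed)
    members, nbrs = _epitope_adjacency(antigen)
    n_noise = int(round(noise_fraction * n_peptides))
    sequences = []
    for _ in range(n_peptides - n_noise):
        path = _random_simple_path(members, nbrs, peptide_length, rng)
        letters = [r.aa for r in path]
        for i in range(len(letters)):
            if rng.random() < mutation_rate:
                letters[i] = str(_ALPHA[rng.integers(0, 20)])
        sequences.append("".join(letters))
    for _ in range(n_noise):
        sequences.append("".join(_ALPHA[rng.integers(0, 20, size=peptide_length)]))
    perm = rng.permutation(n_peptides)
    return [Peptide(f"pep{i + 1}", sequences[j]) for i, j in enumerate(perm)]


def write_fasta(panel: list[Peptide], path) -> None:
    with open(path, "w") as fh:
        for pep in panel:
            fh.write(f">{pep.name}\n{pep.sequence}\n")
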