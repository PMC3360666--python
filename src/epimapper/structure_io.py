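"""Read antigen chains from PDB files and classify solvent-exposed residues.

An antigen chain is reduced to an ordered list of residues carrying Cα/Cβ
coordinates (Cα substitutes for glycine or a missing Cβ, so every residue has
a patch-center coordinate), a relative solvent accessibility in [0, 1], and a
surface flag.  Accessibility is computed with a rolling-probe (Shrake–Rupley)
algorithm over the heavy atoms of the chain in isolation and normalized by
Gly-X-Gly reference areas.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from Bio.PDB import PDBParser

logger = logging.getLogger(__name__)

#: heavy-atom van der Waals radii (Å), keyed by element symbol
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "SE": 1.90,
    "P": 1.80,
    "H": 1.20,
}
DEFAULT_RADIUS = 1.70
PROBE_RADIUS = 1.4

#: maximum accessible surface areas (Å²) of residue X in an extended
#: Gly-X-Gly tripeptide (theoretical values, Tien et al. 2013), used to
#: normalize absolute SASA into relative accessibility.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # selenomethionine is retained as methionine
    "MSE": "M",
}

DEFAULT_RSA_THRESHOLD = 0.10


class Atom(NamedTuple):
    name: str
    element: str
    xyz: np.ndarray


ResidueKey = tuple[str, int, str]


@dataclass(eq=False)
class Residue:
    """One amino acid of an antigen chain.

    Identity semantics: residues compare by object identity; use ``key``
    (chain, number, insertion code) for value comparisons.

    ``cb_xyz`` is always populated: for glycine (or any residue whose Cβ is
    missing from the deposited coordinates) the Cα position is used instead.
    """

    chain_id: str
    seq_num: int
    icode: str
    aa: str
    ca_xyz: np.ndarray
    cb_xyz: np.ndarray
    atoms: list[Atom] = field(default_factory=list, repr=False)
    rel_sasa: float | None = None
    is_surface: bool = False

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_num, self.icode)


@dataclass
class AntigenChain:
    pdb_id: str
    chain_id: str
    residues: list[Residue]

    @property
    def n_surface(self) -> int:
        return sum(r.is_surface for r in self.residues)

    @property
    def surface_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_surface]

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)


class ChainNotFoundError(KeyError):
    pass


class EmptyChainError(ValueError):
    pass


def _as_handle(pdb_source):
    """Accept a path, a file handle, or raw PDB text."""
    if hasattr(pdb_source, "read"):
        return pdb_source
    if isinstance(pdb_source, (str, os.PathLike)):
        s = str(pdb_source)
        if "\n" in s or s.lstrip().startswith(("ATOM", "HETATM", "HEADER", "MODEL", "REMARK")):
            return io.StringIO(s)
        return open(s)
    raise TypeError(f"cannot read PDB from {type(pdb_source)!r}")


def read_pdb_chain(pdb_source, chain_id: str, pdb_id: str = "") -> AntigenChain:
    """Parse one chain of a PDB file into an :class:`AntigenChain`.

    Only standard amino acids (plus MSE→M) with a Cα atom are kept; waters,
    ligands and other heteroatoms are excluded.  Alternate locations are
    resolved to the highest-occupancy conformer (Biopython's default child
    selection; ties keep the first encountered).  Author numbering and
    insertion codes are preserved.
    """
    parser = PDBParser(QUIET=True)
    with _as_handle(pdb_source) as handle:
        structure = parser.get_structure(pdb_id or "antigen", handle)
    model = next(structure.get_models())
    available = [c.id for c in model]
    if chain_id not in available:
        raise ChainNotFoundError(
            f"chain {chain_id!r} not found; available chains: {sorted(available)}"
        )
    residues: list[Residue] = []
    for res in model[chain_id]:
        hetflag, seq_num, icode = res.id
        resname = res.get_resname().strip()
        if resname not in THREE_TO_ONE:
            if hetflag.strip() and resname not in ("HOH", "WAT"):
                logger.warning("dropping non-standard residue %s %s%s", resname, seq_num, icode)
            continue
        if "CA" not in res:
            logger.warning("dropping residue %s %s%s without CA", resname, seq_num, icode)
            continue
        ca = np.asarray(res["CA"].get_coord(), dtype=float)
        cb = np.asarray(res["CB"].get_coord(), dtype=float) if "CB" in res else ca.copy()
        atoms = [
            Atom(a.get_name(), (a.element or a.get_name()[0]).upper(),
                 np.asarray(a.get_coord(), dtype=float))
            for a in res
            if (a.element or "").upper() != "H"
        ]
        residues.append(
            Residue(
                chain_id=chain_id,
                seq_num=seq_num,
                icode=icode.strip() or "",
                aa=THREE_TO_ONE[resname],
                ca_xyz=ca,
                cb_xyz=cb,
                atoms=atoms,
            )
        )
    if not residues:
        raise EmptyChainError(f"chain {chain_id!r} contains no standard amino-acid residues")
    residues.sort(key=lambda r: (r.seq_num, r.icode))
    return AntigenChain(pdb_id=pdb_id, chain_id=chain_id, residues=residues)


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-section spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)], axis=1
    )


def shrake_rupley_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = 256,
) -> np.ndarray:
    """Per-atom accessible surface area (Å²) by rolling-probe point sampling.

    Each atom is expanded by the probe radius and covered with ``n_points``
    quasi-uniform test points; the accessible area is the fraction of points
    not buried inside any neighbouring expanded sphere.
    """
    coords = np.asarray(coords, dtype=float)
    expanded = np.asarray(radii, dtype=float) + probe_radius
    n = len(coords)
    unit = _sphere_points(n_points)
    areas = np.empty(n)
    # neighbour lists keep the point-in-sphere test quadratic only locally
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    max_r = expanded.max()
    for i in range(n):
        pts = coords[i] + expanded[i] * unit
        nbrs = [j for j in tree.query_ball_point(coords[i], expanded[i] + max_r) if j != i]
        if nbrs:
            d2 = ((pts[:, None, :] - coords[nbrs][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (expanded[nbrs] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * expanded[i] ** 2
    return areas


def classify_surface(
    chain: AntigenChain,
    rsa_threshold: float = DEFAULT_RSA_THRESHOLD,
    n_points: int = 256,
) -> AntigenChain:
    """Compute relative SASA for every residue and flag surface residues.

    The chain is treated in isolation (no occlusion by other chains).  The
    relative accessibility is the summed heavy-atom SASA of the residue
    divided by its Gly-X-Gly reference area, clipped to [0, 1]; residues with
    relative SASA ≥ ``rsa_threshold`` are marked as surface.
    """
    if len(chain.residues) < 1:
        raise EmptyChainError("cannot classify an empty chain")
    coords, radii, owner = [], [], []
    for idx, res in enumerate(chain.residues):
        atoms = res.atoms or [Atom("CA", "C", res.ca_xyz), Atom("CB", "C", res.cb_xyz)]
        for atom in atoms:
            coords.append(atom.xyz)
            radii.append(VDW_RADII.get(atom.element, DEFAULT_RADIUS))
            owner.append(idx)
    areas = shrake_rupley_sasa(np.asarray(coords), np.asarray(radii), n_points=n_points)
    per_res = np.zeros(len(chain.residues))
    np.add.at(per_res, owner, areas)
    out = []
    for idx, res in enumerate(chain.residues):
        rel = float(min(per_res[idx] / MAX_ASA[res.aa], 1.0))
        out.append(replace(res, rel_sasa=rel, is_surface=rel >= rsa_threshold))
    return AntigenChain(pdb_id=chain.pdb_id, chain_id=chain.chain_id, residues=out)


def write_pdb(chain: AntigenChain, path=None) -> str:
    """Serialize a chain back to minimal standard PDB text (ATOM records)."""
    one_to_three = {v: k for k, v in THREE_TO_ONE.items() if k != "MSE"}
    lines = []
    serial = 1
    for res in chain.residues:
        resname = one_to_three[res.aa]
        atoms = res.atoms or [Atom("CA", "C", res.ca_xyz)] + (
            [Atom("CB", "C", res.cb_xyz)] if not np.allclose(res.cb_xyz, res.ca_xyz) else []
        )
        for atom in atoms:
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            x, y, z = atom.xyz
            lines.append(
                f"ATOM  {serial:5d} {name}{'':1s}{resname:>3s} {res.chain_id}"
                f"{res.seq_num:4d}{res.icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
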