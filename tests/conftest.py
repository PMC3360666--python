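import numpy as np
import pytest

from epimapper.structure_io import AntigenChain, Atom, Residue
from epimapper.synthetic_fixtures import make_antigen, make_panel


def make_chain(coords, seq=None, chain_id="A", surface=True) -> AntigenChain:
    """Bare chain for graph/search tests: Cβ at the given coordinates, every
    residue pre-classified as surface (no SASA computation involved)."""
    coords = np.asarray(coords, dtype=float)
    seq = seq or "A" * len(coords)
    residues = [
        Residue(
            chain_id=chain_id,
            seq_num=i + 1,
            icode="",
            aa=seq[i],
            ca_xyz=coords[i],
            cb_xyz=coords[i],
            atoms=[Atom("CA", "C", coords[i])],
            rel_sasa=1.0 if surface else 0.0,
            is_surface=surface,
        )
        for i in range(len(coords))
    ]
    return AntigenChain(pdb_id="toy", chain_id=chain_id, residues=residues)


@pytest.fixture(scope="session")
def antigen60():
    return make_antigen(60, seed=1)


@pytest.fixture(scope="session")
def panel20(antigen60):
    return make_panel(antigen60, n_peptides=20, peptide_length=8, noise_fraction=0.2, seed=1)
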