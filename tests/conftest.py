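import numpy as np
import pytest

from edgetic.structures import AtomRecord, ResidueSite, StructureFragment

BACKBONE = ("N", "CA", "C", "O")


def make_residue(chain, num, name, state, atoms):
    """atoms: iterable of (atom name, element, xyz)."""
    res = ResidueSite(chain_id=chain, number=num, icode="", name=name,
                      state=state)
    for aname, element, xyz in atoms:
        side = aname not in BACKBONE or (state == "G" and aname == "CA")
        res.atoms.append(AtomRecord(name=aname, element=element,
                                    coords=np.asarray(xyz, dtype=float),
                                    is_side_chain=side))
    return res


def make_fragment(fragment_id, residues, structure_id="s",
                  polymer_type="protein"):
    return StructureFragment(fragment_id=fragment_id,
                             structure_id=structure_id,
                             polymer_type=polymer_type,
                             residues=list(residues))


def single_atom_fragment(fragment_id, specs, chain="A"):
    """specs: iterable of (state, one-letter element, xyz) — one CB per residue."""
    residues = []
    for i, (state, element, xyz) in enumerate(specs, start=1):
        residues.append(make_residue(chain, i, state, state,
                                     [("CB", element, xyz)]))
    return make_fragment(fragment_id, residues)


@pytest.fixture
def two_cb_fragments():
    def build(distance):
        a = single_atom_fragment("fa", [("A", "C", (0.0, 0.0, 0.0))])
        b = single_atom_fragment("fb", [("A", "C", (distance, 0.0, 0.0))],
                                 chain="B")
        return a, b
    return build
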