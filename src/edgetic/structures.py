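"""Structure parsing into typed fragments, residues, atoms and ligands.

Each input file is treated as one biological assembly: polymer chains become
:class:`StructureFragment` objects (protein, DNA or RNA), non-solvent het
groups become :class:`LigandInstance` objects, and modified residues carried
in the polymer (phospho-Ser/Thr/Tyr, acetyl-Lys) are kept as polymer residues
with a modified state symbol.  The residue alphabet has 24 symbols: the 20
standard amino acids plus ``Sp``, ``Tp``, ``Yp`` and ``Ka``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

from .errors import EmptyModelError, StructureFormatError

#: Backbone atom names; everything else on a polymer residue is side chain.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}

#: Modified residues carried in the polymer: het code -> state symbol.
MODIFIED_3TO_STATE = {"SEP": "Sp", "TPO": "Tp", "PTR": "Yp", "ALY": "Ka"}
#: State symbol -> parent standard residue (one-letter).
MODIFIED_PARENT = {"Sp": "S", "Tp": "T", "Yp": "Y", "Ka": "K"}
STATE_TO_3 = {**{v: k for k, v in AA_3TO1.items()},
              **{v: k for k, v in MODIFIED_3TO_STATE.items()}}

STANDARD_AA = tuple(AA_1TO3)
ALPHABET = STANDARD_AA + ("Sp", "Tp", "Yp", "Ka")
UNKNOWN = "UNKNOWN"

DNA_CODES = {"DA": "A", "DC": "C", "DG": "G", "DT": "T", "DI": "I", "DU": "U"}
RNA_CODES = {"A": "A", "C": "C", "G": "G", "U": "U", "I": "I"}

#: Default crystallization-solvent / additive exclusion list (configurable).
DEFAULT_SOLVENT_EXCLUSIONS = frozenset(
    {"HOH", "DOD", "GOL", "EDO", "PEG", "SO4", "PO4", "CL", "NA"}
)


@dataclass(frozen=True)
class SolventExclusionList:
    """Case-insensitive set of het codes dropped during parsing."""

    codes: frozenset = DEFAULT_SOLVENT_EXCLUSIONS

    def __post_init__(self):
        object.__setattr__(self, "codes",
                           frozenset(c.upper() for c in self.codes))

    def __contains__(self, het_code: str) -> bool:
        return het_code.upper() in self.codes


@dataclass
class AtomRecord:
    name: str
    element: str
    coords: np.ndarray  # Å, shape (3,)
    is_side_chain: bool
    alt_loc: str | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise StructureFormatError(f"non-finite coordinates for atom {self.name}")
        if not self.element:
            raise StructureFormatError(f"empty element for atom {self.name}")


@dataclass
class ResidueSite:
    chain_id: str
    number: int
    icode: str
    name: str          # 3-letter code as read from the file
    state: str         # 24-symbol alphabet member or UNKNOWN
    atoms: list = field(default_factory=list)

    @property
    def side_chain_atoms(self) -> list:
        return [a for a in self.atoms if a.is_side_chain]

    @property
    def one_letter(self) -> str:
        """Sequence letter: parent residue for modified states, X for unknown."""
        if self.state in MODIFIED_PARENT:
            return MODIFIED_PARENT[self.state]
        if self.state in AA_1TO3:
            return self.state
        if self.name in DNA_CODES:
            return DNA_CODES[self.name]
        if self.name in RNA_CODES:
            return RNA_CODES[self.name]
        return "X"


@dataclass
class StructureFragment:
    fragment_id: str
    structure_id: str
    polymer_type: str  # protein | dna | rna
    residues: list = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LigandInstance:
    ligand_id: str
    het_code: str
    chem_class: str = "Organic"
    atoms: list = field(default_factory=list)


@dataclass
class StructureModel:
    structure_id: str
    fragments: list = field(default_factory=list)
    ligands: list = field(default_factory=list)

    def fragment(self, fragment_id: str) -> StructureFragment:
        for f in self.fragments:
            if f.fragment_id == fragment_id:
                return f
        raise KeyError(fragment_id)


def classify_residue(name: str) -> str:
    """Map a residue code to its state symbol (total function).

    SEP/TPO/PTR/ALY map to the phospho/acetyl symbols, the 20 standard codes
    to one-letter symbols, anything else to ``UNKNOWN``.
    """
    code = name.strip().upper()
    if code in AA_3TO1:
        return AA_3TO1[code]
    if code in MODIFIED_3TO_STATE:
        return MODIFIED_3TO_STATE[code]
    return UNKNOWN


def _looks_like_cif(document: str) -> bool:
    head = document.lstrip()[:2000]
    return head.startswith("data_") or "_atom_site." in head


def _best_conformers(residue: gemmi.Residue) -> list:
    """Keep one conformer per atom name: highest occupancy, ties by alt-loc."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        if atom.element.is_hydrogen:
            continue  # hydrogens ignored by every distance rule
        prev = best.get(atom.name)
        if prev is None:
            best[atom.name] = atom
            continue
        if (atom.occ, -ord(atom.altloc or "~")) > (prev.occ, -ord(prev.altloc or "~")):
            best[atom.name] = atom
    return [best[name] for name in sorted(best)]


def _to_atom_record(atom: gemmi.Atom, residue_state: str) -> AtomRecord:
    side = atom.name not in BACKBONE_ATOMS
    # Glycine carries no side-chain atoms: its CA is the surrogate side chain
    # so that the contact rules can ever register a glycine contact.
    if residue_state == "G" and atom.name == "CA":
        side = True
    return AtomRecord(
        name=atom.name,
        element=atom.element.name,
        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
        is_side_chain=side,
        alt_loc=atom.altloc or None,
    )


def parse_structure(document: str,
                    exclusions: SolventExclusionList | None = None,
                    structure_id: str | None = None) -> StructureModel:
    """Parse PDB or mmCIF text into a :class:`StructureModel`.

    Polymer chains become fragments, het groups not on the solvent exclusion
    list become ligands, waters and excluded hets are dropped.
    """
    if exclusions is None:
        exclusions = SolventExclusionList()
    try:
        if _looks_like_cif(document):
            block = gemmi.cif.read_string(document).sole_block()
            st = gemmi.make_structure_from_block(block)
        else:
            st = gemmi.read_pdb_string(document)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"unparseable structure document: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError("document contains no model")

    sid = structure_id or (st.name.strip() or "structure")
    model = st[0]
    out = StructureModel(structure_id=sid)
    for chain in model:
        protein_res: list[ResidueSite] = []
        nucleic_res: list[ResidueSite] = []
        nucleic_names: list[str] = []
        for residue in chain:
            rname = residue.name.strip().upper()
            state = classify_residue(rname)
            is_nucleic = rname in DNA_CODES or rname in RNA_CODES
            site = ResidueSite(
                chain_id=chain.name,
                number=residue.seqid.num,
                icode=(residue.seqid.icode or "").strip(),
                name=rname,
                state=state if not is_nucleic else UNKNOWN,
            )
            site.atoms = [_to_atom_record(a, site.state)
                          for a in _best_conformers(residue)]
            if state != UNKNOWN and not is_nucleic:
                protein_res.append(site)
            elif is_nucleic:
                nucleic_res.append(site)
                nucleic_names.append(rname)
            else:
                if rname in exclusions or residue.is_water():
                    continue
                out.ligands.append(LigandInstance(
                    ligand_id=f"{sid}:{chain.name}:{rname}{residue.seqid.num}",
                    het_code=rname,
                    atoms=site.atoms,
                ))
        if protein_res:
            out.fragments.append(StructureFragment(
                fragment_id=f"{sid}:{chain.name}",
                structure_id=sid,
                polymer_type="protein",
                residues=protein_res,
            ))
        if nucleic_res:
            ptype = "dna" if all(n in DNA_CODES for n in nucleic_names) else "rna"
            out.fragments.append(StructureFragment(
                fragment_id=f"{sid}:{chain.name}:na",
                structure_id=sid,
                polymer_type=ptype,
                residues=nucleic_res,
            ))
    if not out.fragments:
        raise EmptyModelError(f"structure {sid} has zero polymer chains")
    return out


def write_pdb(model: StructureModel) -> str:
    """Serialize a model back to PDB-format text (fixtures and round-trips)."""
    lines = []
    serial = 1

    def fmt(record, serial, name, resname, chain, resnum, icode, coords, element):
        aname = name if len(name) == 4 else f" {name:<3s}"
        return (f"{record:<6s}{serial:>5d} {aname:<4s} {resname:>3s} {chain:1s}"
                f"{resnum:>4d}{icode or ' ':1s}   "
                f"{coords[0]:8.3f}{coords[1]:8.3f}{coords[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}")

    for frag in model.fragments:
        for res in frag.residues:
            for atom in res.atoms:
                lines.append(fmt("ATOM", serial, atom.name, res.name,
                                 res.chain_id, res.number, res.icode,
                                 atom.coords, atom.element))
                serial += 1
        last = frag.residues[-1]
        lines.append(f"TER   {serial:>5d}      {last.name:>3s} "
                     f"{last.chain_id:1s}{last.number:>4d}")
        serial += 1
    for lig in model.ligands:
        chain = lig.ligand_id.split(":")[1] if ":" in lig.ligand_id else "X"
        try:
            resnum = int("".join(ch for ch in lig.ligand_id.split(":")[-1]
                                 if ch.isdigit()) or "1")
        except ValueError:
            resnum = 1
        for atom in lig.atoms:
            lines.append(fmt("HETATM", serial, atom.name, lig.het_code,
                             chain, resnum, "", atom.coords, atom.element))
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
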