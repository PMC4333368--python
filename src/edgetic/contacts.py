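"""Residue-level contact detection and interface assembly.

Three contact rules are used throughout:

* generic — any side-chain atom pair within 5.0 Å (protein–protein), or a
  protein side-chain atom within 5.0 Å of any partner atom (ligand / nucleic
  partners).  Protein–protein interfaces require at least 30 residue pairs in
  generic contact; ligand and nucleic interfaces require at least one.
* vdw — side-chain carbon/sulfur pairs within 4.5 Å between residues whose
  side chains have a hydrophobic functional aspect.
* electrostatic — side-chain N/O contacts within 5.5 Å (upper limit of
  hydrogen-bonding/electrostatic distances) between residues with polar or
  charged functional aspects; mixed pairs count when at least one partner
  atom is N or O.

All thresholds are inclusive.  Glycine participates through its CA surrogate
side chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ConfigError
from .structures import LigandInstance, StructureFragment

GENERIC_THRESHOLD = 5.0
VDW_THRESHOLD = 4.5
ELECTROSTATIC_THRESHOLD = 5.5

#: Residues whose side chains carry a van der Waals functional aspect.
VDW_RESIDUES = frozenset(
    {"A", "C", "F", "G", "I", "L", "M", "P", "V", "W", "Y", "Yp", "Ka"})
#: Residues whose side chains carry an electrostatic/H-bond functional aspect.
ELECTROSTATIC_RESIDUES = frozenset(
    {"D", "E", "H", "K", "N", "Q", "R", "S", "T", "W", "Y", "Sp", "Tp", "Yp", "Ka"})

MIN_PP_CONTACTS = 30


@dataclass(frozen=True)
class ContactRule:
    kind: str  # generic | vdw | electrostatic
    threshold: float

    def __post_init__(self):
        if self.kind not in ("generic", "vdw", "electrostatic"):
            raise ConfigError(f"unknown contact rule kind: {self.kind!r}")
        if self.threshold <= 0:
            raise ConfigError("contact threshold must be positive")


GENERIC_RULE = ContactRule("generic", GENERIC_THRESHOLD)
VDW_RULE = ContactRule("vdw", VDW_THRESHOLD)
ELECTROSTATIC_RULE = ContactRule("electrostatic", ELECTROSTATIC_THRESHOLD)
DEFAULT_RULES = (GENERIC_RULE, VDW_RULE, ELECTROSTATIC_RULE)


@dataclass
class ResiduePairContact:
    """One residue pair (or residue–ligand pair) in contact."""

    fragment_a: str
    residue_a: int                 # 1-based index within fragment A
    partner_id: str                # fragment id or ligand id
    residue_b: int | None          # 1-based index, None for ligand partners
    kinds: frozenset = frozenset()
    min_distance: float = float("inf")
    state_a: str = ""
    state_b: str | None = None  # None for ligand/nucleic partners


@dataclass
class Interface:
    interface_type: str  # protein-protein | protein-chemical | protein-dna/rna
    member_ids: tuple
    contacts: list = field(default_factory=list)
    member_sequences: tuple = ()
    structure_id: str = ""
    group_id: int | None = None
    representative: bool = True
    chem_class: str | None = None
    #: residue states of the protein member(s); background for molar fractions
    protein_states: tuple = ()


def _functional_atoms(residue, rule_kind: str):
    """Atoms of one protein residue eligible under a rule.

    Returns (atom, requires_no_flag) pairs; for the electrostatic rule the
    boolean marks whether the atom satisfies the N/O requirement (a valid
    electrostatic pair needs at least one such atom).
    """
    out = []
    for atom in residue.side_chain_atoms:
        el = atom.element.upper()
        if rule_kind == "generic":
            out.append((atom, True))
        elif rule_kind == "vdw":
            if residue.state in VDW_RESIDUES and el in ("C", "S"):
                out.append((atom, True))
        elif rule_kind == "electrostatic":
            vdw_side = residue.state in VDW_RESIDUES and el in ("C", "S")
            elec_side = residue.state in ELECTROSTATIC_RESIDUES and el in ("N", "O")
            if elec_side:
                out.append((atom, True))
            elif vdw_side:
                out.append((atom, False))
    return out


def _collect(fragment: StructureFragment, rule_kind: str):
    coords, res_idx, is_no = [], [], []
    for i, res in enumerate(fragment.residues, start=1):
        for atom, no_flag in _functional_atoms(res, rule_kind):
            coords.append(atom.coords)
            res_idx.append(i)
            is_no.append(no_flag)
    if not coords:
        return np.empty((0, 3)), np.empty(0, int), np.empty(0, bool)
    return np.asarray(coords), np.asarray(res_idx), np.asarray(is_no)


def detect_contacts(part_a: StructureFragment,
                    part_b,
                    rule: ContactRule = GENERIC_RULE) -> list[ResiduePairContact]:
    """Residue pairs of ``part_a`` × ``part_b`` in contact under ``rule``.

    ``part_b`` may be another fragment (protein or nucleic) or a
    :class:`LigandInstance`.  For non-protein partners only the generic rule
    applies: a protein side-chain atom within threshold of any partner atom.
    Output is sorted by (fragment, residue index).
    """
    if isinstance(part_b, LigandInstance) or (
            isinstance(part_b, StructureFragment) and part_b.polymer_type != "protein"):
        if rule.kind != "generic":
            raise ConfigError(
                "only the generic rule applies to ligand/nucleic partners")
        return _detect_vs_nonprotein(part_a, part_b, rule)

    ca, ia, noa = _collect(part_a, rule.kind)
    cb, ib, nob = _collect(part_b, rule.kind)
    if ca.size == 0 or cb.size == 0:
        return []
    dist = cdist(ca, cb)
    within = dist <= rule.threshold
    if rule.kind == "electrostatic":
        # at least one of the two atoms must be N/O
        within &= noa[:, None] | nob[None, :]
    pairs: dict[tuple[int, int], float] = {}
    for ai, bi in zip(*np.nonzero(within)):
        key = (ia[ai], ib[bi])
        d = dist[ai, bi]
        if d < pairs.get(key, np.inf):
            pairs[key] = d
    return [
        ResiduePairContact(
            fragment_a=part_a.fragment_id, residue_a=ra,
            partner_id=part_b.fragment_id, residue_b=rb,
            kinds=frozenset({rule.kind}), min_distance=pairs[(ra, rb)],
            state_a=part_a.residues[ra - 1].state,
            state_b=part_b.residues[rb - 1].state)
        for ra, rb in sorted(pairs)
    ]


def _detect_vs_nonprotein(fragment, partner, rule):
    ca, ia, _ = _collect(fragment, "generic")
    if isinstance(partner, LigandInstance):
        part_atoms = partner.atoms
        partner_id = partner.ligand_id
        partner_res = [None] * len(part_atoms)
        coords_b = [a.coords for a in part_atoms]
    else:
        partner_id = partner.fragment_id
        coords_b, partner_res = [], []
        for j, res in enumerate(partner.residues, start=1):
            for atom in res.atoms:
                coords_b.append(atom.coords)
                partner_res.append(j)
    if ca.size == 0 or not coords_b:
        return []
    dist = cdist(ca, np.asarray(coords_b))
    within = dist <= rule.threshold
    pairs: dict[tuple, float] = {}
    for ai, bi in zip(*np.nonzero(within)):
        key = (ia[ai], partner_res[bi])
        d = dist[ai, bi]
        if d < pairs.get(key, np.inf):
            pairs[key] = d
    return [
        ResiduePairContact(
            fragment_a=fragment.fragment_id, residue_a=ra,
            partner_id=partner_id, residue_b=rb,
            kinds=frozenset({rule.kind}), min_distance=pairs[(ra, rb)],
            state_a=fragment.residues[ra - 1].state, state_b=None)
        for ra, rb in sorted(pairs, key=lambda k: (k[0], k[1] if k[1] else 0))
    ]


def _merge_kinds(fragment_a, fragment_b) -> list[ResiduePairContact]:
    """Generic contacts annotated with any vdw/electrostatic kinds present."""
    merged: dict[tuple[int, int], ResiduePairContact] = {}
    for c in detect_contacts(fragment_a, fragment_b, GENERIC_RULE):
        merged[(c.residue_a, c.residue_b)] = c
    for rule in (VDW_RULE, ELECTROSTATIC_RULE):
        for c in detect_contacts(fragment_a, fragment_b, rule):
            key = (c.residue_a, c.residue_b)
            if key in merged:
                prev = merged[key]
                prev.kinds = prev.kinds | c.kinds
                prev.min_distance = min(prev.min_distance, c.min_distance)
            else:
                merged[key] = c
    return [merged[k] for k in sorted(merged)]


def define_interfaces(models, class_map=None) -> list[Interface]:
    """Assemble interfaces of the three types from one model or a list.

    Protein–protein interfaces require ≥30 generic residue-pair contacts;
    protein–chemical and protein–DNA/RNA interfaces require ≥1.
    """
    from .potentials import ChemicalClassMap
    if class_map is None:
        class_map = ChemicalClassMap()
    if hasattr(models, "fragments"):
        models = [models]
    interfaces: list[Interface] = []
    for model in models:
        prot = [f for f in model.fragments if f.polymer_type == "protein"]
        nuc = [f for f in model.fragments if f.polymer_type != "protein"]
        for i, fa in enumerate(prot):
            for fb in prot[i + 1:]:
                generic = detect_contacts(fa, fb, GENERIC_RULE)
                if len(generic) >= MIN_PP_CONTACTS:
                    interfaces.append(Interface(
                        interface_type="protein-protein",
                        member_ids=(fa.fragment_id, fb.fragment_id),
                        contacts=_merge_kinds(fa, fb),
                        member_sequences=(fa.sequence, fb.sequence),
                        structure_id=model.structure_id,
                        protein_states=tuple(r.state for r in fa.residues)
                        + tuple(r.state for r in fb.residues),
                    ))
            for nf in nuc:
                contacts = detect_contacts(fa, nf, GENERIC_RULE)
                if contacts:
                    interfaces.append(Interface(
                        interface_type="protein-dna/rna",
                        member_ids=(fa.fragment_id, nf.fragment_id),
                        contacts=contacts,
                        member_sequences=(fa.sequence, nf.sequence),
                        structure_id=model.structure_id,
                        chem_class="DNA/RNA",
                        protein_states=tuple(r.state for r in fa.residues),
                    ))
            for lig in model.ligands:
                contacts = detect_contacts(fa, lig, GENERIC_RULE)
                if contacts:
                    interfaces.append(Interface(
                        interface_type="protein-chemical",
                        member_ids=(fa.fragment_id, lig.ligand_id),
                        contacts=contacts,
                        member_sequences=(fa.sequence, lig.het_code),
                        structure_id=model.structure_id,
                        chem_class=class_map.lookup(lig.het_code),
                        protein_states=tuple(r.state for r in fa.residues),
                    ))
    return interfaces


def _group_key(interface: Interface):
    seq_a, seq_b = interface.member_sequences
    pairs = frozenset((c.residue_a, c.residue_b) for c in interface.contacts)
    if interface.interface_type == "protein-protein" and seq_b < seq_a:
        seq_a, seq_b = seq_b, seq_a
        pairs = frozenset((b, a) for a, b in pairs)
    return (interface.interface_type, seq_a, seq_b, pairs)


def deduplicate_interfaces(interfaces) -> list[Interface]:
    """Group interfaces with identical member sequences and contact sets.

    Exactly one representative per group: the lexicographically smallest
    (structure id, member ids).
    """
    groups: dict = {}
    for iface in interfaces:
        groups.setdefault(_group_key(iface), []).append(iface)
    out = []
    for gid, key in enumerate(sorted(groups, key=repr)):
        members = sorted(groups[key], key=lambda i: (i.structure_id, i.member_ids))
        for rank, iface in enumerate(members):
            iface.group_id = gid
            iface.representative = rank == 0
            out.append(iface)
    return out


def representatives(interfaces) -> list[Interface]:
    return [i for i in deduplicate_interfaces(interfaces) if i.representative]


def contact_jaccard(contacts_a, contacts_b) -> float:
    """Jaccard index |A∩B| / |A∪B| of two contact-label sets (0 if both empty)."""
    a, b = set(contacts_a), set(contacts_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)
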