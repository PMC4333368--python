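"""Seeded synthetic fixtures: toy complexes with planted contacts, sequence
corpora with planted identity ladders, and biased change sets.

Chains are idealized extended backbones with a single pseudo side-chain atom
per residue placed to satisfy the planted distances; no stereochemical realism
is attempted because the contact rules consult only distances, atom names and
elements.  Every generator is a pure function of its spec and seed, and every
planted property is verified with the corresponding detection module before
the fixture is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contacts import GENERIC_RULE, detect_contacts
from .errors import GenerationError, InputError
from .pipeline import SiteChange
from .structures import AA_1TO3, STANDARD_AA, StructureModel, parse_structure

_X_STRIDE = 6.0          # Å between residue slots; > generic threshold
_CHAIN_GAP = 9.0         # baseline separation between the two chains
_SIDE_ELEMENT = {"CB": "C"}


@dataclass(frozen=True)
class ComplexSpec:
    seed: int
    residues_per_chain: int = 40
    #: (residue index, target distance Å) planted between chains A and B
    contact_pairs: tuple = ()
    #: (het code, element, anchor residue in chain A, distance Å)
    ligands: tuple = ()
    #: residue indices of chain A contacted by a nucleic chain, with distance
    nucleic_contacts: tuple = ()
    #: (chain index 0/1, residue index, 3-letter code) modified residues
    modified_residues: tuple = ()
    noise_sigma: float = 0.1
    sequences: tuple | None = None  # optional explicit chain sequences

    def __post_init__(self):
        for idx, dist in self.contact_pairs:
            if not 0 < dist <= GENERIC_RULE.threshold:
                raise InputError(f"planted distance {dist} outside (0, 5]")
            if not 1 <= idx <= self.residues_per_chain:
                raise InputError(f"contact residue {idx} out of range")


@dataclass(frozen=True)
class CorpusSpec:
    seed: int
    identity_ladder: tuple = (90.0, 70.0, 50.0)
    length: int = 300
    n_sites: int = 10

    def __post_init__(self):
        if self.length < 50:
            raise InputError("corpus sequences must be >= 50 residues")
        for i in self.identity_ladder:
            if not 0 <= i <= 100:
                raise InputError(f"ladder identity {i} outside [0, 100]")


def _random_sequence(rng, length, forbid_g_at=()):
    letters = list(STANDARD_AA)
    seq = [letters[rng.integers(20)] for _ in range(length)]
    non_g = [a for a in letters if a != "G"]
    for pos in forbid_g_at:
        if seq[pos - 1] == "G":
            seq[pos - 1] = non_g[rng.integers(len(non_g))]
    return "".join(seq)


def _pdb_text(spec: ComplexSpec, rng) -> str:
    n = spec.residues_per_chain
    planted = dict(spec.contact_pairs)
    nucleic = dict(spec.nucleic_contacts)
    forbidden = set(planted) | set(nucleic) | {a for _, _, a, _ in spec.ligands}
    if spec.sequences is not None:
        seq_a, seq_b = spec.sequences
    else:
        seq_a = _random_sequence(rng, n, forbid_g_at=forbidden)
        seq_b = _random_sequence(rng, n, forbid_g_at=set(planted))
    mods = {(c, i): code for c, i, code in spec.modified_residues}

    lines = []
    serial = 1

    def atom(name, res3, chain, resnum, xyz, element, record="ATOM"):
        nonlocal serial
        noisy = np.asarray(xyz) + rng.normal(0.0, spec.noise_sigma, 3)
        aname = f" {name:<3s}"
        lines.append(
            f"{record:<6s}{serial:>5d} {aname:<4s} {res3:>3s} {chain:1s}"
            f"{resnum:>4d}    {noisy[0]:8.3f}{noisy[1]:8.3f}{noisy[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}")
        serial += 1

    def res3_of(chain_idx, i, letter):
        return mods.get((chain_idx, i), AA_1TO3[letter])

    anchors = {}
    for chain_idx, (chain, seq, y_bb) in enumerate(
            (("A", seq_a, -1.5), ("B", seq_b, _CHAIN_GAP + 1.5))):
        for i in range(1, n + 1):
            x = i * _X_STRIDE
            letter = seq[i - 1]
            res3 = res3_of(chain_idx, i, letter)
            atom("N", res3, chain, i, (x - 0.8, y_bb, 0.0), "N")
            atom("CA", res3, chain, i, (x, y_bb, 0.0), "C")
            atom("C", res3, chain, i, (x + 0.8, y_bb, 0.0), "C")
            atom("O", res3, chain, i, (x + 0.8, y_bb - 1.2, 0.0), "O")
            if letter != "G":
                if chain == "A" and i in planted:
                    cb = (x, 0.0, 0.0)
                elif chain == "B" and i in planted:
                    cb = (x, planted[i], 0.0)
                elif chain == "A":
                    cb = (x, -3.5, 0.0)
                else:
                    cb = (x, _CHAIN_GAP + 3.5, 0.0)
                atom("CB", res3, chain, i, cb, "C")
                if chain == "A":
                    anchors[i] = np.asarray(cb, dtype=float)
    for k, (het, element, anchor_res, dist) in enumerate(spec.ligands, start=1):
        base = anchors.get(anchor_res)
        if base is None:
            raise GenerationError(f"ligand anchor residue {anchor_res} has no CB")
        atom(element.upper(), het, "L", k, base + np.array([0, 0, dist]),
             element, record="HETATM")
    for k, i in enumerate(sorted(nucleic), start=1):
        base = anchors.get(i)
        if base is None:
            raise GenerationError(f"nucleic anchor residue {i} has no CB")
        atom("P", "DA", "N", k, base + np.array([0, 0, -nucleic[i]]), "P")
    lines.append("END")
    return "\n".join(lines) + "\n"


def generate_complex(spec: ComplexSpec, max_retries: int = 20) -> str:
    """PDB text whose generic contacts equal exactly the planted set.

    The structure is re-parsed and verified with the contact detector before
    being returned; with coordinate noise the draw is retried a bounded number
    of times.
    """
    rng = np.random.default_rng(spec.seed)
    planted = {(i, i) for i, _ in spec.contact_pairs}
    for _ in range(max_retries):
        text = _pdb_text(spec, rng)
        model = parse_structure(text, structure_id=f"cx{spec.seed}")
        prot = [f for f in model.fragments if f.polymer_type == "protein"]
        found = {(c.residue_a, c.residue_b)
                 for c in detect_contacts(prot[0], prot[1], GENERIC_RULE)}
        if found != planted:
            continue
        ok = True
        for k, (het, _, anchor, dist) in enumerate(spec.ligands):
            lig = model.ligands[k]
            cs = detect_contacts(prot[0], lig, GENERIC_RULE)
            if dist <= GENERIC_RULE.threshold and \
                    {c.residue_a for c in cs} != {anchor}:
                ok = False
        nuc = [f for f in model.fragments if f.polymer_type != "protein"]
        if spec.nucleic_contacts:
            want = {i for i, d in spec.nucleic_contacts
                    if d <= GENERIC_RULE.threshold}
            got = {c.residue_a for c in detect_contacts(prot[0], nuc[0],
                                                        GENERIC_RULE)}
            ok = ok and got == want
        if ok:
            return text
    raise GenerationError(
        f"could not satisfy complex spec after {max_retries} draws "
        f"(seed {spec.seed})")


def generate_model(spec: ComplexSpec) -> StructureModel:
    """Convenience: generate and parse in one step."""
    return parse_structure(generate_complex(spec),
                           structure_id=f"cx{spec.seed}")


@dataclass
class Corpus:
    query: object                  # SequenceRecord
    templates: list                # SequenceRecord per ladder identity
    template_identity: dict        # template id -> planted identity
    gold_sites: list               # planted functional-site positions
    #: template id -> set of template residue indices at interfaces
    interface_positions: dict = field(default_factory=dict)


def generate_corpus(spec: CorpusSpec):
    """Query + template ladder with exact planted identities and gold sites.

    Each ladder value ``i`` yields a template differing from the query at
    exactly ``round(L·(1−i/100))`` positions, spread evenly so that a local
    alignment recovers close to the planted identity.  Planted functional
    sites are recorded as gold labels and as interface positions on every
    template (coordinates coincide: substitutions never create indels).
    """
    from .mapping import SequenceRecord
    rng = np.random.default_rng(spec.seed)
    length = spec.length
    query = SequenceRecord(id=f"q{spec.seed}",
                           sequence=_random_sequence(rng, length))
    sites = sorted(rng.choice(np.arange(1, length + 1), size=spec.n_sites,
                              replace=False).tolist())
    corpus = Corpus(query=query, templates=[], template_identity={},
                    gold_sites=sites)
    letters = list(STANDARD_AA)
    for ident in spec.identity_ladder:
        n_sub = round(length * (1 - ident / 100.0))
        if n_sub == 0 and ident < 100:
            n_sub = 1
        # even spread with jitter keeps local alignments near-global
        slots = np.linspace(0, length - 1, num=n_sub, dtype=int) if n_sub else []
        seq = list(query.sequence)
        for pos in slots:
            choices = [a for a in letters if a != seq[pos]]
            seq[pos] = choices[rng.integers(len(choices))]
        tid = f"t{int(round(ident))}_{spec.seed}"
        corpus.templates.append(SequenceRecord(id=tid, sequence="".join(seq)))
        corpus.template_identity[tid] = 100.0 * (length - n_sub) / length
        corpus.interface_positions[tid] = set(sites)
    return corpus


def generate_change_set(sequences: dict, interface_positions: dict,
                        bias: float, n: int, seed: int):
    """Change set with an expected fraction ``bias`` at interface residues.

    ``interface_positions`` maps protein id to the set of its interface
    positions; remaining changes are uniform over non-interface positions.
    Positions are sampled without replacement across the whole set.
    """
    if not 0 <= bias <= 1:
        raise InputError("bias must be within [0, 1]")
    rng = np.random.default_rng(seed)
    iface_pool, other_pool = [], []
    for pid in sorted(sequences):
        iface = interface_positions.get(pid, set())
        for pos in range(1, len(sequences[pid]) + 1):
            (iface_pool if pos in iface else other_pool).append((pid, pos))
    if n > len(iface_pool) + len(other_pool):
        raise InputError(f"requested {n} changes but only "
                         f"{len(iface_pool) + len(other_pool)} positions exist")
    rng.shuffle(iface_pool)
    rng.shuffle(other_pool)
    letters = list(STANDARD_AA)
    changes = []
    for _ in range(n):
        take_iface = rng.random() < bias
        pool = iface_pool if take_iface else other_pool
        if not pool:
            raise InputError("candidate pool exhausted for requested bias")
        pid, pos = pool.pop()
        wt = sequences[pid][pos - 1]
        alt = [a for a in letters if a != wt]
        changes.append(SiteChange(protein_id=pid, position=pos, wt=wt,
                                  change=alt[rng.integers(len(alt))]))
    return changes
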