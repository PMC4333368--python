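"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's vectorized implementations: explicit
nested loops over atoms, counts and tables.
"""

import math

from scipy import stats

VDW_SET = {"A", "C", "F", "G", "I", "L", "M", "P", "V", "W", "Y", "Yp", "Ka"}
ELEC_SET = {"D", "E", "H", "K", "N", "Q", "R", "S", "T", "W", "Y",
            "Sp", "Tp", "Yp", "Ka"}


def _dist(p, q):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))


def _eligible(residue, atom, kind):
    if not atom.is_side_chain:
        return None
    el = atom.element.upper()
    if kind == "generic":
        return "any"
    if kind == "vdw":
        return "cs" if residue.state in VDW_SET and el in ("C", "S") else None
    if kind == "electrostatic":
        if residue.state in ELEC_SET and el in ("N", "O"):
            return "no"
        if residue.state in VDW_SET and el in ("C", "S"):
            return "cs"
        return None
    raise ValueError(kind)


def brute_force_protein_contacts(frag_a, frag_b, kind, threshold):
    """All residue pairs with an eligible atom pair within threshold."""
    found = {}
    for i, ra in enumerate(frag_a.residues, start=1):
        for j, rb in enumerate(frag_b.residues, start=1):
            for atom_a in ra.atoms:
                ka = _eligible(ra, atom_a, kind)
                if ka is None:
                    continue
                for atom_b in rb.atoms:
                    kb = _eligible(rb, atom_b, kind)
                    if kb is None:
                        continue
                    if kind == "electrostatic" and "no" not in (ka, kb):
                        continue
                    d = _dist(atom_a.coords, atom_b.coords)
                    if d <= threshold:
                        found[(i, j)] = min(d, found.get((i, j), 1e9))
    return found


def brute_force_partner_contacts(frag, partner_atoms, threshold):
    """Protein side-chain atoms vs any partner atom (ligand/nucleic rule)."""
    found = {}
    for i, res in enumerate(frag.residues, start=1):
        for atom in res.atoms:
            if not atom.is_side_chain:
                continue
            for patom in partner_atoms:
                d = _dist(atom.coords, patom.coords)
                if d <= threshold:
                    found[i] = min(d, found.get(i, 1e9))
    return found


def brute_force_ipp(interfaces, pseudocount=0.0):
    """Counting oracle for the protein-protein pair-potential block."""
    pair_counts = {}
    comp = {}
    for iface in interfaces:
        if iface.interface_type != "protein-protein" or not iface.representative:
            continue
        participants = set()
        for c in iface.contacts:
            participants.add(("a", c.residue_a, c.state_a))
            participants.add(("b", c.residue_b, c.state_b))
            if c.kinds & {"vdw", "electrostatic"}:
                for key in ((c.state_a, c.state_b), (c.state_b, c.state_a)):
                    pair_counts[key] = pair_counts.get(key, 0) + 1
        for _, _, state in participants:
            comp[state] = comp.get(state, 0) + 1
    total_res = sum(comp.values())
    x = {s: n / total_res for s, n in comp.items()}
    present = sorted(x)
    denom = sum(pair_counts.values()) + pseudocount * len(present) ** 2
    ipp = {}
    for a in present:
        for b in present:
            f_obs = (pair_counts.get((a, b), 0) + pseudocount) / denom
            if f_obs > 0:
                ipp[(a, b)] = math.log(f_obs / (x[a] * x[b]))
    return ipp


def fisher_two_sided_enumeration(table):
    """Sum hypergeometric pmf over tables with same margins and pmf <= observed."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    rv = stats.hypergeom(n, row1, col1)
    p_obs = rv.pmf(a)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    total = 0.0
    for k in range(lo, hi + 1):
        pk = rv.pmf(k)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(1.0, total)


def auc_by_pair_counting(labels, scores):
    """AUC = P(score_pos > score_neg) + 0.5 P(tie), by explicit pairs."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
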