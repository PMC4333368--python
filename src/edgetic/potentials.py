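"""Interface pair-potentials and change-impact scores.

A pair-potential ``IPP(a, p) = log(f_obs / f_exp)`` measures how often residue
type ``a`` is observed in contact with partner ``p`` (another residue, DNA/RNA,
or a chemical class) relative to a molar-fraction random expectation.  For
protein–protein interfaces the expectation is the product of interface residue
frequencies; for DNA/RNA and chemical classes it is the molar fraction of the
residue among residues of proteins contacting that partner class.

``ie_change`` sums, over a site's interface contacts, the difference between
the potential of the changed residue and that of the wild type: positive
values predict the change enhances the interaction, negative that it
diminishes it.  The total positional impact score adds, for each interaction
type hit at the site, the highest absolute ``ie_change`` plus one — the plus
one keeps sites at interfaces with incalculable potentials non-zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .contacts import Interface
from .errors import DerivationError, InputError
from .structures import ALPHABET

#: Chemical classes with derivable potentials by default.
DEFAULT_POTENTIAL_CLASSES = ("Zn", "Mg", "Fe", "Mn", "Cu", "DNA/RNA")

#: Classes unusable when max |IPP| over residues falls below this (log units).
CLASS_EXCLUSION_THRESHOLD = 1.0

_DEFAULT_HET_CLASSES = {
    "ZN": "Zn", "MG": "Mg", "FE": "Fe", "FE2": "Fe", "MN": "Mn", "CU": "Cu",
    "CA": "Ca", "K": "K", "NA": "Na", "CO": "Co", "NI": "Ni",
    "ATP": "Nucleotide", "ADP": "Nucleotide", "GTP": "Nucleotide",
    "GDP": "Nucleotide", "NAD": "Cofactor", "FAD": "Cofactor",
    "HEM": "Cofactor",
}


@dataclass(frozen=True)
class ChemicalClassMap:
    """Total map het code -> chemical class; unknown codes fall to Organic."""

    mapping: dict = field(default_factory=dict)
    catch_all: str = "Organic"

    def lookup(self, het_code: str) -> str:
        code = het_code.upper()
        if code in self.mapping:
            return self.mapping[code]
        return _DEFAULT_HET_CLASSES.get(code, self.catch_all)


@dataclass
class FrequencyTable:
    """Counts and frequencies a potential matrix was derived from."""

    pair_counts: pd.DataFrame            # ordered residue-pair contact counts
    residue_fractions: pd.Series         # interface molar fractions
    f_obs: pd.DataFrame
    f_exp: pd.DataFrame
    class_counts: dict = field(default_factory=dict)      # class -> Series
    class_fractions: dict = field(default_factory=dict)   # class -> Series
    pseudocount: float = 0.0
    total_contacts: float = 0.0


@dataclass
class PairPotentialMatrix:
    """IPP values over the 24-symbol alphabet vs residues and partner classes.

    ``values`` rows are indexed by the alphabet; columns are the alphabet
    followed by partner classes (``DNA/RNA``, metal ions...).  Entries are in
    log units of ``log_base`` (natural by default); NaN marks pairs with no
    derivable parameter.
    """

    values: pd.DataFrame
    capped: pd.DataFrame | None = None
    usable: dict = field(default_factory=dict)   # partner class -> bool
    log_base: float = math.e

    @property
    def alphabet(self):
        return tuple(self.values.index)

    @property
    def partner_classes(self):
        return tuple(c for c in self.values.columns if c not in self.values.index)

    def ipp(self, symbol: str, partner: str) -> float:
        try:
            return float(self.values.at[symbol, partner])
        except KeyError as exc:
            raise InputError(f"symbol not in matrix: {exc}") from exc

    def is_usable(self, partner: str) -> bool:
        if partner in self.values.index:
            return True
        return bool(self.usable.get(partner, False))

    def display_values(self, cap: float = 9.0) -> pd.DataFrame:
        """×10 integers capped at ``cap`` in magnitude, as printed in figures."""
        scaled = (self.values * 10).round()
        return scaled.clip(lower=-cap, upper=cap)

    def to_tsv(self, path) -> None:
        rows = []
        for a in self.values.index:
            for p in self.values.columns:
                v = self.values.at[a, p]
                rows.append({
                    "symbol": a, "partner": p,
                    "value": "" if pd.isna(v) else f"{v:.6g}",
                    "capped": int(bool(self.capped is not None
                                       and self.capped.at[a, p])),
                    "usable": int(self.is_usable(p)),
                })
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, source) -> "PairPotentialMatrix":
        df = pd.read_csv(source, sep="\t", dtype={"symbol": str, "partner": str})
        symbols = list(dict.fromkeys(df["symbol"]))
        partners = list(dict.fromkeys(df["partner"]))
        values = pd.DataFrame(np.nan, index=symbols, columns=partners)
        capped = pd.DataFrame(False, index=symbols, columns=partners)
        usable: dict = {}
        for row in df.itertuples(index=False):
            values.at[row.symbol, row.partner] = row.value
            capped.at[row.symbol, row.partner] = bool(row.capped)
            if row.partner not in symbols:
                usable[row.partner] = bool(row.usable)
        return cls(values=values, capped=capped, usable=usable)


def load_reference_matrix() -> PairPotentialMatrix:
    """Packaged synthetic reference matrix.

    A reconstruction on the ×10 integer grid of published interface
    pair-potentials: cells are chosen from canonical interface preferences
    (charge complementarity, hydrophobic/aromatic packing, phospho-residues
    behaving like acidic residues, acetyl-lysine preferring hydrophobic
    environments) and constrained so the published worked impact examples
    (D→L against two Phe = 2.4; R→C against two Glu = −3.8) hold exactly.
    It is synthetic package data, not a derived matrix.
    """
    ref = resources.files("edgetic") / "data" / "reference_ipp_synthetic.tsv"
    with resources.as_file(ref) as path:
        return PairPotentialMatrix.from_tsv(path)


def _meaningful(contact) -> bool:
    return bool(contact.kinds & {"vdw", "electrostatic"})


def derive_ipp(interfaces,
               pseudocount: float = 1.0,
               log_base: float = math.e,
               class_exclusion_threshold: float = CLASS_EXCLUSION_THRESHOLD,
               representatives_only: bool = True,
               ) -> tuple[PairPotentialMatrix, FrequencyTable]:
    """Derive pair-potentials from interfaces.

    Protein–protein counts use meaningful (vdw/electrostatic) contacts and a
    product-of-fractions expectation; DNA/RNA and chemical-class counts use
    generic contacts and the molar fraction of residues in proteins contacting
    the class.  ``pseudocount`` is added to every pair cell among symbols
    present at the interfaces.  Chemical classes with max |IPP| below the
    exclusion threshold are flagged unusable.
    """
    ifaces = [i for i in interfaces
              if (i.representative or not representatives_only)]
    if not ifaces:
        raise DerivationError("no interfaces to derive potentials from")
    symbols = list(ALPHABET)
    idx = {s: k for k, s in enumerate(symbols)}
    n = len(symbols)
    log = (lambda x: math.log(x)) if log_base == math.e else \
        (lambda x: math.log(x) / math.log(log_base))

    pair_counts = np.zeros((n, n))
    comp = np.zeros(n)
    class_counts: dict[str, np.ndarray] = {}
    class_bg: dict[str, np.ndarray] = {}
    for iface in ifaces:
        if iface.interface_type == "protein-protein":
            seen = set()
            for c in iface.contacts:
                seen.add(("a", c.residue_a, c.state_a))
                seen.add(("b", c.residue_b, c.state_b))
                if _meaningful(c) and c.state_a in idx and c.state_b in idx:
                    pair_counts[idx[c.state_a], idx[c.state_b]] += 1
                    pair_counts[idx[c.state_b], idx[c.state_a]] += 1
            for _, _, state in seen:
                if state in idx:
                    comp[idx[state]] += 1
        else:
            cls = iface.chem_class or "Organic"
            cnt = class_counts.setdefault(cls, np.zeros(n))
            bg = class_bg.setdefault(cls, np.zeros(n))
            for c in iface.contacts:
                if c.state_a in idx:
                    cnt[idx[c.state_a]] += 1
            for state in iface.protein_states:
                if state in idx:
                    bg[idx[state]] += 1

    columns = symbols + sorted(class_counts)
    values = pd.DataFrame(np.nan, index=symbols, columns=columns)
    usable: dict[str, bool] = {}

    # residue-residue block
    f_obs_df = pd.DataFrame(np.nan, index=symbols, columns=symbols)
    f_exp_df = pd.DataFrame(np.nan, index=symbols, columns=symbols)
    fractions = pd.Series(0.0, index=symbols)
    total = pair_counts.sum()
    if comp.sum() > 0:
        x = comp / comp.sum()
        fractions = pd.Series(x, index=symbols)
        present = np.nonzero(x > 0)[0]
        denom = total + pseudocount * len(present) ** 2
        if denom <= 0:
            raise DerivationError("no meaningful protein-protein contacts counted")
        for a in present:
            for b in present:
                f_obs = (pair_counts[a, b] + pseudocount) / denom
                f_exp = x[a] * x[b]
                f_obs_df.iat[a, b] = f_obs
                f_exp_df.iat[a, b] = f_exp
                if f_obs > 0:
                    values.iat[a, b] = log(f_obs / f_exp)

    # partner-class columns
    cls_counts_out, cls_frac_out = {}, {}
    for cls in sorted(class_counts):
        cnt, bg = class_counts[cls], class_bg[cls]
        if bg.sum() == 0:
            continue
        x = bg / bg.sum()
        present = np.nonzero(x > 0)[0]
        denom = cnt.sum() + pseudocount * len(present)
        col = np.full(n, np.nan)
        for a in present:
            f_obs = (cnt[a] + pseudocount) / denom
            if f_obs > 0:
                col[a] = log(f_obs / x[a])
        values[cls] = col
        finite = col[np.isfinite(col)]
        usable[cls] = bool(finite.size and np.max(np.abs(finite))
                           >= class_exclusion_threshold)
        cls_counts_out[cls] = pd.Series(cnt, index=symbols)
        cls_frac_out[cls] = pd.Series(x, index=symbols)

    matrix = PairPotentialMatrix(values=values, usable=usable, log_base=log_base)
    freq = FrequencyTable(
        pair_counts=pd.DataFrame(pair_counts, index=symbols, columns=symbols),
        residue_fractions=fractions,
        f_obs=f_obs_df, f_exp=f_exp_df,
        class_counts=cls_counts_out, class_fractions=cls_frac_out,
        pseudocount=pseudocount, total_contacts=float(total),
    )
    return matrix, freq


def ie_change(wt: str, change: str, partner_symbols,
              matrix: PairPotentialMatrix) -> float:
    """Direction-of-effect score for replacing ``wt`` by ``change``.

    Sum over partner symbols (residue states, ``DNA/RNA``, or chemical
    classes) of ``IPP(change, p) − IPP(wt, p)``; contacts are presumed
    unchanged by the substitution.  Partners from unusable chemical classes,
    or with no derivable potential, contribute zero.
    """
    for sym in (wt, change):
        if sym not in matrix.values.index:
            raise InputError(f"symbol not in alphabet: {sym!r}")
    if wt == change:
        return 0.0
    score = 0.0
    for p in partner_symbols:
        if p not in matrix.values.columns:
            raise InputError(f"partner not in matrix: {p!r}")
        if not matrix.is_usable(p):
            continue
        diff = matrix.values.at[change, p] - matrix.values.at[wt, p]
        if np.isfinite(diff):
            score += float(diff)
    return score


def site_impact_score(per_type_ie, per_type_hit) -> float:
    """Total positional impact: Σ over hit types of (max |IE| + 1).

    ``per_type_ie`` maps interaction type to its per-partner IE values;
    ``per_type_hit`` lists types with at least one interface hit.  A hit type
    whose IE values are all incalculable contributes exactly 1.
    """
    score = 0.0
    for itype in per_type_hit:
        ies = [v for v in per_type_ie.get(itype, ())
               if v is not None and np.isfinite(v)]
        score += (max(abs(v) for v in ies) if ies else 0.0) + 1.0
    return score


def protein_impact_score(site_scores) -> float:
    """Total protein impact: arithmetic sum of site scores (0 when empty)."""
    return float(sum(site_scores))
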