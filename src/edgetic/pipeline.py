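"""End-to-end scoring: interaction filtering, change-to-interface mapping,
per-partner IE scores, confidence, and export tables.

Wild-type residue identities come from the query sequence; partner residue
identities for the potential lookup come from the template structure, with
contacts presumed conserved across the template match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .calibration import CalibrationCurve, fpr_at_identity
from .errors import InputError
from .potentials import PairPotentialMatrix, ie_change, site_impact_score

logger = logging.getLogger(__name__)

TYPE_OF_INTERFACE = {
    "protein-protein": "protein",
    "protein-chemical": "chemical",
    "protein-dna/rna": "dna/rna",
}


@dataclass(frozen=True)
class InteractionRecord:
    id_a: str
    id_b: str
    method_class: str = ""
    pubmed_id: str = ""
    direct_physical: bool = False

    @property
    def pair(self):
        return tuple(sorted((self.id_a, self.id_b)))


@dataclass(frozen=True)
class StringencyConfig:
    min_identity: float = 0.0
    require_direct_physical: bool = False
    require_high_quality: bool = False
    exclude_high_throughput: bool = False
    high_throughput_threshold: int = 300
    high_quality_evidence: int = 2
    #: drop protein-protein hits lacking a filtered interaction record
    require_known_interaction: bool = False
    neutral_epsilon: float = 0.1


@dataclass(frozen=True)
class SiteChange:
    protein_id: str
    position: int  # 1-based
    wt: str
    change: str


@dataclass
class InterfaceHit:
    interaction_type: str      # protein | chemical | dna/rna
    partner_id: str            # fragment/ligand id of the partner
    partner_proteins: tuple    # query proteins mapped to the partner fragment
    template_identity: float
    partner_symbols: tuple
    ie: float | None
    known_interaction: bool = False
    structure_only: bool = False


@dataclass
class SitePrediction:
    change: SiteChange
    hits: list = field(default_factory=list)
    per_type_fpr: dict = field(default_factory=dict)
    score: float = 0.0


def filter_interactions(records, config: StringencyConfig):
    """Apply stringency filters and deduplicate on the unordered pair.

    High-throughput publications contribute ≥ ``high_throughput_threshold``
    records; high-quality pairs have evidence from ≥2 distinct publications or
    detection methods.  With the HT exclusion on, pairs whose entire evidence
    is high-throughput are removed.
    """
    pub_counts: dict[str, int] = {}
    for r in records:
        pub_counts[r.pubmed_id] = pub_counts.get(r.pubmed_id, 0) + 1
    ht_pubs = {p for p, n in pub_counts.items()
               if n >= config.high_throughput_threshold}

    by_pair: dict[tuple, list[InteractionRecord]] = {}
    for r in records:
        by_pair.setdefault(r.pair, []).append(r)

    kept = []
    for pair in sorted(by_pair):
        evidence = by_pair[pair]
        if config.require_direct_physical:
            evidence = [r for r in evidence if r.direct_physical]
        if config.exclude_high_throughput:
            evidence = [r for r in evidence if r.pubmed_id not in ht_pubs]
        if not evidence:
            continue
        pubs = {r.pubmed_id for r in evidence}
        methods = {r.method_class for r in evidence}
        high_quality = (len(pubs) >= config.high_quality_evidence
                        or len(methods) >= config.high_quality_evidence)
        if config.require_high_quality and not high_quality:
            continue
        kept.append(evidence[0])
    return kept


def _contacts_at(interface, fragment_id, residue_index):
    """Contacts of one residue within an interface, viewed from that residue."""
    out = []
    for c in interface.contacts:
        if c.fragment_a == fragment_id and c.residue_a == residue_index:
            out.append(c)
    return out


def predict_sites(changes, position_maps: dict, interfaces,
                  matrix: PairPotentialMatrix,
                  sequences: dict,
                  calibration: CalibrationCurve | None = None,
                  interactions=None,
                  fragment_to_proteins: dict | None = None,
                  config: StringencyConfig = StringencyConfig(),
                  ) -> list[SitePrediction]:
    """Score a change list against mapped interfaces.

    ``position_maps`` maps protein id to its :class:`PositionMap`;
    ``fragment_to_proteins`` maps a fragment id to query proteins covering it
    (used to look up interaction records for protein partners).  Changes at
    unmapped or non-interface positions yield a prediction with zero hits and
    score 0; wild-type mismatches are skipped with a logged validation error.
    """
    fragment_to_proteins = fragment_to_proteins or {}
    known_pairs = set()
    if interactions is not None:
        known_pairs = {r.pair for r in filter_interactions(interactions, config)}

    by_residue: dict[tuple, list] = {}
    for iface in interfaces:
        for c in iface.contacts:
            by_residue.setdefault((c.fragment_a, c.residue_a), []).append(iface)

    predictions = []
    for change in changes:
        seq = sequences.get(change.protein_id)
        if seq is None or change.position > len(seq) \
                or seq[change.position - 1] != change.wt:
            logger.error("wild-type mismatch for %s %s%d%s: skipped",
                         change.protein_id, change.wt, change.position,
                         change.change)
            continue
        pred = SitePrediction(change=change)
        pmap = position_maps.get(change.protein_id)
        mapped = pmap.fragment_residue(change.position) if pmap else None
        if mapped is not None:
            frag_id, frag_res, identity = mapped
            if identity >= config.min_identity:
                seen = set()
                for iface in by_residue.get((frag_id, frag_res), []):
                    key = id(iface)
                    if key in seen:
                        continue
                    seen.add(key)
                    pred.hits.append(_score_hit(
                        iface, frag_id, frag_res, identity, change,
                        matrix, fragment_to_proteins, known_pairs,
                        interactions is not None))
        per_type_ie: dict[str, list] = {}
        hit_types = set()
        for hit in pred.hits:
            hit_types.add(hit.interaction_type)
            per_type_ie.setdefault(hit.interaction_type, []).append(hit.ie)
        pred.score = site_impact_score(per_type_ie, hit_types)
        if calibration is not None:
            for hit in pred.hits:
                if hit.interaction_type not in pred.per_type_fpr:
                    pred.per_type_fpr[hit.interaction_type] = fpr_at_identity(
                        calibration, hit.template_identity, hit.interaction_type)
        predictions.append(pred)
    return predictions


def _score_hit(iface, frag_id, frag_res, identity, change, matrix,
               fragment_to_proteins, known_pairs, filtering_enabled):
    itype = TYPE_OF_INTERFACE[iface.interface_type]
    contacts = _contacts_at(iface, frag_id, frag_res)
    if itype == "protein":
        partner_symbols = tuple(c.state_b for c in contacts
                                if c.state_b is not None)
    else:
        partner = iface.chem_class or "Organic"
        partner_symbols = tuple(partner for _ in contacts)
    try:
        ie = ie_change(change.wt, change.change, partner_symbols, matrix)
    except InputError:
        ie = None  # symbol or partner without derivable potential
    partner_id = next(m for m in iface.member_ids if m != frag_id)
    partner_proteins = tuple(sorted(fragment_to_proteins.get(partner_id, ())))
    known = False
    if itype == "protein" and filtering_enabled:
        known = any(tuple(sorted((change.protein_id, p))) in known_pairs
                    for p in partner_proteins)
    return InterfaceHit(
        interaction_type=itype, partner_id=partner_id,
        partner_proteins=partner_proteins, template_identity=identity,
        partner_symbols=partner_symbols, ie=ie,
        known_interaction=known,
        structure_only=(itype == "protein" and filtering_enabled and not known),
    )


def _effect_label(ie: float, eps: float) -> str:
    if ie is None or abs(ie) <= eps:
        return "neutral"
    return "enhance" if ie > 0 else "diminish"


def export_results(predictions, site_path, protein_path, edge_path,
                   config: StringencyConfig = StringencyConfig()) -> None:
    """Write per-site and per-protein TSVs and a network edge list.

    Edge labels follow the sign of IE (enhance >0, diminish <0, neutral within
    ±epsilon) and become ``mixed`` when different changes on the same edge
    disagree.
    """
    site_rows, edge_votes = [], {}
    protein_scores: dict[str, float] = {}
    for pred in predictions:
        ch = pred.change
        protein_scores[ch.protein_id] = (
            protein_scores.get(ch.protein_id, 0.0) + pred.score)
        if not pred.hits:
            site_rows.append({
                "protein_id": ch.protein_id, "position": ch.position,
                "wt": ch.wt, "change": ch.change, "interaction_type": "",
                "partner_id": "", "template_identity": "", "ie": "",
                "fpr": "", "site_score": pred.score, "known_interaction": "",
            })
        for hit in pred.hits:
            site_rows.append({
                "protein_id": ch.protein_id, "position": ch.position,
                "wt": ch.wt, "change": ch.change,
                "interaction_type": hit.interaction_type,
                "partner_id": hit.partner_id,
                "template_identity": round(hit.template_identity, 2),
                "ie": "" if hit.ie is None else round(hit.ie, 4),
                "fpr": pred.per_type_fpr.get(hit.interaction_type, ""),
                "site_score": pred.score,
                "known_interaction": int(hit.known_interaction),
            })
            if hit.interaction_type == "protein" and hit.ie is not None:
                targets = hit.partner_proteins or (hit.partner_id,)
                for partner in targets:
                    edge_votes.setdefault(
                        tuple(sorted((ch.protein_id, partner))), []).append(hit.ie)

    columns = ["protein_id", "position", "wt", "change", "interaction_type",
               "partner_id", "template_identity", "ie", "fpr", "site_score",
               "known_interaction"]
    pd.DataFrame(site_rows, columns=columns).to_csv(
        site_path, sep="\t", index=False)

    prot_rows = [{"protein_id": pid, "protein_score": score}
                 for pid, score in sorted(protein_scores.items())]
    pd.DataFrame(prot_rows, columns=["protein_id", "protein_score"]).to_csv(
        protein_path, sep="\t", index=False)

    edge_rows = []
    for (a, b), ies in sorted(edge_votes.items()):
        labels = {_effect_label(ie, config.neutral_epsilon) for ie in ies}
        non_neutral = labels - {"neutral"}
        if len(non_neutral) > 1:
            label = "mixed"
        elif non_neutral:
            label = next(iter(non_neutral))
        else:
            label = "neutral"
        edge_rows.append({"protein_a": a, "protein_b": b,
                          "n_changes": len(ies), "effect": label})
    pd.DataFrame(edge_rows, columns=["protein_a", "protein_b", "n_changes",
                                     "effect"]).to_csv(
        edge_path, sep="\t", index=False)
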