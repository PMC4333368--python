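"""Identity-calibrated confidence for interface-site predictions.

Gold-standard positives are sites seen in contact through near-identical
templates (≥90% identity); negatives are sites only ever implicated through
remote templates (≤20% identity) and not in the positives.  Sweeping the
identity threshold over the 20–90% band of predictions yields, per interaction
type, a step curve of (threshold, FPR, TPR) used to attach a false-positive
rate to any prediction made at a given template identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import CalibrationError, InputError

logger = logging.getLogger(__name__)

POSITIVE_IDENTITY = 90.0
NEGATIVE_IDENTITY = 20.0
INTERACTION_TYPES = ("protein", "chemical", "dna/rna")


@dataclass(frozen=True)
class ContactEvidence:
    """One template-based observation that a site contacts a molecule type."""

    protein_id: str
    position: int
    interaction_type: str  # protein | chemical | dna/rna
    identity: float        # percent identity of the template match

    @property
    def site(self):
        return (self.protein_id, self.position)


@dataclass
class GoldStandard:
    positives: dict = field(default_factory=dict)  # type -> set of sites
    negatives: dict = field(default_factory=dict)


@dataclass
class CalibrationCurve:
    """Per interaction type, ordered (identity threshold, FPR, TPR) triples."""

    points: dict = field(default_factory=dict)  # type -> list[(t, fpr, tpr)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"type": t, "threshold": thr, "fpr": fpr, "tpr": tpr}
            for t, pts in self.points.items() for thr, fpr, tpr in pts
        ]
        return pd.DataFrame(rows, columns=["type", "threshold", "fpr", "tpr"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, source) -> "CalibrationCurve":
        df = pd.read_csv(source, sep="\t")
        points: dict = {}
        for row in df.itertuples(index=False):
            points.setdefault(row.type, []).append(
                (float(row.threshold), float(row.fpr), float(row.tpr)))
        for pts in points.values():
            pts.sort()
        return cls(points=points)


def build_gold_standard(evidence) -> GoldStandard:
    """Partition sites into positives and negatives per interaction type.

    Positives: any evidence at ≥90% identity.  Negatives: evidence at ≤20%
    identity and not positive (positives take precedence).
    """
    gold = GoldStandard()
    by_type: dict[str, list[ContactEvidence]] = {}
    for ev in evidence:
        by_type.setdefault(ev.interaction_type, []).append(ev)
    any_positive = False
    for itype, evs in by_type.items():
        pos = {e.site for e in evs if e.identity >= POSITIVE_IDENTITY}
        neg = {e.site for e in evs if e.identity <= NEGATIVE_IDENTITY} - pos
        gold.positives[itype] = pos
        gold.negatives[itype] = neg
        any_positive = any_positive or bool(pos)
    if not any_positive:
        raise CalibrationError(
            "no templates at >=90% identity: calibration impossible")
    return gold


def calibrate(gold: GoldStandard, predictions,
              thresholds=range(20, 91)) -> CalibrationCurve:
    """TPR/FPR per identity threshold from the 20–90% prediction band.

    A site counts as predicted at threshold ``t`` if any template of identity
    ≥ t predicts it in contact.
    """
    by_type: dict[str, list[ContactEvidence]] = {}
    for ev in predictions:
        by_type.setdefault(ev.interaction_type, []).append(ev)
    curve = CalibrationCurve()
    for itype in sorted(set(gold.positives) | set(by_type)):
        pos = gold.positives.get(itype, set())
        neg = gold.negatives.get(itype, set())
        if not pos or not neg:
            empty = "positive" if not pos else "negative"
            raise CalibrationError(
                f"degenerate gold standard for {itype!r}: empty {empty} class")
        evs = by_type.get(itype, [])
        points = []
        for t in thresholds:
            predicted = {e.site for e in evs if e.identity >= t}
            tpr = len(predicted & pos) / len(pos)
            fpr = len(predicted & neg) / len(neg)
            points.append((float(t), fpr, tpr))
        curve.points[itype] = points
    return curve


def fpr_at_identity(curve: CalibrationCurve, identity: float,
                    interaction_type: str) -> float:
    """Step-function FPR lookup at a template identity.

    Returns the FPR of the largest calibrated threshold ≤ identity; identities
    below the calibrated range fall back to the worst (largest) calibrated
    FPR with a logged flag.
    """
    pts = curve.points.get(interaction_type)
    if not pts:
        raise InputError(f"no calibration for type {interaction_type!r}")
    eligible = [(t, fpr) for t, fpr, _ in pts if t <= identity]
    if not eligible:
        worst = max(fpr for _, fpr, _ in pts)
        logger.warning("identity %.1f below calibrated range for %s; "
                       "reporting worst FPR %.3f",
                       identity, interaction_type, worst)
        return worst
    return max(eligible)[1]
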