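"""Readers and writers for the plain-text exchange formats.

Change lists, interaction tables and benchmark records are TSV; sequences are
FASTA (via biopython); thresholds travel as a JSON config.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

from .errors import InputError
from .mapping import SequenceRecord
from .pipeline import InteractionRecord, SiteChange, StringencyConfig


def read_fasta(source) -> list[SequenceRecord]:
    if isinstance(source, str) and "\n" in source:
        source = _io.StringIO(source)
    return [SequenceRecord(id=rec.id, sequence=str(rec.seq).upper())
            for rec in SeqIO.parse(source, "fasta")]


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_changes(source) -> list[SiteChange]:
    """TSV with columns protein_id, position, wt, change."""
    df = pd.read_csv(source, sep="\t", dtype=str)
    required = {"protein_id", "position", "wt", "change"}
    if not required.issubset(df.columns):
        raise InputError(f"change list needs columns {sorted(required)}")
    return [SiteChange(protein_id=r.protein_id, position=int(r.position),
                       wt=r.wt, change=r.change)
            for r in df.itertuples(index=False)]


def write_changes(changes, path) -> None:
    pd.DataFrame([{"protein_id": c.protein_id, "position": c.position,
                   "wt": c.wt, "change": c.change} for c in changes]).to_csv(
        path, sep="\t", index=False)


def read_interactions(source) -> list[InteractionRecord]:
    """TSV with columns id_a, id_b, method_class, pubmed_id, direct_physical."""
    df = pd.read_csv(source, sep="\t", dtype=str)
    required = {"id_a", "id_b", "method_class", "pubmed_id", "direct_physical"}
    if not required.issubset(df.columns):
        raise InputError(f"interaction table needs columns {sorted(required)}")
    return [InteractionRecord(
        id_a=r.id_a, id_b=r.id_b, method_class=r.method_class,
        pubmed_id=r.pubmed_id,
        direct_physical=str(r.direct_physical).lower() in ("1", "true", "yes"))
        for r in df.itertuples(index=False)]


@dataclass(frozen=True)
class DirectionBenchmarkRecord:
    protein_id: str
    position: int
    wt: str
    change: str
    partner: str
    effect: str  # disabling | enabling | neutral
    ie: float = 0.0

    def __post_init__(self):
        if self.effect not in ("disabling", "enabling", "neutral"):
            raise InputError(f"unknown effect label {self.effect!r}")


def read_benchmark(source) -> list[DirectionBenchmarkRecord]:
    df = pd.read_csv(source, sep="\t", dtype=str)
    required = {"protein_id", "position", "wt", "change", "partner", "effect"}
    if not required.issubset(df.columns):
        raise InputError(f"benchmark needs columns {sorted(required)}")
    return [DirectionBenchmarkRecord(
        protein_id=r.protein_id, position=int(r.position), wt=r.wt,
        change=r.change, partner=r.partner, effect=r.effect,
        ie=float(getattr(r, "ie", 0.0) or 0.0))
        for r in df.itertuples(index=False)]


def interfaces_to_frame(interfaces) -> pd.DataFrame:
    rows = []
    for iface in interfaces:
        for c in iface.contacts:
            rows.append({
                "type": iface.interface_type,
                "members": "|".join(iface.member_ids),
                "residue_a": c.residue_a,
                "residue_b": "" if c.residue_b is None else c.residue_b,
                "state_a": c.state_a,
                "state_b": c.state_b or "",
                "kinds": ",".join(sorted(c.kinds)),
                "min_distance": round(c.min_distance, 3),
                "group_id": iface.group_id,
                "representative": int(iface.representative),
            })
    return pd.DataFrame(rows, columns=[
        "type", "members", "residue_a", "residue_b", "state_a", "state_b",
        "kinds", "min_distance", "group_id", "representative"])


def position_map_to_frame(pmap) -> pd.DataFrame:
    """PositionMap as a table: query id, position, fragment, residue, identity."""
    rows = []
    for pos in sorted(pmap.best):
        match, frag_res = pmap.best[pos]
        rows.append({"query_id": pmap.query_id, "position": pos,
                     "fragment_id": match.fragment_id,
                     "fragment_residue": frag_res,
                     "identity": round(match.identity, 2)})
    return pd.DataFrame(rows, columns=["query_id", "position", "fragment_id",
                                       "fragment_residue", "identity"])


def load_config(path) -> StringencyConfig:
    with open(path) as fh:
        raw = json.load(fh)
    return StringencyConfig(**raw)
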