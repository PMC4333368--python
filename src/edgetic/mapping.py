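"""Sequence-to-structure mapping by local alignment.

Queries are aligned against every fragment sequence with a local affine-gap
aligner under BLOSUM62.  Match significance is a Karlin–Altschul E-value with
the standard ungapped BLOSUM62 parameters (λ = 0.3176, K = 0.134) evaluated
over the total library size; matches above the threshold (0.0001 by default)
are dropped.  For every query position the covering match with the highest
percent identity is retained (ties: longer alignment, then fragment id).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import InputError

KA_LAMBDA = 0.3176
KA_K = 0.134
DEFAULT_EVALUE = 1e-4

_VALID = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise InputError(f"empty sequence for {self.id!r}")
        bad = set(self.sequence.upper()) - _VALID
        if bad:
            raise InputError(f"invalid residues in {self.id!r}: {sorted(bad)}")


@dataclass
class SequenceStructureMatch:
    query_id: str
    fragment_id: str
    #: 1-based (query position, fragment residue index) pairs
    aligned_pairs: list
    identity: float          # percent over aligned columns (gaps excluded)
    evalue: float
    score: float

    @property
    def length(self) -> int:
        return len(self.aligned_pairs)


@dataclass
class PositionMap:
    """Best covering match per 1-based query position."""

    query_id: str
    best: dict = field(default_factory=dict)  # position -> (match, frag residue)

    def fragment_residue(self, position: int):
        """(fragment id, residue index, identity) or None."""
        entry = self.best.get(position)
        if entry is None:
            return None
        match, frag_res = entry
        return match.fragment_id, frag_res, match.identity


def _make_aligner(open_gap=-11.0, extend_gap=-1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def karlin_altschul_evalue(score: float, query_len: int, library_len: int) -> float:
    """E = K·m·n·exp(−λS) with fixed ungapped BLOSUM62 parameters."""
    return KA_K * query_len * library_len * math.exp(-KA_LAMBDA * score)


def align_and_map(query: SequenceRecord,
                  fragment_library,
                  evalue_threshold: float = DEFAULT_EVALUE,
                  ) -> tuple[list[SequenceStructureMatch], PositionMap]:
    """Align a query against a library of (id, sequence) records.

    ``fragment_library`` is an iterable of objects with ``id``/``sequence``
    attributes (e.g. :class:`SequenceRecord`) or of
    :class:`~edgetic.structures.StructureFragment` objects.
    """
    library = []
    for frag in fragment_library:
        fid = getattr(frag, "fragment_id", None) or frag.id
        library.append((fid, frag.sequence.upper()))
    if not library:
        raise InputError("fragment library is empty")
    qseq = query.sequence.upper()
    total_len = sum(len(s) for _, s in library)
    aligner = _make_aligner()

    matches: list[SequenceStructureMatch] = []
    for fid, fseq in sorted(library):
        try:
            alignment = aligner.align(qseq, fseq)[0]
        except (IndexError, ValueError):
            continue
        score = float(alignment.score)
        if score <= 0:
            continue
        evalue = karlin_altschul_evalue(score, len(qseq), total_len)
        if evalue > evalue_threshold:
            continue
        pairs, identical = [], 0
        for (qs, qe), (fs, fe) in zip(*alignment.aligned):
            for k in range(qe - qs):
                qi, fi = qs + k, fs + k
                pairs.append((qi + 1, fi + 1))
                if qseq[qi] == fseq[fi]:
                    identical += 1
        if not pairs:
            continue
        identity = 100.0 * identical / len(pairs)
        matches.append(SequenceStructureMatch(
            query_id=query.id, fragment_id=fid, aligned_pairs=pairs,
            identity=identity, evalue=evalue, score=score))

    pmap = PositionMap(query_id=query.id)
    ranked = sorted(matches,
                    key=lambda m: (-m.identity, -m.length, m.fragment_id))
    for match in ranked:
        for qpos, fres in match.aligned_pairs:
            if qpos not in pmap.best:
                pmap.best[qpos] = (match, fres)
    return matches, pmap


def disorder_mask(scores, window: int = 11, threshold: float = 0.5):
    """Flag residues whose mean disorder over a centred window is ≥ threshold.

    Windows are truncated at the sequence ends.  Scores must lie in [0, 1].
    """
    if window < 1 or window % 2 == 0:
        raise InputError("window must be odd and >= 1")
    scores = np.asarray(list(scores), dtype=float)
    if scores.size and (scores.min() < 0 or scores.max() > 1):
        raise InputError("disorder scores must be within [0, 1]")
    half = window // 2
    padded = np.concatenate([[0.0], np.cumsum(scores)])
    n = scores.size
    out = np.empty(n, dtype=bool)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = (padded[hi] - padded[lo]) / (hi - lo) >= threshold
    return out
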