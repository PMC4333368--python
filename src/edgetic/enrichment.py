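"""Shuffled-null enrichment statistics, accessibility classes, ROC and score
combination.

The null model relocates each change to a random position carrying the same
wild-type residue (within the same protein, or in a random protein from the
dataset), never re-selecting the original site.  The surface-biased variant
additionally requires the destination to fall in the same relative-accessibility
class (buried ≤5%, intermediate ≤25%, exposed >25%, or no-3D), which preserves
the dataset's four-class histogram exactly.  Real-vs-shuffled overlap with an
interface class is assessed by a two-sided Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn import metrics as _skm

from .errors import InputError

PROBE_RADIUS = 1.4
N_SPHERE_POINTS = 256

#: van der Waals radii (Å) by element for the rolling-probe surface.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
             "ZN": 1.39, "MG": 1.73, "FE": 1.40, "MN": 1.40, "CU": 1.40}
DEFAULT_RADIUS = 1.70

ACCESSIBILITY_CLASSES = ("buried", "intermediate", "exposed", "no3D")


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def shrake_rupley_area(coords, radii, which=None,
                       probe: float = PROBE_RADIUS,
                       n_points: int = N_SPHERE_POINTS) -> np.ndarray:
    """Accessible surface area (Å²) per atom by sphere-point sampling.

    ``which`` optionally restricts the computation to a subset of atom
    indices; occlusion always considers every atom in ``coords``.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float) + probe
    n = len(coords)
    targets = range(n) if which is None else which
    unit = _sphere_points(n_points)
    areas = np.zeros(n)
    for i in targets:
        pts = coords[i] + radii[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        d0 = np.linalg.norm(coords - coords[i], axis=1)
        neighbours = np.nonzero((d0 < radii + radii[i]) &
                                (np.arange(n) != i))[0]
        for j in neighbours:
            # a sample point is buried if it falls inside atom j's expanded sphere
            accessible &= np.linalg.norm(pts - coords[j], axis=1) >= radii[j]
            if not accessible.any():
                break
        areas[i] = accessible.sum() / n_points * 4 * np.pi * radii[i] ** 2
    return areas


def _atom_arrays(atoms):
    coords = np.array([a.coords for a in atoms], dtype=float)
    radii = np.array([VDW_RADII.get(a.element.upper(), DEFAULT_RADIUS)
                      for a in atoms])
    return coords, radii


def relative_accessibility(fragment, residue_index: int,
                           context_atoms=None,
                           n_points: int = N_SPHERE_POINTS):
    """Relative solvent accessibility (percent) of one residue.

    Probe-rolling (1.4 Å) accessible surface of the residue's atoms within
    the fragment (plus optional extra context atoms), divided by the surface
    of the same residue in an extracted tripeptide (the residue with only its
    two flanking residues retained — the standard reference-state convention,
    evaluated on the actual atoms rather than a tabulated maximum), ×100,
    capped at 100.  Returns None for a residue with no atoms (no-3D
    downstream).
    """
    residue = fragment.residues[residue_index - 1]
    if not residue.atoms:
        return None
    context = [a for res in fragment.residues for a in res.atoms]
    if context_atoms:
        context = context + list(context_atoms)
    offset = sum(len(res.atoms) for res in fragment.residues[:residue_index - 1])
    target = list(range(offset, offset + len(residue.atoms)))
    coords, radii = _atom_arrays(context)
    in_context = shrake_rupley_area(coords, radii, which=target,
                                    n_points=n_points)[target].sum()

    lo = max(0, residue_index - 2)
    tri_res = fragment.residues[lo:residue_index + 1]
    tri_atoms = [a for res in tri_res for a in res.atoms]
    tri_offset = sum(len(res.atoms)
                     for res in tri_res[:residue_index - 1 - lo])
    tri_target = list(range(tri_offset, tri_offset + len(residue.atoms)))
    tri_coords, tri_radii = _atom_arrays(tri_atoms)
    reference = shrake_rupley_area(tri_coords, tri_radii, which=tri_target,
                                   n_points=n_points)[tri_target].sum()
    if reference <= 0:
        return None
    return min(100.0, 100.0 * in_context / reference)


def accessibility_class(value) -> str:
    """buried (≤5), intermediate (>5, ≤25), exposed (>25), or no3D (missing)."""
    if value is None:
        return "no3D"
    if value < 0:
        raise InputError("accessibility must be non-negative")
    if value <= 5.0:
        return "buried"
    if value <= 25.0:
        return "intermediate"
    return "exposed"


@dataclass(frozen=True)
class ShuffleSpec:
    mode: str = "positions"  # positions | proteins-and-positions
    surface_biased: bool = False
    seed: int = 0
    replicates: int = 1

    def __post_init__(self):
        if self.mode not in ("positions", "proteins-and-positions"):
            raise InputError(f"unknown shuffle mode {self.mode!r}")
        if self.replicates < 1:
            raise InputError("replicate count must be >= 1")


def _candidate_positions(sequences: dict) -> dict:
    """(protein, wt residue) -> sorted positions carrying that residue."""
    index: dict = {}
    for pid in sorted(sequences):
        for pos, aa in enumerate(sequences[pid], start=1):
            index.setdefault((pid, aa), []).append(pos)
    return index


def shuffle_sites(dataset, sequences: dict, spec: ShuffleSpec,
                  classes: dict | None = None,
                  rng: np.random.Generator | None = None):
    """Relocate every site to a random legal destination.

    ``dataset`` is a list of objects with ``protein_id``/``position``/``wt``/
    ``change`` attributes; ``sequences`` maps protein id to sequence.  A legal
    destination carries the same wild-type residue and is never the original
    site.  In surface-biased mode (``classes`` maps (protein, position) to an
    accessibility class) the multiset of destination classes must equal the
    multiset of original classes: destinations are drawn greedily against the
    histogram quota, with bounded retries over site orderings.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if spec.surface_biased and classes is None:
        raise InputError("surface-biased shuffle requires accessibility classes")
    index = _candidate_positions(sequences)
    protein_ids = sorted(sequences)

    def candidates_for(site):
        if spec.mode == "positions":
            pools = [(site.protein_id, index.get((site.protein_id, site.wt), []))]
        else:
            pools = [(pid, index.get((pid, site.wt), [])) for pid in protein_ids]
        return [(pid, pos) for pid, positions in pools for pos in positions
                if (pid, pos) != (site.protein_id, site.position)]

    def fail(site):
        raise InputError(
            f"no legal shuffle destination for {site.wt} at "
            f"{site.protein_id}:{site.position}")

    if not spec.surface_biased:
        out = []
        for site in dataset:
            cands = candidates_for(site)
            if not cands:
                fail(site)
            pid, pos = cands[rng.integers(len(cands))]
            out.append(type(site)(protein_id=pid, position=pos,
                                  wt=site.wt, change=site.change))
        return out

    quota_template: dict[str, int] = {}
    for site in dataset:
        cls = classes.get((site.protein_id, site.position), "no3D")
        quota_template[cls] = quota_template.get(cls, 0) + 1
    for _ in range(100):
        quota = dict(quota_template)
        order = rng.permutation(len(dataset))
        placed: dict[int, tuple] = {}
        ok = True
        for k in order:
            site = dataset[k]
            cands = [c for c in candidates_for(site)
                     if quota.get(classes.get(c, "no3D"), 0) > 0]
            if not cands:
                if not candidates_for(site):
                    fail(site)
                ok = False
                break
            pid, pos = cands[rng.integers(len(cands))]
            quota[classes.get((pid, pos), "no3D")] -= 1
            placed[k] = (pid, pos)
        if ok:
            return [type(s)(protein_id=placed[k][0], position=placed[k][1],
                            wt=s.wt, change=s.change)
                    for k, s in enumerate(dataset)]
    raise InputError("surface-biased shuffle could not satisfy the class "
                     "histogram after bounded retries")


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher's exact p for a 2×2 table of non-negative integers.

    The p-value sums hypergeometric probabilities of all tables with the same
    margins whose probability does not exceed the observed table's.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 2) or (table < 0).any():
        raise InputError("table must be 2x2 with non-negative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise InputError("Fisher test undefined for a zero margin")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


@dataclass
class EnrichmentResult:
    interaction_type: str
    real_count: int
    dataset_size: int
    shuffled_counts: list
    table: np.ndarray
    p_value: float
    spec: ShuffleSpec | None = None


def enrichment_test(dataset, in_class, sequences: dict, spec: ShuffleSpec,
                    classes: dict | None = None,
                    interaction_type: str = "protein") -> EnrichmentResult:
    """Real-vs-shuffled overlap with an interface class.

    ``in_class`` is a predicate on (protein id, position) marking sites of the
    interaction class under test.  All shuffle replicates are pooled into the
    shuffled column of the 2×2 table; per-replicate counts are retained.
    """
    if not dataset:
        raise InputError("enrichment test requires a non-empty dataset")
    rng = np.random.default_rng(spec.seed)
    real = sum(1 for s in dataset if in_class(s.protein_id, s.position))
    shuffled_counts = []
    for _ in range(spec.replicates):
        shuf = shuffle_sites(dataset, sequences, spec, classes=classes, rng=rng)
        shuffled_counts.append(
            sum(1 for s in shuf if in_class(s.protein_id, s.position)))
    n = len(dataset)
    pooled = int(sum(shuffled_counts))
    pooled_n = n * spec.replicates
    table = np.array([[real, n - real], [pooled, pooled_n - pooled]])
    p = fisher_exact_two_sided(table)
    return EnrichmentResult(interaction_type=interaction_type, real_count=real,
                            dataset_size=n, shuffled_counts=shuffled_counts,
                            table=table, p_value=p, spec=spec)


def direction_roc(records, positive_labels=frozenset({"disabling", "enabling"}),
                  score_mode: str = "abs"):
    """ROC for predicting annotated interaction effects from IE scores.

    ``records`` carry an ``effect`` label (disabling/enabling/neutral) and a
    predicted ``ie``.  Scores are |IE| by default (``score_mode='signed'``
    evaluates a single direction with the raw value).  Returns (fpr, tpr,
    thresholds, auc).
    """
    labels, scores = [], []
    for r in records:
        labels.append(1 if r.effect in positive_labels else 0)
        scores.append(abs(r.ie) if score_mode == "abs" else r.ie)
    labels = np.asarray(labels)
    if labels.all() or not labels.any():
        raise InputError("direction ROC requires both classes present")
    fpr, tpr, thr = _skm.roc_curve(labels, np.asarray(scores, dtype=float))
    return fpr, tpr, thr, float(_skm.auc(fpr, tpr))


def combine_scores(per_method: dict) -> tuple[dict, list]:
    """Normalized-average combination of per-mutation scores across methods.

    Each method is min–max normalized to [0, 1] over the dataset, then scores
    are averaged per mutation over the methods reporting it.  A method with
    constant scores contributes 0.5 everywhere and is flagged.  Returns
    (combined scores, flagged methods).
    """
    if not per_method:
        raise InputError("at least one method required")
    flagged = []
    normalized: dict = {}
    for method, scores in per_method.items():
        vals = np.array(list(scores.values()), dtype=float)
        lo, hi = vals.min(), vals.max()
        if hi == lo:
            flagged.append(method)
            normalized[method] = {k: 0.5 for k in scores}
        else:
            normalized[method] = {k: (v - lo) / (hi - lo)
                                  for k, v in scores.items()}
    combined: dict = {}
    keys = sorted({k for scores in per_method.values() for k in scores})
    for k in keys:
        vals = [normalized[m][k] for m in per_method if k in per_method[m]]
        combined[k] = float(np.mean(vals))
    return combined, flagged
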