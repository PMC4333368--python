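import numpy as np
import pytest

from edgetic.enrichment import (ShuffleSpec, accessibility_class,
                                combine_scores, direction_roc,
                                enrichment_test, fisher_exact_two_sided,
                                relative_accessibility, shrake_rupley_area,
                                shuffle_sites)
from edgetic.errors import InputError
from edgetic.io import DirectionBenchmarkRecord
from edgetic.pipeline import SiteChange

from .conftest import make_fragment, make_residue
from .oracles import auc_by_pair_counting, fisher_two_sided_enumeration

AA = list("ACDEFGHIKLMNPQRSTVWY")


def _random_proteins(n_prot=8, length=150, seed=0):
    rng = np.random.default_rng(seed)
    return {f"p{i}": "".join(rng.choice(AA, length)) for i in range(n_prot)}


def _backbone(x, with_cb=True):
    atoms = [("N", "N", (x - 0.8, 0, 0)), ("CA", "C", (x, 0, 0)),
             ("C", "C", (x + 0.8, 0, 0)), ("O", "O", (x + 0.8, -1.2, 0))]
    if with_cb:
        atoms.append(("CB", "C", (x, 1.5, 0)))
    return atoms


# ---------------------------------------------------------------- accessibility

def test_extended_tripeptide_centre_is_exposed():
    frag = make_fragment("f", [
        make_residue("A", i + 1, "ALA", "A", _backbone(3.8 * i))
        for i in range(5)])
    value = relative_accessibility(frag, 3)
    assert value >= 80.0


def test_enclosed_residue_is_buried():
    # target residue 2 with benign sequence neighbours; an occluding shell
    # placed as a distant (non-flanking) residue so the reference state is open
    n = 400
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    th = np.pi * (1 + 5 ** 0.5) * k
    centre = np.array([3.8, 0.5, 0.0])
    shell = [("X", "C", centre + 4.5 * np.array([np.sin(p) * np.cos(t),
                                                 np.sin(p) * np.sin(t),
                                                 np.cos(p)]))
             for p, t in zip(phi, th)]
    frag = make_fragment("f", [
        make_residue("A", 1, "GLY", "G", [("CA", "C", (60.0, 0, 0))]),
        make_residue("A", 2, "ALA", "A", _backbone(3.8)),
        make_residue("A", 3, "GLY", "G", [("CA", "C", (70.0, 0, 0))]),
        make_residue("A", 4, "UNK", "UNKNOWN", shell),
    ])
    value = relative_accessibility(frag, 2)
    assert value is not None and value < 5.0


def test_accessibility_converges_with_sampling_density():
    """Low-sample result agrees with a high-sample oracle of the same model."""
    frag = make_fragment("f", [
        make_residue("A", i + 1, "ALA", "A", _backbone(3.8 * i))
        for i in range(4)])
    coarse = relative_accessibility(frag, 2, n_points=128)
    fine = relative_accessibility(frag, 2, n_points=2048)
    assert coarse == pytest.approx(fine, abs=3.0)


def test_sphere_area_of_isolated_atom():
    # isolated carbon: expanded-sphere area 4*pi*(1.7+1.4)^2
    area = shrake_rupley_area(np.zeros((1, 3)), np.array([1.7]))
    assert area[0] == pytest.approx(4 * np.pi * 3.1 ** 2, rel=1e-6)


def test_missing_residue_is_no3d():
    frag = make_fragment("f", [make_residue("A", 1, "ALA", "A", [])])
    assert relative_accessibility(frag, 1) is None
    assert accessibility_class(None) == "no3D"


@pytest.mark.parametrize("value,expected", [
    (0.0, "buried"), (5.0, "buried"), (5.01, "intermediate"),
    (25.0, "intermediate"), (25.01, "exposed"), (100.0, "exposed"),
])
def test_accessibility_class_boundaries(value, expected):
    assert accessibility_class(value) == expected


def test_negative_accessibility_rejected():
    with pytest.raises(InputError):
        accessibility_class(-1.0)


# -------------------------------------------------------------------- shuffles

def test_shuffle_preserves_wt_and_avoids_origin():
    sequences = _random_proteins(seed=1)
    rng = np.random.default_rng(2)
    sites = []
    for _ in range(300):
        pid = f"p{rng.integers(8)}"
        pos = int(rng.integers(1, 151))
        sites.append(SiteChange(pid, pos, sequences[pid][pos - 1], "A"))
    for mode in ("positions", "proteins-and-positions"):
        spec = ShuffleSpec(mode=mode, seed=7)
        shuffled = shuffle_sites(sites, sequences, spec)
        assert len(shuffled) == len(sites)
        for orig, new in zip(sites, shuffled):
            assert new.wt == orig.wt
            assert sequences[new.protein_id][new.position - 1] == new.wt
            assert (new.protein_id, new.position) != \
                (orig.protein_id, orig.position)
            if mode == "positions":
                assert new.protein_id == orig.protein_id


def test_shuffle_single_legal_destination_is_deterministic():
    sequences = {"p": "RAAR"}
    site = SiteChange("p", 1, "R", "C")
    for seed in range(5):
        out = shuffle_sites([site], sequences, ShuffleSpec(seed=seed))
        assert out[0].position == 4
    with pytest.raises(InputError, match="no legal"):
        shuffle_sites([SiteChange("p", 2, "A", "G")],
                      {"p": "RACR"}, ShuffleSpec(seed=0))


def test_surface_biased_shuffle_preserves_class_histogram():
    sequences = _random_proteins(seed=3)
    rng = np.random.default_rng(4)
    classes = {}
    for pid, seq in sequences.items():
        for pos in range(1, len(seq) + 1):
            classes[(pid, pos)] = ("buried", "intermediate", "exposed",
                                   "no3D")[rng.integers(4)]
    sites = []
    for _ in range(200):
        pid = f"p{rng.integers(8)}"
        pos = int(rng.integers(1, 151))
        sites.append(SiteChange(pid, pos, sequences[pid][pos - 1], "A"))
    spec = ShuffleSpec(mode="positions", surface_biased=True, seed=11)
    shuffled = shuffle_sites(sites, sequences, spec, classes=classes)

    def histogram(ss):
        h = {}
        for s in ss:
            c = classes[(s.protein_id, s.position)]
            h[c] = h.get(c, 0) + 1
        return h

    assert histogram(shuffled) == histogram(sites)


def test_shuffle_seeded_reruns_identical():
    sequences = _random_proteins(seed=5)
    sites = [SiteChange("p0", i, sequences["p0"][i - 1], "A")
             for i in range(1, 51)]
    spec = ShuffleSpec(seed=42)
    a = shuffle_sites(sites, sequences, spec)
    b = shuffle_sites(sites, sequences, spec)
    assert a == b


# ---------------------------------------------------------------------- fisher

def test_fisher_matches_enumeration_on_named_tables():
    assert fisher_exact_two_sided([[0, 5], [5, 0]]) == \
        pytest.approx(2 / 252, rel=1e-9)
    assert fisher_exact_two_sided([[1, 1], [1, 1]]) == pytest.approx(1.0)
    assert fisher_exact_two_sided([[10, 10], [10, 10]]) == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(4))
def test_fisher_matches_enumeration_random_tables(seed):
    rng = np.random.default_rng(seed)
    for _ in range(60):
        table = rng.integers(0, 50, size=(2, 2))
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            continue
        assert fisher_exact_two_sided(table) == \
            pytest.approx(fisher_two_sided_enumeration(table), rel=1e-7)


def test_fisher_zero_margin_rejected():
    with pytest.raises(InputError):
        fisher_exact_two_sided([[0, 0], [1, 2]])


# ------------------------------------------------------------------ enrichment

def _enrichment_setup(seed):
    sequences = _random_proteins(n_prot=10, length=200, seed=seed)
    iface = {pid: set(range(1, 41)) for pid in sequences}
    members = {(p, pos) for p, ss in iface.items() for pos in ss}
    return sequences, iface, members


def test_planted_enrichment_is_significant():
    from edgetic.fixtures import generate_change_set
    sequences, iface, members = _enrichment_setup(0)
    changes = generate_change_set(sequences, iface, bias=1.0, n=200, seed=1)
    res = enrichment_test(changes, lambda p, q: (p, q) in members, sequences,
                          ShuffleSpec(seed=1, replicates=10))
    assert res.p_value < 1e-3
    assert res.real_count == 200
    assert res.table.sum() == 200 + 200 * 10


def test_enrichment_empty_dataset_rejected():
    with pytest.raises(InputError):
        enrichment_test([], lambda p, q: True, {"p": "AA"}, ShuffleSpec(seed=0))


# ------------------------------------------------------------------------- ROC

def test_direction_roc_separable():
    records = [DirectionBenchmarkRecord("p", i, "A", "V", "x", "disabling",
                                        ie=-2.0 - i) for i in range(10)] + \
              [DirectionBenchmarkRecord("p", i, "A", "V", "x", "neutral",
                                        ie=0.1) for i in range(10)]
    _, _, _, auc = direction_roc(records)
    assert auc == 1.0


def test_direction_roc_matches_pair_counting_oracle():
    rng = np.random.default_rng(12)
    records = []
    labels, scores = [], []
    for i in range(200):
        effect = ("disabling", "enabling", "neutral")[rng.integers(3)]
        ie = float(rng.normal())
        records.append(DirectionBenchmarkRecord("p", i, "A", "V", "x",
                                                effect, ie=ie))
        labels.append(1 if effect != "neutral" else 0)
        scores.append(abs(ie))
    _, _, _, auc = direction_roc(records)
    assert auc == pytest.approx(auc_by_pair_counting(labels, scores), abs=1e-12)


def test_direction_roc_single_class_rejected():
    records = [DirectionBenchmarkRecord("p", 1, "A", "V", "x", "neutral")]
    with pytest.raises(InputError):
        direction_roc(records)


def test_label_permutation_auc_near_half():
    rng = np.random.default_rng(99)
    aucs = []
    for _ in range(50):
        records = [DirectionBenchmarkRecord(
            "p", i, "A", "V", "x",
            "disabling" if rng.random() < 0.5 else "neutral",
            ie=float(rng.normal())) for i in range(400)]
        try:
            aucs.append(direction_roc(records)[3])
        except InputError:
            continue
    assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)


# --------------------------------------------------------------- combine_scores

def test_combine_scores_examples():
    combined, flagged = combine_scores({
        "m1": {"a": 0.0, "b": 10.0},
        "m2": {"a": 5.0, "b": 5.0},
    })
    assert combined == {"a": 0.25, "b": 0.75}
    assert flagged == ["m2"]
    one, flagged = combine_scores({"m": {"a": 1.0, "b": 3.0, "c": 2.0}})
    assert one == {"a": 0.0, "b": 1.0, "c": 0.5} and not flagged


def test_combine_scores_preserves_shared_ranking():
    s1 = {"a": 1.0, "b": 2.0, "c": 5.0}
    s2 = {"a": 10.0, "b": 30.0, "c": 80.0}
    combined, _ = combine_scores({"m1": s1, "m2": s2})
    assert combined["a"] < combined["b"] < combined["c"]
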