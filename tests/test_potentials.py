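import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edgetic.contacts import define_interfaces, representatives
from edgetic.errors import DerivationError, InputError
from edgetic.fixtures import ComplexSpec, generate_model
from edgetic.potentials import (ChemicalClassMap, derive_ipp, ie_change,
                                load_reference_matrix, protein_impact_score,
                                site_impact_score)
from edgetic.structures import ALPHABET

from .oracles import brute_force_ipp


@pytest.fixture(scope="module")
def reference_matrix():
    return load_reference_matrix()


@pytest.fixture(scope="module")
def half_a_half_v():
    """Interface composition 1/2 A, 1/2 V; all meaningful contacts A-A.

    A-A pairs sit at vdw distance; V-V pairs in the 4.5-5.0 band register
    generically but not as meaningful contacts.
    """
    seq = "".join("A" if i % 2 == 0 else "V" for i in range(40))
    pairs = tuple((i, 4.0 if i % 2 == 1 else 4.9) for i in range(1, 41))
    model = generate_model(ComplexSpec(seed=13, residues_per_chain=40,
                                       sequences=(seq, seq),
                                       contact_pairs=pairs, noise_sigma=0.0))
    return define_interfaces(model)


def test_half_a_half_v_gives_ln4(half_a_half_v):
    matrix, freq = derive_ipp(half_a_half_v, pseudocount=0.0)
    assert freq.residue_fractions["A"] == pytest.approx(0.5)
    assert freq.residue_fractions["V"] == pytest.approx(0.5)
    assert matrix.ipp("A", "A") == pytest.approx(math.log(4), abs=1e-9)


def test_ipp_zero_when_obs_equals_exp():
    """Two symbols contacting at their background rates: all IPP = 0."""
    # 1/2 A, 1/2 V with contact counts proportional to f_exp:
    # A-A : A-V : V-A : V-V = 1 : 1 : 1 : 1 over ordered pairs.
    seq_a = "AVAV" * 10
    seq_b = "AAVV" * 10
    # pairs (i,i): states (A,A),(V,A),(A,V),(V,V) repeating -> equal counts
    pairs = tuple((i, 4.0) for i in range(1, 41))
    model = generate_model(ComplexSpec(seed=17, residues_per_chain=40,
                                       sequences=(seq_a, seq_b),
                                       contact_pairs=pairs, noise_sigma=0.0))
    matrix, freq = derive_ipp(define_interfaces(model), pseudocount=0.0)
    for a in ("A", "V"):
        for b in ("A", "V"):
            assert matrix.ipp(a, b) == pytest.approx(0.0, abs=1e-9)
            assert ie_change(a, b, ["A", "V"], matrix) == pytest.approx(0.0)


@pytest.mark.parametrize("seed", [21, 22, 23])
def test_derivation_matches_counting_oracle(seed):
    rng = np.random.default_rng(seed)
    pairs = tuple((i, float(rng.uniform(3.5, 5.0))) for i in range(1, 33))
    model = generate_model(ComplexSpec(seed=seed, residues_per_chain=40,
                                       contact_pairs=pairs))
    ifaces = representatives(define_interfaces(model))
    for kappa in (0.0, 1.0):
        matrix, _ = derive_ipp(ifaces, pseudocount=kappa)
        want = brute_force_ipp(ifaces, pseudocount=kappa)
        for (a, b), value in want.items():
            assert matrix.ipp(a, b) == pytest.approx(value, abs=1e-12)
        # symmetry of the residue-residue block
        block = matrix.values.loc[list(ALPHABET), list(ALPHABET)].to_numpy(float)
        assert np.array_equal(np.isnan(block), np.isnan(block.T))
        finite = np.isfinite(block)
        assert np.allclose(block[finite], block.T[finite])


def test_derivation_order_invariance(half_a_half_v):
    m1, _ = derive_ipp(half_a_half_v, pseudocount=1.0)
    m2, _ = derive_ipp(list(reversed(half_a_half_v)), pseudocount=1.0)
    a = m1.values.to_numpy(float)
    b = m2.values.to_numpy(float)
    assert np.allclose(a[np.isfinite(a)], b[np.isfinite(b)])


def test_empty_interface_set_rejected():
    with pytest.raises(DerivationError):
        derive_ipp([])


def test_chemical_class_usability():
    """A metal contacting one residue type strongly is usable; a class whose
    contact profile mirrors the background is flagged unusable."""
    seq20 = "ACDEFGHIKLMNPQRSTVWY"
    model = generate_model(ComplexSpec(
        seed=31, residues_per_chain=20,
        sequences=(seq20, seq20),
        ligands=(("ZN", "ZN", 2, 3.0),)))  # anchored at the lone Cys
    ifaces = [i for i in define_interfaces(model)
              if i.interface_type == "protein-chemical"]
    matrix, _ = derive_ipp(ifaces, pseudocount=0.0)
    # only Cys contacts Zn while Cys is 1/20 of the background: ln 20 > 1
    assert matrix.ipp("C", "Zn") == pytest.approx(math.log(20), abs=1e-9)
    assert matrix.is_usable("Zn")

    # all-background contacts: every residue of a uniform-composition protein
    # touches the class equally -> |IPP| = 0 < 1 -> unusable
    seq = "ACDEFGHIKLMNPQRSTVWY" * 2
    lig = tuple(("MG", "MG", i, 3.0) for i in range(1, 41)
                if seq[i - 1] != "G")
    model2 = generate_model(ComplexSpec(seed=33, residues_per_chain=40,
                                        sequences=(seq, seq), ligands=lig,
                                        noise_sigma=0.0))
    ifaces2 = [i for i in define_interfaces(model2)
               if i.interface_type == "protein-chemical"]
    matrix2, _ = derive_ipp(ifaces2, pseudocount=0.0)
    assert not matrix2.is_usable("Mg")
    # an unusable class contributes nothing to IE
    assert ie_change("A", "W", ["Mg"], matrix2) == 0.0


def test_worked_examples_from_reference_matrix(reference_matrix):
    assert ie_change("D", "L", ["F", "F"], reference_matrix) == \
        pytest.approx(2.4, abs=0.1)
    assert ie_change("R", "C", ["E", "E"], reference_matrix) == \
        pytest.approx(-3.8, abs=0.1)


def test_ie_change_basics(reference_matrix):
    assert ie_change("D", "D", ["F", "F"], reference_matrix) == 0.0
    assert ie_change("D", "L", [], reference_matrix) == 0.0
    with pytest.raises(InputError):
        ie_change("B", "L", ["F"], reference_matrix)
    with pytest.raises(InputError):
        ie_change("D", "L", ["not-a-partner"], reference_matrix)


@settings(deadline=None, max_examples=60)
@given(st.sampled_from(ALPHABET), st.sampled_from(ALPHABET),
       st.lists(st.sampled_from(ALPHABET + ("DNA/RNA", "Zn")), max_size=8))
def test_ie_antisymmetry_and_additivity(wt, change, partners):
    matrix = load_reference_matrix()
    fwd = ie_change(wt, change, partners, matrix)
    assert fwd == pytest.approx(-ie_change(change, wt, partners, matrix))
    half = len(partners) // 2
    assert fwd == pytest.approx(
        ie_change(wt, change, partners[:half], matrix)
        + ie_change(wt, change, partners[half:], matrix))


def test_reference_matrix_shape_and_symmetry(reference_matrix):
    assert set(reference_matrix.alphabet) == set(ALPHABET)
    block = reference_matrix.values.loc[list(ALPHABET), list(ALPHABET)]
    assert np.allclose(block.to_numpy(float), block.to_numpy(float).T)
    assert set(reference_matrix.partner_classes) == \
        {"DNA/RNA", "Zn", "Mg", "Fe", "Mn", "Cu"}
    display = reference_matrix.display_values()
    assert display.abs().max().max() <= 9


def test_site_score_rules():
    per_type = {"protein": [2.4, -3.8], "dna/rna": [1.0]}
    assert site_impact_score(per_type, {"protein", "dna/rna"}) == \
        pytest.approx(6.8)
    assert site_impact_score({}, set()) == 0.0
    # a hit type with only incalculable IE values contributes exactly 1
    assert site_impact_score({"chemical": [None]}, {"chemical"}) == 1.0


def test_protein_score_is_sum():
    assert protein_impact_score([6.8, 1.0]) == pytest.approx(7.8)
    assert protein_impact_score([]) == 0.0
    assert protein_impact_score([2.0]) == 2.0


def test_matrix_tsv_roundtrip(tmp_path, reference_matrix):
    path = tmp_path / "matrix.tsv"
    reference_matrix.to_tsv(path)
    from edgetic.potentials import PairPotentialMatrix
    loaded = PairPotentialMatrix.from_tsv(path)
    a = reference_matrix.values.to_numpy(float)
    b = loaded.values.to_numpy(float)
    assert np.allclose(a[np.isfinite(a)], b[np.isfinite(b)])
    assert loaded.usable == {c: True for c in reference_matrix.partner_classes}


def test_chemical_class_map_total():
    cmap = ChemicalClassMap()
    assert cmap.lookup("ZN") == "Zn"
    assert cmap.lookup("weird") == "Organic"
    cmap2 = ChemicalClassMap(mapping={"XYZ": "Drug"})
    assert cmap2.lookup("xyz") == "Drug"
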