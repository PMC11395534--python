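"""Centered/averaged Broto-Moreau autocorrelations and the descriptor pool."""
import numpy as np
import pytest

from pyrimqsar import aatsc, atsc, model_descriptors, pair_count, parse_smiles
from pyrimqsar.autocorr import (
    DescriptorConfig,
    DescriptorVector,
    MODEL_DESCRIPTOR_NAMES,
    descriptor_pool,
)

HEAVY = DescriptorConfig(include_hydrogens=False)


def test_hand_values_three_atom_path():
    mol = parse_smiles("CCC")
    w = np.array([1.0, 2.0, 3.0])
    assert atsc(mol, 1, "e", HEAVY, weights=w) == pytest.approx(0.0, abs=1e-10)
    assert atsc(mol, 2, "e", HEAVY, weights=w) == pytest.approx(-1.0, abs=1e-10)
    assert aatsc(mol, 2, "e", HEAVY, weights=w) == pytest.approx(-1.0, abs=1e-10)


def test_hand_values_two_atom():
    mol = parse_smiles("CC")
    assert atsc(mol, 1, "e", HEAVY, weights=np.array([1.0, 3.0])) == pytest.approx(
        -1.0, abs=1e-10
    )


def test_constant_weights_vanish():
    mol = parse_smiles("CCOCC")
    for k in range(1, 5):
        assert atsc(mol, k, "e", HEAVY, weights=np.ones(mol.n_atoms)) == 0.0


def test_benzene_pair_counts():
    benzene = parse_smiles("c1ccccc1")
    assert pair_count(benzene, 1, HEAVY) == 6
    assert pair_count(benzene, 3, HEAVY) == 3
    # Sum over k >= 1 of Delta_k partitions all heavy-atom pairs
    for smi in ("c1ccccc1", "CCOC", "ClCCCc1cnc(Cl)nc1Cl"):
        mol = parse_smiles(smi)
        a = mol.n_atoms
        assert sum(pair_count(mol, k, HEAVY) for k in range(1, a)) == a * (a - 1) // 2


def test_benzene_homoatomic_zero():
    benzene = parse_smiles("c1ccccc1")
    assert aatsc(benzene, 2, "s", HEAVY) == pytest.approx(0.0, abs=1e-12)
    assert atsc(benzene, 3, "e", HEAVY) == pytest.approx(0.0, abs=1e-12)


def test_aatsc_is_atsc_over_pairs(blind_compounds):
    for mol in blind_compounds.values():
        for scheme in "scep":
            for k in range(1, 7):
                n = pair_count(mol, k)
                if n:
                    assert aatsc(mol, k, scheme) == pytest.approx(
                        atsc(mol, k, scheme) / n, abs=1e-12
                    )
                else:
                    assert aatsc(mol, k, scheme) == 0.0


def test_brute_force_oracle(blind_compounds):
    """atsc equals a double loop over the heavy-atom distance matrix."""
    from pyrimqsar import distance_matrix
    from pyrimqsar.atomprops import atom_weighting

    for mol in blind_compounds.values():
        d = distance_matrix(mol)
        for scheme in "ep":
            w = atom_weighting(mol, scheme).values
            c = w - w.mean()
            for k in (1, 2, 3, 4):
                ref = sum(
                    c[i] * c[j]
                    for i in range(mol.n_atoms)
                    for j in range(i + 1, mol.n_atoms)
                    if d[i, j] == k
                )
                assert atsc(mol, k, scheme, HEAVY) == pytest.approx(ref, abs=1e-10)


def test_homogeneity():
    """Scaling weights by c scales ATSC by c^2."""
    mol = parse_smiles("CCNCO")
    w = np.array([0.3, -1.2, 0.8, 2.0, -0.5])
    for k in (1, 2, 3):
        assert atsc(mol, k, "e", HEAVY, weights=3.0 * w) == pytest.approx(
            9.0 * atsc(mol, k, "e", HEAVY, weights=w), abs=1e-10
        )


def test_ordered_pairs_convention():
    mol = parse_smiles("CCOC")
    ordered = DescriptorConfig(include_hydrogens=True, ordered_pairs=True)
    default = DescriptorConfig()
    for k in (1, 2, 3):
        assert atsc(mol, k, "e", ordered) == pytest.approx(2.0 * atsc(mol, k, "e", default))
        # AATSC is convention-independent: Delta_k doubles too
        assert aatsc(mol, k, "e", ordered) == pytest.approx(aatsc(mol, k, "e", default))
        assert pair_count(mol, k, ordered) == 2 * pair_count(mol, k, default)


def test_hydrogen_inclusion_changes_values():
    mol = parse_smiles("CCO")
    with_h = DescriptorConfig(include_hydrogens=True)
    assert atsc(mol, 1, "e", with_h) != pytest.approx(atsc(mol, 1, "e", HEAVY))
    assert pair_count(mol, 1, with_h) > pair_count(mol, 1, HEAVY)


def test_lag_validation():
    mol = parse_smiles("CC")
    with pytest.raises(ValueError):
        atsc(mol, 0, "e")
    with pytest.raises(ValueError):
        aatsc(mol, -1, "e")
    with pytest.raises(ValueError):
        pair_count(mol, -1)
    assert atsc(mol, 99, "e") == 0.0  # no pair at lag 99
    assert aatsc(mol, 99, "e") == 0.0


def test_model_descriptors_shape(blind_compounds):
    vec = model_descriptors(blind_compounds["cpd41"])
    assert vec.names == list(MODEL_DESCRIPTOR_NAMES)
    assert np.all(np.isfinite(vec.values))
    assert vec["MDEN-23"] >= 0.0
    no_n = model_descriptors(parse_smiles("CCOCC"))
    assert no_n["MDEN-23"] == 0.0


def test_descriptor_vector_validation():
    with pytest.raises(ValueError):
        DescriptorVector(["a", "a"], np.array([1.0, 2.0]))
    with pytest.raises(ValueError):
        DescriptorVector(["a"], np.array([np.nan]))


def test_descriptor_pool_consistency(blind_compounds):
    mols = list(blind_compounds.values())
    pool = descriptor_pool(mols, max_lag=4)
    assert list(pool.index) == [m.name for m in mols]
    mol = mols[1]
    row = pool.loc[mol.name]
    assert row["ATSC3e"] == pytest.approx(atsc(mol, 3, "e"), abs=1e-12)
    assert row["AATSC2s"] == pytest.approx(aatsc(mol, 2, "s"), abs=1e-12)
    assert {f"MDEN-{s}{t}" for s in (1, 2, 3) for t in range(s, 4)} <= set(pool.columns)
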