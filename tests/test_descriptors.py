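"""CTD and ligand descriptor correctness against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from deeplip.descriptors import (AMINO_ACIDS, CTD_GROUPINGS,
                                 PropertyGrouping, ctd_composition,
                                 ctd_distribution, ctd_transition,
                                 descriptor_registry, ligand_descriptors,
                                 pocket_ctd)
from deeplip.errors import AlphabetError, SequenceLengthError
from deeplip.structure_io import Bond, Ligand, LigandAtom

HYDRO = CTD_GROUPINGS[0]  # hydrophobicity


# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------

def oracle_composition(seq, grouping):
    out = []
    for g in grouping.groups:
        out.append(100.0 * sum(c in g for c in seq) / len(seq))
    return np.array(out)


def oracle_transition(seq, grouping):
    cls = [next(k for k, g in enumerate(grouping.groups) if c in g)
           for c in seq]
    out = []
    for a, b in ((0, 1), (0, 2), (1, 2)):
        count = sum(1 for x, y in zip(cls, cls[1:])
                    if {x, y} == {a, b})
        out.append(100.0 * count / (len(seq) - 1))
    return np.array(out)


def oracle_distribution(seq, grouping):
    import math

    n = len(seq)
    out = []
    for g in grouping.groups:
        positions = [k + 1 for k, c in enumerate(seq) if c in g]
        if not positions:
            out.extend([0.0] * 5)
            continue
        ng = len(positions)
        picks = [positions[0]] + [
            positions[max(1, math.ceil(q * ng / 4)) - 1] for q in (1, 2, 3, 4)]
        out.extend(100.0 * p / n for p in picks)
    return np.array(out)


def random_sequences(n, rng, min_len=2, max_len=200):
    for _ in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        yield "".join(rng.choice(list(AMINO_ACIDS), size=length))


# ---------------------------------------------------------------------------
# CTD
# ---------------------------------------------------------------------------

def test_groupings_partition_the_alphabet():
    assert len(CTD_GROUPINGS) == 7
    for grouping in CTD_GROUPINGS:
        joined = "".join(grouping.groups)
        assert sorted(joined) == sorted(AMINO_ACIDS)


def test_bad_grouping_rejected():
    with pytest.raises(ValueError):
        # C appears twice and W is missing: not a partition
        PropertyGrouping("broken", ("AC", "CDE", "FGHIKLMNPQRSTVY"))


def test_composition_examples():
    assert np.allclose(ctd_composition("AAA", HYDRO), [0, 100, 0])
    assert np.allclose(ctd_composition("AR", HYDRO), [50, 50, 0])


def test_transition_examples():
    assert np.allclose(ctd_transition("AR", HYDRO), [100, 0, 0])
    assert np.allclose(ctd_transition("AAAA", HYDRO), [0, 0, 0])


def test_distribution_examples():
    d = ctd_distribution("RA", HYDRO)
    assert np.allclose(d[0:5], [50] * 5)     # polar class: R at position 1/2
    assert np.allclose(d[5:10], [100] * 5)   # neutral class: A at position 2/2
    assert np.allclose(d[10:15], [0] * 5)    # hydrophobic absent
    d = ctd_distribution("RRRR", HYDRO)
    assert np.allclose(d[0:5], [25, 25, 50, 75, 100])


def test_ctd_errors():
    with pytest.raises(SequenceLengthError):
        ctd_composition("", HYDRO)
    with pytest.raises(SequenceLengthError):
        ctd_transition("A", HYDRO)
    with pytest.raises(AlphabetError):
        ctd_composition("AXB", HYDRO)


def test_ctd_blocks_match_brute_force_oracles(rng):
    for seq in random_sequences(100, rng):
        for grouping in CTD_GROUPINGS:
            c = ctd_composition(seq, grouping)
            assert np.allclose(c, oracle_composition(seq, grouping))
            assert abs(c.sum() - 100.0) < 1e-9
            t = ctd_transition(seq, grouping)
            assert np.allclose(t, oracle_transition(seq, grouping))
            assert np.all((t >= 0) & (t <= 100))
            # transition is invariant under sequence reversal
            assert np.allclose(t, ctd_transition(seq[::-1], grouping))
            d = ctd_distribution(seq, grouping)
            assert np.allclose(d, oracle_distribution(seq, grouping))
            for g in range(3):
                block = d[5 * g:5 * g + 5]
                assert np.all(np.diff(block) >= -1e-12)
                assert np.all(block <= 100.0)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.text(alphabet=AMINO_ACIDS, min_size=2, max_size=300))
def test_ctd_invariants_hold_for_arbitrary_sequences(seq):
    """Composition sums to 100; transitions bounded; distributions
    monotone per class; full vector always 147-long."""
    for grouping in CTD_GROUPINGS:
        c = ctd_composition(seq, grouping)
        assert abs(c.sum() - 100.0) < 1e-9
        assert np.all((c >= 0) & (c <= 100))
        t = ctd_transition(seq, grouping)
        assert np.all((t >= 0) & (t <= 100))
        d = ctd_distribution(seq, grouping)
        for g in range(3):
            block = d[5 * g:5 * g + 5]
            assert np.all(np.diff(block) >= -1e-12)
            assert np.all((block >= 0) & (block <= 100))
    assert len(pocket_ctd(seq)) == 147


def test_pocket_ctd_length_and_block_layout():
    vec = pocket_ctd("AR")
    assert len(vec) == 147
    first = np.concatenate([ctd_composition("AR", HYDRO),
                            ctd_transition("AR", HYDRO),
                            ctd_distribution("AR", HYDRO)])
    assert np.allclose(vec.values[:21], first)
    # deterministic
    assert np.array_equal(vec.values, pocket_ctd("AR").values)


# ---------------------------------------------------------------------------
# ligand descriptors
# ---------------------------------------------------------------------------

def _methane_like():
    return Ligand([LigandAtom("C", np.zeros(3))], [], name="methane-like")


def _benzene_like():
    atoms = []
    for k in range(6):
        ang = np.pi * k / 3
        atoms.append(LigandAtom("C", 1.39 * np.array(
            [np.cos(ang), np.sin(ang), 0.0])))
    bonds = [Bond(k, (k + 1) % 6, "aromatic") for k in range(6)]
    return Ligand(atoms, bonds, name="benzene-like")


def test_registry_frozen_and_sized():
    names, version = descriptor_registry()
    assert len(names) == 196
    assert len(set(names)) == 196
    assert descriptor_registry()[0] == names
    assert version


def test_ligand_vector_length_and_counts():
    vec = ligand_descriptors(_methane_like())
    assert len(vec) == 196
    assert vec.as_dict()["HeavyAtomCount"] == 1.0
    assert np.all(np.isfinite(vec.values))


def test_full_registry_computable_on_benzene_like():
    vec = ligand_descriptors(_benzene_like())
    assert len(vec) == 196
    assert np.all(np.isfinite(vec.values))
    assert vec.as_dict()["RingCount"] == 1.0


def test_molecular_weight_matches_hand_sum(small_dataset):
    samples, _, _ = small_dataset
    lig = samples[0].ligand
    masses = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "H": 1.008}
    hand = sum(masses[a.element] for a in lig.atoms)
    vec = ligand_descriptors(lig)
    # HeavyAtomMolWt ignores implicit hydrogens entirely
    assert vec.as_dict()["HeavyAtomMolWt"] == pytest.approx(hand, rel=1e-3)


def test_ligand_descriptors_invariant_to_atom_order(small_dataset):
    samples, _, _ = small_dataset
    lig = samples[1].ligand
    n = len(lig.atoms)
    rng = np.random.default_rng(0)
    perm = rng.permutation(n)
    inv = np.argsort(perm)
    atoms = [lig.atoms[p] for p in perm]
    bonds = [Bond(int(inv[b.i]), int(inv[b.j]), b.order) for b in lig.bonds]
    shuffled = Ligand(atoms, bonds, name=lig.name)
    v1 = ligand_descriptors(lig).values
    v2 = ligand_descriptors(shuffled).values
    assert np.allclose(v1, v2, atol=1e-8)
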