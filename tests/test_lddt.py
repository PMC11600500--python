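"""Superposition-free lDDT against an independent brute-force oracle."""

import numpy as np
import pytest

from rnaqa.lddt import (
    NoContactsError,
    StructureMismatchError,
    THRESHOLDS,
    global_lddt,
    per_nucleotide_lddt,
    reference_pairs,
)
from rnaqa.structure_io import Atom, Nucleotide, RNAStructure
from rnaqa.synthetic import make_native, perturb
from conftest import random_rotation, toy_structure


def brute_force_lddt(model, native, radius=15.0):
    """O(n^2 atoms^2) reference implementation: enumerate every heavy-atom
    pair across different nucleotides within the radius and count threshold
    preservation. Returns (per_nucleotide with NaN, global)."""
    atoms_n = [(i, name, a.coords) for i, nt in enumerate(native.nucleotides)
               for name, a in nt.atoms.items()]
    atoms_m = {(i, name): a.coords for i, nt in enumerate(model.nucleotides)
               for name, a in nt.atoms.items()}
    L = native.L
    totals, counts = np.zeros(L), np.zeros(L)
    frac_sum, n_pairs = 0.0, 0
    for a in range(len(atoms_n)):
        for b in range(a + 1, len(atoms_n)):
            ri, ni, xi = atoms_n[a]
            rj, nj, xj = atoms_n[b]
            if ri == rj:
                continue
            d_ref = np.linalg.norm(xi - xj)
            if d_ref >= radius:
                continue
            mi, mj = atoms_m.get((ri, ni)), atoms_m.get((rj, nj))
            if mi is None or mj is None:
                frac = 0.0
            else:
                dev = abs(np.linalg.norm(mi - mj) - d_ref)
                frac = sum(dev < t for t in THRESHOLDS) / len(THRESHOLDS)
            totals[ri] += frac
            counts[ri] += 1
            totals[rj] += frac
            counts[rj] += 1
            frac_sum += frac
            n_pairs += 1
    per = np.full(L, np.nan)
    per[counts > 0] = totals[counts > 0] / counts[counts > 0]
    return per, (frac_sum / n_pairs if n_pairs else np.nan)


def _single_atom_pairs(d):
    nts = [Nucleotide(1, "A", {"P": Atom("P", np.zeros(3))}),
           Nucleotide(2, "C", {"P": Atom("P", np.array([d, 0.0, 0.0]))})]
    return RNAStructure("pairtoy", "A", nts)


def test_reference_pairs_radius():
    assert reference_pairs(_single_atom_pairs(100.0)) == []
    pairs = reference_pairs(_single_atom_pairs(5.0))
    assert len(pairs) == 1
    assert pairs[0].d_ref == pytest.approx(5.0)
    assert (pairs[0].res_i, pairs[0].res_j) == (1, 2)


def test_reference_pairs_match_brute_force():
    rng = np.random.default_rng(0)
    s = toy_structure(rng, 10)
    atoms = [(i, name, a.coords) for i, nt in enumerate(s.nucleotides)
             for name, a in nt.atoms.items()]
    expected = set()
    for a in range(len(atoms)):
        for b in range(a + 1, len(atoms)):
            ri, ni, xi = atoms[a]
            rj, nj, xj = atoms[b]
            if ri == rj or np.linalg.norm(xi - xj) >= 15.0:
                continue
            if ri > rj:
                (ri, ni, xi), (rj, nj, xj) = (rj, nj, xj), (ri, ni, xi)
            expected.add((ri + 1, rj + 1, ni, nj, round(np.linalg.norm(xi - xj), 9)))
    got = {(p.res_i, p.res_j, p.name_i, p.name_j, round(p.d_ref, 9))
           for p in reference_pairs(s)}
    assert got == expected


def test_self_comparison_is_exactly_one(helix20):
    scores = per_nucleotide_lddt(helix20, helix20)
    assert np.all(scores.per_nucleotide[scores.defined] == 1.0)
    assert global_lddt(helix20, helix20) == 1.0


def test_hand_computed_single_pair_case():
    """One reference pair, d_ref = 5.0, model distance 6.5: deviation 1.5 is
    inside the 2 A and 4 A tolerances only, so the score is exactly 0.5."""
    native = _single_atom_pairs(5.0)
    model = _single_atom_pairs(6.5)
    scores = per_nucleotide_lddt(model, native)
    np.testing.assert_array_equal(scores.per_nucleotide, [0.5, 0.5])
    assert global_lddt(model, native) == 0.5


def test_rigid_motion_invariance_is_exact(helix20):
    rng = np.random.default_rng(1)
    decoy = perturb(helix20, "gaussian", 1.0, seed=2)
    base = global_lddt(decoy, helix20)
    for _ in range(3):
        Q, b = random_rotation(rng), rng.normal(size=3) * 40
        assert global_lddt(decoy.transformed(Q, b), helix20) == base
        assert global_lddt(decoy, helix20.transformed(Q, b)) == base


def test_matches_brute_force_oracle_on_random_toys():
    rng = np.random.default_rng(42)
    for trial in range(50):
        L = int(rng.integers(2, 11))
        native = toy_structure(rng, L, atoms_per_nt=int(rng.integers(2, 5)))
        model = toy_structure(rng, L, atoms_per_nt=5)
        # align atom names/codes with native so matching is positional
        model = RNAStructure(model.id, "A", [
            Nucleotide(nt.index, native.nucleotides[i].code,
                       {n: model.nucleotides[i].atoms[n]
                        for n in model.nucleotides[i].atoms})
            for i, nt in enumerate(model.nucleotides)])
        per_exp, glob_exp = brute_force_lddt(model, native)
        scores = per_nucleotide_lddt(model, native)
        np.testing.assert_allclose(scores.per_nucleotide[scores.defined],
                                   per_exp[~np.isnan(per_exp)], atol=1e-12)
        np.testing.assert_array_equal(scores.defined, ~np.isnan(per_exp))
        if not np.isnan(glob_exp):
            assert global_lddt(model, native) == pytest.approx(glob_exp, abs=1e-12)


def test_missing_model_atoms_count_as_unpreserved(helix20):
    stripped = RNAStructure("stripped", "A", [
        Nucleotide(nt.index, nt.code,
                   {n: a for n, a in nt.atoms.items() if n != "P"})
        for nt in helix20.nucleotides])
    full = global_lddt(helix20, helix20)
    partial = global_lddt(stripped, helix20)
    assert partial < full == 1.0


def test_isolated_nucleotide_is_masked_not_zero():
    nts = [Nucleotide(1, "A", {"P": Atom("P", np.zeros(3))}),
           Nucleotide(2, "C", {"P": Atom("P", np.array([5.0, 0, 0]))}),
           Nucleotide(3, "G", {"P": Atom("P", np.array([500.0, 0, 0]))})]
    native = RNAStructure("iso", "A", nts)
    scores = per_nucleotide_lddt(native, native)
    assert list(scores.defined) == [True, True, False]
    assert np.isnan(scores.per_nucleotide[2])


def test_length_and_code_mismatch_raise(helix20, coil16):
    with pytest.raises(StructureMismatchError):
        global_lddt(coil16, helix20)
    swapped = RNAStructure("sw", "A", [
        Nucleotide(nt.index, "U" if nt.code == "A" else "A", dict(nt.atoms))
        for nt in helix20.nucleotides])
    with pytest.raises(StructureMismatchError):
        global_lddt(swapped, helix20)


def test_no_contacts_error():
    nts = [Nucleotide(1, "A", {"P": Atom("P", np.zeros(3))}),
           Nucleotide(2, "C", {"P": Atom("P", np.array([500.0, 0, 0]))})]
    s = RNAStructure("far", "A", nts)
    with pytest.raises(NoContactsError):
        global_lddt(s, s)


def test_monotone_degradation_in_noise(helix20):
    amps = [0.0, 0.5, 1.0, 2.0, 4.0, 8.0]
    means = []
    for amp in amps:
        vals = [global_lddt(perturb(helix20, "gaussian", amp, seed=s), helix20)
                for s in range(5)]
        means.append(np.mean(vals))
    assert all(a >= b - 1e-9 for a, b in zip(means, means[1:]))
    assert means[0] == 1.0
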