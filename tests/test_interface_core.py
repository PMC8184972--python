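"""Interface assignment, contact counting, iRMSD / f_Nal and de-duplication."""

import numpy as np
import pytest

from piscore.interface_core import (assign_interface, compute_fnal,
                                    compute_irmsd, count_contact_pairs,
                                    deduplicate_interfaces,
                                    enumerate_interfaces, interface_similarity,
                                    superpose)
from piscore.structure_io import Atom, Chain, Residue, Structure, apply_rigid_transform

from conftest import make_c3_trimer


def strand_structure(n_a, n_b, separation, spacing=3.8):
    """Two parallel CA-only strands with known pairwise geometry."""

    def strand(cid, n, x):
        residues = [Residue("ALA", i + 1, cid,
                            [Atom("CA", "C", [x, 0.0, i * spacing])])
                    for i in range(n)]
        return Chain(cid, residues)

    return Structure(id="strands", chains=[strand("A", n_a, 0.0),
                                           strand("B", n_b, separation)])


class TestAssignInterface:
    def test_no_interface_beyond_cutoff(self):
        s = strand_structure(12, 12, separation=9.0)
        assert assign_interface(s, "A", "B") is None

    def test_matches_brute_force_on_random_ca_clouds(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            xa = rng.uniform(0, 25, size=(30, 3))
            xb = rng.uniform(0, 25, size=(30, 3))
            s = Structure(id="r", chains=[
                Chain("A", [Residue("ALA", i + 1, "A", [Atom("CA", "C", x)])
                            for i, x in enumerate(xa)]),
                Chain("B", [Residue("ALA", i + 1, "B", [Atom("CA", "C", x)])
                            for i, x in enumerate(xb)])])
            iface = assign_interface(s, "A", "B", cutoff=7.0, min_residues=1)
            d = np.linalg.norm(xa[:, None] - xb[None], axis=2)
            expect_a = {("A", i + 1, "") for i in np.flatnonzero((d <= 7.0).any(axis=1))}
            expect_b = {("B", j + 1, "") for j in np.flatnonzero((d <= 7.0).any(axis=0))}
            if not expect_a or not expect_b:
                assert iface is None
            else:
                assert iface.residues_a == expect_a
                assert iface.residues_b == expect_b

    def test_below_minimum_size_interface_not_scored(self):
        # 9 residues on one side and 8 on the other: excluded from scoring
        s = strand_structure(9, 8, separation=5.0)
        assert assign_interface(s, "A", "B", min_residues=10) is None
        assert assign_interface(s, "A", "B", min_residues=8) is not None

    def test_symmetry_swaps_sides_only(self, toy_complex):
        ab = assign_interface(toy_complex, "A", "B")
        ba = assign_interface(toy_complex, "B", "A")
        assert ab.residues_a == ba.residues_b
        assert ab.residues_b == ba.residues_a


class TestEnumerate:
    def test_trimer_has_three_interfaces(self):
        s = make_c3_trimer()
        interfaces = enumerate_interfaces(s)
        assert len(interfaces) == 3
        assert [(i.chain_a, i.chain_b) for i in interfaces] == \
            [("A", "B"), ("A", "C"), ("B", "C")]

    def test_distant_third_chain_excluded(self, toy_complex):
        far = apply_rigid_transform(toy_complex.chain("B"), np.eye(3),
                                    np.array([200.0, 0, 0]))
        far_renamed = Chain("C", [Residue(r.name, r.seq_id, "C", r.atoms)
                                  for r in far.residues])
        s = Structure(id="dimer+1", chains=list(toy_complex.chains) + [far_renamed])
        interfaces = enumerate_interfaces(s)
        assert [(i.chain_a, i.chain_b) for i in interfaces] == [("A", "B")]

    def test_single_chain_warns_and_returns_empty(self, toy_complex):
        s = Structure(id="mono", chains=[toy_complex.chain("A")])
        with pytest.warns(UserWarning):
            assert enumerate_interfaces(s) == []


class TestContacts:
    def test_counts_match_brute_force_on_random_fixtures(self, toy_complex):
        rng = np.random.default_rng(7)
        iface = assign_interface(toy_complex, "A", "B")
        for cutoff in (3.5, 4.5, 6.0):
            n = count_contact_pairs(iface, toy_complex, heavy_cutoff=cutoff)
            # independent O(n^2) enumeration
            atoms_a = [(a, r) for key in iface.residues_a
                       for r in [toy_complex.residue(key)] for a in r.heavy_atoms()]
            atoms_b = [(a, r) for key in iface.residues_b
                       for r in [toy_complex.residue(key)] for a in r.heavy_atoms()]
            brute = sum(1 for aa, _ in atoms_a for bb, _ in atoms_b
                        if np.linalg.norm(aa.coord - bb.coord) <= cutoff)
            assert n == brute
        del rng

    def test_single_engineered_contact(self):
        s = strand_structure(12, 12, separation=6.5)
        iface = assign_interface(s, "A", "B", min_residues=1)
        # CA-CA 6.5 A apart: no heavy-atom contact at 4.5, all 144 pairs at 7
        assert count_contact_pairs(iface, s, heavy_cutoff=4.5) == 0
        assert count_contact_pairs(iface, s, heavy_cutoff=6.6) > 0


class TestSuperpose:
    def test_identical_sets_give_zero_rmsd_identity_rotation(self):
        x = np.random.default_rng(0).uniform(0, 10, (6, 3))
        tr = superpose(x, x)
        assert tr.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-9)

    def test_recovers_known_transform(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(-5, 5, (10, 3))
        from scipy.spatial.transform import Rotation
        R = Rotation.random(random_state=3).as_matrix()
        t = np.array([1.0, -2.0, 3.0])
        y = x @ R.T + t
        tr = superpose(x, y)
        assert tr.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(tr.rotation, R, atol=1e-8)

    def test_agrees_with_independent_implementation(self):
        # scipy's align_vectors is an independent Kabsch implementation
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(2)
        a = rng.uniform(-5, 5, (4, 3))
        b = a.copy()
        b[0] += [1.0, 0.5, -0.3]
        tr = superpose(a, b)
        rot, rssd = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
        assert tr.rmsd == pytest.approx(rssd / np.sqrt(len(a)), abs=1e-4)

    def test_degenerate_inputs_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(ValueError, match="collinear|degenerate"):
            superpose(line, line + 1.0)
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestIrmsdFnal:
    def test_identical_model_scores_zero_and_one(self, toy_complex, toy_interface):
        assert compute_irmsd(toy_complex, toy_complex, toy_interface) == \
            pytest.approx(0.0, abs=1e-9)
        assert compute_fnal(toy_interface, toy_interface) == 1.0

    def test_irmsd_invariant_under_global_rigid_transform(self, toy_complex,
                                                          toy_interface):
        from scipy.spatial.transform import Rotation
        R = Rotation.random(random_state=5).as_matrix()
        t = np.array([4.0, -7.0, 2.0])
        moved = Structure(id="moved", chains=[
            apply_rigid_transform(c, R, t) for c in toy_complex.chains])
        assert compute_irmsd(moved, toy_complex, toy_interface) == \
            pytest.approx(0.0, abs=1e-6)

    def test_displaced_residue_matches_independent_rmsd(self):
        from scipy.spatial.transform import Rotation
        s = strand_structure(10, 10, separation=6.0)
        iface = assign_interface(s, "A", "B", min_residues=1)
        model = strand_structure(10, 10, separation=6.0)
        model.chain("A").residues[0].atoms[0].coord = \
            model.chain("A").residues[0].atoms[0].coord + np.array([2.0, 0, 0])
        val = compute_irmsd(model, s, iface)
        nat = np.array([s.residue(k).ca.coord for k in sorted(iface.residues)])
        mod = np.array([model.residue(k).ca.coord for k in sorted(iface.residues)])
        _, rssd = Rotation.align_vectors(nat - nat.mean(0), mod - mod.mean(0))
        assert val == pytest.approx(rssd / np.sqrt(len(nat)), abs=1e-4)

    def test_fnal_counts_recovered_native_residues(self):
        native = strand_structure(10, 10, separation=6.0)
        nat_iface = assign_interface(native, "A", "B", min_residues=1)
        assert len(nat_iface.residues) == 20
        # slide chain B along the strand by 5 residues: half the native
        # interface residues of B fall out, A residues still within cutoff
        model = strand_structure(10, 10, separation=6.0)
        moved = apply_rigid_transform(model.chain("B"), np.eye(3),
                                      np.array([0.0, 0.0, 5 * 3.8]))
        model = Structure(id="slid", chains=[model.chain("A"), moved])
        mod_iface = assign_interface(model, "A", "B", min_residues=1)
        fnal = compute_fnal(mod_iface, nat_iface)
        expect = len(nat_iface.residues & mod_iface.residues) / len(nat_iface.residues)
        assert fnal == pytest.approx(expect)
        assert 0.0 < fnal < 1.0

    def test_disjoint_interfaces_score_zero(self):
        native = strand_structure(20, 20, separation=6.0)
        nat = assign_interface(native, "A", "B", min_residues=1)
        fake = type(nat)(chain_a="A", chain_b="B",
                         residues_a={("A", 100 + i, "") for i in range(5)},
                         residues_b={("B", 100 + i, "") for i in range(5)},
                         cutoff_used=7.0)
        assert compute_fnal(fake, nat) == 0.0


class TestSimilarityDedup:
    def test_self_similarity_is_one(self, toy_complex, toy_interface):
        assert interface_similarity(toy_interface, toy_interface,
                                    toy_complex) == pytest.approx(1.0)

    def test_c3_copies_are_similar_and_deduplicated(self):
        s = make_c3_trimer()
        interfaces = enumerate_interfaces(s)
        assert len(interfaces) == 3
        sim = interface_similarity(interfaces[0], interfaces[1], s)
        assert sim >= 0.7
        kept = deduplicate_interfaces(interfaces, s, threshold=0.7)
        assert len(kept) == 1

    def test_unrelated_folds_dissimilar(self, toy_complex):
        helix_iface = assign_interface(toy_complex, "A", "B")
        lattice = strand_structure(25, 25, separation=6.0, spacing=6.0)
        lat_iface = assign_interface(lattice, "A", "B", min_residues=1)
        sim = interface_similarity(helix_iface, lat_iface, toy_complex, lattice)
        assert sim < 0.3

    def test_dedup_keeps_dissimilar_and_handles_empty(self, toy_complex):
        assert deduplicate_interfaces([], toy_complex) == []
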