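"""Residue-class fractions, H-bonds, salt bridges, solvation, p-value,
conservation and the assembled 12-feature vector."""

import numpy as np
import pytest

from piscore.interface_core import Interface, assign_interface
from piscore.physchem_features import (FEATURE_NAMES, ConservationTable,
                                       FeatureError, HBondCriteria,
                                       SaltBridgeCriteria, SolvationParams,
                                       _SasaBundle, compute_feature_vector,
                                       conserved_interface_count,
                                       count_hydrogen_bonds,
                                       count_salt_bridges, hydrophobic_pvalue,
                                       interface_solvation_energy,
                                       residue_class_fractions)
from piscore.structure_io import Atom, Chain, Residue, Structure, apply_rigid_transform
from piscore.surface_geometry import RadiiSet, sasa


def pair_structure(residues_a, residues_b):
    return Structure(id="pair", chains=[Chain("A", residues_a),
                                        Chain("B", residues_b)])


def simple_interface(structure):
    ra = {r.key for r in structure.chain("A").residues}
    rb = {r.key for r in structure.chain("B").residues}
    return Interface(chain_a="A", chain_b="B", residues_a=ra, residues_b=rb,
                     cutoff_used=7.0)


def residue(name, seq, chain, atoms):
    return Residue(name, seq, chain, [Atom(n, e, c) for n, e, c in atoms])


class TestClassFractions:
    def test_hand_counted_fractions(self):
        names_a = ["ASP", "GLU", "LYS", "ARG", "SER"]  # 4 charged, 1 polar
        names_b = ["GLY", "GLY", "ALA", "LEU", "PRO"]  # 2 hydrophobic
        res_a = [residue(n, i + 1, "A", [("CA", "C", [0, 0, i * 3.8])])
                 for i, n in enumerate(names_a)]
        res_b = [residue(n, i + 1, "B", [("CA", "C", [5, 0, i * 3.8])])
                 for i, n in enumerate(names_b)]
        s = pair_structure(res_a, res_b)
        charged, polar, hydrophobic = residue_class_fractions(simple_interface(s), s)
        assert charged == pytest.approx(0.4)
        assert polar == pytest.approx(0.1)
        assert hydrophobic == pytest.approx(0.2)
        assert charged + polar + hydrophobic <= 1.0

    def test_all_glycine_interface_scores_zero(self):
        res_a = [residue("GLY", i + 1, "A", [("CA", "C", [0, 0, i * 3.8])])
                 for i in range(4)]
        res_b = [residue("GLY", i + 1, "B", [("CA", "C", [5, 0, i * 3.8])])
                 for i in range(4)]
        s = pair_structure(res_a, res_b)
        assert residue_class_fractions(simple_interface(s), s) == (0.0, 0.0, 0.0)


class TestHydrogenBonds:
    def _fixture(self, d):
        res_a = [residue("ALA", 1, "A",
                         [("N", "N", [0, 0, 0]), ("CA", "C", [1.2, 0.8, 0]),
                          ("C", "C", [2.4, 0, 0]), ("O", "O", [2.6, -1.2, 0])])]
        res_b = [residue("ALA", 1, "B",
                         [("N", "N", [d, 0, 0]), ("CA", "C", [d + 1.2, 0.8, 0]),
                          ("C", "C", [d + 2.4, 0, 0]), ("O", "O", [d - 2.9, 0, 0])])]
        # place B's O so that A's N ... B's O distance = d - 2.9
        return pair_structure(res_a, res_b)

    def test_backbone_pair_within_criterion_counts_once(self):
        s = self._fixture(5.8)  # A:N to B:O at 2.9 A
        n = count_hydrogen_bonds(simple_interface(s), s)
        assert n >= 1

    def test_pair_beyond_criterion_not_counted(self):
        res_a = [residue("ALA", 1, "A", [("N", "N", [0, 0, 0])])]
        res_b = [residue("ALA", 1, "B", [("O", "O", [5.0, 0, 0])])]
        s = pair_structure(res_a, res_b)
        assert count_hydrogen_bonds(simple_interface(s), s) == 0

    def test_count_matches_brute_force_and_tightening_monotone(self, toy_complex):
        iface = assign_interface(toy_complex, "A", "B")
        loose = count_hydrogen_bonds(iface, toy_complex, HBondCriteria(max_distance=4.0))
        default = count_hydrogen_bonds(iface, toy_complex)
        tight = count_hydrogen_bonds(iface, toy_complex, HBondCriteria(max_distance=2.5))
        assert tight <= default <= loose

        # independent enumeration at the default criterion
        crit = HBondCriteria()
        brute = 0
        for keys_d, keys_a in ((iface.residues_a, iface.residues_b),
                               (iface.residues_b, iface.residues_a)):
            for kd in keys_d:
                for ka in keys_a:
                    rd, ra = toy_complex.residue(kd), toy_complex.residue(ka)
                    for don in crit.donor_atoms(rd):
                        for acc in crit.acceptor_atoms(ra):
                            if np.linalg.norm(don.coord - acc.coord) <= 3.5:
                                brute += 1
        assert default == brute


class TestSaltBridges:
    def test_lys_glu_pair_counts(self):
        res_a = [residue("LYS", 1, "A", [("NZ", "N", [0, 0, 0])])]
        res_b = [residue("GLU", 1, "B", [("OE1", "O", [3.2, 0, 0])])]
        s = pair_structure(res_a, res_b)
        assert count_salt_bridges(simple_interface(s), s) == 1

    def test_like_charges_do_not_count(self):
        res_a = [residue("LYS", 1, "A", [("NZ", "N", [0, 0, 0])])]
        res_b = [residue("LYS", 1, "B", [("NZ", "N", [3.2, 0, 0])])]
        s = pair_structure(res_a, res_b)
        assert count_salt_bridges(simple_interface(s), s) == 0

    def test_bidentate_arginine_counts_once_per_residue_pair(self):
        res_a = [residue("ARG", 1, "A", [("NH1", "N", [0, 0, 0]),
                                         ("NH2", "N", [0, 2.0, 0]),
                                         ("NE", "N", [-1.0, 1.0, 0])])]
        res_b = [residue("ASP", 1, "B", [("OD1", "O", [3.0, 0, 0]),
                                         ("OD2", "O", [3.0, 2.0, 0])])]
        s = pair_structure(res_a, res_b)
        assert count_salt_bridges(simple_interface(s), s) == 1


class TestSolvationEnergy:
    def test_separated_chains_have_zero_energy(self, toy_complex):
        far_b = apply_rigid_transform(toy_complex.chain("B"), np.eye(3),
                                      np.array([100.0, 0, 0]))
        s = Structure(id="far", chains=[toy_complex.chain("A"), far_b])
        assert abs(interface_solvation_energy(s, "A", "B")) < 0.01

    def test_equals_direct_sigma_weighted_delta_asa(self, toy_complex):
        value = interface_solvation_energy(toy_complex, "A", "B")
        # independent route through public sasa calls
        radii = RadiiSet()
        params = SolvationParams()
        ca, cb = toy_complex.chain("A"), toy_complex.chain("B")
        pair = Structure(id="p", chains=[ca, cb])
        asa_pair = sasa(pair, radii)
        asa_iso = np.concatenate([sasa(ca, radii), sasa(cb, radii)])
        atoms = [(a, r) for c in (ca, cb) for r in c.residues
                 for a in r.heavy_atoms()]
        expect = sum(params.sigma_for(r.name, a) * d for (a, r), d
                     in zip(atoms, asa_pair - asa_iso)) / 1000.0
        assert value == pytest.approx(expect, abs=1e-9)
        assert value < 0  # burying the toy interface is favourable

    def test_single_buried_carbon_formula(self):
        # sigma_C = 16 cal/mol/A^2; delta ASA of -10 A^2 -> -0.16 kcal/mol
        params = SolvationParams()
        assert params.sigma["C"] * (-10.0) / 1000.0 == pytest.approx(-0.16)


class TestHydrophobicPValue:
    def test_deterministic_under_seed(self, toy_complex, toy_interface):
        p1 = hydrophobic_pvalue(toy_complex, toy_interface, n_samples=200, seed=3)
        p2 = hydrophobic_pvalue(toy_complex, toy_interface, n_samples=200, seed=3)
        assert p1 == p2
        assert 1 / 201 <= p1 <= 1.0

    def test_patch_drawn_interfaces_give_uniformish_p(self):
        from piscore.synthetic_decoys import ToyComplexSpec, make_toy_complex
        s = make_toy_complex(ToyComplexSpec(seed=6, n_residues=40))
        pvals = _patch_null_pvalues(s, n_interfaces=40, patch_size=12,
                                    n_samples=200, seed=0)
        assert 0.35 < np.mean(pvals) < 0.65

    def test_most_hydrophobic_patch_is_significant(self):
        from piscore.synthetic_decoys import ToyComplexSpec, make_toy_complex
        from piscore.physchem_features import _surface_residue_energies
        s = make_toy_complex(ToyComplexSpec(seed=6, n_residues=40))
        radii, params = RadiiSet(), SolvationParams()
        bundle = _SasaBundle.compute(s, "A", "B", radii, 960)
        keys, gains, cas = _surface_residue_energies(s, "A", "B", params,
                                                     radii, 960, bundle=bundle)
        # engineer the interface as the most hydrophobic connected patch:
        # grow greedily from the most hydrophobic residue
        from scipy.spatial import cKDTree
        tree = cKDTree(cas)
        adj = tree.query_ball_point(cas, r=10.0)
        start = int(np.argmin(gains))
        patch = {start}
        while len(patch) < 12:
            frontier = {j for i in patch for j in adj[i]} - patch
            patch.add(min(frontier, key=lambda j: gains[j]))
        patch_keys = {keys[i] for i in patch}
        iface = Interface(chain_a="A", chain_b="B",
                          residues_a={k for k in patch_keys if k[0] == "A"} or
                          {keys[start]},
                          residues_b={k for k in patch_keys if k[0] == "B"},
                          cutoff_used=7.0)
        p = hydrophobic_pvalue(s, iface, n_samples=400, seed=1,
                               _bundle=bundle)
        assert p <= 0.05


def _patch_null_pvalues(structure, n_interfaces, patch_size, n_samples, seed):
    """p-values of interfaces drawn by the same random-patch procedure."""
    from scipy.spatial import cKDTree
    from piscore.physchem_features import _grow_patch, _surface_residue_energies
    radii, params = RadiiSet(), SolvationParams()
    bundle = _SasaBundle.compute(structure, "A", "B", radii, 960)
    keys, gains, cas = _surface_residue_energies(structure, "A", "B", params,
                                                 radii, 960, bundle=bundle)
    tree = cKDTree(cas)
    adjacency = [sorted(set(nb) - {i}) for i, nb
                 in enumerate(tree.query_ball_point(cas, r=10.0))]
    rng = np.random.default_rng(seed)
    pvals = []
    for k in range(n_interfaces):
        patch = _grow_patch(rng, adjacency, len(keys), patch_size)
        patch_keys = {keys[i] for i in patch}
        iface = Interface(chain_a="A", chain_b="B",
                          residues_a={x for x in patch_keys if x[0] == "A"},
                          residues_b={x for x in patch_keys if x[0] == "B"},
                          cutoff_used=7.0)
        pvals.append(hydrophobic_pvalue(structure, iface, n_samples=n_samples,
                                        seed=seed + 1000 + k, _bundle=bundle))
    return np.array(pvals)


class TestConservation:
    def test_hand_built_table_counts_top_quartile(self):
        # chain A has 8 scored residues; scores 1..8, top-25% = scores 1,2
        scores = {("A", i + 1): float(i + 1) for i in range(8)}
        table = ConservationTable(scores=scores, conserved_cutoff=0.25)
        iface = Interface(chain_a="A", chain_b="B",
                          residues_a={("A", 1, ""), ("A", 2, ""), ("A", 5, "")},
                          residues_b=set(), cutoff_used=7.0)
        count, imputed = conserved_interface_count(iface, table)
        assert (count, imputed) == (2, False)

    def test_uniform_scores_tie_rule(self):
        scores = {("A", i + 1): 1.0 for i in range(12)}
        table = ConservationTable(scores=scores, conserved_cutoff=0.25)
        iface = Interface(chain_a="A", chain_b="B",
                          residues_a={("A", i + 1, "") for i in range(8)},
                          residues_b=set(), cutoff_used=7.0)
        count, imputed = conserved_interface_count(iface, table)
        assert count == round(0.25 * 8)
        assert not imputed

    def test_missing_table_imputes_and_flags(self, toy_interface):
        count, imputed = conserved_interface_count(toy_interface, None)
        assert imputed
        assert count == round(0.25 * len(toy_interface.residues))

    def test_from_file_roundtrip(self, tmp_path):
        path = tmp_path / "cons.tsv"
        path.write_text("# chain seq score\nA 1 -0.5\nA 2 0.3\nB 1 0.1\n")
        table = ConservationTable.from_file(path)
        assert table.scores[("A", 1)] == -0.5
        assert len(table.scores) == 3


class TestFeatureVector:
    def test_twelve_finite_fields_on_toy(self, toy_complex, toy_interface):
        vec = compute_feature_vector(toy_complex, toy_interface,
                                     pvalue_samples=100)
        arr = vec.as_array()
        assert arr.shape == (12,)
        assert np.all(np.isfinite(arr))
        assert len(FEATURE_NAMES) == 12
        assert vec.num_intf_residues == len(toy_interface.residues)

    def test_no_interface_rejected_with_named_feature(self, toy_complex):
        with pytest.raises(FeatureError, match="num_intf_residues"):
            compute_feature_vector(toy_complex, None)

    def test_separated_chains_rejected(self, toy_complex, toy_interface):
        far_b = apply_rigid_transform(toy_complex.chain("B"), np.eye(3),
                                      np.array([80.0, 0, 0]))
        s = Structure(id="far", chains=[toy_complex.chain("A"), far_b])
        with pytest.raises(FeatureError, match="sc"):
            compute_feature_vector(s, toy_interface)

    def test_deterministic_given_seed(self, toy_complex, toy_interface):
        v1 = compute_feature_vector(toy_complex, toy_interface,
                                    pvalue_samples=100, seed=9)
        v2 = compute_feature_vector(toy_complex, toy_interface,
                                    pvalue_samples=100, seed=9)
        assert np.array_equal(v1.as_array(), v2.as_array())
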