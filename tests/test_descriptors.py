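"""Topological descriptors against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest

from qsartox.descriptors import (
    UndefinedIndexError,
    atom_and_group_counts,
    balaban_index,
    chi_index,
    compute_descriptor_block,
    estate_indices,
    flexibility_phi,
    hbond_counts,
    kappa_indices,
    molecular_weight,
    path_count,
    randic_index,
    wiener_index,
)
from qsartox.graph import Atom, MolecularGraph, MoleculeError, parse_smiles

from oracles import chi_oracle, path_count_oracle, wiener_oracle


class TestMolecularWeight:
    @pytest.mark.parametrize(
        "smiles, expected",
        [("c1ccccc1", 78.11), ("C", 16.04), ("CC", 30.07), ("Oc1ccccc1", 94.11)],
    )
    def test_standard_masses(self, smiles, expected):
        assert molecular_weight(parse_smiles(smiles)) == pytest.approx(
            expected, abs=0.01
        )


class TestWiener:
    @pytest.mark.parametrize(
        "name, expected",
        [("ethane", 1), ("n-butane", 10), ("cyclopropane", 3)],
    )
    def test_known_values(self, molecules, name, expected):
        assert wiener_index(molecules[name]) == expected

    def test_equals_all_pairs_shortest_path_oracle(self, molecules):
        for name, g in molecules.items():
            assert wiener_index(g) == wiener_oracle(g), name

    def test_disconnected_rejected(self):
        g = MolecularGraph(atoms=(Atom("C", 4), Atom("C", 4)), bonds=())
        with pytest.raises(MoleculeError):
            wiener_index(g)


class TestRandic:
    def test_ethane(self, molecules):
        assert randic_index(molecules["ethane"]) == pytest.approx(1.0)

    def test_butane_closed_form(self, molecules):
        expected = 2 / math.sqrt(2) + 0.5
        assert randic_index(molecules["n-butane"]) == pytest.approx(expected)

    def test_isobutane_closed_form(self, molecules):
        assert randic_index(molecules["isobutane"]) == pytest.approx(3 / math.sqrt(3))

    def test_single_atom_error(self):
        with pytest.raises(UndefinedIndexError):
            randic_index(parse_smiles("C"))

    def test_equals_first_order_chi(self, molecules):
        for name, g in molecules.items():
            if g.n_bonds:
                assert randic_index(g) == pytest.approx(
                    chi_index(g, 1, "path"), abs=1e-12
                ), name


class TestChi:
    def test_butane_second_order_path(self, molecules):
        # two 2-edge paths, each over degrees (1, 2, 2)
        expected = 2 * (1 * 2 * 2) ** -0.5
        assert chi_index(molecules["n-butane"], 2, "path") == pytest.approx(expected)

    def test_butane_has_no_three_edge_cluster(self, molecules):
        assert chi_index(molecules["n-butane"], 3, "cluster") == 0.0

    def test_isobutane_cluster(self, molecules):
        # one star: central degree 3 and three degree-1 leaves
        expected = (1 * 1 * 1 * 3) ** -0.5
        assert chi_index(molecules["isobutane"], 3, "cluster") == pytest.approx(expected)

    @pytest.mark.parametrize("order", [0, 1, 2, 3, 4])
    @pytest.mark.parametrize("kind", ["path", "cluster", "path-cluster"])
    @pytest.mark.parametrize("valence", [False, True])
    def test_matches_exhaustive_enumeration(self, molecules, order, kind, valence):
        for name in ("n-pentane", "neopentane", "toluene", "4-nitroaniline"):
            g = molecules[name]
            assert chi_index(g, order, kind, valence) == pytest.approx(
                chi_oracle(g, order, kind, valence), abs=1e-10
            ), name


class TestKappa:
    def test_butane_kappa1(self, molecules):
        k1, _, _ = kappa_indices(molecules["n-butane"])
        assert k1 == pytest.approx(4.0)

    @pytest.mark.parametrize("A", [3, 5, 8])
    def test_path_graph_kappa1_equals_A(self, A):
        g = parse_smiles("C" * A)
        k1, _, _ = kappa_indices(g)
        assert k1 == pytest.approx(float(A), abs=1e-12)

    def test_alpha_correction_identity_for_sp3_carbon(self, molecules):
        # all-sp3-carbon skeletons have alpha = 0, so kappa_a == kappa
        plain = kappa_indices(molecules["n-butane"])
        corrected = kappa_indices(molecules["n-butane"], alpha_corrected=True)
        assert plain == pytest.approx(corrected)

    def test_path_counts_match_oracle(self, molecules):
        for name, g in molecules.items():
            for length in (1, 2, 3):
                assert path_count(g, length) == path_count_oracle(g, length), (
                    name,
                    length,
                )

    def test_too_few_atoms(self, molecules):
        with pytest.raises(UndefinedIndexError):
            kappa_indices(molecules["ethane"])


class TestFlexibility:
    def test_pentane_identity(self, molecules):
        k1a, k2a, _ = kappa_indices(molecules["n-pentane"], alpha_corrected=True)
        assert flexibility_phi(molecules["n-pentane"]) == pytest.approx(k1a * k2a / 5)

    def test_positive_everywhere(self, molecules):
        for name, g in molecules.items():
            if g.n_atoms >= 3:
                assert flexibility_phi(g) > 0, name

    def test_ring_closure_reduces_flexibility(self, molecules):
        hexane = parse_smiles("CCCCCC")
        assert flexibility_phi(hexane) > flexibility_phi(molecules["cyclohexane"])


class TestBalaban:
    def test_ethane(self, molecules):
        assert balaban_index(molecules["ethane"]) == pytest.approx(1.0)

    def test_butane(self, molecules):
        assert balaban_index(molecules["n-butane"]) == pytest.approx(1.9747, abs=1e-4)

    def test_benzene_literature_value(self, molecules):
        assert balaban_index(molecules["benzene"]) == pytest.approx(2.0, abs=1e-12)


class TestEstate:
    def test_ethane_closed_form(self, molecules):
        # I(CH3) = ((2/2)^2 * (4 - 3) + 1) / 1 = 2; symmetric, no perturbation
        S, total = estate_indices(molecules["ethane"])
        np.testing.assert_allclose(S, [2.0, 2.0])
        assert total == pytest.approx(4.0)

    def test_molecular_sum_equals_intrinsic_sum(self, molecules):
        """Perturbations are antisymmetric, so they cancel in the sum."""
        from qsartox._elements import PRINCIPAL_QUANTUM
        from qsartox.descriptors import valence_deltas

        for name, g in molecules.items():
            deg = np.maximum(g.degrees().astype(float), 1.0)
            dv = valence_deltas(g)
            L = np.array([PRINCIPAL_QUANTUM[a.symbol] for a in g.atoms])
            I = ((2.0 / L) ** 2 * dv + 1.0) / deg
            _, total = estate_indices(g)
            assert total == pytest.approx(I.sum(), abs=1e-10), name

    def test_nitrile_nitrogen_dominates_neighbours(self, molecules):
        g = molecules["benzonitrile"]
        S, _ = estate_indices(g)
        n_idx = next(i for i, a in enumerate(g.atoms) if a.symbol == "N")
        carbons = [S[i] for i, a in enumerate(g.atoms) if a.symbol == "C"]
        assert S[n_idx] > max(carbons)


class TestCounts:
    def test_trichlorophenol(self, molecules):
        c = atom_and_group_counts(molecules["2,4,6-trichlorophenol"])
        assert c["NHal"] == 3
        assert c["NOH"] == 1

    def test_benzene_all_zero(self, molecules):
        c = atom_and_group_counts(molecules["benzene"])
        assert all(v == 0 for v in c.values())

    def test_nitroaniline(self, molecules):
        c = atom_and_group_counts(molecules["4-nitroaniline"])
        assert c["NNO2"] == 1
        assert c["NNH2"] == 1
        assert c["NN"] == 2

    @pytest.mark.parametrize(
        "smiles, key, expected",
        [
            ("CC(=O)OC(C)=O", "Nanh", 1),  # acetic anhydride
            ("CC=O", "NCHO", 1),  # acetaldehyde
            ("CC(O)=O", "NOH", 0),  # acetic acid: carboxyl OH excluded
            ("CC#N", "NCN", 1),  # acetonitrile
            ("CC(C)C", "NCH3", 3),  # isobutane methyls
        ],
    )
    def test_group_matching_rules(self, smiles, key, expected):
        assert atom_and_group_counts(parse_smiles(smiles))[key] == expected


class TestHbond:
    @pytest.mark.parametrize(
        "name, donors, acceptors",
        [
            ("phenol", 1, 1),
            ("aniline", 1, 1),
            ("benzene", 0, 0),
        ],
    )
    def test_convention(self, molecules, name, donors, acceptors):
        assert hbond_counts(molecules[name]) == (donors, acceptors)

    def test_pyridine_nitrogen_accepts(self):
        assert hbond_counts(parse_smiles("c1ccncc1")) == (0, 1)

    def test_pyrrole_nitrogen_does_not_accept(self):
        assert hbond_counts(parse_smiles("c1cc[nH]c1")) == (1, 0)

    def test_amide_nitrogen_does_not_accept(self):
        # acetamide: NH2 donates, carbonyl O accepts, N excluded
        assert hbond_counts(parse_smiles("CC(N)=O")) == (1, 1)


class TestPermutationInvariance:
    def test_descriptor_row_invariant_under_relabelling(self, molecules):
        rng = np.random.default_rng(7)
        for name in ("n-pentane", "toluene", "4-nitroaniline", "cyclohexane"):
            g = molecules[name]
            base = compute_descriptor_block([("m", g)]).drop(columns="compound_id")
            perm = list(rng.permutation(g.n_atoms))
            shuffled = compute_descriptor_block(
                [("m", g.relabelled(perm))]
            ).drop(columns="compound_id")
            np.testing.assert_allclose(
                base.to_numpy(float), shuffled.to_numpy(float), atol=1e-12
            )


class TestDescriptorBlock:
    def test_two_compound_batch(self, molecules):
        df = compute_descriptor_block(
            [("ethane", molecules["ethane"]), ("benzene", molecules["benzene"])]
        )
        assert df.shape[0] == 2
        np.testing.assert_allclose(df["MW"], [30.07, 78.11], atol=0.01)

    def test_empty_batch_errors(self):
        with pytest.raises(MoleculeError):
            compute_descriptor_block([])

    def test_skip_mode_drops_bad_structure(self, molecules, caplog):
        broken = MolecularGraph(atoms=(Atom("C", 4), Atom("C", 4)), bonds=())
        with caplog.at_level("WARNING"):
            df = compute_descriptor_block(
                [("ok", molecules["ethane"]), ("bad", broken)], on_error="skip"
            )
        assert df.shape[0] == 1
        assert "bad" in caplog.text

    def test_abort_mode_names_compound(self, molecules):
        broken = MolecularGraph(atoms=(Atom("C", 4), Atom("C", 4)), bonds=())
        with pytest.raises(MoleculeError, match="bad"):
            compute_descriptor_block(
                [("ok", molecules["ethane"]), ("bad", broken)], on_error="abort"
            )
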