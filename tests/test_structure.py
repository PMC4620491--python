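"""Collective variables and structural observables."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bexfes.structure import (
    ALPHA_SWITCHING,
    COORDINATION_SWITCHING,
    Conformation,
    ConfigurationError,
    SwitchingParams,
    alphabeta_similarity,
    assign_secondary_structure,
    build_backbone,
    coordination_number,
    dihedral,
    phi_psi,
    radius_of_gyration,
    sasa_per_residue,
    ss_segment_count,
    switching,
)
from bexfes.synthetic import make_toy_peptide


class TestSwitching:
    @pytest.mark.parametrize("r,p,expected", [
        (0.0, COORDINATION_SWITCHING, 1.0),
        (0.4, COORDINATION_SWITCHING, 0.5),          # r = r0 → n/m
        (0.2, COORDINATION_SWITCHING, (1 - 0.5**4) / (1 - 0.5**8)),
        (0.1, ALPHA_SWITCHING, 0.5),
    ])
    def test_reference_values(self, r, p, expected):
        assert switching(r, p) == pytest.approx(expected, abs=1e-9)

    @given(st.floats(min_value=0.0, max_value=5.0))
    @settings(max_examples=100, deadline=None)
    def test_bounded_and_monotone(self, r):
        p = COORDINATION_SWITCHING
        v = switching(r, p)
        assert 0.0 < v <= 1.0
        assert switching(r + 0.05, p) <= v + 1e-12

    def test_below_d0_clamps_to_one(self):
        p = SwitchingParams(n=4, m=8, r0=0.4, d0=0.3)
        assert switching(0.1, p) == 1.0

    def test_invalid_exponents_rejected(self):
        with pytest.raises(ConfigurationError):
            SwitchingParams(n=8, m=4, r0=0.4)


class TestCoordination:
    def test_single_pair_at_r0(self):
        # two CB atoms exactly 4 Å (= r0 = 0.4 nm) apart
        res = [
            {"N": [0, 1, 0], "CA": [0, 0, 0], "C": [1, 0, 0], "CB": [0, 0, 1]},
            {"N": [4, 1, 0], "CA": [4, 0, 0], "C": [5, 0, 0], "CB": [4, 0, 1]},
        ]
        conf = Conformation("AA", res)
        assert coordination_number(conf, [1, 2]) == pytest.approx(0.5)

    def test_single_residue_selection_is_zero(self, helix40):
        assert coordination_number(helix40, [5]) == 0.0

    def test_compact_exceeds_extended(self, helix40, strand40):
        sel = range(1, 41)
        assert coordination_number(helix40, sel) > coordination_number(strand40, sel)


class TestSegmentCounts:
    def test_ideal_helix_window_count(self, helix40):
        # 35 windows of 6 residues, each with near-zero RMSD to the template
        assert ss_segment_count(helix40, "alpha") == pytest.approx(35.0, abs=1.0)

    def test_helix_is_not_sheet(self, helix40):
        assert ss_segment_count(helix40, "antibeta") < 1.0
        assert ss_segment_count(helix40, "parabeta") < 1.0

    def test_coil_alpha_low_on_average(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vals = [ss_segment_count(make_toy_peptide(10, "C" * 10, seed=s), "alpha")
                    for s in range(20)]
        assert np.mean(vals) < 0.5

    def test_short_chain_returns_zero(self):
        conf = make_toy_peptide(4, "EEEE", seed=0)
        with pytest.warns(UserWarning):
            assert ss_segment_count(conf, "alpha") == 0.0


class TestAlphaBetaSimilarity:
    @staticmethod
    def _conf_with_chi1(chi_deg):
        # leucine-like residue with CG placed to give the requested chi1
        n = np.array([0.0, 1.4, 0.0])
        ca = np.array([0.0, 0.0, 0.0])
        c = np.array([1.4, -0.5, 0.0])
        cb = np.array([-1.0, -0.8, 0.7])
        # rotate an initial CG about the CA-CB axis until chi1 matches
        axis = (cb - ca) / np.linalg.norm(cb - ca)
        perp = np.cross(axis, n - ca)
        perp /= np.linalg.norm(perp)
        best = None
        for ang in np.arange(0, 360, 0.25):
            cg = cb + 1.53 * (math.cos(math.radians(ang)) * perp
                              + math.sin(math.radians(ang)) * np.cross(axis, perp))
            d = dihedral(n, ca, cb, cg)
            if best is None or abs((d - chi_deg + 180) % 360 - 180) < best[0]:
                best = (abs((d - chi_deg + 180) % 360 - 180), cg)
        res = [{"N": n, "CA": ca, "C": c, "CB": cb, "CG": best[1]},
               {"N": [5, 0, 0], "CA": [6, 0, 0], "C": [7, 0, 0]},
               {"N": [9, 0, 0], "CA": [10, 0, 0], "C": [11, 0, 0]}]
        return Conformation("LGG", res)

    def test_equal_to_reference_counts_residues(self):
        conf = self._conf_with_chi1(60.0)
        ref = {1: dihedral(conf.atom(1, "N"), conf.atom(1, "CA"),
                           conf.atom(1, "CB"), conf.atom(1, "CG"))}
        assert alphabeta_similarity(conf, ref) == pytest.approx(1.0, abs=1e-6)

    def test_antipodal_reference_gives_zero(self):
        conf = self._conf_with_chi1(60.0)
        actual = dihedral(conf.atom(1, "N"), conf.atom(1, "CA"),
                          conf.atom(1, "CB"), conf.atom(1, "CG"))
        assert alphabeta_similarity(conf, {1: actual + 180.0}) == pytest.approx(0.0, abs=1e-6)

    def test_quarter_turn_contributes_half(self):
        conf = self._conf_with_chi1(60.0)
        actual = dihedral(conf.atom(1, "N"), conf.atom(1, "CA"),
                          conf.atom(1, "CB"), conf.atom(1, "CG"))
        assert alphabeta_similarity(conf, {1: actual + 90.0}) == pytest.approx(0.5, abs=1e-6)


class TestSecondaryStructure:
    def test_ideal_helix_interior_is_h(self, helix40):
        labels = assign_secondary_structure(helix40)
        assert all(lab == "H" for lab in labels[1:-1])
        assert labels[0] == "C" and labels[-1] == "C"

    def test_ideal_strand_is_e(self):
        conf = make_toy_peptide(10, "E" * 10, seed=0)
        labels = assign_secondary_structure(conf)
        assert all(lab == "E" for lab in labels[1:-1])

    def test_ppii_box_labelled_p(self):
        conf = build_backbone("A" * 8, [-75.0] * 8, [150.0] * 8)
        labels = assign_secondary_structure(conf)
        assert all(lab == "P" for lab in labels[1:-1])

    def test_two_residue_peptide_all_coil(self):
        res = [{"N": [0, 1, 0], "CA": [0, 0, 0], "C": [1, 0, 0]},
               {"N": [2, 0, 0], "CA": [3, 0, 0], "C": [4, 0, 0]}]
        labels = assign_secondary_structure(Conformation("AA", res))
        assert labels == ["C", "C"]

    def test_labels_partition_residues(self, helix40, coil10):
        for conf in (helix40, coil10):
            labels = assign_secondary_structure(conf)
            assert len(labels) == conf.n_res
            assert set(labels) <= set("HEPC")


class TestSasa:
    def test_isolated_atom_matches_analytic_sphere(self):
        res = [{"N": [0, 0, 0], "CA": [100, 0, 0], "C": [200, 0, 0]}]
        conf = Conformation("A", res)
        areas = sasa_per_residue(conf)
        # three isolated atoms: N (1.55) and two C (1.70), all + 1.4 probe
        expected = 4 * math.pi * ((1.55 + 1.4) ** 2 + 2 * (1.7 + 1.4) ** 2)
        assert areas.sum() == pytest.approx(expected, rel=0.01)

    def test_distant_atoms_unoccluded(self):
        near = Conformation("A", [{"N": [0, 0, 0], "CA": [50, 0, 0], "C": [100, 0, 0]}])
        one = 4 * math.pi * (1.7 + 1.4) ** 2
        assert sasa_per_residue(near).sum() - 4 * math.pi * (1.55 + 1.4) ** 2 \
            == pytest.approx(2 * one, rel=0.01)

    def test_compact_helix_buries_surface(self, helix40, strand40):
        assert sasa_per_residue(helix40).sum() < sasa_per_residue(strand40).sum()

    def test_agrees_with_independent_implementation(self, helix40):
        import biotite.structure as struc

        from bexfes.structure import element_of

        n_atoms = sum(len(r) for r in helix40.residues)
        arr = struc.AtomArray(n_atoms)
        for i, (resi, name, xyz) in enumerate(helix40.atoms()):
            arr.coord[i] = xyz
            arr.res_id[i] = resi
            arr.res_name[i] = "ALA"
            arr.atom_name[i] = name
            arr.element[i] = element_of(name)
            arr.chain_id[i] = "A"
        ref = np.nansum(struc.sasa(arr, probe_radius=1.4, point_number=960,
                                   vdw_radii="Single"))
        assert sasa_per_residue(helix40).sum() == pytest.approx(ref, rel=0.02)

    def test_quadrature_converged(self, helix40):
        a = sasa_per_residue(helix40, n_points=960).sum()
        b = sasa_per_residue(helix40, n_points=1920).sum()
        assert abs(a - b) / b < 0.005


class TestRadiusOfGyration:
    def test_two_point_value(self):
        conf = Conformation("A", [{"N": [0, 0, 0], "CA": [2, 0, 0], "C": [1, 0, 0]}])
        sub = Conformation("A", [{"N": [0, 0, 0], "CA": [2, 0, 0], "C": [1, 0, 0]}])
        # direct formula on the three atoms
        assert radius_of_gyration(sub) == pytest.approx(
            math.sqrt(np.mean([1.0, 1.0, 0.0])))

    def test_rigid_motion_invariance(self, helix40):
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("xyz", [10, 40, 70], degrees=True).as_matrix()
        moved = helix40.transformed(rot, np.array([5.0, -3.0, 2.0]))
        assert radius_of_gyration(moved) == pytest.approx(radius_of_gyration(helix40))
        assert ss_segment_count(moved, "alpha") == pytest.approx(
            ss_segment_count(helix40, "alpha"), abs=1e-6)
        assert coordination_number(moved, range(1, 41)) == pytest.approx(
            coordination_number(helix40, range(1, 41)))

    def test_extended_exceeds_helical(self, helix40, strand40):
        assert radius_of_gyration(strand40) > radius_of_gyration(helix40)


class TestBackboneBuilder:
    def test_requested_dihedrals_are_built(self):
        conf = build_backbone("AAAAA", [-57.0] * 5, [-47.0] * 5)
        phi, psi = phi_psi(conf)
        assert np.allclose(phi[1:], -57.0, atol=1e-6)
        assert np.allclose(psi[:-1], -47.0, atol=1e-6)

    def test_minimal_three_residue_coil(self):
        conf = make_toy_peptide(3, "CCC", seed=0)
        assert conf.n_res == 3

    def test_invalid_ss_code_rejected(self):
        with pytest.raises(ConfigurationError):
            make_toy_peptide(4, "HXHH", seed=0)

    def test_seeds_change_coil_coordinates(self):
        a = make_toy_peptide(10, "C" * 10, seed=1)
        b = make_toy_peptide(10, "C" * 10, seed=2)
        assert a.sequence == b.sequence
        assert not np.allclose(a.coords(), b.coords())

    def test_helix_fraction_of_all_h_build(self, helix40):
        labels = assign_secondary_structure(helix40)
        assert labels.count("H") / len(labels) >= 0.8
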