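import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydrodecomp import geometry
from hydrodecomp.geometry import (
    Atom,
    BONDI_RADII,
    CoordinateParseError,
    Molecule,
    assign_radii,
    read_coordinates,
    shrake_rupley_asa,
    sphere_points,
)

from conftest import mc_asa_oracle


def single_atom(element="C", radius=None):
    mol = Molecule(element, (Atom(element, np.zeros(3)),))
    return assign_radii(mol) if radius is None else Molecule(
        element, (Atom(element, np.zeros(3), radius),)
    )


class TestReaders:
    def test_xyz_benzene_has_six_carbons_six_hydrogens(self, benzene_xyz):
        mol = read_coordinates(benzene_xyz)
        assert len(mol) == 12
        assert sorted(mol.elements) == ["C"] * 6 + ["H"] * 6

    def test_xyz_count_mismatch_is_rejected(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("3\ncomment\nC 0 0 0\nH 1 0 0\n")
        with pytest.raises(CoordinateParseError, match="3 atoms but 2"):
            read_coordinates(p)

    def test_unknown_element_names_the_line(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("1\ncomment\nXx 0 0 0\n")
        with pytest.raises(CoordinateParseError, match="line 3.*Xx"):
            read_coordinates(p)

    def test_pdb_and_xyz_agree_on_elements_and_coordinates(self, benzene_xyz, benzene_pdb):
        a = read_coordinates(benzene_xyz)
        b = read_coordinates(benzene_pdb)
        assert sorted(a.elements) == sorted(b.elements)
        # PDB stores 3 decimals; geometries should agree to that precision
        np.testing.assert_allclose(a.coordinates, b.coordinates, atol=1e-3)

    def test_missing_file_raises_oserror(self, tmp_path):
        with pytest.raises(OSError):
            read_coordinates(tmp_path / "nope.xyz")


class TestRadii:
    def test_default_bondi_assignment(self, benzene):
        mol = assign_radii(benzene)
        by_el = {a.element: a.vdw_radius for a in mol.atoms}
        assert by_el == {"C": 1.70, "H": 1.20}

    def test_missing_element_is_reported(self, benzene):
        with pytest.raises(KeyError, match="H"):
            assign_radii(benzene, {"C": 1.70})

    def test_custom_override_applies_to_all_atoms(self, benzene):
        mol = assign_radii(benzene, {"C": 1.90, "H": 1.20})
        assert all(a.vdw_radius == 1.90 for a in mol.atoms if a.element == "C")

    def test_order_preserved(self, benzene):
        mol = assign_radii(benzene)
        assert mol.elements == benzene.elements


class TestSpherePoints:
    def test_points_lie_on_unit_sphere(self):
        pts = sphere_points(960)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)

    def test_deterministic(self):
        assert np.array_equal(sphere_points(100), sphere_points(100))

    def test_quasi_uniform_centroid_near_origin(self):
        assert np.linalg.norm(sphere_points(960).mean(axis=0)) < 1e-2


class TestShrakeRupley:
    def test_isolated_atom_matches_closed_form(self):
        res = shrake_rupley_asa(single_atom("C"), probe_radius=1.4, n_sphere_points=960)
        exact = 4 * math.pi * (1.70 + 1.4) ** 2
        assert res.total_asa == pytest.approx(exact, rel=5e-3)
        assert res.total_asa == pytest.approx(120.76, abs=0.05)

    def test_disjoint_spheres_are_additive(self):
        far = Molecule("pair", (Atom("C", np.zeros(3), 1.70), Atom("C", np.array([100.0, 0, 0]), 1.70)))
        one = shrake_rupley_asa(single_atom("C"), 1.4, 960).total_asa
        two = shrake_rupley_asa(far, 1.4, 960).total_asa
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_overlapping_spheres_strictly_subadditive(self):
        close = Molecule("pair", (Atom("C", np.zeros(3), 1.70), Atom("C", np.array([2.0, 0, 0]), 1.70)))
        one = shrake_rupley_asa(single_atom("C"), 1.4, 960).total_asa
        two = shrake_rupley_asa(close, 1.4, 960).total_asa
        assert two < 2 * one

    def test_total_never_increases_as_atoms_approach(self):
        prev = math.inf
        for d in np.linspace(8.0, 0.5, 16):
            mol = Molecule("pair", (Atom("C", np.zeros(3), 1.70), Atom("C", np.array([d, 0, 0]), 1.70)))
            total = shrake_rupley_asa(mol, 1.4, 960).total_asa
            assert total <= prev + 1e-9
            prev = total

    def test_total_is_sum_of_per_atom(self, benzene_with_radii):
        res = shrake_rupley_asa(benzene_with_radii)
        assert res.total_asa == sum(res.per_atom_asa)
        assert all(v >= 0 for v in res.per_atom_asa)

    def test_deterministic_bit_identical(self, benzene_with_radii):
        a = shrake_rupley_asa(benzene_with_radii, 1.4, 960)
        b = shrake_rupley_asa(benzene_with_radii, 1.4, 960)
        assert a == b

    def test_unassigned_radii_raise_state_error(self, benzene):
        with pytest.raises(RuntimeError, match="assign_radii"):
            shrake_rupley_asa(benzene)

    def test_negative_probe_rejected(self, benzene_with_radii):
        with pytest.raises(ValueError):
            shrake_rupley_asa(benzene_with_radii, probe_radius=-0.1)

    def test_exclude_hydrogens_gives_smaller_heavy_surface(self, benzene_with_radii):
        with_h = shrake_rupley_asa(benzene_with_radii)
        no_h = shrake_rupley_asa(benzene_with_radii, include_hydrogens=False)
        h_idx = [i for i, el in enumerate(benzene_with_radii.elements) if el == "H"]
        assert all(no_h.per_atom_asa[i] == 0.0 for i in h_idx)
        assert 0 < no_h.total_asa < with_h.total_asa

    @pytest.mark.parametrize("fixture_name", ["benzene", "naphthalene_like", "methane_like"])
    def test_matches_monte_carlo_oracle_within_one_percent(self, fixture_name):
        from hydrodecomp.synthetic import make_fixture_geometry

        mol = assign_radii(make_fixture_geometry(fixture_name))
        sr = shrake_rupley_asa(mol, 1.4, 960).total_asa
        mc = mc_asa_oracle(mol, 1.4, n_samples_per_atom=100_000, seed=99)
        assert sr == pytest.approx(mc, rel=0.01)

    @settings(max_examples=20, deadline=None)
    @given(radius=st.floats(0.5, 3.0), probe=st.floats(0.0, 2.0))
    def test_isolated_sphere_closed_form_property(self, radius, probe):
        mol = single_atom("C", radius=radius)
        res = shrake_rupley_asa(mol, probe_radius=probe, n_sphere_points=960)
        exact = 4 * math.pi * (radius + probe) ** 2
        assert abs(res.total_asa - exact) / exact <= 0.005


class TestMoleculeInvariants:
    def test_duplicate_positions_rejected(self):
        with pytest.raises(ValueError, match="identical positions"):
            Molecule("dup", (Atom("C", np.zeros(3)), Atom("H", np.zeros(3))))

    def test_empty_molecule_rejected(self):
        with pytest.raises(ValueError):
            Molecule("empty", ())

    def test_nonfinite_position_rejected(self):
        with pytest.raises(ValueError):
            Atom("C", np.array([0.0, np.nan, 0.0]))
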