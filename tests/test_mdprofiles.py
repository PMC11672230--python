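"""Atomistic interfacial metrics: density profiles, contacts, RMSD."""

import numpy as np
import pytest

import adlayer as al
from adlayer.mdprofiles import (
    AtomSet,
    average_density_profile,
    profile_extent,
    read_pdb,
    read_xyzm,
    write_xyzm,
)
from adlayer.layers import volume_fraction_profile


def brute_force_contacts(protein, surface, cutoff):
    count = 0
    for p in protein.coordinates:
        d = np.sqrt(np.sum((surface.coordinates - p) ** 2, axis=1))
        if np.any(d <= cutoff * (1 + 1e-12)):
            count += 1
    return count


class TestDensityProfile:
    def test_point_mass_in_single_bin(self):
        atoms = AtomSet(np.array([[0.0, 0.0, 30.0]] * 5), np.full(5, 12.0))
        prof = al.density_profile(atoms, bin_width=1.0)
        assert prof.total_mass == pytest.approx(60.0)
        assert np.sum(prof.density > 0) == 1

    def test_uniform_slab_is_flat(self, rng):
        n = 40000
        coords = np.column_stack(
            [rng.uniform(-50, 50, n), rng.uniform(-50, 50, n), rng.uniform(0, 40, n)]
        )
        atoms = AtomSet(coords, np.ones(n))
        prof = al.density_profile(atoms, bin_width=2.0)
        occupied = prof.density[(prof.z > 2) & (prof.z < 38)]
        assert prof.total_mass == pytest.approx(n)
        assert np.std(occupied) / np.mean(occupied) < 0.05  # flat within counting noise

    def test_mass_conserved_under_rebinning(self, rng):
        atoms = al.make_pseudo_protein("flat_on", 27.5, seed=3)
        masses = [
            al.density_profile(atoms, bin_width=w).total_mass for w in (0.5, 1.0, 2.0, 3.7)
        ]
        assert np.allclose(masses, atoms.total_mass, rtol=1e-9)

    def test_atoms_below_surface_warn_but_bin(self):
        atoms = AtomSet(np.array([[0, 0, -5.0], [0, 0, 5.0]]), np.array([1.0, 1.0]))
        with pytest.warns(UserWarning):
            prof = al.density_profile(atoms, surface_z=0.0)
        assert prof.total_mass == pytest.approx(2.0)

    def test_snapshot_average(self):
        a = AtomSet(np.array([[0, 0, 10.0]]), np.array([2.0]))
        b = AtomSet(np.array([[0, 0, 30.0]]), np.array([4.0]))
        prof = average_density_profile([a, b], bin_width=1.0)
        assert prof.total_mass == pytest.approx(3.0)  # mean over snapshots


class TestMassCenter:
    def test_two_equal_masses(self):
        atoms = AtomSet(np.array([[0, 0, 10.0], [0, 0, 30.0]]), np.array([1.0, 1.0]))
        assert al.md_mass_center_distance(atoms) == pytest.approx(20.0)

    def test_translation_equivariance(self, rng):
        atoms = al.make_pseudo_protein("tilted", 30.0, seed=5)
        c0 = al.md_mass_center_distance(atoms)
        c5 = al.md_mass_center_distance(atoms.translated([0, 0, 5.0]))
        assert c5 - c0 == pytest.approx(5.0, abs=1e-9)

    def test_constructed_center(self):
        atoms = al.make_pseudo_protein("flat_on", 27.5, seed=1)
        assert al.md_mass_center_distance(atoms) == pytest.approx(27.5, abs=0.1)

    def test_empty_selection_rejected(self):
        empty = AtomSet(np.empty((0, 3)), np.empty(0))
        with pytest.raises(ValueError):
            al.md_mass_center_distance(empty)


class TestContacts:
    def test_distant_protein_has_no_contacts(self):
        surface = al.make_surface_slab(size=40.0)
        protein = AtomSet(np.array([[0, 0, 20.0]]), np.array([12.0]))
        assert al.contact_count(protein, surface, cutoff=5.0) == 0

    def test_closed_boundary_at_cutoff(self):
        surface = AtomSet(np.array([[0.0, 0.0, 0.0]]), np.array([60.0]))
        protein = AtomSet(np.array([[0.0, 0.0, 5.0]]), np.array([12.0]))
        assert al.contact_count(protein, surface, cutoff=5.0) == 1

    def test_empty_group_warns_zero(self):
        protein = al.make_pseudo_protein("flat_on", 27.5, seed=2)
        empty = AtomSet(np.empty((0, 3)), np.empty(0))
        with pytest.warns(UserWarning):
            assert al.contact_count(empty, protein, cutoff=5.0) == 0
        with pytest.warns(UserWarning):
            assert al.contact_count(protein, empty, cutoff=5.0) == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        """Tree-based counting equals the exhaustive pairwise loop."""
        rng = np.random.default_rng(seed)
        n_p, n_s = rng.integers(50, 400), rng.integers(50, 400)
        protein = AtomSet(rng.uniform(-30, 30, (n_p, 3)), np.ones(n_p))
        surface = AtomSet(
            np.column_stack(
                [rng.uniform(-30, 30, (n_s, 2)), rng.uniform(-6, 0, (n_s, 1))]
            ),
            np.ones(n_s),
        )
        cutoff = float(rng.uniform(2.0, 8.0))
        assert al.contact_count(protein, surface, cutoff) == brute_force_contacts(
            protein, surface, cutoff
        )

    def test_pseudo_protein_touches_surface(self):
        surface = al.make_surface_slab(size=240.0, top_z=0.0)
        protein = al.make_pseudo_protein("flat_on", 27.5, seed=4)
        assert al.contact_count(protein, surface, cutoff=5.0) > 0


class TestRmsd:
    def test_identical_sets(self, rng):
        a = rng.normal(size=(50, 3))
        assert al.rmsd(a, a) == 0.0

    def test_uniform_displacement(self, rng):
        a = rng.normal(size=(50, 3))
        b = a + np.array([3.0, 0.0, 4.0])  # |d| = 5
        assert al.rmsd(a, b, superpose=False) == pytest.approx(5.0)

    def test_rotation_invariance_after_superposition(self, rng):
        from scipy.spatial.transform import Rotation

        a = rng.normal(size=(80, 3)) * 10
        rot = Rotation.from_euler("xyz", [40, -25, 110], degrees=True)
        b = rot.apply(a) + np.array([5.0, -2.0, 7.0])
        assert al.rmsd(a, b, superpose=True) < 1e-8
        assert al.rmsd(a, b, superpose=True) <= al.rmsd(a, b, superpose=False)

    def test_triangle_inequality_raw(self, rng):
        a, b, c = (rng.normal(size=(30, 3)) for _ in range(3))
        assert al.rmsd(a, c) <= al.rmsd(a, b) + al.rmsd(b, c) + 1e-12

    def test_mismatched_counts_rejected(self, rng):
        with pytest.raises(ValueError):
            al.rmsd(rng.normal(size=(10, 3)), rng.normal(size=(11, 3)))


class TestCompareProfiles:
    def test_self_comparison(self, stack_ph55):
        nr = volume_fraction_profile(stack_ph55, dz=0.5)
        md = al.DensityProfile(z=nr.z.copy(), density=nr.phi.copy(), bin_width=0.5)
        rep = al.compare_profiles(md, nr)
        assert rep["overlap"] == pytest.approx(1.0, abs=0.02)
        assert rep["mass_center_difference"] == pytest.approx(0.0, abs=0.2)

    def test_disjoint_supports(self):
        md = al.DensityProfile(z=np.linspace(100, 120, 21), density=np.ones(21), bin_width=1.0)
        nr = al.VolumeFractionProfile(z=np.linspace(0, 20, 21), phi=np.ones(21) * 0.4)
        rep = al.compare_profiles(md, nr)
        assert rep["overlap"] == 0.0

    def test_md_center_vs_nr_step_profile(self, stack_ph55):
        """Pseudo-protein at 27.5 A vs the pH 5.5 step profile: ~1.1 A apart."""
        atoms = al.make_pseudo_protein("flat_on", 27.5, seed=8)
        md = al.density_profile(atoms, bin_width=1.0)
        nr = volume_fraction_profile(stack_ph55, dz=0.1)
        rep = al.compare_profiles(md, nr)
        assert rep["mass_center_difference"] == pytest.approx(27.5 - 26.36, abs=0.3)
        assert 0.0 < rep["overlap"] <= 1.0

    def test_tilted_extends_beyond_flat(self):
        flat = al.make_pseudo_protein("flat_on", center_z=None, seed=6)
        tilt = al.make_pseudo_protein("tilted", center_z=None, seed=6)
        pf = al.density_profile(flat, bin_width=1.0)
        pt = al.density_profile(tilt, bin_width=1.0)
        ext_f = profile_extent(pf.z, pf.density * pf.bin_width)
        ext_t = profile_extent(pt.z, pt.density * pt.bin_width)
        assert ext_t - ext_f > 10.0


class TestReaders:
    def test_xyzm_round_trip(self, tmp_path):
        atoms = al.make_pseudo_protein("flat_on", 27.5, seed=9, n_per_fragment=30)
        p = tmp_path / "conf.xyzm"
        write_xyzm(p, atoms)
        back = read_xyzm(p)
        assert np.allclose(back.coordinates, atoms.coordinates, atol=1e-3)
        assert back.total_mass == pytest.approx(atoms.total_mass, rel=1e-4)

    def test_pdb_reader(self, tmp_path):
        pdb = tmp_path / "mini.pdb"
        pdb.write_text(
            "ATOM      1  N   ALA A   1      10.000  10.000  25.000  1.00  0.00           N\n"
            "ATOM      2  CA  ALA A   1      11.000  10.000  26.000  1.00  0.00           C\n"
            "ATOM      3  O   ALA A   1      12.000  10.000  27.000  1.00  0.00           O\n"
            "ATOM      4  CB  ALA B   2      13.000  10.000  28.000  1.00  0.00           C\n"
            "END\n"
        )
        atoms = read_pdb(pdb)
        assert len(atoms) == 4
        assert atoms.total_mass == pytest.approx(14.007 + 12.011 + 15.999 + 12.011)
        chain_a = read_pdb(pdb, selection="A")
        assert len(chain_a) == 3

    def test_surface_plane(self):
        surf = al.make_surface_slab(size=20.0, top_z=3.5)
        assert al.surface_plane(surf) == pytest.approx(3.5)

    def test_malformed_xyzm_rejected(self, tmp_path):
        p = tmp_path / "bad.xyzm"
        p.write_text("X 1.0 2.0\n")
        with pytest.raises(ValueError):
            read_xyzm(p)
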