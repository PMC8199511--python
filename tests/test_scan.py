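"""Orientation scan, stationary points, structures, hydrogen bonds."""

import math

import numpy as np
import pytest

from elfx.fixtures import (builtin_geometry, builtin_pair, planted_map,
                           synthetic_site_model)
from elfx.scan import (ScanConfig, count_hydrogen_bonds, export_structure,
                       find_stationary_points, orientation_quaternions,
                       placed_pair, principal_axis_frame, scan_map)
from elfx.topology import ReactiveSiteModel
from elfx.units import ANGSTROM_PER_BOHR, BOHR_PER_ANGSTROM
from elfx.wavefunction import Molecule


class TestConfig:
    def test_uneven_step_rejected(self):
        with pytest.raises(ValueError):
            ScanConfig(theta_step=7.0)
        with pytest.raises(ValueError):
            ScanConfig(distance=-1.0)

    def test_default_grid_shape(self):
        cfg = ScanConfig()
        assert len(cfg.thetas) == 19
        assert len(cfg.phis) == 37


class TestQuaternionSet:
    def test_normalized_and_deterministic(self):
        q1 = orientation_quaternions(576)
        q2 = orientation_quaternions(576)
        assert np.array_equal(q1, q2)
        assert np.allclose(np.linalg.norm(q1, axis=1), 1.0, atol=1e-12)

    def test_prefix_nesting(self):
        # a finer coarse grid extends the coarser one
        q1 = orientation_quaternions(144)
        q2 = orientation_quaternions(576)
        assert np.array_equal(q2[:144], q1)

    def test_covers_rotations(self):
        q = orientation_quaternions(576)
        rng = np.random.default_rng(0)
        for _ in range(20):
            r = rng.normal(size=4)
            r /= np.linalg.norm(r)
            dots = np.abs(q @ r)
            ang = 2 * math.degrees(math.acos(min(dots.max(), 1.0)))
            assert ang < 60.0


class TestPrincipalFrame:
    def test_planar_molecule_normal_is_z(self):
        g = builtin_geometry("guanine")
        axes = principal_axis_frame(g)
        # all atoms lie in the xy plane of the principal frame
        r = (g.coords - g.center_of_mass()) @ axes.T
        assert np.max(np.abs(r[:, 2])) < 1e-6
        assert np.allclose(axes @ axes.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(axes) == pytest.approx(1.0, abs=1e-12)

    def test_deterministic_sign_convention(self):
        w = builtin_geometry("water")
        a1 = principal_axis_frame(w)
        a2 = principal_axis_frame(w.translated([3.0, -1.0, 2.0]))
        assert np.allclose(a1, a2, atol=1e-9)


class TestScanMap:
    def test_single_site_models_give_constant_map(self):
        fixed = ReactiveSiteModel(None, [[0.0, 0, 0]], [1.0], [0.0])
        mobile = ReactiveSiteModel(None, [[0.0, 0, 0]], [0.0], [1.0])
        cfg = ScanConfig(theta_step=45.0, phi_step=90.0,
                         coarse_orientations=64, refine=False)
        emap = scan_map(fixed, mobile, cfg)
        d = 8.0 * BOHR_PER_ANGSTROM
        assert np.allclose(emap.energies, -1.0 / d, atol=1e-8)

    def test_stored_orientation_reproduces_stored_energy(self):
        fixed = synthetic_site_model(21, n_sites=3, n_nuclei=2)
        mobile = synthetic_site_model(22, n_sites=3, n_nuclei=2)
        cfg = ScanConfig(theta_step=60.0, phi_step=120.0,
                         coarse_orientations=96)
        emap = scan_map(fixed, mobile, cfg)
        from elfx.scan import _body_frame, _placed_energy
        fpf = _body_frame(fixed)
        mbf = _body_frame(mobile)
        for i in range(len(emap.thetas)):
            for j in range(len(emap.phis)):
                if not np.isfinite(emap.energies[i, j]):
                    continue
                pl = emap.placement(i, j)
                e = _placed_energy(fpf, mbf, pl.translation,
                                   pl.quaternion,
                                   cfg.clash_radius * BOHR_PER_ANGSTROM,
                                   penalty=False)
                assert e == pytest.approx(emap.energies[i, j], abs=1e-10)

    def test_optimizer_matches_exhaustive_rotation_search(self):
        """Mobile with one off-centre El site: the best orientation at a
        probe cell must match a dense brute-force rotation scan."""
        fixed = ReactiveSiteModel(None, [[0.0, 0, 0]], [1.0], [0.0])
        mobile = ReactiveSiteModel(
            Molecule(["H"], [[0, 0, 0]]),
            [[1.5, 0.4, -0.2]], [0.0], [0.8])
        cfg = ScanConfig(theta_step=90.0, phi_step=180.0,
                         coarse_orientations=576)
        emap = scan_map(fixed, mobile, cfg)
        # brute force at the theta=90, phi=0 cell: the orientation term
        # is minimized when the El site points straight at the fixed Nu
        # site (distance d - |r_site|); the mobile nucleus at the COM
        # adds a constant Z_B (0 - N_Nu,A) / d
        d = 8.0 * BOHR_PER_ANGSTROM
        site_r = np.linalg.norm(mobile.sites[0]
                                - mobile.molecule.center_of_mass())
        e_best = -0.8 / (d - site_r) - 1.0 / d
        i = list(emap.thetas).index(90.0)
        j = list(emap.phis).index(0.0)
        assert emap.energies[i, j] == pytest.approx(e_best, rel=1e-4)

    def test_bitwise_determinism(self):
        fixed = synthetic_site_model(31, n_sites=4, n_nuclei=2)
        mobile = synthetic_site_model(32, n_sites=3, n_nuclei=2)
        cfg = ScanConfig(theta_step=60.0, phi_step=120.0,
                         coarse_orientations=64)
        m1 = scan_map(fixed, mobile, cfg)
        m2 = scan_map(fixed, mobile, cfg)
        assert np.array_equal(m1.energies, m2.energies)
        assert np.array_equal(m1.quaternions, m2.quaternions)

    def test_finer_coarse_grid_never_raises_cells(self):
        fixed = synthetic_site_model(41, n_sites=3, n_nuclei=1)
        mobile = synthetic_site_model(42, n_sites=3, n_nuclei=1)
        base = ScanConfig(theta_step=90.0, phi_step=180.0,
                          coarse_orientations=144, refine=False)
        fine = ScanConfig(theta_step=90.0, phi_step=180.0,
                          coarse_orientations=576, refine=False)
        e1 = scan_map(fixed, mobile, base).energies
        e2 = scan_map(fixed, mobile, fine).energies
        assert np.all(e2 <= e1 + 1e-12)


class TestStationaryPoints:
    def test_constant_map_single_minimum(self):
        emap = planted_map([], background=-1.0)
        pts = find_stationary_points(emap)
        assert len(pts) == 1

    def test_planted_two_wells_recovered(self):
        wells = [(60.0, 120.0, 2.0, 18.0), (120.0, 300.0, 1.5, 18.0)]
        emap = planted_map(wells)
        pts = find_stationary_points(emap, top_k=5)
        assert len(pts) >= 2
        for (t0, p0, _, _), got in zip(wells, pts[:2]):
            assert abs(got.theta - t0) <= 10.0
            d = min(abs(got.phi - p0), 360 - abs(got.phi - p0))
            assert d <= 10.0

    def test_ranked_by_energy(self):
        emap = planted_map([(40, 50, 1.0, 15.0), (140, 250, 3.0, 15.0)])
        pts = find_stationary_points(emap)
        energies = [p.energy for p in pts]
        assert energies == sorted(energies)
        assert pts[0].theta == pytest.approx(140, abs=10)


class TestStructures:
    def _map_with_identity(self):
        fixed = ReactiveSiteModel(
            builtin_geometry("water"), [[0.0, 0, 0.5]], [0.5], [0.0])
        mobile = ReactiveSiteModel(
            builtin_geometry("water"), [[0.0, 0, 0.5]], [0.0], [0.5])
        cfg = ScanConfig(theta_step=90.0, phi_step=180.0,
                         coarse_orientations=32, refine=False)
        return scan_map(fixed, mobile, cfg)

    def test_export_com_distance_and_round_trip(self, tmp_path):
        emap = self._map_with_identity()
        pl = emap.placement(1, 0)       # theta=90, phi=0
        fixed_mol, mobile_mol = placed_pair(emap, pl)
        com = np.linalg.norm(fixed_mol.center_of_mass()
                             - mobile_mol.center_of_mass())
        assert com * ANGSTROM_PER_BOHR == pytest.approx(8.0, abs=1e-3)
        path = tmp_path / "pair.xyz"
        export_structure(fixed_mol, mobile_mol, path, comment="probe")
        back = Molecule.from_xyz(path)
        ref = np.vstack([fixed_mol.coords, mobile_mol.coords])
        assert np.allclose(back.coords, ref, atol=1e-6 * BOHR_PER_ANGSTROM)


class TestHydrogenBonds:
    def test_water_dimer_exactly_one(self):
        dim = builtin_geometry("water_dimer")
        a = Molecule(dim.symbols[:3], dim.coords[:3])
        b = Molecule(dim.symbols[3:], dim.coords[3:])
        contacts = count_hydrogen_bonds(a, b)
        assert len(contacts) == 1
        di, hi, ai, tag = contacts[0]
        assert tag == "A->B"

    def test_far_apart_zero(self):
        a = builtin_geometry("water")
        b = builtin_geometry("water").translated(
            np.array([20.0, 0, 0]) * BOHR_PER_ANGSTROM)
        assert count_hydrogen_bonds(a, b) == []

    def test_wc_reference_three_bonds_pattern(self):
        g, c = builtin_pair("gc_wc_reference")
        contacts = count_hydrogen_bonds(g, c)
        assert len(contacts) == 3
        kinds = set()
        for di, hi, ai, tag in contacts:
            don = (g if tag == "A->B" else c)
            acc = (c if tag == "A->B" else g)
            kinds.add((don.symbols[di], acc.symbols[ai], tag))
        # N-H...O and N-H...N from guanine, N-H...O from cytosine
        assert ("N", "O", "A->B") in kinds
        assert ("N", "N", "A->B") in kinds
        assert ("N", "O", "B->A") in kinds

    def test_overlapping_molecules_audit_error(self):
        a = builtin_geometry("water")
        with pytest.raises(ValueError):
            count_hydrogen_bonds(a, a)
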