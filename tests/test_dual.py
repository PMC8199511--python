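"""Monopole dual energy: printed-formula checks, brute-force oracle,
invariances, and the grid-integral (Fukui quadrature) oracle."""

import numpy as np
import pytest

from elfx.dual import (ClashError, RigidPlacement, edual,
                       edual_integral_oracle, transform_sites)
from elfx.fields import ScalarFieldGrid
from elfx.fixtures import synthetic_site_model
from elfx.topology import ReactiveSiteModel
from elfx.wavefunction import Molecule


def bare_model(sites, n_nu, n_el, molecule=None):
    return ReactiveSiteModel(molecule, np.asarray(sites, float),
                             np.asarray(n_nu, float),
                             np.asarray(n_el, float))


def naive_edual(ma, mb, literal=False):
    """Independent term-by-term double loop."""
    tot = 0.0
    for i in range(ma.nsites):
        for j in range(mb.nsites):
            r = np.linalg.norm(ma.sites[i] - mb.sites[j])
            tot += (2 * ma.n_nu[i] * mb.n_nu[j]
                    - ma.n_nu[i] * mb.n_el[j]
                    - ma.n_el[i] * mb.n_nu[j]) / r
    scale_a = ma.nsites if literal else 1
    scale_b = mb.nsites if literal else 1
    if ma.molecule is not None:
        for z, R in zip(ma.molecule.charges, ma.molecule.coords):
            for j in range(mb.nsites):
                r = np.linalg.norm(mb.sites[j] - R)
                tot += scale_a * z * (mb.n_el[j] - mb.n_nu[j]) / r
    if mb.molecule is not None:
        for z, R in zip(mb.molecule.charges, mb.molecule.coords):
            for i in range(ma.nsites):
                r = np.linalg.norm(ma.sites[i] - R)
                tot += scale_b * z * (ma.n_el[i] - ma.n_nu[i]) / r
    return tot


class TestPrintedFormula:
    def test_single_nu_el_pair(self):
        a = bare_model([[0, 0, 0]], [1.0], [0.0])
        b = bare_model([[10, 0, 0]], [0.0], [1.0])
        assert edual(a, b).total == pytest.approx(-0.1, abs=1e-14)

    def test_nu_nu_factor_two(self):
        a = bare_model([[0, 0, 0]], [1.0], [0.0])
        b = bare_model([[10, 0, 0]], [1.0], [0.0])
        assert edual(a, b).total == pytest.approx(0.2, abs=1e-14)

    def test_no_el_el_term(self):
        a = bare_model([[0, 0, 0]], [0.0], [1.0])
        b = bare_model([[10, 0, 0]], [0.0], [1.0])
        assert edual(a, b).total == 0.0

    def test_breakdown_sums_to_total(self):
        a = synthetic_site_model(1, n_sites=4, n_nuclei=3)
        b = synthetic_site_model(2, n_sites=3, n_nuclei=2)
        b = transform_sites(b, RigidPlacement([1, 0, 0, 0],
                                              [20.0, 0, 0]))
        br = edual(a, b)
        assert br.total == pytest.approx(
            br.nu_nu + br.nuA_elB + br.elA_nuB + br.nucA_sitesB
            + br.nucB_sitesA, abs=1e-12)

    def test_matches_naive_loop_on_random_models(self):
        for seed in range(100):
            a = synthetic_site_model(seed, n_sites=1 + seed % 4,
                                     n_nuclei=seed % 4)
            b = synthetic_site_model(1000 + seed, n_sites=1 + seed % 3,
                                     n_nuclei=(seed + 1) % 3)
            b = transform_sites(b, RigidPlacement(
                [1, 0, 0, 0], [15.0 + seed % 5, 0, 0]))
            assert edual(a, b).total == pytest.approx(
                naive_edual(a, b), abs=1e-12)

    def test_literal_eq7_nesting(self):
        a = synthetic_site_model(5, n_sites=3, n_nuclei=2)
        b = synthetic_site_model(6, n_sites=4, n_nuclei=2)
        b = transform_sites(b, RigidPlacement([1, 0, 0, 0], [18.0, 0, 0]))
        lit = edual(a, b, literal_eq7=True).total
        assert lit == pytest.approx(naive_edual(a, b, literal=True),
                                    abs=1e-12)

    def test_clash_raises(self):
        a = bare_model([[0, 0, 0]], [1.0], [0.0])
        b = bare_model([[0.3, 0, 0]], [0.0], [1.0])
        with pytest.raises(ClashError):
            edual(a, b)


class TestTransformSites:
    def test_identity(self):
        m = synthetic_site_model(3, n_sites=4, n_nuclei=2)
        out = transform_sites(m, RigidPlacement.identity())
        assert np.allclose(out.sites, m.sites)
        assert np.allclose(out.molecule.coords, m.molecule.coords)

    def test_half_turn_about_z(self):
        m = bare_model([[1.0, 0, 0]], [1.0], [0.0])
        out = transform_sites(m, RigidPlacement([0, 0, 0, 1], [0, 0, 0]))
        assert np.allclose(out.sites[0], [-1, 0, 0], atol=1e-12)

    def test_rigidity(self, rng):
        m = synthetic_site_model(9, n_sites=5, n_nuclei=3)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        out = transform_sites(m, RigidPlacement(q, rng.normal(size=3)))
        d0 = np.linalg.norm(m.sites[:, None] - m.sites[None], axis=2)
        d1 = np.linalg.norm(out.sites[:, None] - out.sites[None], axis=2)
        assert np.allclose(d0, d1, atol=1e-10)
        assert np.allclose(out.n_nu, m.n_nu)

    def test_non_unit_quaternion_rejected(self):
        with pytest.raises(ValueError):
            RigidPlacement([1.0, 0.1, 0, 0], [0, 0, 0])


class TestInvariances:
    def _pair(self):
        a = synthetic_site_model(11, n_sites=4, n_nuclei=3)
        b = synthetic_site_model(12, n_sites=3, n_nuclei=2)
        return a, transform_sites(
            b, RigidPlacement([1, 0, 0, 0], [16.0, 2.0, -1.0]))

    def test_global_rigid_motion(self, rng):
        a, b = self._pair()
        e0 = edual(a, b).total
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        t = rng.normal(size=3) * 5
        pl = RigidPlacement(q, t)
        e1 = edual(transform_sites(a, pl), transform_sites(b, pl)).total
        assert e1 == pytest.approx(e0, abs=1e-10)

    def test_ab_symmetry(self):
        a, b = self._pair()
        assert edual(a, b).total == pytest.approx(edual(b, a).total,
                                                  abs=1e-12)

    def test_population_scaling_linearity(self):
        a, b = self._pair()
        lam = 0.37
        a2 = ReactiveSiteModel(a.molecule, a.sites, lam * a.n_nu,
                               lam * a.n_el)
        e = edual(a, b)
        e2 = edual(a2, b)
        assert e2.nuA_elB == pytest.approx(lam * e.nuA_elB, abs=1e-12)
        assert e2.elA_nuB == pytest.approx(lam * e.elA_nuB, abs=1e-12)
        assert e2.nu_nu == pytest.approx(lam * e.nu_nu, abs=1e-12)
        # nuclear coupling to A's sites scales; to B's sites does not
        assert e2.nucB_sitesA == pytest.approx(lam * e.nucB_sitesA,
                                               abs=1e-12)
        assert e2.nucA_sitesB == pytest.approx(e.nucA_sitesB, abs=1e-12)


# ---------------------------------------------------------------------------
# grid-integral oracle
# ---------------------------------------------------------------------------

def delta_grids(center, w_nu, w_el):
    """3^3 grid holding point-like Fukui densities at the center node."""
    axes = np.eye(3) * 1.0
    origin = np.asarray(center, float) - 1.0
    vn = np.zeros((3, 3, 3))
    ve = np.zeros((3, 3, 3))
    vn[1, 1, 1] = w_nu
    ve[1, 1, 1] = w_el
    return (ScalarFieldGrid(origin, axes, vn, tag="rho"),
            ScalarFieldGrid(origin, axes, ve, tag="rho"))


def gaussian_grids(center, sigma, n=25, spacing=0.5, offset=0.4,
                   w_nu=1.0, w_el=0.4):
    # unequal Nu/El weights keep the net monopole coefficient
    # (2 w_nu^A w_nu^B - w_nu^A w_el^B - w_el^A w_nu^B) nonzero, so the
    # interaction has a genuine 1/r leading term
    g = np.arange(n) * spacing
    origin = np.asarray(center, float) - g[-1] / 2
    X, Y, Z = np.meshgrid(*[origin[i] + g for i in range(3)],
                          indexing="ij")
    def bump(c, w):
        r2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
        v = np.exp(-r2 / (2 * sigma ** 2))
        return w * v / (v.sum() * spacing ** 3)
    c = np.asarray(center, float)
    f_nu = bump(c + [0, offset, 0], w_nu)
    f_el = bump(c - [0, offset, 0], w_el)
    axes = np.eye(3) * spacing
    return (ScalarFieldGrid(origin, axes, f_nu, tag="rho"),
            ScalarFieldGrid(origin, axes, f_el, tag="rho"))


def monopole_of(grids, nuclei=None):
    f_nu, f_el = grids
    pts = f_nu.points()
    dv = f_nu.voxel_volume
    wn = f_nu.values.ravel() * dv
    we = f_el.values.ravel() * dv
    sites = np.vstack([wn @ pts / wn.sum(), we @ pts / we.sum()])
    model = ReactiveSiteModel(nuclei, sites,
                              np.array([wn.sum(), 0.0]),
                              np.array([0.0, we.sum()]))
    return model


NO_NUCLEI = (np.zeros(0), np.zeros((0, 3)))


class TestIntegralOracle:
    def test_point_distributions_exact(self):
        ga = delta_grids([0, 0, 0], 0.8, 0.3)
        gb = delta_grids([12, 0, 0], 0.5, 0.9)
        e_int = edual_integral_oracle(ga, gb, NO_NUCLEI, NO_NUCLEI)
        a = ReactiveSiteModel(None, [[0, 0, 0]], [0.8], [0.3])
        b = ReactiveSiteModel(None, [[12, 0, 0]], [0.5], [0.9])
        assert e_int == pytest.approx(edual(a, b).total, rel=1e-12)

    def test_gaussian_toys_within_5_percent_at_20_bohr(self):
        ga = gaussian_grids([0, 0, 0], 0.9)
        gb = gaussian_grids([20, 0, 0], 0.9)
        e_int = edual_integral_oracle(ga, gb, NO_NUCLEI, NO_NUCLEI)
        e_mono = edual(monopole_of(ga), monopole_of(gb)).total
        assert abs(e_mono - e_int) / abs(e_int) < 0.05

    def test_leading_order_one_over_r(self):
        ga = gaussian_grids([0, 0, 0], 0.9)
        gb1 = gaussian_grids([20, 0, 0], 0.9)
        gb2 = gaussian_grids([40, 0, 0], 0.9)
        e1 = edual_integral_oracle(ga, gb1, NO_NUCLEI, NO_NUCLEI)
        e2 = edual_integral_oracle(ga, gb2, NO_NUCLEI, NO_NUCLEI)
        assert abs(e2) == pytest.approx(abs(e1) / 2, rel=0.1)

    def test_monopole_error_decreases_with_separation(self):
        errs = []
        ga = gaussian_grids([0, 0, 0], 0.9, spacing=0.4)
        ma = monopole_of(ga)
        for sep in (10.0, 20.0, 40.0):
            gb = gaussian_grids([sep, 0, 0], 0.9, spacing=0.4)
            e_int = edual_integral_oracle(ga, gb, NO_NUCLEI, NO_NUCLEI)
            e_mono = edual(ma, monopole_of(gb)).total
            errs.append(abs(e_mono - e_int) / abs(e_int))
        assert errs[0] >= errs[1] >= errs[2]

    def test_overlapping_boxes_rejected(self):
        ga = gaussian_grids([0, 0, 0], 0.9)
        gb = gaussian_grids([5, 0, 0], 0.9)
        with pytest.raises(ValueError):
            edual_integral_oracle(ga, gb, NO_NUCLEI, NO_NUCLEI)

    def test_nuclear_terms_in_oracle(self):
        # a single nucleus near B couples to A's Fukui charge difference
        ga = delta_grids([0, 0, 0], 1.0, 0.0)
        gb = delta_grids([15, 0, 0], 0.0, 1.0)
        za = (np.array([2.0]), np.array([[0.0, 1.0, 0.0]]))
        zb = (np.array([1.0]), np.array([[15.0, 1.0, 0.0]]))
        e_int = edual_integral_oracle(ga, gb, za, zb)
        a = ReactiveSiteModel(
            Molecule(["He"], [[0.0, 1.0, 0.0]]), [[0, 0, 0]], [1.0], [0.0])
        b = ReactiveSiteModel(
            Molecule(["H"], [[15.0, 1.0, 0.0]]), [[15, 0, 0]], [0.0],
            [1.0])
        assert e_int == pytest.approx(edual(a, b).total, rel=1e-12)
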