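"""Built-in inputs: toy wavefunctions, geometries, synthetic models.

Everything the package needs to exercise itself offline lives here:
analytic single-Gaussian-orbital wavefunctions with closed-form density
ingredients (the cross-implementation oracle for the generic
evaluator), idealized monomer geometries, a reference Watson-Crick
guanine-cytosine pair, and seeded generators for random site models and
planted energy maps.

Geometry provenance: water, ammonia and formaldehyde use textbook
experimental parameters (r_OH = 0.957 A / 104.5 deg; r_NH = 1.012 A /
106.7 deg; r_CO = 1.205 A, r_CH = 1.111 A / 116.1 deg); the water dimer
is an idealized single-donor Cs-like arrangement with O...O = 2.95 A.
The nucleobases are MMFF94-optimized canonical tautomers constrained to
planarity; the reference pair places rigid cytosine against guanine's
Watson-Crick edge at canonical heavy-atom hydrogen-bond distances
(N4...O6 = 2.91 A, N3...N1 = 2.95 A, O2...N2 = 2.86 A).  Downstream
results never depend on these coordinates beyond the
hydrogen-bond-pattern level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .basis import ContractedBasis, Shell
from .scan import EdualMap, ScanConfig
from .topology import ReactiveSiteModel
from .units import BOHR_PER_ANGSTROM
from .wavefunction import Molecule, PointEvaluation, WavefunctionModel

__all__ = ["AnalyticToyWavefunction", "toy_wavefunction",
           "builtin_geometry", "builtin_pair", "fixture_names",
           "synthetic_site_model", "planted_map"]


# ---------------------------------------------------------------------------
# Analytic toy wavefunctions
# ---------------------------------------------------------------------------

@dataclass
class ToyOrbital:
    center: np.ndarray
    alpha: float
    occupation: float


class AnalyticToyWavefunction:
    """Normalized s-Gaussian orbitals with closed-form rho, grad, tau.

    phi_i(r) = (2 a_i / pi)^{3/4} exp(-a_i |r - c_i|^2); the closed
    forms below are exact, so they anchor the generic Gaussian-basis
    evaluator in tests.
    """

    def __init__(self, orbitals):
        self.orbitals = orbitals

    def rho(self, points):
        pts = np.asarray(points, float).reshape(-1, 3)
        out = np.zeros(len(pts))
        for orb in self.orbitals:
            if orb.occupation == 0:
                continue
            d2 = np.sum((pts - orb.center) ** 2, axis=1)
            norm2 = (2.0 * orb.alpha / math.pi) ** 1.5
            out += orb.occupation * norm2 * np.exp(-2.0 * orb.alpha * d2)
        return out

    def grad_rho(self, points):
        pts = np.asarray(points, float).reshape(-1, 3)
        out = np.zeros((len(pts), 3))
        for orb in self.orbitals:
            if orb.occupation == 0:
                continue
            d = pts - orb.center
            d2 = np.sum(d * d, axis=1)
            norm2 = (2.0 * orb.alpha / math.pi) ** 1.5
            phi2 = norm2 * np.exp(-2.0 * orb.alpha * d2)
            out += orb.occupation * (-4.0 * orb.alpha) * d \
                * phi2[:, None]
        return out

    def tau(self, points):
        pts = np.asarray(points, float).reshape(-1, 3)
        out = np.zeros(len(pts))
        for orb in self.orbitals:
            if orb.occupation == 0:
                continue
            d2 = np.sum((pts - orb.center) ** 2, axis=1)
            norm2 = (2.0 * orb.alpha / math.pi) ** 1.5
            phi2 = norm2 * np.exp(-2.0 * orb.alpha * d2)
            out += 0.5 * orb.occupation * 4.0 * orb.alpha ** 2 * d2 * phi2
        return out

    def point_evaluation(self, points):
        pts = np.asarray(points, float).reshape(-1, 3)
        return PointEvaluation(pts, self.rho(pts), self.grad_rho(pts),
                               self.tau(pts), "N")

    def nelec(self):
        return sum(o.occupation for o in self.orbitals)

    def to_wavefunction_model(self, molecule=None):
        """Express the same orbitals in the generic evaluator's terms."""
        shells = [Shell(0, o.center, np.array([o.alpha]), np.array([1.0]))
                  for o in self.orbitals]
        basis = ContractedBasis.from_shells(shells)
        n = len(self.orbitals)
        C = np.eye(n)
        occ = np.array([o.occupation for o in self.orbitals], float)
        # stable fake energies: occupied below virtuals, input order kept
        ene = np.array([(-2.0 + 0.1 * i) if occ[i] > 0 else (1.0 + 0.1 * i)
                        for i in range(n)])
        if molecule is None:
            molecule = Molecule(["He"] * max(1, len(self.orbitals)),
                                np.array([o.center for o in
                                          self.orbitals]) if self.orbitals
                                else np.zeros((1, 3)),
                                np.full(max(1, len(self.orbitals)), 2.0))
        return WavefunctionModel(molecule, basis, C, occ, ene)


def toy_wavefunction(spec):
    """Build an AnalyticToyWavefunction from (center, alpha, occupation)
    triples.  Exponents must be positive; occupations 0 or 2."""
    orbitals = []
    for center, alpha, occ in spec:
        if alpha <= 0:
            raise ValueError(f"exponent must be positive, got {alpha}")
        if occ not in (0, 2, 0.0, 2.0):
            raise ValueError(f"occupation must be 0 or 2, got {occ}")
        orbitals.append(ToyOrbital(np.asarray(center, float), float(alpha),
                                   float(occ)))
    return AnalyticToyWavefunction(orbitals)


# ---------------------------------------------------------------------------
# Built-in geometries (angstrom source text, converted to bohr)
# ---------------------------------------------------------------------------

_WATER = """\
O 0.0000 0.0000 0.1173
H 0.0000 0.7572 -0.4692
H 0.0000 -0.7572 -0.4692
"""

_AMMONIA = """\
N 0.0000 0.0000 0.0000
H 0.9376 0.0000 -0.3808
H -0.4688 0.8119 -0.3808
H -0.4688 -0.8119 -0.3808
"""

_FORMALDEHYDE = """\
C 0.0000 0.0000 0.0000
O 0.0000 0.0000 1.2050
H 0.9430 0.0000 -0.5870
H -0.9430 0.0000 -0.5870
"""

_WATER_DIMER = """\
O 0.0000 0.0000 0.0000
H 0.9570 0.0000 0.0000
H -0.2396 0.9265 0.0000
O 2.9500 0.0000 0.0000
H 3.1896 0.9265 0.0000
H 3.1896 -0.9265 0.0000
"""

_GUANINE = """\
N -2.7347 0.9420 0.0000
C -1.4844 0.4169 0.0000
N -0.4451 1.2086 0.0000
C 0.7265 0.5372 0.0000
N 1.9676 1.0976 0.0000
C 2.8728 0.0686 0.0000
N 2.2831 -1.1103 0.0000
C 0.9427 -0.8199 0.0000
C -0.2175 -1.6833 0.0000
O -0.2038 -2.9102 0.0000
N -1.4045 -0.9616 0.0000
H -3.4453 0.4625 0.0000
H -2.7292 1.9428 0.0000
H 2.1707 2.0857 0.0000
H 3.9406 0.2416 0.0000
H -2.2395 -1.5181 0.0000
"""

_CYTOSINE = """\
N -2.2840 0.3143 0.0000
C -0.9216 0.2095 0.0000
C -0.2925 -1.1322 0.0000
C 1.0377 -1.1418 0.0000
N 1.7232 0.0340 0.0000
C 1.1210 1.2695 0.0000
O 1.8259 2.2744 0.0000
N -0.2484 1.3192 0.0000
H -2.8187 -0.3855 0.0000
H -2.5952 1.2616 0.0000
H -0.9006 -2.0232 0.0000
H 1.6200 -2.0558 0.0000
H 2.7332 0.0560 0.0000
"""

# cytosine rigidly docked on guanine's Watson-Crick edge (same guanine
# frame as above)
_CYTOSINE_WC = """\
N -2.8886 -4.0569 0.0000
C -4.1027 -3.4298 0.0000
C -5.3431 -4.2404 0.0000
C -6.4797 -3.5493 0.0000
N -6.4448 -2.1886 0.0000
C -5.2830 -1.4542 0.0000
O -5.3543 -0.2288 0.0000
N -4.0920 -2.1319 0.0000
H -2.8017 -4.9332 0.0000
H -2.1259 -3.4146 0.0000
H -5.2942 -5.3181 0.0000
H -7.4556 -4.0207 0.0000
H -7.2924 -1.6390 0.0000
"""

_GEOMETRIES = {
    "water": _WATER,
    "ammonia": _AMMONIA,
    "formaldehyde": _FORMALDEHYDE,
    "water_dimer": _WATER_DIMER,
    "guanine": _GUANINE,
    "cytosine": _CYTOSINE,
}


def _parse_block(text):
    syms, xyz = [], []
    for ln in text.strip().splitlines():
        parts = ln.split()
        syms.append(parts[0])
        xyz.append([float(v) for v in parts[1:4]])
    return syms, np.array(xyz) * BOHR_PER_ANGSTROM


def fixture_names():
    return sorted(_GEOMETRIES) + ["gc_wc_reference"]


def builtin_geometry(name):
    """Return a built-in Molecule by name (see `fixture_names`)."""
    if name == "gc_wc_reference":
        gs, gx = _parse_block(_GUANINE)
        cs, cx = _parse_block(_CYTOSINE_WC)
        return Molecule(gs + cs, np.vstack([gx, cx]))
    if name not in _GEOMETRIES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {fixture_names()}")
    syms, xyz = _parse_block(_GEOMETRIES[name])
    return Molecule(syms, xyz)


def builtin_pair(name="gc_wc_reference"):
    """The reference complex as its two separate monomers."""
    if name != "gc_wc_reference":
        raise KeyError(f"unknown pair fixture {name!r}")
    gs, gx = _parse_block(_GUANINE)
    cs, cx = _parse_block(_CYTOSINE_WC)
    return Molecule(gs, gx), Molecule(cs, cx)


# ---------------------------------------------------------------------------
# Synthetic models and maps
# ---------------------------------------------------------------------------

def synthetic_site_model(seed, n_sites=4, spread=2.0, n_nuclei=0):
    """Reproducible random reactive-site model (bohr).

    Each site is exclusively nucleophilic or electrophilic with a
    population drawn from U(0.05, 1.0); optional light nuclei are
    scattered in the same region.
    """
    rng = np.random.default_rng(seed)
    sites = rng.uniform(-spread, spread, size=(n_sites, 3))
    pops = rng.uniform(0.05, 1.0, size=n_sites)
    is_nu = rng.random(n_sites) < 0.5
    n_nu = np.where(is_nu, pops, 0.0)
    n_el = np.where(is_nu, 0.0, pops)
    molecule = None
    if n_nuclei:
        zs = rng.choice([1, 6, 7, 8], size=n_nuclei)
        coords = rng.uniform(-spread, spread, size=(n_nuclei, 3))
        from .units import SYMBOLS
        molecule = Molecule([SYMBOLS[int(z)] for z in zs], coords,
                            np.asarray(zs, float))
    return ReactiveSiteModel(molecule, sites, n_nu, n_el,
                             {"source_field": "synthetic", "seed": seed})


def planted_map(wells, theta_step=10.0, phi_step=10.0, background=0.0):
    """Synthetic EdualMap with Gaussian wells planted on the sphere.

    ``wells`` is a list of (theta_deg, phi_deg, depth, width_deg).
    """
    cfg = ScanConfig(theta_step=theta_step, phi_step=phi_step)
    thetas, phis = cfg.thetas, cfg.phis
    E = np.full((len(thetas), len(phis)), background)
    for (t0, p0, depth, width) in wells:
        v0 = _sph_vec(t0, p0)
        for i, t in enumerate(thetas):
            for j, p in enumerate(phis):
                ang = math.degrees(math.acos(np.clip(
                    _sph_vec(t, p) @ v0, -1, 1)))
                E[i, j] -= depth * math.exp(-0.5 * (ang / width) ** 2)
    Q = np.zeros((len(thetas), len(phis), 4))
    Q[..., 0] = 1.0
    return EdualMap(thetas, phis, E, Q, cfg)


def _sph_vec(tdeg, pdeg):
    t, p = math.radians(tdeg), math.radians(pdeg)
    return np.array([math.sin(t) * math.cos(p),
                     math.sin(t) * math.sin(p), math.cos(t)])
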