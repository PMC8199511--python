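"""Rigid-body (theta, phi) scan of the dual interaction energy.

The fixed molecule is oriented along its principal axes of inertia
(z = largest moment, x = smallest, signs fixed by third moments).  The
mobile molecule's centre of mass is placed on a sphere of fixed radius
around the fixed molecule's centre of mass at each polar/azimuthal
angle pair; at each placement the mobile orientation is optimized by a
deterministic coarse search over a uniform quaternion set followed by
derivative-free local refinement, and the best (lowest)
E_dual is recorded.  Stationary points of the resulting map are local
minima on the sphere topology (periodic azimuth, degenerate poles).

Orientations bringing any intermolecular atom pair closer than the
clash radius are rejected (the monopole 1/r score has no repulsive
wall).  An optional post-scan rigid refinement relaxes the separation
and orientation jointly to produce contact-realistic structures before
hydrogen bonds are counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .dual import (RigidPlacement, edual, edual_batch, quaternion_to_matrix)
from .units import ANGSTROM_PER_BOHR, BOHR_PER_ANGSTROM

__all__ = ["ScanConfig", "EdualMap", "StationaryPoint", "scan_map",
           "find_stationary_points", "export_structure",
           "count_hydrogen_bonds", "principal_axis_frame",
           "orientation_quaternions", "refine_separation"]

CLASH_RADIUS_ANGSTROM = 1.5


@dataclass
class ScanConfig:
    """Scan protocol settings.

    Angles in degrees, distance in angstrom.  Defaults follow the
    centre-of-mass-on-a-sphere protocol: d = 8 A, 10 degree steps,
    576 coarse orientations, 1e-8 hartree refinement tolerance.
    """
    distance: float = 8.0
    theta_step: float = 10.0
    phi_step: float = 10.0
    coarse_orientations: int = 576
    refine_tol: float = 1e-8
    refine: bool = True
    clash_radius: float = CLASH_RADIUS_ANGSTROM
    exhaustive: bool = False

    def __post_init__(self):
        if self.distance <= 0:
            raise ValueError("distance must be positive")
        for step, span in ((self.theta_step, 180.0), (self.phi_step, 360.0)):
            if step <= 0 or abs(span / step - round(span / step)) > 1e-9:
                raise ValueError(f"step {step} must evenly divide {span}")

    @property
    def thetas(self):
        return np.arange(0.0, 180.0 + 0.5 * self.theta_step,
                         self.theta_step)

    @property
    def phis(self):
        return np.arange(0.0, 360.0 + 0.5 * self.phi_step, self.phi_step)


@dataclass
class StationaryPoint:
    theta: float
    phi: float
    energy: float
    quaternion: np.ndarray
    cell: tuple


@dataclass
class EdualMap:
    """Best-orientation E_dual(theta, phi) map."""
    thetas: np.ndarray
    phis: np.ndarray
    energies: np.ndarray           # (ntheta, nphi)
    quaternions: np.ndarray        # (ntheta, nphi, 4)
    config: ScanConfig
    fixed: object = None           # ReactiveSiteModel (principal frame)
    mobile: object = None          # ReactiveSiteModel (body frame)
    orientation_pool: np.ndarray = None   # exhaustive-mode energies

    def placement(self, i, j):
        t = math.radians(self.thetas[i])
        p = math.radians(self.phis[j])
        d = self.config.distance * BOHR_PER_ANGSTROM
        pos = d * np.array([math.sin(t) * math.cos(p),
                            math.sin(t) * math.sin(p), math.cos(t)])
        return RigidPlacement(self.quaternions[i, j], pos)


def orientation_quaternions(n):
    """Deterministic uniform covering of SO(3) by n unit quaternions.

    Drawn from a fixed-seed Gaussian stream (exactly uniform on SO(3)
    in distribution); the stream is sequential, so the set for a larger
    n is a superset of the set for a smaller n — refining the coarse
    grid can therefore never raise a scanned minimum.
    """
    rng = np.random.default_rng(987654321)
    q = rng.normal(size=(n, 4))
    return q / np.linalg.norm(q, axis=1, keepdims=True)


def principal_axis_frame(molecule):
    """Rotation matrix into the molecule's principal-axes frame.

    Rows are the x, y, z axes: x = smallest moment of inertia,
    z = largest (the out-of-plane normal for planar molecules).  The
    sign of each axis is fixed by requiring a non-negative third mass
    moment (falling back to the first atom's coordinate when that
    moment vanishes); y completes a right-handed frame.
    """
    m = molecule.masses()
    r = molecule.coords - molecule.center_of_mass()
    inertia = np.einsum("i,ij,ik->jk", m, r, r)
    inertia = np.trace(inertia) * np.eye(3) - inertia
    w, v = np.linalg.eigh(inertia)   # ascending: x first, z last
    axes = v.T.copy()
    for k in (0, 2):
        proj = r @ axes[k]
        third = np.sum(m * proj ** 3)
        if abs(third) < 1e-9:
            nz = proj[np.abs(proj) > 1e-9]
            third = nz[0] if len(nz) else 1.0
        if third < 0:
            axes[k] = -axes[k]
    axes[1] = np.cross(axes[2], axes[0])
    return axes


def _body_frame(model):
    """Centre a site model on its molecular COM, principal axes.

    Models without nuclei (synthetic fixtures) are centred on their
    site centroid in the identity frame.
    """
    if model.molecule is None:
        com = model.sites.mean(axis=0)
        return model.transformed(np.eye(3), -com)
    com = model.molecule.center_of_mass()
    axes = principal_axis_frame(model.molecule)
    return model.transformed(axes, -axes @ com)


def scan_map(fixed, mobile, config=None):
    """Scan all (theta, phi) placements of the mobile molecule.

    Both arguments are ReactiveSiteModels in their own molecular
    frames; the fixed model is re-expressed in its principal-axes frame
    and the mobile model in its own body frame before scanning.
    Returns an EdualMap whose stored per-cell quaternion reproduces the
    stored energy on re-evaluation.
    """
    config = config or ScanConfig()
    fixed_pf = _body_frame(fixed)
    mobile_bf = _body_frame(mobile)
    thetas = config.thetas
    phis = config.phis
    quats = orientation_quaternions(config.coarse_orientations)
    rots = np.array([quaternion_to_matrix(q) for q in quats])

    sa = fixed_pf.sites
    ra = (fixed_pf.molecule.coords if fixed_pf.molecule is not None
          else np.zeros((0, 3)))
    za = fixed_pf.coulomb_charges
    sb0 = mobile_bf.sites
    rb0 = (mobile_bf.molecule.coords if mobile_bf.molecule is not None
           else np.zeros((0, 3)))
    zb = mobile_bf.coulomb_charges
    # pre-rotate all coarse orientations once (placement only adds t)
    sb_rot = np.einsum("oij,sj->osi", rots, sb0)
    rb_rot = np.einsum("oij,aj->oai", rots, rb0)
    clash_bohr = config.clash_radius * BOHR_PER_ANGSTROM
    d = config.distance * BOHR_PER_ANGSTROM

    nE = np.full((len(thetas), len(phis)), np.inf)
    nQ = np.zeros((len(thetas), len(phis), 4))
    nQ[..., 0] = 1.0
    pool = (np.full((len(thetas), len(phis), len(quats)), np.inf)
            if config.exhaustive else None)

    for i, tdeg in enumerate(thetas):
        t = math.radians(tdeg)
        for j, pdeg in enumerate(phis):
            p = math.radians(pdeg)
            pos = d * np.array([math.sin(t) * math.cos(p),
                                math.sin(t) * math.sin(p), math.cos(t)])
            sb = sb_rot + pos
            rb = rb_rot + pos
            # clash: any intermolecular atom-atom pair too close
            dd = np.linalg.norm(rb[:, :, None, :] - ra[None, None, :, :],
                                axis=3)
            ok = dd.min(axis=(1, 2), initial=np.inf) >= clash_bohr
            e = edual_batch(sa, fixed_pf.n_nu, fixed_pf.n_el, za, ra,
                            sb, mobile_bf.n_nu, mobile_bf.n_el, zb, rb)
            e[~ok] = np.inf
            if pool is not None:
                pool[i, j] = e
            k = int(np.argmin(e))
            if not np.isfinite(e[k]):
                continue
            best_q, best_e = quats[k], e[k]
            if config.refine:
                best_q, best_e = _refine_orientation(
                    fixed_pf, mobile_bf, pos, quats[k], e[k], config)
            nE[i, j] = best_e
            nQ[i, j] = best_q
    return EdualMap(thetas, phis, nE, nQ, config, fixed_pf, mobile_bf, pool)


def _quat_multiply(q1, q2):
    w1, x1, y1, z1 = q1
    w2, x2, y2, z2 = q2
    return np.array([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2])


def _rotvec_quat(v):
    a = np.linalg.norm(v)
    if a < 1e-300:
        return np.array([1.0, 0, 0, 0])
    ax = v / a
    return np.concatenate([[math.cos(a / 2)], math.sin(a / 2) * ax])


def _placed_energy(fixed_pf, mobile_bf, pos, q, clash_bohr, penalty=True):
    R = quaternion_to_matrix(q)
    sb = mobile_bf.sites @ R.T + pos
    ra = (fixed_pf.molecule.coords if fixed_pf.molecule is not None
          else np.zeros((0, 3)))
    za = fixed_pf.coulomb_charges
    rb0 = (mobile_bf.molecule.coords if mobile_bf.molecule is not None
           else np.zeros((0, 3)))
    zb = mobile_bf.coulomb_charges
    rb = rb0 @ R.T + pos
    dd = np.linalg.norm(rb[:, None, :] - ra[None], axis=2)
    mind = dd.min(initial=np.inf)
    if mind < clash_bohr:
        if not penalty:
            return np.inf
        return 10.0 + (clash_bohr - mind)
    e = edual_batch(fixed_pf.sites, fixed_pf.n_nu, fixed_pf.n_el,
                    za, ra, sb[None], mobile_bf.n_nu, mobile_bf.n_el,
                    zb, rb[None])[0]
    return e


def _refine_orientation(fixed_pf, mobile_bf, pos, q0, e0, config):
    clash_bohr = config.clash_radius * BOHR_PER_ANGSTROM

    def objective(v):
        q = _quat_multiply(_rotvec_quat(v), q0)
        q /= np.linalg.norm(q)
        return _placed_energy(fixed_pf, mobile_bf, pos, q, clash_bohr)

    res = minimize(objective, np.zeros(3), method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": config.refine_tol,
                            "maxiter": 200, "initial_simplex":
                            np.vstack([np.zeros(3), 0.15 * np.eye(3)])})
    q = _quat_multiply(_rotvec_quat(res.x), q0)
    q /= np.linalg.norm(q)
    e = _placed_energy(fixed_pf, mobile_bf, pos, q, clash_bohr,
                       penalty=False)
    if e <= e0:
        return q, e
    return q0, e0


# ---------------------------------------------------------------------------
# Stationary points
# ---------------------------------------------------------------------------

def find_stationary_points(emap, top_k=5, merge_deg=15.0):
    """Local minima of the map on the sphere (phi periodic, pole rows
    degenerate), ranked by energy and deduplicated within an angular
    tolerance (degrees of arc on the sphere)."""
    E = emap.energies
    nt, npz = E.shape
    if not np.any(np.isfinite(E)):
        raise ValueError("map has no finite cells")
    nphi = npz - 1 if abs(emap.phis[-1] - emap.phis[0] - 360.0) < 1e-9 \
        else npz
    minima = []
    for i in range(nt):
        for j in range(nphi):
            e = E[i, j]
            if not np.isfinite(e):
                continue
            if _is_local_min(E, i, j, nt, nphi):
                minima.append(StationaryPoint(
                    emap.thetas[i], emap.phis[j], float(e),
                    emap.quaternions[i, j].copy(), (i, j)))
    minima.sort(key=lambda s: s.energy)
    kept = []
    for s in minima:
        if all(_sphere_angle(s, o) > merge_deg for o in kept):
            kept.append(s)
    return kept[:top_k]


def _neighbors(i, j, nt, nphi):
    out = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            ii = i + di
            jj = (j + dj) % nphi
            if 0 <= ii < nt:
                out.append((ii, jj))
    # poles: theta row 0 / nt-1 are physically single points; compare
    # against the whole adjacent row
    if i == 1:
        out.extend((0, k) for k in range(nphi))
    if i == nt - 2:
        out.extend((nt - 1, k) for k in range(nphi))
    if i in (0, nt - 1):
        adj = 1 if i == 0 else nt - 2
        out.extend((adj, k) for k in range(nphi))
        out = [c for c in out if c[0] != i]
    return set(out)


def _is_local_min(E, i, j, nt, nphi):
    e = E[i, j]
    for (ii, jj) in _neighbors(i, j, nt, nphi):
        if E[ii, jj] < e:
            return False
    # plateau dedup: first cell (row-major) of an exactly-flat
    # neighborhood wins
    for (ii, jj) in _neighbors(i, j, nt, nphi):
        if E[ii, jj] == e and (ii, jj) < (i, j):
            return False
    return True


def _sphere_angle(a, b):
    def vec(s):
        t, p = math.radians(s.theta), math.radians(s.phi)
        return np.array([math.sin(t) * math.cos(p),
                         math.sin(t) * math.sin(p), math.cos(t)])
    c = float(np.clip(vec(a) @ vec(b), -1.0, 1.0))
    return math.degrees(math.acos(c))


# ---------------------------------------------------------------------------
# Structures, separation refinement, hydrogen bonds
# ---------------------------------------------------------------------------

def placed_pair(emap, placement):
    """(fixed Molecule, placed mobile Molecule) for a placement."""
    fixed_mol = emap.fixed.molecule
    mobile_mol = emap.mobile.molecule.transformed(
        placement.rotation, placement.translation)
    return fixed_mol, mobile_mol


def export_structure(fixed_mol, mobile_mol, path, comment=""):
    """Concatenated XYZ (angstrom), fixed molecule first."""
    n = fixed_mol.natoms + mobile_mol.natoms
    lines = [str(n), comment]
    for mol in (fixed_mol, mobile_mol):
        for s, r in zip(mol.symbols, mol.coords * ANGSTROM_PER_BOHR):
            lines.append(f"{s:<3s} {r[0]:15.8f} {r[1]:15.8f} {r[2]:15.8f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def refine_separation(emap, point, d_bounds=(3.0, 12.0)):
    """Jointly relax separation, sphere angles and orientation at a
    stationary point (rigid monomers).

    Returns (placement, energy, d_angstrom).  The monopole score has no
    repulsive wall, so the approach is limited by the clash radius; the
    optimizer works on a penalized objective and the reported energy is
    re-evaluated without penalty.
    """
    cfg = emap.config
    clash_bohr = cfg.clash_radius * BOHR_PER_ANGSTROM
    q0 = point.quaternion
    x0 = np.array([cfg.distance, point.theta, point.phi, 0.0, 0.0, 0.0])

    def build(x):
        dA, tdeg, pdeg = x[0], x[1], x[2]
        t, p = math.radians(tdeg), math.radians(pdeg)
        pos = dA * BOHR_PER_ANGSTROM * np.array(
            [math.sin(t) * math.cos(p), math.sin(t) * math.sin(p),
             math.cos(t)])
        q = _quat_multiply(_rotvec_quat(x[3:6]), q0)
        return pos, q / np.linalg.norm(q)

    def objective(x):
        if not d_bounds[0] <= x[0] <= d_bounds[1]:
            return 50.0 + abs(x[0])
        pos, q = build(x)
        return _placed_energy(emap.fixed, emap.mobile, pos, q, clash_bohr)

    simplex = np.vstack([x0] + [x0 + step for step in
                                np.diag([0.5, 5.0, 5.0, 0.1, 0.1, 0.1])])
    res = minimize(objective, x0, method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": cfg.refine_tol,
                            "maxiter": 2000, "maxfev": 4000,
                            "initial_simplex": simplex})
    pos, q = build(res.x)
    e = _placed_energy(emap.fixed, emap.mobile, pos, q, clash_bohr,
                       penalty=False)
    placement = RigidPlacement(q, pos)
    return placement, float(e), float(res.x[0])


def count_hydrogen_bonds(mol_a, mol_b, heavy_cut=3.5, angle_min=120.0,
                         hx_bond=1.25, h_acc_cut=2.5):
    """Donor-H...acceptor contacts between two molecules.

    A contact requires donor (N/O with a covalently bound H, H within
    ``hx_bond`` A) and acceptor (N/O on the other molecule), donor to
    acceptor heavy-atom distance <= ``heavy_cut`` A, a hydrogen to
    acceptor distance <= ``h_acc_cut`` A (2.5 A default), and a D-H...A angle >=
    ``angle_min`` degrees (the H...A condition suppresses the
    bifurcated secondary contacts a heavy-atom cutoff alone admits).
    Returns a list of (donor_index, hydrogen_index, acceptor_index,
    molecule_tag) with indices local to each molecule and tag "A->B" or
    "B->A".
    """
    ca = mol_a.coords * ANGSTROM_PER_BOHR
    cb = mol_b.coords * ANGSTROM_PER_BOHR
    if np.linalg.norm(ca[:, None] - cb[None], axis=2).min() < 0.5:
        raise ValueError("molecules overlap; geometry audit failed")
    out = []
    for tag, don, acc in (("A->B", mol_a, mol_b), ("B->A", mol_b, mol_a)):
        dc = don.coords * ANGSTROM_PER_BOHR
        ac = acc.coords * ANGSTROM_PER_BOHR
        for di, (ds, dr) in enumerate(zip(don.symbols, dc)):
            if ds not in ("N", "O"):
                continue
            for hi, (hs, hr) in enumerate(zip(don.symbols, dc)):
                if hs != "H" or np.linalg.norm(hr - dr) > hx_bond:
                    continue
                for ai, (asym, ar) in enumerate(zip(acc.symbols, ac)):
                    if asym not in ("N", "O"):
                        continue
                    if np.linalg.norm(ar - dr) > heavy_cut:
                        continue
                    if np.linalg.norm(ar - hr) > h_acc_cut:
                        continue
                    v1 = dr - hr
                    v2 = ar - hr
                    cosang = v1 @ v2 / (np.linalg.norm(v1)
                                        * np.linalg.norm(v2))
                    ang = math.degrees(math.acos(np.clip(cosang, -1, 1)))
                    if ang >= angle_min:
                        out.append((di, hi, ai, tag))
    return out
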