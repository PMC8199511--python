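"""Wavefunction models and pointwise density machinery.

This module owns the closed-shell single-determinant wavefunction: its
geometry, basis and molecular orbitals, and the evaluation of every
pointwise ingredient the localization fields need — the total electron
density rho, its analytic gradient, the positive-definite kinetic-energy
density tau, and the frontier (HOMO/LUMO) densities, including the
"N+1" variant in which the LUMO is populated at frozen geometry and
orbitals.

Wavefunctions come from three places: the built-in RHF backend
(`compute_wavefunction`), Molden files, or AIM wfx files
(`load_wavefunction`).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

from .basis import CART_COMPONENTS, ContractedBasis, Shell, _dfact
from .units import ATOMIC_MASSES, ATOMIC_NUMBERS, BOHR_PER_ANGSTROM

__all__ = [
    "Molecule", "WavefunctionModel", "PointEvaluation",
    "compute_wavefunction", "load_wavefunction", "write_molden", "evaluate",
    "evaluate_many",
    "FormatError", "UnsupportedSystemError", "NoVirtualOrbitalError",
    "MissingEngineError", "DENSITY_FLOOR",
]

# Points where rho_N falls below this are treated as vacuum by the field
# builders (avoids 0/0 in the frontier weight x(r)).
DENSITY_FLOOR = 1e-12


class FormatError(ValueError):
    """A wavefunction file could not be parsed."""


class UnsupportedSystemError(ValueError):
    """Open-shell or otherwise unsupported electronic structure."""


class NoVirtualOrbitalError(ValueError):
    """An operation needed a LUMO but the model carries no virtuals."""


class MissingEngineError(RuntimeError):
    """An optional external quantum-chemistry engine is not installed."""


# ---------------------------------------------------------------------------
# Molecule
# ---------------------------------------------------------------------------

@dataclass
class Molecule:
    """A molecular geometry with nuclear charges, in bohr.

    ``charge`` is the total molecular charge; ``multiplicity`` must be 1
    (the whole package is closed-shell only).
    """
    symbols: tuple
    coords: np.ndarray
    charges: np.ndarray = None
    charge: int = 0
    multiplicity: int = 1

    def __post_init__(self):
        self.symbols = tuple(self.symbols)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.charges is None:
            self.charges = np.array(
                [ATOMIC_NUMBERS[s] for s in self.symbols], dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        if not (len(self.symbols) == len(self.coords) == len(self.charges)):
            raise ValueError("symbols, coords and charges lengths differ")
        if len(self.symbols) == 0:
            raise ValueError("empty molecule")
        if np.any(self.charges < 1) or np.any(
                np.abs(self.charges - np.round(self.charges)) > 1e-12):
            raise ValueError("nuclear charges must be positive integers")
        if self.multiplicity != 1:
            raise UnsupportedSystemError(
                "only closed-shell singlets are supported")

    @property
    def natoms(self):
        return len(self.symbols)

    @property
    def nelec(self):
        return int(round(self.charges.sum())) - self.charge

    def masses(self):
        return np.array([ATOMIC_MASSES[int(z)] for z in self.charges])

    def center_of_mass(self):
        m = self.masses()
        return m @ self.coords / m.sum()

    def translated(self, shift):
        return Molecule(self.symbols, self.coords + np.asarray(shift),
                        self.charges.copy(), self.charge, self.multiplicity)

    def transformed(self, rotation, translation):
        """Rigidly move the molecule: r -> R r + t (bohr)."""
        R = np.asarray(rotation, float)
        return Molecule(self.symbols, self.coords @ R.T + translation,
                        self.charges.copy(), self.charge, self.multiplicity)

    # -- XYZ interface (angstrom) ------------------------------------------
    @classmethod
    def from_xyz_string(cls, text, charge=0, multiplicity=1):
        lines = text.strip().splitlines()
        n = int(lines[0].split()[0])
        syms, xyz = [], []
        for ln in lines[2:2 + n]:
            parts = ln.split()
            syms.append(parts[0])
            xyz.append([float(v) for v in parts[1:4]])
        return cls(syms, np.array(xyz) * BOHR_PER_ANGSTROM,
                   charge=charge, multiplicity=multiplicity)

    @classmethod
    def from_xyz(cls, path, **kw):
        with open(path) as fh:
            return cls.from_xyz_string(fh.read(), **kw)

    def to_xyz_string(self, comment=""):
        out = [str(self.natoms), comment]
        for s, r in zip(self.symbols, self.coords / BOHR_PER_ANGSTROM):
            out.append(f"{s:<3s} {r[0]:15.8f} {r[1]:15.8f} {r[2]:15.8f}")
        return "\n".join(out) + "\n"

    def to_xyz(self, path, comment=""):
        with open(path, "w") as fh:
            fh.write(self.to_xyz_string(comment))


# ---------------------------------------------------------------------------
# WavefunctionModel
# ---------------------------------------------------------------------------

class WavefunctionModel:
    """Closed-shell wavefunction: geometry + Cartesian-Gaussian MOs.

    The MO coefficient matrix is always expressed over an internal
    Cartesian contracted basis (spherical-harmonic input bases are
    transformed on load).  Frontier orbitals within
    ``degeneracy_threshold`` hartree of the HOMO (LUMO) energy are
    treated as a degenerate set and their densities averaged.
    """

    def __init__(self, molecule, basis, mo_coeff, mo_occ, mo_energy,
                 degeneracy_threshold=1e-5, scf_energy=None):
        self.molecule = molecule
        self.basis = basis
        self.mo_coeff = np.asarray(mo_coeff, float)
        self.mo_occ = np.asarray(mo_occ, float)
        self.mo_energy = np.asarray(mo_energy, float)
        self.degeneracy_threshold = degeneracy_threshold
        self.scf_energy = scf_energy
        if not np.all((np.abs(self.mo_occ) < 1e-12)
                      | (np.abs(self.mo_occ - 2.0) < 1e-12)):
            raise UnsupportedSystemError(
                "occupations must be 0 or 2 (closed shell)")
        self.mo_occ = np.round(self.mo_occ)
        if not np.any(self.mo_occ > 0):
            raise ValueError("no occupied orbitals")

    @property
    def nelec(self):
        return int(round(self.mo_occ.sum()))

    @property
    def homo(self):
        """0-based index of the highest occupied MO."""
        return int(np.max(np.nonzero(self.mo_occ > 0)[0]))

    @property
    def lumo(self):
        """0-based index of the lowest unoccupied MO."""
        i = self.homo + 1
        if i >= self.mo_coeff.shape[1]:
            raise NoVirtualOrbitalError(
                "wavefunction carries no virtual orbitals (no LUMO)")
        return i

    def frontier_indices(self, side):
        """Indices of the (possibly degenerate) HOMO or LUMO set."""
        if side == "HOMO":
            ref = self.mo_energy[self.homo]
            pool = np.nonzero(self.mo_occ > 0)[0]
        elif side == "LUMO":
            ref = self.mo_energy[self.lumo]
            pool = np.arange(self.homo + 1, self.mo_coeff.shape[1])
        else:
            raise ValueError(side)
        sel = pool[np.abs(self.mo_energy[pool] - ref)
                   < self.degeneracy_threshold]
        return sel if len(sel) else np.array([self.homo if side == "HOMO"
                                              else self.lumo])


# ---------------------------------------------------------------------------
# Pointwise evaluation
# ---------------------------------------------------------------------------

@dataclass
class PointEvaluation:
    """rho, grad(rho) and tau of one density variant at a point set.

    Units: rho in e/bohr^3, tau in hartree/bohr^3 (positive-definite
    convention tau = 1/2 sum_i w_i |grad phi_i|^2).
    """
    points: np.ndarray
    rho: np.ndarray
    grad: np.ndarray
    tau: np.ndarray
    variant: str


def _eval_basis_chunk(basis, pts):
    """Values and gradients of every contracted basis function at pts."""
    n = len(pts)
    vals = np.empty((n, basis.nbf))
    grads = np.empty((3, n, basis.nbf))
    for i in range(basis.nbf):
        d = pts - basis.centers[i]
        r2 = np.einsum("ij,ij->i", d, d)
        s0 = np.zeros(n)
        s1 = np.zeros(n)
        for p in range(basis.pstart[i], basis.pstart[i] + basis.nprim[i]):
            e = basis.coefs[p] * np.exp(-basis.exps[p] * r2)
            s0 += e
            s1 += basis.exps[p] * e
        l, m, nn = basis.lmn[i]
        px = d[:, 0] ** l if l else 1.0
        py = d[:, 1] ** m if m else 1.0
        pz = d[:, 2] ** nn if nn else 1.0
        poly = px * py * pz
        vals[:, i] = poly * s0
        powers = (l, m, nn)
        axes = (px, py, pz)
        for ax in range(3):
            k = powers[ax]
            dk = d[:, ax]
            rest = 1.0
            for j in range(3):
                if j != ax:
                    rest = rest * axes[j]
            lower = k * dk ** (k - 1) if k else 0.0
            grads[ax, :, i] = lower * rest * s0 - 2.0 * dk * poly * s1
    return vals, grads


def _variant_weights(wf, variant, fukui_normalization):
    """(orbital indices, weights) defining one density variant."""
    unit = fukui_normalization == "unit"
    if variant == "N":
        idx = np.nonzero(wf.mo_occ > 0)[0]
        return idx, wf.mo_occ[idx]
    if variant == "HOMO":
        idx = wf.frontier_indices("HOMO")
        w = (1.0 if unit else 2.0) / len(idx)
        return idx, np.full(len(idx), w)
    if variant == "LUMO":
        idx = wf.frontier_indices("LUMO")
        w = (1.0 if unit else 2.0) / len(idx)
        return idx, np.full(len(idx), w)
    if variant == "N+1":
        i1, w1 = _variant_weights(wf, "N", fukui_normalization)
        i2, w2 = _variant_weights(wf, "LUMO", fukui_normalization)
        return np.concatenate([i1, i2]), np.concatenate([w1, w2])
    raise ValueError(f"unknown variant {variant!r}")


def evaluate_many(wf, points, variants, fukui_normalization="unit",
                  chunk=20000):
    """Evaluate several density variants sharing one basis evaluation.

    Returns a dict variant -> PointEvaluation.
    """
    pts = np.asarray(points, float).reshape(-1, 3)
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite coordinates in point set")
    sel = {v: _variant_weights(wf, v, fukui_normalization)
           for v in variants}
    all_idx = np.unique(np.concatenate([idx for idx, _ in sel.values()]))
    pos = {int(i): k for k, i in enumerate(all_idx)}
    C = wf.mo_coeff[:, all_idx]
    n = len(pts)
    out = {v: PointEvaluation(pts, np.empty(n), np.empty((n, 3)),
                              np.empty(n), v) for v in variants}
    for a in range(0, n, chunk):
        b = min(a + chunk, n)
        vals, grads = _eval_basis_chunk(wf.basis, pts[a:b])
        phi = vals @ C                      # (nc, norb)
        dphi = np.stack([grads[ax] @ C for ax in range(3)])
        for v, (idx, w) in sel.items():
            cols = np.array([pos[int(i)] for i in idx])
            p = phi[:, cols]
            d = dphi[:, :, cols]
            out[v].rho[a:b] = np.einsum("po,o->p", p * p, w)
            for ax in range(3):
                out[v].grad[a:b, ax] = 2.0 * np.einsum(
                    "po,o->p", p * d[ax], w)
            out[v].tau[a:b] = 0.5 * np.einsum("xpo,o->p", d * d, w)
    return out


def evaluate(wf, points, variant="N", fukui_normalization="unit",
             chunk=20000):
    """Evaluate rho, grad(rho), tau of a density variant at points (bohr).

    ``variant`` is one of ``N`` (ground-state density), ``HOMO`` /
    ``LUMO`` (frontier Fukui densities, unit-normalized by default) or
    ``N+1`` (ground state plus the LUMO density, frozen orbitals).
    """
    return evaluate_many(wf, points, [variant], fukui_normalization,
                         chunk)[variant]


# ---------------------------------------------------------------------------
# Built-in / external computation
# ---------------------------------------------------------------------------

def mulliken_charges(wf):
    """Net atomic charges q_A = Z_A - (D S)_AA (Mulliken condensation).

    These are the atomic monopoles of the neutral molecular frame: the
    nuclear charge screened by the ground-state electron population
    assigned to the atom.
    """
    from .integrals import _one_electron
    b = wf.basis
    Z = np.asarray(wf.molecule.charges, float)
    S, _, _ = _one_electron(b.nbf, b.lmn, b.centers, b.nprim, b.pstart,
                            b.exps, b.coefs, np.zeros(0),
                            np.zeros((0, 3)))
    D = (wf.mo_coeff * wf.mo_occ) @ wf.mo_coeff.T
    diag = np.diag(D @ S)
    pops = np.array([diag[b.bf_atom == a].sum()
                     for a in range(wf.molecule.natoms)])
    return Z - pops


def compute_wavefunction(molecule, method="hf", basis="sto-3g",
                         scf_convergence=1e-9, degeneracy_threshold=1e-5):
    """Compute a closed-shell wavefunction for a molecule.

    ``method='hf'`` uses the built-in RHF backend.  Any other method
    string requires the optional external engine (pyscf); a clear
    dependency error is raised when it is absent.
    """
    if method.lower() in ("hf", "rhf", "scf"):
        from .scf import rhf
        res = rhf(molecule, basis_name=basis, conv_tol=scf_convergence)
        return WavefunctionModel(molecule, res.basis, res.mo_coeff,
                                 res.mo_occ, res.mo_energy,
                                 degeneracy_threshold=degeneracy_threshold,
                                 scf_energy=res.energy)
    try:
        import pyscf  # noqa: F401
    except ImportError as exc:
        raise MissingEngineError(
            f"method {method!r} requires the optional external "
            "quantum-chemistry engine (pyscf), which is not installed; "
            "the built-in backend provides method='hf'") from exc
    return _pyscf_wavefunction(molecule, method, basis, scf_convergence,
                               degeneracy_threshold)


def _pyscf_wavefunction(molecule, method, basis, conv, degeneracy_threshold):
    # optional hook; exercised only when pyscf is installed
    import tempfile

    from pyscf import dft, gto
    from pyscf.tools import molden as pyscf_molden
    mol = gto.M(atom=[(s, tuple(r)) for s, r in
                      zip(molecule.symbols, molecule.coords)],
                unit="Bohr", basis=basis, charge=molecule.charge, spin=0)
    mf = dft.RKS(mol)
    mf.xc = method
    mf.conv_tol = conv
    mf.kernel()
    if not mf.converged:
        raise RuntimeError("external SCF did not converge")
    with tempfile.NamedTemporaryFile(suffix=".molden", mode="w",
                                     delete=False) as fh:
        pyscf_molden.from_scf(mf, fh.name)
        return _load_molden(fh.name, degeneracy_threshold)


# ---------------------------------------------------------------------------
# Cartesian <-> spherical transformation (for Molden input)
# ---------------------------------------------------------------------------

_C2S_CACHE = {}


def _real_sph(l, m, theta, phi):
    from scipy.special import sph_harm_y
    if m == 0:
        return np.real(sph_harm_y(l, 0, theta, phi))
    y = sph_harm_y(l, abs(m), theta, phi)
    if m > 0:
        return math.sqrt(2.0) * (-1.0) ** m * np.real(y)
    return math.sqrt(2.0) * (-1.0) ** abs(m) * np.imag(y)


def cart_to_sph_matrix(l):
    """Matrix M ((2l+1) x ncart): spherical functions (Molden m-order
    0,+1,-1,+2,-2,...) as combinations of *normalized* Cartesian
    components (Molden Cartesian order)."""
    if l in _C2S_CACHE:
        return _C2S_CACHE[l]
    comps = CART_COMPONENTS[l]
    # deterministic quasi-uniform directions
    k = np.arange(64 + 32 * l)
    z = 1.0 - 2.0 * (k + 0.5) / len(k)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    theta = np.arccos(np.clip(z, -1, 1))
    xs = np.sin(theta) * np.cos(phi)
    ys = np.sin(theta) * np.sin(phi)
    zs = np.cos(theta)
    A = np.empty((len(k), len(comps)))
    for i, (a, b, c) in enumerate(comps):
        df = _dfact(2 * a - 1) * _dfact(2 * b - 1) * _dfact(2 * c - 1)
        A[:, i] = xs ** a * ys ** b * zs ** c / math.sqrt(df)
    morder = [0]
    for m in range(1, l + 1):
        morder.extend([m, -m])
    # overlap metric of normalized Cartesian components (same exponent)
    G = np.empty((len(comps), len(comps)))
    for i, ci in enumerate(comps):
        for j, cj in enumerate(comps):
            ss = [ci[t] + cj[t] for t in range(3)]
            if any(s % 2 for s in ss):
                G[i, j] = 0.0
                continue
            num = _dfact(ss[0] - 1) * _dfact(ss[1] - 1) * _dfact(ss[2] - 1)
            den = math.sqrt(
                _dfact(2 * ci[0] - 1) * _dfact(2 * ci[1] - 1)
                * _dfact(2 * ci[2] - 1) * _dfact(2 * cj[0] - 1)
                * _dfact(2 * cj[1] - 1) * _dfact(2 * cj[2] - 1))
            G[i, j] = num / den
    M = np.empty((2 * l + 1, len(comps)))
    for row, m in enumerate(morder):
        target = _real_sph(l, m, theta, phi)
        w, *_ = np.linalg.lstsq(A, target, rcond=None)
        w[np.abs(w) < 1e-12] = 0.0
        M[row] = w / math.sqrt(w @ G @ w)
    _C2S_CACHE[l] = M
    return M


# ---------------------------------------------------------------------------
# Molden writer / reader
# ---------------------------------------------------------------------------

_SHELL_LETTERS = {0: "s", 1: "p", 2: "d", 3: "f"}
_SHELL_L = {v: k for k, v in _SHELL_LETTERS.items()}


def write_molden(wf, path):
    """Write a Cartesian-basis Molden file (AU geometry)."""
    mol = wf.molecule
    lines = ["[Molden Format]", "[Title]", "elfx wavefunction", "[Atoms] AU"]
    for i, (s, z, r) in enumerate(zip(mol.symbols, mol.charges, mol.coords)):
        lines.append(f"{s:<3s} {i + 1:4d} {int(z):4d} "
                     f"{r[0]:18.10f} {r[1]:18.10f} {r[2]:18.10f}")
    lines.append("[GTO]")
    by_atom = {}
    for sh in wf.basis.shells:
        by_atom.setdefault(sh.atom_index, []).append(sh)
    for ai in range(mol.natoms):
        lines.append(f"{ai + 1} 0")
        for sh in by_atom.get(ai, []):
            lines.append(f" {_SHELL_LETTERS[sh.l]}  {len(sh.exps)} 1.00")
            for a, c in zip(sh.exps, sh.coefs):
                lines.append(f"  {a:20.10e} {c:20.10e}")
        lines.append("")
    lines.append("[MO]")
    for i in range(wf.mo_coeff.shape[1]):
        lines.append(" Sym= A")
        lines.append(f" Ene= {wf.mo_energy[i]:.10f}")
        lines.append(" Spin= Alpha")
        lines.append(f" Occup= {wf.mo_occ[i]:.6f}")
        for j in range(wf.mo_coeff.shape[0]):
            lines.append(f" {j + 1:4d} {wf.mo_coeff[j, i]:20.12e}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_molden(text):
    sections = {}
    current = None
    flags = set()
    for raw in text.splitlines():
        line = raw.strip()
        m = re.match(r"\[([^\]]+)\]\s*(.*)", line)
        if m:
            name = m.group(1).strip().lower()
            if name in ("5d", "7f", "5d7f", "5d10f", "9g"):
                flags.add(name)
                continue
            current = name
            sections[current] = {"header": m.group(2).strip(), "lines": []}
            continue
        if current is not None and line:
            sections[current]["lines"].append(raw)
    return sections, flags


def _load_molden(path, degeneracy_threshold):
    with open(path) as fh:
        text = fh.read()
    sections, flags = _parse_molden(text)
    if "atoms" not in sections or "gto" not in sections or "mo" not in sections:
        raise FormatError(f"{path}: missing [Atoms]/[GTO]/[MO] section")
    unit = sections["atoms"]["header"].lower()
    scale = 1.0 if unit.startswith("au") else BOHR_PER_ANGSTROM
    syms, charges, coords = [], [], []
    for ln in sections["atoms"]["lines"]:
        parts = ln.split()
        syms.append(parts[0])
        charges.append(float(parts[2]))
        coords.append([float(v) * scale for v in parts[3:6]])
    molecule = Molecule(syms, np.array(coords), np.array(charges))

    sph_d = bool({"5d", "5d7f", "5d10f"} & flags)
    sph_f = bool({"7f", "5d7f"} & flags) or ("5d" in flags)
    if "5d10f" in flags:
        sph_f = False

    shells = []
    lines = sections["gto"]["lines"]
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if not parts:
            i += 1
            continue
        atom_idx = int(parts[0]) - 1
        i += 1
        while i < len(lines):
            parts = lines[i].split()
            if not parts:
                i += 1
                break
            if parts[0].lower() not in _SHELL_L and parts[0].lower() != "sp":
                break  # next atom header
            letter = parts[0].lower()
            nprim = int(parts[1])
            exps, c1, c2 = [], [], []
            for p in range(nprim):
                i += 1
                vals = [float(v.replace("D", "e").replace("d", "e"))
                        for v in lines[i].split()]
                exps.append(vals[0])
                c1.append(vals[1])
                if letter == "sp":
                    c2.append(vals[2])
            i += 1
            center = molecule.coords[atom_idx]
            if letter == "sp":
                shells.append(Shell(0, center, np.array(exps),
                                    np.array(c1), atom_idx))
                shells.append(Shell(1, center, np.array(exps),
                                    np.array(c2), atom_idx))
            else:
                shells.append(Shell(_SHELL_L[letter], center,
                                    np.array(exps), np.array(c1), atom_idx))
    basis = ContractedBasis.from_shells(shells)

    # per-shell count of coefficients as stored in the file
    blocks = []  # (n_file_funcs, transform or None)
    for sh in shells:
        sph = (sh.l == 2 and sph_d) or (sh.l == 3 and sph_f)
        if sph:
            blocks.append((2 * sh.l + 1, cart_to_sph_matrix(sh.l)))
        else:
            blocks.append((len(CART_COMPONENTS[sh.l]), None))
    nfile = sum(b[0] for b in blocks)

    mo_lines = sections["mo"]["lines"]
    energies, occs, coeff_cols = [], [], []
    cur = None
    for ln in mo_lines:
        s = ln.strip()
        low = s.lower()
        if low.startswith("ene="):
            if cur is not None:
                coeff_cols.append(cur)
            energies.append(float(s.split("=")[1]))
            cur = np.zeros(nfile)
        elif low.startswith("occup="):
            occs.append(float(s.split("=")[1]))
        elif low.startswith(("sym=", "spin=")):
            if low.startswith("spin=") and "beta" in low:
                raise UnsupportedSystemError(
                    f"{path}: beta spin block found; closed-shell only")
        else:
            parts = s.split()
            if len(parts) == 2 and cur is not None:
                cur[int(parts[0]) - 1] = float(parts[1])
    if cur is not None:
        coeff_cols.append(cur)
    if not coeff_cols:
        raise FormatError(f"{path}: no MO coefficients found")
    C_file = np.array(coeff_cols).T          # (nfile, nmo)

    # expand file rows (possibly spherical) into Cartesian rows
    C = np.zeros((basis.nbf, C_file.shape[1]))
    fpos = 0
    cpos = 0
    for (nf, M), sh in zip(blocks, shells):
        nc = len(CART_COMPONENTS[sh.l])
        blk = C_file[fpos:fpos + nf]
        if M is None:
            C[cpos:cpos + nc] = blk
        else:
            C[cpos:cpos + nc] = M.T @ blk
        fpos += nf
        cpos += nc
    occs = np.array(occs)
    if np.any((occs > 1e-12) & (np.abs(occs - 2.0) > 1e-6)):
        raise UnsupportedSystemError(
            f"{path}: fractional/odd occupations; closed-shell only")
    return WavefunctionModel(molecule, basis, C, np.round(occs),
                             np.array(energies),
                             degeneracy_threshold=degeneracy_threshold)


# ---------------------------------------------------------------------------
# wfx reader
# ---------------------------------------------------------------------------

_WFX_TYPES = {1: (0, 0, 0),
              2: (1, 0, 0), 3: (0, 1, 0), 4: (0, 0, 1),
              5: (2, 0, 0), 6: (0, 2, 0), 7: (0, 0, 2),
              8: (1, 1, 0), 9: (1, 0, 1), 10: (0, 1, 1),
              11: (3, 0, 0), 12: (0, 3, 0), 13: (0, 0, 3),
              14: (2, 1, 0), 15: (2, 0, 1), 16: (0, 2, 1),
              17: (1, 2, 0), 18: (1, 0, 2), 19: (0, 1, 2),
              20: (1, 1, 1)}


def _wfx_tag(text, name, path):
    m = re.search(rf"<{re.escape(name)}>(.*?)</{re.escape(name)}>",
                  text, re.S)
    if not m:
        raise FormatError(f"{path}: wfx tag <{name}> missing")
    return m.group(1)


def _load_wfx(path, degeneracy_threshold):
    with open(path) as fh:
        text = fh.read()
    syms = _wfx_tag(text, "Nuclear Names", path).split()
    Z = [float(v) for v in _wfx_tag(text, "Atomic Numbers", path).split()]
    xyz = np.array([float(v) for v in _wfx_tag(
        text, "Nuclear Cartesian Coordinates", path).split()]).reshape(-1, 3)
    syms = [re.sub(r"\d+$", "", s) for s in syms]
    molecule = Molecule(syms, xyz, np.array(Z))
    centers = [int(v) - 1 for v in
               _wfx_tag(text, "Primitive Centers", path).split()]
    ptypes = [int(v) for v in
              _wfx_tag(text, "Primitive Types", path).split()]
    exps = np.array([float(v.replace("D", "e").replace("d", "e")) for v in
                     _wfx_tag(text, "Primitive Exponents", path).split()])
    occs = np.array([float(v) for v in _wfx_tag(
        text, "Molecular Orbital Occupation Numbers", path).split()])
    enes = np.array([float(v) for v in _wfx_tag(
        text, "Molecular Orbital Energies", path).split()])
    if np.any((occs > 1e-12) & (np.abs(occs - 2.0) > 1e-6)):
        raise UnsupportedSystemError(f"{path}: closed-shell only")
    coef_block = _wfx_tag(text, "Molecular Orbital Primitive Coefficients",
                          path)
    coef_block = re.sub(r"<MO Number>.*?</MO Number>", " ", coef_block,
                        flags=re.S)
    coefs = np.array([float(v.replace("D", "e").replace("d", "e"))
                      for v in coef_block.split()])
    nprim = len(exps)
    nmo = len(occs)
    if len(coefs) != nprim * nmo:
        raise FormatError(f"{path}: coefficient count mismatch "
                          f"({len(coefs)} != {nprim}x{nmo})")
    C = coefs.reshape(nmo, nprim).T
    lmn = np.array([_WFX_TYPES[t] for t in ptypes], dtype=np.int64)
    cen = np.array([molecule.coords[c] for c in centers])
    basis = ContractedBasis.raw_primitives(lmn, cen, exps,
                                           [centers[i] for i in
                                            range(nprim)])
    return WavefunctionModel(molecule, basis, C, occs, enes,
                             degeneracy_threshold=degeneracy_threshold)


def load_wavefunction(path, format=None, degeneracy_threshold=1e-5):
    """Load a wavefunction from a Molden or AIM wfx file.

    ``format`` is inferred from the extension when omitted.
    """
    if format is None:
        p = str(path).lower()
        format = "wfx" if p.endswith(".wfx") else "molden"
    if format == "molden":
        return _load_molden(path, degeneracy_threshold)
    if format == "wfx":
        return _load_wfx(path, degeneracy_threshold)
    raise FormatError(f"unsupported wavefunction format {format!r}")
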