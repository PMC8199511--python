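"""Restricted Hartree–Fock backend.

A deliberately small closed-shell RHF solver (core-Hamiltonian guess,
DIIS acceleration) over the in-package Gaussian integrals.  It exists so
that frontier-orbital fields for the built-in fixture molecules can be
produced without any external quantum-chemistry engine; it is not a
general-purpose electronic-structure code.
"""

from __future__ import annotations

import numpy as np

from .basis import build_basis
from .integrals import build_integrals

__all__ = ["SCFResult", "rhf", "SCFConvergenceError"]


class SCFConvergenceError(RuntimeError):
    """Raised when the SCF iterations fail to converge; carries the
    per-iteration energy log in ``iterations``."""

    def __init__(self, message, iterations):
        super().__init__(message)
        self.iterations = iterations


class SCFResult:
    """Converged RHF solution.

    Attributes
    ----------
    energy : float
        Total electronic + nuclear-repulsion energy (hartree).
    mo_coeff : (nbf, nmo) ndarray
        MO coefficients over the Cartesian contracted basis.
    mo_energy : (nmo,) ndarray
    mo_occ : (nmo,) ndarray of 0.0 / 2.0
    basis : ContractedBasis
    """

    def __init__(self, energy, mo_coeff, mo_energy, mo_occ, basis,
                 converged, iterations):
        self.energy = energy
        self.mo_coeff = mo_coeff
        self.mo_energy = mo_energy
        self.mo_occ = mo_occ
        self.basis = basis
        self.converged = converged
        self.iterations = iterations


def nuclear_repulsion(molecule):
    Z = np.asarray(molecule.charges, float)
    R = np.asarray(molecule.coords, float)
    e = 0.0
    for i in range(len(Z)):
        for j in range(i):
            e += Z[i] * Z[j] / np.linalg.norm(R[i] - R[j])
    return e


def rhf(molecule, basis_name="sto-3g", conv_tol=1e-9, max_cycles=200,
        diis_size=8):
    """Solve closed-shell RHF for a molecule.

    Parameters
    ----------
    molecule : Molecule
        Must be a singlet with an even electron count.
    basis_name : str
        Name understood by `elfx.basis.build_basis`.
    conv_tol : float
        Convergence threshold on the energy change and on the DIIS
        error norm (hartree).
    """
    if molecule.multiplicity != 1:
        raise ValueError("built-in RHF backend is closed-shell only")
    nelec = int(round(sum(molecule.charges))) - molecule.charge
    if nelec % 2 != 0:
        raise ValueError(f"odd electron count {nelec}: closed-shell only")
    nocc = nelec // 2

    basis = build_basis(molecule, basis_name)
    S, T, V, eri = build_integrals(basis, molecule)
    H = T + V
    e_nuc = nuclear_repulsion(molecule)

    # symmetric orthogonalisation, dropping near-dependent combinations
    w, U = np.linalg.eigh(S)
    keep = w > 1e-10
    X = U[:, keep] / np.sqrt(w[keep])

    def solve_fock(F):
        Fp = X.T @ F @ X
        eps, Cp = np.linalg.eigh(Fp)
        return eps, X @ Cp

    eps, C = solve_fock(H)
    D = 2.0 * C[:, :nocc] @ C[:, :nocc].T

    diis_F, diis_err = [], []
    log = []
    e_old = 0.0
    converged = False
    for cycle in range(max_cycles):
        J = np.einsum("pqrs,rs->pq", eri, D, optimize=True)
        K = np.einsum("prqs,rs->pq", eri, D, optimize=True)
        F = H + J - 0.5 * K
        e_elec = 0.5 * np.sum(D * (H + F))
        err = F @ D @ S - S @ D @ F
        err_norm = np.max(np.abs(err))
        log.append((cycle, e_elec + e_nuc, err_norm))

        if abs(e_elec + e_nuc - e_old) < conv_tol and err_norm < 1e-6:
            converged = True
            break
        e_old = e_elec + e_nuc

        diis_F.append(F)
        diis_err.append(X.T @ err @ X)
        if len(diis_F) > diis_size:
            diis_F.pop(0)
            diis_err.pop(0)
        if len(diis_F) >= 2:
            n = len(diis_F)
            B = np.empty((n + 1, n + 1))
            B[-1, :] = -1.0
            B[:, -1] = -1.0
            B[-1, -1] = 0.0
            for i in range(n):
                for j in range(n):
                    B[i, j] = np.sum(diis_err[i] * diis_err[j])
            rhs = np.zeros(n + 1)
            rhs[-1] = -1.0
            try:
                c = np.linalg.solve(B, rhs)[:n]
                F = sum(ci * Fi for ci, Fi in zip(c, diis_F))
            except np.linalg.LinAlgError:
                pass

        eps, C = solve_fock(F)
        D = 2.0 * C[:, :nocc] @ C[:, :nocc].T

    if not converged:
        raise SCFConvergenceError(
            f"RHF did not converge in {max_cycles} cycles "
            f"(last dE={log[-1][1] - log[-2][1]:.3e})", log)

    occ = np.zeros(C.shape[1])
    occ[:nocc] = 2.0
    return SCFResult(e_elec + e_nuc, C, eps, occ, basis, converged, log)
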