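"""Localization fields on rectilinear grids.

Builds the ELF kernel chi = (tau - |grad rho|^2 / 8 rho) / (c_F rho^{5/3}),
the Lorentzian map ELF = 1/(1+chi^2), and the frontier-weighted variant
ELF_x in which the kernel is divided by 2x(r), with

    x = rho_HOMO / rho_N          (nucleophilic side)
    x = rho_LUMO / rho_{N+1}      (electrophilic side)

On the electrophilic side the kernel itself is built consistently from
rho_{N+1} and tau_{N+1} (ground-state orbitals plus the LUMO at frozen
geometry).  Fields travel as Gaussian cube files.

Conventions: points with rho below the density floor are vacuum and all
fields are set to 0 there (not 1), so no spurious far-field attractors
can form; the Pauli kinetic term is clamped to 0 when it dips below
-1e-10 from round-off.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .units import BOHR_PER_ANGSTROM, C_FERMI, SYMBOLS
from .wavefunction import DENSITY_FLOOR, Molecule, evaluate, evaluate_many

__all__ = ["ScalarFieldGrid", "make_grid", "elf_kernel", "elf_from_kernel",
           "elfx_field", "write_cube", "read_cube", "CubeParseError",
           "X_FLOOR"]

# below this frontier weight the ELF_x value is defined as 0
X_FLOOR = 1e-10

# Pauli kinetic term round-off clamp
_KED_EPS = 1e-10


class CubeParseError(ValueError):
    def __init__(self, path, lineno, message):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


@dataclass
class ScalarFieldGrid:
    """One scalar field on an axis-aligned rectilinear grid (bohr).

    ``values`` has shape (nx, ny, nz); node (i,j,k) sits at
    origin + i*axes[0] + j*axes[1] + k*axes[2].
    """
    origin: np.ndarray
    axes: np.ndarray            # (3,3) axis step vectors
    values: np.ndarray
    tag: str = "rho"
    variant: str = "N"

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float)
        self.axes = np.asarray(self.axes, float).reshape(3, 3)
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if self.tag in ("elf", "elf_x"):
            if self.values.min() < 0.0 or self.values.max() > 1.0:
                raise ValueError(f"{self.tag} values outside [0, 1]")
        if self.tag in ("chi", "chi_x") and self.values.min() < 0.0:
            raise ValueError(f"{self.tag} values must be >= 0")

    @property
    def shape(self):
        return self.values.shape

    @property
    def voxel_volume(self):
        return abs(np.linalg.det(self.axes))

    def points(self):
        """All node coordinates, shape (nx*ny*nz, 3), C order."""
        nx, ny, nz = self.values.shape
        i, j, k = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                              indexing="ij")
        idx = np.stack([i.ravel(), j.ravel(), k.ravel()], axis=1)
        return self.origin + idx @ self.axes

    def node_position(self, index):
        return self.origin + np.asarray(index, float) @ self.axes

    def integral(self):
        return self.values.sum() * self.voxel_volume

    def congruent(self, other):
        return (self.values.shape == other.values.shape
                and np.allclose(self.origin, other.origin, atol=1e-10)
                and np.allclose(self.axes, other.axes, atol=1e-10))

    def with_values(self, values, tag=None, variant=None):
        return replace(self, values=values,
                       tag=self.tag if tag is None else tag,
                       variant=self.variant if variant is None else variant)


def make_grid(molecule, spacing=0.2, margin=5.0):
    """Axis-aligned grid geometry enclosing all nuclei plus a margin.

    ``spacing`` and ``margin`` are in bohr.  Returns an empty
    ScalarFieldGrid (zero values) carrying the geometry.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if margin < 0:
        raise ValueError("margin must be >= 0")
    lo = molecule.coords.min(axis=0) - margin
    hi = molecule.coords.max(axis=0) + margin
    counts = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 2)
    axes = np.eye(3) * spacing
    return ScalarFieldGrid(lo, axes, np.zeros(counts), tag="rho")


def elf_kernel(evaluation):
    """ELF kernel chi from a PointEvaluation (any density variant).

    Vacuum points (rho below the density floor) get chi = 0 by
    convention.
    """
    rho = evaluation.rho
    live = rho > DENSITY_FLOOR
    chi = np.zeros_like(rho)
    g2 = np.einsum("ij,ij->i", evaluation.grad, evaluation.grad)
    pauli = evaluation.tau[live] - g2[live] / (8.0 * rho[live])
    pauli = np.where((pauli < 0) & (pauli > -_KED_EPS), 0.0, pauli)
    chi[live] = pauli / (C_FERMI * rho[live] ** (5.0 / 3.0))
    return chi


def elf_from_kernel(chi):
    """Lorentzian localization map ELF = 1 / (1 + chi^2)."""
    chi = np.asarray(chi, float)
    if np.any(chi < 0):
        raise ValueError("ELF kernel must be non-negative")
    return 1.0 / (1.0 + chi * chi)


def elfx_field(wf, grid, side, fukui_normalization="unit",
               return_fukui=False):
    """Build the frontier-weighted localization field ELF_x on a grid.

    Parameters
    ----------
    wf : WavefunctionModel
    grid : ScalarFieldGrid
        Geometry template (values ignored).
    side : {"nucleophilic", "electrophilic"}
        Nucleophilic uses the HOMO weight over the N-electron kernel;
        electrophilic uses the LUMO weight with the kernel built from
        the N+1 density and kinetic-energy density.
    return_fukui : bool
        Also return the matching frontier (Fukui) density on the grid.

    Returns
    -------
    ScalarFieldGrid (tag ``elf_x``), optionally plus the Fukui density
    grid (tag ``rho``, variant HOMO/LUMO).
    """
    if side not in ("nucleophilic", "electrophilic"):
        raise ValueError(f"side must be nucleophilic/electrophilic, "
                         f"got {side!r}")
    pts = grid.points()
    if side == "nucleophilic":
        evs = evaluate_many(wf, pts, ["N", "HOMO"], fukui_normalization)
        base, front = evs["N"], evs["HOMO"]
    else:
        evs = evaluate_many(wf, pts, ["N+1", "LUMO"], fukui_normalization)
        base, front = evs["N+1"], evs["LUMO"]
    chi = elf_kernel(base)
    live = base.rho > DENSITY_FLOOR
    x = np.zeros_like(chi)
    x[live] = front.rho[live] / base.rho[live]
    elfx = np.zeros_like(chi)
    ok = live & (x > X_FLOOR)
    chix = chi[ok] / (2.0 * x[ok])
    elfx[ok] = 1.0 / (1.0 + chix * chix)
    shape = grid.values.shape
    out = grid.with_values(elfx.reshape(shape), tag="elf_x",
                           variant="HOMO" if side == "nucleophilic"
                           else "LUMO")
    if not return_fukui:
        return out
    fuk = grid.with_values(front.rho.reshape(shape), tag="rho",
                           variant=front.variant)
    return out, fuk


# ---------------------------------------------------------------------------
# Gaussian cube I/O
# ---------------------------------------------------------------------------

def write_cube(field, molecule, path, comment="elfx scalar field"):
    """Write a Gaussian cube file (bohr, z-fastest ordering)."""
    nx, ny, nz = field.values.shape
    with open(path, "w") as fh:
        fh.write(f"{comment}\n{field.tag} variant={field.variant}\n")
        o = field.origin
        fh.write(f"{molecule.natoms:5d} {o[0]:12.6f} {o[1]:12.6f} "
                 f"{o[2]:12.6f}\n")
        for n, ax in zip((nx, ny, nz), field.axes):
            fh.write(f"{n:5d} {ax[0]:12.6f} {ax[1]:12.6f} {ax[2]:12.6f}\n")
        for z, r in zip(molecule.charges, molecule.coords):
            fh.write(f"{int(z):5d} {float(z):12.6f} {r[0]:12.6f} "
                     f"{r[1]:12.6f} {r[2]:12.6f}\n")
        flat = field.values.reshape(nx * ny, nz)
        for row in flat:
            for a in range(0, nz, 6):
                fh.write("".join(f"{v:14.6e}" for v in row[a:a + 6]) + "\n")


def read_cube(path):
    """Read a Gaussian cube file -> (ScalarFieldGrid, Molecule).

    Negative voxel counts (the angstrom header flag) are converted to
    bohr on read.
    """
    with open(path) as fh:
        lines = fh.readlines()
    try:
        parts = lines[2].split()
        natoms = int(parts[0])
        origin = np.array([float(v) for v in parts[1:4]])
    except (IndexError, ValueError) as exc:
        raise CubeParseError(path, 3, f"bad header line: {exc}")
    counts = []
    axes = []
    to_bohr = 1.0
    for i in range(3):
        try:
            parts = lines[3 + i].split()
            counts.append(int(parts[0]))
            axes.append([float(v) for v in parts[1:4]])
        except (IndexError, ValueError) as exc:
            raise CubeParseError(path, 4 + i, f"bad axis line: {exc}")
    counts = np.array(counts)
    axes = np.array(axes)
    if np.any(counts < 0):
        # negative counts flag angstrom units for origin and axes
        to_bohr = BOHR_PER_ANGSTROM
        counts = np.abs(counts)
    origin = origin * to_bohr
    axes = axes * to_bohr
    syms, charges, coords = [], [], []
    for i in range(abs(natoms)):
        try:
            parts = lines[6 + i].split()
            z = int(parts[0])
            syms.append(SYMBOLS.get(z, "X"))
            charges.append(z)
            coords.append([float(v) * to_bohr for v in parts[2:5]])
        except (IndexError, ValueError) as exc:
            raise CubeParseError(path, 7 + i, f"bad atom line: {exc}")
    vals = []
    for ln_no, ln in enumerate(lines[6 + abs(natoms):],
                               start=7 + abs(natoms)):
        for tok in ln.split():
            try:
                vals.append(float(tok))
            except ValueError:
                raise CubeParseError(path, ln_no, f"bad value {tok!r}")
    expected = int(np.prod(counts))
    if len(vals) != expected:
        raise CubeParseError(path, len(lines),
                             f"expected {expected} values, got {len(vals)}")
    values = np.array(vals).reshape(counts)
    molecule = Molecule(syms, np.array(coords), np.array(charges, float))
    return ScalarFieldGrid(origin, axes, values, tag="unknown"), molecule
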