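# elfx

Frontier-weighted electron-localization topology and monopole
dual-energy prediction of hydrogen-bonded complex geometries.

`elfx` answers a structural question with orbital-level ingredients:
given two closed-shell molecules, from which direction and in which
orientation do they prefer to meet?  It locates each molecule's
nucleophilic and electrophilic domains as attraction basins of the
frontier-weighted localization function

    ELF_x(r) = 1 / (1 + (chi(r) / 2x(r))^2),

where `chi` is the ELF kernel (Pauli kinetic-energy density over its
homogeneous-gas value) and `x = rho_HOMO/rho_N` (nucleophilic side) or
`rho_LUMO/rho_{N+1}` (electrophilic side).  Condensing the HOMO/LUMO
(Fukui) densities over those basins gives each molecule a set of point
monopoles `(r_Omega, N_Nu, N_El)`.  Two molecules are then scored by
the monopole Coulomb stabilization

    E_dual = sum_ab [2 N_Nu N_Nu - N_Nu N_El - N_El N_Nu]/r
           + sum q_A (N_El - N_Nu)/r + (A <-> B),

and a rigid-body scan of all polar/azimuthal placements of one molecule
around the other (centre-of-mass distance frozen, orientation optimized
per cell) maps `E_dual(theta, phi)`, whose minima predict the
hydrogen-bonded arrangements.  The flagship case is the guanine–
cytosine pair and its Watson–Crick geometry.

Everything runs offline: a built-in restricted Hartree–Fock backend
(Gaussian integrals + DIIS SCF) supplies wavefunctions for the built-in
geometries (water, ammonia, formaldehyde, water dimer, guanine,
cytosine, a reference Watson–Crick pair); Molden and AIM wfx files are
read, Gaussian cube files are read and written.

## Worked example

Water's reactive sites in three lines:

```python
from elfx.pipeline import site_model_for
from elfx.topology import sites_dataframe

model, diag = site_model_for("water", spacing=0.25, margin=5.0)
print(sites_dataframe(model, "water").round(3).to_string(index=False))
```

```
molecule          side      x      y      z  population_e source_field  grid_spacing
   water  nucleophilic  0.529  0.037  0.194         0.500        elf_x          0.25
   water  nucleophilic -0.529  0.037  0.194         0.500        elf_x          0.25
   water electrophilic  0.000  2.952 -0.072         0.049        elf_x          0.25
   water electrophilic  0.000 -3.014  0.060         0.044        elf_x          0.25
   water electrophilic  0.000  0.957 -0.599         0.257        elf_x          0.25
   water electrophilic  0.000 -1.022 -0.599         0.260        elf_x          0.25
   water electrophilic  0.000  0.037 -0.337         0.331        elf_x          0.25
   water electrophilic  0.000  0.037  0.716         0.042        elf_x          0.25
```

The two 0.50-electron nucleophilic sites are the out-of-plane lobes of
the oxygen lone-pair HOMO; the large electrophilic sites cap the O-H
bonds on the hydrogen side.  Coordinates are in angstrom, populations
in electrons of the unit-normalized Fukui densities.

The full base-pair protocol is one call (several minutes: two SCF
solutions, four fields on ~300k-node grids, a 19 x 37 x 576 orientation
scan):

```python
from elfx.pipeline import run_pipeline
man = run_pipeline({}, out_dir="gc_run")   # guanine fixed, cytosine mobile
for sp in man["stationary_points"]:
    print(sp["rank"], sp["theta"], sp["phi"],
          round(sp["edual_refined"], 3),
          round(sp["com_separation_angstrom"], 2),
          sp["n_hydrogen_bonds"])
```

```
0 70.0 350.0 -0.268 5.91 0
1 110.0 350.0 -0.225 7.95 0
2 70.0 20.0 -0.734 7.19 1
3 110.0 20.0 -0.749 7.2 3
```

The map's attractive basin sits on guanine's Watson–Crick face (the
reference WC direction is theta 90, phi 30); rigid refinement of the
global minimum relaxes the centre-of-mass separation to 5.9 angstrom,
and the neighbouring stationary points refine into structures held by
up to three N-H...N/O hydrogen bonds.  `gc_run/` holds the site tables
(CSV/JSON), the map (`edual_map.csv`), the stationary-point report,
XYZ structures and a checksummed manifest.  See `docs/methods.md` for
the model, every default, and what the desk-scale level of theory does
and does not reproduce.

There is also a CLI (`elfx fixtures`, `elfx field`, `elfx basins`,
`elfx dual`, `elfx scan`, `elfx run`) for shell use; each subcommand is
a thin wrapper over the functions above.

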