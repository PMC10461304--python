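# rotoshear

Rotational and conformational analysis of coarse-grained bead-model proteins
under shear flow.

A flexible molecule's laboratory-frame ("apparent") angular velocity, solved
from `J·ω = L`, mixes pure rotation with vibrations that carry angular
momentum.  `rotoshear` also determines the Eckart corotating frame — the
mass-weighted optimal superposition onto a reference structure, which
satisfies the Eckart condition `Σ mα cα × ρα = 0` — and from it the pure
angular velocity `Ω`, the per-bead split of vibrational velocity into
angular-momentum-free and angular parts, and the five-term kinetic-energy
decomposition (translational, rotational, two vibrational terms, Coriolis
coupling).  The package additionally provides:

- **`trajgen`** — synthetic trajectory generators with exact analytic
  velocities: rigid rotors, angular-momentum-free breathing, counter-twisting
  halves (vibrational angular momentum), sheared spherical bead lattices
  (the Einstein `ω = γ̇/2` limit is exact by construction), displacement
  composition with COM drift, and self-avoiding toy bead chains.
- **`eckart`** — lab and Eckart angular velocities, the velocity split
  `Δv = ṽ + u` with the exact identity `ω = Ω + Ω_vib`, Eckart-condition
  residuals, Coriolis-coupling perturbation checks, and finite-difference
  velocities for velocity-free inputs.
- **`energetics`** — the lab triple and Eckart quintuple of kinetic-energy
  terms, their machine-precision closures, the inter-frame bridging
  relations, and block-averaged time-series statistics.
- **`observables`** — gyration tensor / Rg, shear-normalized gyration
  diagonals, RMSD and RMSF with optional mass-weighted superposition.
- **`elastic_network`** — elastic networks built from a 0.5–0.9 nm distance
  window (k = 550 kJ mol⁻¹ nm⁻²) with irreversible bond breaking at
  `Rc = 1.35·r0`, harmonic energies, and break-event bookkeeping.
- **`shear_boundary`** — pure-function open-boundary formulas: the shear
  momentum-flux tensor, the buffer momentum balance and force distribution,
  DPD weight functions obeying `ω_D = (ω_R)²`, and the buffer feedback rule.
- **`interface`** — GRO (velocity columns) and extended-XYZ trajectory I/O,
  PDB structure reading, backbone-bead coarse-graining, TOML config, and the
  CLI.

Units are amu / nm / ps throughout (so energies are kJ/mol); angular
velocities are reported per ns in CSV outputs.

## CLI

```sh
# synthetic fixture with ground-truth sidecar (GRO + extended XYZ + JSON)
rotoshear generate --kind composite --n-beads 40 --omega3 5 --out fixture/

# lab + Eckart angular velocities and the kinetic-energy decomposition
rotoshear analyze --traj fixture/traj.extxyz --reference fixture/structure.gro \
    --default-mass 1 --out analysis/

# Rg / gyration tensor / RMSD / RMSF
rotoshear observables --traj fixture/traj.extxyz --out obs/

# breakable elastic network over a trajectory
rotoshear en --structure fixture/structure.gro --traj fixture/traj.extxyz \
    --multiplier 1.35 --out en/
```

`analyze` emits `angular_velocity.csv`, `energetics.csv`, and `summary.json`
(means, block standard errors, and fractional contributions under both
normalizations); `en` emits the network as JSON plus a GROMACS-style bond
table, break events, and per-frame intact counts.

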